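"""One-shot reproduction of the published reference results.

Recomputes, from the packaged six-drug table, the 4-h first-order
extrapolations of the rat removal rates, the four cross-species
regression fits with best-model selection, and the group-mean Kt/V
check, and compares each against the published reference value at a
stated tolerance.

Tolerances reflect how each reference value was produced: the 4-h
column was published per-animal-averaged (so the group-level formula
agrees only to ~0.1 percentage point for AMK and ~0.3 for VPA), and the
regression statistics were fitted on unrounded data (so table-rounded
inputs reproduce them to ±0.005). The Kt/V reference is a per-animal
mean whose raw inputs are unpublished; the group-mean recomputation is
only required to land inside the published mean ± SD band.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .crossspecies import (
    DialyzabilityModel,
    RangeConvention,
    load_fixture_tables,
)
from .metrics import DialysisSession, extrapolate_removal, kt_v_daugirdas

__all__ = ["Check", "reproduce_report", "REFERENCE_REGRESSION"]

# Published reference regression statistics for the six-drug table
# (adjusted r-squared and slope per equation, overall p for Eq 1).
REFERENCE_REGRESSION = {
    "adj_r2": {1: 0.812, 2: 0.936, 3: 0.749, 4: 0.751},
    "a1": {1: 1.264, 2: 1.227},
    "p_eq1": 0.009,
    "selected": 2,
}
_ADJ_R2_TOL = 0.005
_A1_TOL = 0.005
_P_TOL = 0.002

# Percentage-point tolerance of the 4-h reproduction per drug: the
# published column averaged per-animal extrapolations, which differs
# from the group-level formula in the last digit for AMK and VPA.
_EXTRAP_TOL = {"AMK": 0.1, "VPA": 0.3}
_EXTRAP_TOL_DEFAULT = 0.05

# Group-mean dialysis session (BUN 117 -> 106 mg/dL over 2 h; body
# weight 660.8 -> 658.4 g, ultrafiltration taken as the weight loss).
GROUP_MEAN_SESSION = DialysisSession(
    bun_pre=117.0,
    bun_post=106.0,
    duration=2.0,
    ultrafiltration_volume=660.8 - 658.4,
    body_weight_post=658.4,
    unit_system="g_g",
)
KTV_REFERENCE = (0.13, 0.06)  # published mean ± SD


@dataclass(frozen=True)
class Check:
    name: str
    computed: float
    expected: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.expected) <= self.tolerance

    def to_dict(self) -> dict:
        d = asdict(self)
        d["passed"] = self.passed
        return d


def reproduce_report(convention: RangeConvention | None = None) -> dict:
    """Run the full reproduction and return a structured report.

    Returns a dict with ``checks`` (list of :class:`Check` dicts),
    ``selected_equation``, ``fits`` (per-equation statistics) and
    ``all_passed``.
    """
    records = load_fixture_tables(convention=convention)
    checks: list[Check] = []

    for rec in records:
        if rec.removal_2h_rat == 0.0:
            computed = 0.0
        else:
            computed = extrapolate_removal(rec.removal_2h_rat, 2.0, 4.0)
        checks.append(
            Check(
                name=f"removal_4h_{rec.name}",
                computed=computed,
                expected=rec.removal_4h_rat,
                tolerance=_EXTRAP_TOL.get(rec.name, _EXTRAP_TOL_DEFAULT),
            )
        )

    results = DialyzabilityModel(records).fit()
    for eq, ref in REFERENCE_REGRESSION["adj_r2"].items():
        checks.append(
            Check(
                name=f"adj_r2_eq{eq}",
                computed=results.fits[eq].adj_r_squared,
                expected=ref,
                tolerance=_ADJ_R2_TOL,
            )
        )
    for eq, ref in REFERENCE_REGRESSION["a1"].items():
        checks.append(
            Check(
                name=f"a1_eq{eq}",
                computed=results.fits[eq].a1,
                expected=ref,
                tolerance=_A1_TOL,
            )
        )
    checks.append(
        Check(
            name="p_eq1",
            computed=results.fits[1].p_value,
            expected=REFERENCE_REGRESSION["p_eq1"],
            tolerance=_P_TOL,
        )
    )
    checks.append(
        Check(
            name="selected_equation",
            computed=float(results.selected_id),
            expected=float(REFERENCE_REGRESSION["selected"]),
            tolerance=0.0,
        )
    )

    ktv = kt_v_daugirdas(GROUP_MEAN_SESSION)
    mean, sd = KTV_REFERENCE
    checks.append(Check(name="kt_v_group_mean", computed=ktv, expected=mean, tolerance=sd))

    return {
        "checks": [c.to_dict() for c in checks],
        "selected_equation": results.selected_id,
        "fits": {
            eq: {
                "a0": f.a0,
                "a1": f.a1,
                "a2": f.a2,
                "r2": f.r_squared,
                "adj_r2": f.adj_r_squared,
                "p": f.p_value,
            }
            for eq, f in results.fits.items()
        },
        "all_passed": all(c.passed for c in checks),
    }
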