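"""Closed-form hemodialysis metrics.

Implements the arterial-venous dialyzer clearance with hematocrit
correction, the second-generation Daugirdas single-pool Kt/V, the
dialysate-recovery drug removal rate, its first-order extrapolation to a
longer session, and the ultrafiltration-based plasma protein binding rate
(PBR).

Conventions
-----------
* Hematocrit is a fraction in [0, 1), not a percent.
* Dialysis duration ``Td`` is in hours; the 0.008 urea-generation
  coefficient in the Daugirdas formula is per hour.
* Ultrafiltration volume and body weight must share a unit system (litres
  with kilograms, or millilitres with grams); the session record declares
  which, and the pair is validated.
* All user-facing rates are percent; fractions appear only internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "DialyzerSample",
    "DialysisSession",
    "RemovalMeasurement",
    "UltrafiltrationPair",
    "NegativeClearanceWarning",
    "hd_clearance",
    "kt_v_daugirdas",
    "drug_removal_rate",
    "extrapolate_removal",
    "protein_binding_rate",
    "UNIT_SYSTEMS",
]

#: Accepted (ultrafiltration volume, body weight) unit pairs. Within each
#: pair the ratio UFV/BW is dimensionless, which is all Kt/V needs.
UNIT_SYSTEMS = frozenset({"L_kg", "mL_g", "g_g", "kg_kg"})


class NegativeClearanceWarning(UserWarning):
    """Outlet concentration exceeded inlet concentration (Cv > Ca)."""


@dataclass(frozen=True)
class DialyzerSample:
    """Paired inlet/outlet concentrations across the dialyzer.

    Parameters
    ----------
    c_inlet : float
        Solute concentration at the dialyzer inlet (e.g. mg/dL). The
        arterial side in an A-V clearance measurement.
    c_outlet : float
        Concentration at the dialyzer outlet, already corrected for the
        hemoconcentration/dilution produced by ultrafiltration (the raw
        correction is an assay-side step and is not modelled here).
    blood_flow : float
        Blood flow Q_B through the dialyzer, mL/min.
    hematocrit : float
        Red-cell volume fraction of blood, in [0, 1]. The degenerate
        value 1 (zero plasma flow) gives zero clearance.
    """

    c_inlet: float
    c_outlet: float
    blood_flow: float
    hematocrit: float = 0.0

    def __post_init__(self) -> None:
        if self.c_inlet < 0 or self.c_outlet < 0:
            raise ValueError("concentrations must be non-negative")
        if self.blood_flow <= 0:
            raise ValueError("blood_flow must be positive")
        if not 0.0 <= self.hematocrit <= 1.0:
            raise ValueError("hematocrit must be a fraction in [0, 1]")


@dataclass(frozen=True)
class DialysisSession:
    """One dialysis run: the inputs of the Daugirdas Kt/V formula.

    ``bun_post > bun_pre`` is physically possible (urea generation
    outpacing removal) and is kept, not rejected; Kt/V is then negative.
    """

    bun_pre: float
    bun_post: float
    duration: float  # hours
    ultrafiltration_volume: float
    body_weight_post: float
    unit_system: str = "L_kg"

    def __post_init__(self) -> None:
        if self.bun_pre <= 0:
            raise ValueError("bun_pre must be positive")
        if self.bun_post < 0:
            raise ValueError("bun_post must be non-negative")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.ultrafiltration_volume < 0:
            raise ValueError("ultrafiltration_volume must be non-negative")
        if self.body_weight_post <= 0:
            raise ValueError("body_weight_post must be positive")
        if self.unit_system not in UNIT_SYSTEMS:
            raise ValueError(
                f"unit_system {self.unit_system!r} not one of {sorted(UNIT_SYSTEMS)}"
            )

    @property
    def urea_ratio(self) -> float:
        """R = BUN_post / BUN_pre."""
        return self.bun_post / self.bun_pre


@dataclass(frozen=True)
class RemovalMeasurement:
    """Recovered dialysate drug mass relative to the administered dose."""

    dialysate_concentration: float  # mg/mL
    dialysate_volume: float  # mL
    dose: float  # mg
    session_duration: float = 2.0  # hours

    def __post_init__(self) -> None:
        if self.dialysate_concentration < 0 or self.dialysate_volume < 0:
            raise ValueError("dialysate concentration and volume must be non-negative")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.session_duration < 0:
            raise ValueError("session_duration must be non-negative")


@dataclass(frozen=True)
class UltrafiltrationPair:
    """Serum total (C_T) and ultrafiltrate (C_F) drug concentrations."""

    c_total: float
    c_filtrate: float

    def __post_init__(self) -> None:
        if self.c_total <= 0:
            raise ValueError("c_total must be positive")
        if self.c_filtrate < 0:
            raise ValueError("c_filtrate must be non-negative")
        if self.c_filtrate > self.c_total:
            raise ValueError(
                "c_filtrate exceeds c_total: negative apparent binding "
                "(assay or filtration artifact)"
            )


def hd_clearance(sample: DialyzerSample) -> float:
    """Dialyzer clearance from the arterial-venous concentration drop.

    CL = (Ca - Cv)/Ca * Q_B * (1 - Hct), in mL/min. The (1 - Hct) factor
    converts blood flow to the plasma flow actually cleared.

    A negative result (outlet above inlet) is returned with a
    :class:`NegativeClearanceWarning` rather than raised: sampling noise
    can produce Cv > Ca in a near-zero-extraction measurement.
    """
    if sample.c_inlet == 0:
        raise ZeroDivisionError(
            "c_inlet is zero: extraction ratio undefined"
        )
    extraction = (sample.c_inlet - sample.c_outlet) / sample.c_inlet
    if extraction < 0:
        warnings.warn(
            f"outlet concentration {sample.c_outlet} exceeds inlet "
            f"{sample.c_inlet}; clearance is negative",
            NegativeClearanceWarning,
            stacklevel=2,
        )
    return extraction * sample.blood_flow * (1.0 - sample.hematocrit)


def kt_v_daugirdas(session: DialysisSession) -> float:
    """Single-pool Kt/V by the second-generation Daugirdas formula.

    Kt/V = -ln(R - 0.008*Td) + (4 - 3.5*R) * UFV/BW,

    with R = BUN_post/BUN_pre, Td the session length in hours, and
    UFV/BW the ultrafiltration volume over post-dialysis body weight in a
    consistent unit pair. Dimensionless.
    """
    r = session.urea_ratio
    log_arg = r - 0.008 * session.duration
    if log_arg <= 0:
        raise ValueError(
            f"Daugirdas log argument non-positive: R={r:.4g}, "
            f"Td={session.duration:.4g} h gives R - 0.008*Td = {log_arg:.4g}"
        )
    ufv_over_bw = session.ultrafiltration_volume / session.body_weight_post
    return -math.log(log_arg) + (4.0 - 3.5 * r) * ufv_over_bw


def drug_removal_rate(m: RemovalMeasurement) -> float:
    """Percent of the administered dose recovered in dialysate.

    removal (%) = 100 * (dialysate concentration * dialysate volume) / dose.

    A result above 100% means more drug was recovered than was given and
    is rejected as a mass-balance violation.
    """
    recovered_mass = m.dialysate_concentration * m.dialysate_volume
    rate = 100.0 * recovered_mass / m.dose
    if rate > 100.0:
        raise ValueError(
            f"recovered mass {recovered_mass:.6g} mg exceeds dose "
            f"{m.dose:.6g} mg (removal {rate:.4g}% > 100%): mass-balance violation"
        )
    return rate


def extrapolate_removal(
    rate_measured: float, t_measured: float, t_target: float = 4.0
) -> float:
    """Extrapolate a removal rate to another session length, first order.

    Treating removal as a mono-exponential depletion of removable drug,
    the surviving fraction after time t is (1 - R/100)^(t/t_measured), so

    R(t_target) = 100 * (1 - (1 - R/100)^(t_target/t_measured)).

    The canonical use is extrapolating a 2-h animal session to the 4-h
    clinical session length (``t_target`` defaults to 4 h). The map is
    monotone and concave in ``t_target``, and is its own inverse under
    swapping of the two times.
    """
    if not 0.0 <= rate_measured < 100.0:
        raise ValueError(
            f"rate_measured must be in [0, 100); got {rate_measured!r} "
            "(100% leaves no surviving fraction to extrapolate)"
        )
    if t_measured <= 0:
        raise ValueError("t_measured must be positive")
    if t_target < 0:
        raise ValueError("t_target must be non-negative")
    # expm1/log1p formulation keeps precision when the surviving
    # fraction is close to 0 or 1
    return 100.0 * -math.expm1(
        (t_target / t_measured) * math.log1p(-rate_measured / 100.0)
    )


def protein_binding_rate(u: UltrafiltrationPair) -> float:
    """Plasma protein binding rate from an ultrafiltration experiment.

    PBR (%) = 100 * (C_T - C_F)/C_T, where C_T is the total serum
    concentration and C_F the free concentration in the ultrafiltrate.
    The unbound percentage is 100 - PBR.
    """
    return 100.0 * (u.c_total - u.c_filtrate) / u.c_total
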