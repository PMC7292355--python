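"""Cross-species prediction of human drug dialyzability from rat data.

Four candidate linear predictors of the human 4-h dialysis removal rate
(DD_human, percent of dose) are built from the rat removal rate and the
species ratios of plasma protein binding and volume of distribution:

    Eq 1:  DD_human = a0 + a1 * R_rat
    Eq 2:  DD_human = a0 + a1 * R_rat * fu_human/fu_rat
    Eq 3:  DD_human = a0 + a1 * R_rat + a2 * Vd_human/Vd_rat
    Eq 4:  DD_human = a0 + a1 * R_rat + a2 * (fu/Vd)_human/(fu/Vd)_rat

where R_rat is the rat 4-h removal rate (percent) and fu = (100 - PBR)
is the unbound percentage. Each is fitted by ordinary least squares and
the winner is the equation with the largest adjusted r-squared; in the
packaged six-drug table that is Eq 2, the protein-binding-adjusted
predictor.

Literature human values are often printed as ranges; a
:class:`RangeConvention` resolves each range to a point. The default
(DD_human at the upper bound, Vd_human at the lower bound) is the
convention that reproduces the published regression statistics from the
printed tables, and is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DrugRecord",
    "RangeConvention",
    "RegressionFit",
    "DialyzabilityModel",
    "DialyzabilityResults",
    "EQUATION_IDS",
    "unbound_ratio",
    "vd_ratio",
    "build_design",
    "fit_ols",
    "fit_all_equations",
    "select_best_model",
    "predict_dd_human",
    "load_fixture_tables",
    "records_from_dataframe",
]

EQUATION_IDS = (1, 2, 3, 4)

_EQUATION_LABELS = {
    1: "DD_human ~ removal_rat",
    2: "DD_human ~ removal_rat * fu_ratio",
    3: "DD_human ~ removal_rat + Vd_ratio",
    4: "DD_human ~ removal_rat + (fu/Vd)_ratio",
}

Bound = Literal["upper", "mid", "lower"]


def _resolve(lo: float, hi: float, how: Bound) -> float:
    if how == "upper":
        return hi
    if how == "lower":
        return lo
    if how == "mid":
        return 0.5 * (lo + hi)
    raise ValueError(f"unknown range convention {how!r}")


@dataclass(frozen=True)
class RangeConvention:
    """How printed human ranges are collapsed to point values.

    dd : bound used for the human dialyzability range.
    vd : bound used for the human volume-of-distribution range.
    """

    dd: Bound = "upper"
    vd: Bound = "lower"


@dataclass(frozen=True)
class DrugRecord:
    """Per-drug cross-species parameters.

    Removal rates and PBR in percent, Vd in L/kg. ``dd_human`` and
    ``vd_human`` are resolved point values; the printed ranges they came
    from are kept alongside.
    """

    name: str
    removal_2h_rat: float
    removal_4h_rat: float
    dd_human: float
    dd_human_range: tuple[float, float]
    pbr_rat: float
    pbr_human: float
    vd_rat: float
    vd_human: float
    vd_human_range: tuple[float, float]

    def __post_init__(self) -> None:
        for label, v in [
            ("removal_2h_rat", self.removal_2h_rat),
            ("removal_4h_rat", self.removal_4h_rat),
            ("dd_human", self.dd_human),
            ("pbr_rat", self.pbr_rat),
            ("pbr_human", self.pbr_human),
        ]:
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{self.name}: {label}={v} outside [0, 100]%")
        if self.vd_rat <= 0 or self.vd_human <= 0:
            raise ValueError(f"{self.name}: volumes of distribution must be positive")
        lo, hi = self.dd_human_range
        if not lo <= self.dd_human <= hi:
            raise ValueError(f"{self.name}: dd_human outside its printed range")
        lo, hi = self.vd_human_range
        if not lo <= self.vd_human <= hi:
            raise ValueError(f"{self.name}: vd_human outside its printed range")


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of one prediction equation."""

    equation_id: int
    a0: float
    a1: float
    a2: float | None
    r_squared: float
    adj_r_squared: float
    p_value: float
    n: int
    coef_se: tuple[float, ...] = ()
    coef_p: tuple[float, ...] = ()

    @property
    def n_predictors(self) -> int:
        return 1 if self.a2 is None else 2

    @property
    def coefficients(self) -> tuple[float, ...]:
        if self.a2 is None:
            return (self.a0, self.a1)
        return (self.a0, self.a1, self.a2)


def unbound_ratio(record: DrugRecord) -> float:
    """Human/rat ratio of unbound drug percentage, (100-PBR_h)/(100-PBR_r)."""
    if record.pbr_rat >= 100.0:
        raise ZeroDivisionError(
            f"{record.name}: rat PBR is 100%, unbound fraction is zero"
        )
    return (100.0 - record.pbr_human) / (100.0 - record.pbr_rat)


def vd_ratio(record: DrugRecord) -> float:
    """Human/rat volume-of-distribution ratio from resolved point values."""
    if record.vd_rat <= 0 or record.vd_human <= 0:
        raise ValueError(f"{record.name}: non-positive volume of distribution")
    return record.vd_human / record.vd_rat


def _predictors(record: DrugRecord, equation_id: int) -> tuple[float, ...]:
    r = record.removal_4h_rat
    if equation_id == 1:
        return (r,)
    if equation_id == 2:
        return (r * unbound_ratio(record),)
    if equation_id == 3:
        return (r, vd_ratio(record))
    if equation_id == 4:
        return (r, unbound_ratio(record) / vd_ratio(record))
    raise ValueError(f"equation_id must be in {EQUATION_IDS}, got {equation_id!r}")


def build_design(
    records: Sequence[DrugRecord], equation_id: int
) -> tuple[np.ndarray, np.ndarray]:
    """(y, X) for one equation: response DD_human, predictors per equation.

    X has no intercept column; the fitter adds it.
    """
    n_pred = 1 if equation_id in (1, 2) else 2
    if len(records) < n_pred + 3:
        raise ValueError(
            f"equation {equation_id} needs at least {n_pred + 3} drugs "
            f"(got {len(records)}) for a meaningful adjusted r-squared"
        )
    y = np.array([rec.dd_human for rec in records], dtype=float)
    X = np.array([_predictors(rec, equation_id) for rec in records], dtype=float)
    return y, X


def fit_ols(y: np.ndarray, X: np.ndarray, equation_id: int) -> RegressionFit:
    """Ordinary least squares with intercept; overall F-test p-value."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    design = sm.add_constant(X, has_constant="raise")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("singular design: duplicated or constant predictor")
    res = sm.OLS(y, design).fit()
    params = res.params
    return RegressionFit(
        equation_id=equation_id,
        a0=float(params[0]),
        a1=float(params[1]),
        a2=float(params[2]) if X.shape[1] == 2 else None,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        p_value=float(res.f_pvalue),
        n=int(res.nobs),
        coef_se=tuple(float(s) for s in res.bse),
        coef_p=tuple(float(p) for p in res.pvalues),
    )


def fit_all_equations(records: Sequence[DrugRecord]) -> dict[int, RegressionFit]:
    """Fit Eqs 1-4 on the same drug set."""
    return {
        eq: fit_ols(*build_design(records, eq), equation_id=eq) for eq in EQUATION_IDS
    }


def select_best_model(fits: Iterable[RegressionFit]) -> int:
    """Equation id with maximal adjusted r-squared; ties go to the lowest id."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits, key=lambda f: (-f.adj_r_squared, f.equation_id)).equation_id


def predict_dd_human(
    fit: RegressionFit, record: DrugRecord, clip: bool = False
) -> float:
    """Evaluate a fitted equation on one drug.

    The raw linear-predictor value is returned by default; ``clip=True``
    bounds it to [0, 100] for reporting.
    """
    x = _predictors(record, fit.equation_id)
    if len(x) != fit.n_predictors:
        raise ValueError(
            f"fit for equation {fit.equation_id} expects {fit.n_predictors} "
            f"predictors, design supplies {len(x)}"
        )
    value = fit.a0 + fit.a1 * x[0]
    if fit.a2 is not None:
        value += fit.a2 * x[1]
    if clip:
        return min(100.0, max(0.0, value))
    return value


# ---------------------------------------------------------------------------
# Model / Results interface


class DialyzabilityModel:
    """Cross-species dialyzability regression over a set of drugs.

    Construct from :class:`DrugRecord` objects (or a data frame via
    :meth:`from_dataframe`); :meth:`fit` runs OLS for one or all four
    candidate equations and returns a :class:`DialyzabilityResults`.
    """

    def __init__(self, records: Sequence[DrugRecord]):
        names = [r.name for r in records]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate drug names: {dup}")
        self.records = list(records)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, convention: RangeConvention | None = None
    ) -> "DialyzabilityModel":
        return cls(records_from_dataframe(df, convention=convention))

    def fit(self, equation_id: int | None = None) -> "DialyzabilityResults":
        """Fit one equation, or all four (default) with best-model selection."""
        if equation_id is None:
            fits = fit_all_equations(self.records)
        else:
            y, X = build_design(self.records, equation_id)
            fits = {equation_id: fit_ols(y, X, equation_id)}
        return DialyzabilityResults(self, fits)


class DialyzabilityResults:
    """Fitted prediction equations with selection and prediction."""

    def __init__(self, model: DialyzabilityModel, fits: dict[int, RegressionFit]):
        self.model = model
        self.fits = fits
        self.selected_id = select_best_model(fits.values())

    @property
    def best_fit(self) -> RegressionFit:
        return self.fits[self.selected_id]

    def predict(
        self, record: DrugRecord, equation_id: int | None = None, clip: bool = False
    ) -> float:
        fit = self.fits[equation_id if equation_id is not None else self.selected_id]
        return predict_dd_human(fit, record, clip=clip)

    def to_frame(self) -> pd.DataFrame:
        """One row per equation: coefficients, r², adjusted r², overall p."""
        rows = []
        for eq in sorted(self.fits):
            f = self.fits[eq]
            rows.append(
                {
                    "equation": eq,
                    "a0": f.a0,
                    "a1": f.a1,
                    "a2": f.a2 if f.a2 is not None else math.nan,
                    "r2": f.r_squared,
                    "adj_r2": f.adj_r_squared,
                    "p": f.p_value,
                    "n": f.n,
                    "selected": eq == self.selected_id,
                }
            )
        return pd.DataFrame(rows)

    def scatter_frame(self) -> pd.DataFrame:
        """Observed DD_human against each equation's first predictor, per drug."""
        rows = []
        for eq, f in sorted(self.fits.items()):
            for rec in self.model.records:
                x = _predictors(rec, eq)
                rows.append(
                    {
                        "equation": eq,
                        "drug": rec.name,
                        "x1": x[0],
                        "x2": x[1] if len(x) == 2 else math.nan,
                        "dd_human_observed": rec.dd_human,
                        "dd_human_fitted": predict_dd_human(f, rec),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Cross-species dialyzability regressions "
            f"(n = {len(self.model.records)} drugs)",
            "",
            f"{'Eq':>2}  {'model':<40} {'a0':>9} {'a1':>8} {'a2':>9} "
            f"{'r2':>7} {'adj r2':>7} {'p':>8}",
        ]
        for eq in sorted(self.fits):
            f = self.fits[eq]
            a2 = f"{f.a2:9.4f}" if f.a2 is not None else f"{'-':>9}"
            mark = " *" if eq == self.selected_id else "  "
            lines.append(
                f"{eq:>2}{mark}{_EQUATION_LABELS[eq]:<40} {f.a0:9.4f} "
                f"{f.a1:8.4f} {a2} {f.r_squared:7.4f} {f.adj_r_squared:7.4f} "
                f"{f.p_value:8.4f}"
            )
        lines.append("")
        lines.append(
            f"* selected by maximal adjusted r2: Eq {self.selected_id} "
            f"({_EQUATION_LABELS[self.selected_id]})"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Fixture table


def records_from_dataframe(
    df: pd.DataFrame, convention: RangeConvention | None = None
) -> list[DrugRecord]:
    """Build records from a table with the packaged-fixture column layout.

    Required columns: drug, removal_2h, removal_4h, dd_human_lo,
    dd_human_hi, pbr_rat, pbr_human, vd_rat, vd_human_lo, vd_human_hi.
    Point values are encoded as lo == hi.
    """
    conv = convention or RangeConvention()
    required = {
        "drug", "removal_2h", "removal_4h", "dd_human_lo", "dd_human_hi",
        "pbr_rat", "pbr_human", "vd_rat", "vd_human_lo", "vd_human_hi",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drug table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        for col in required - {"drug"}:
            if pd.isna(getattr(row, col)):
                raise ValueError(f"drug {row.drug}: missing field {col}")
        dd_range = (float(row.dd_human_lo), float(row.dd_human_hi))
        vd_range = (float(row.vd_human_lo), float(row.vd_human_hi))
        records.append(
            DrugRecord(
                name=str(row.drug),
                removal_2h_rat=float(row.removal_2h),
                removal_4h_rat=float(row.removal_4h),
                dd_human=_resolve(*dd_range, conv.dd),
                dd_human_range=dd_range,
                pbr_rat=float(row.pbr_rat),
                pbr_human=float(row.pbr_human),
                vd_rat=float(row.vd_rat),
                vd_human=_resolve(*vd_range, conv.vd),
                vd_human_range=vd_range,
            )
        )
    return records


def load_fixture_tables(
    convention: RangeConvention | None = None,
) -> list[DrugRecord]:
    """The six packaged drugs (AMK, AP, VCM, DRPM, VPA, APAP).

    Removal rates are the rat 2-h measurements and 4-h first-order
    estimates; human dialyzability and Vd ranges are literature values.
    Aprindine (AP) was not detected in dialysate and is encoded as 0%
    removal in both species.
    """
    with resources.files("dialyzability.data").joinpath("drug_tables.csv").open() as fh:
        df = pd.read_csv(fh)
    return records_from_dataframe(df, convention=convention)
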