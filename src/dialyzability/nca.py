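"""Non-compartmental moment analysis of plasma concentration-time data.

AUC and AUMC by the trapezoid rule over the observed range plus the
standard log-linear tail extrapolation, mean residence time with the
constant-rate-infusion correction, total clearance, and steady-state
volume of distribution per kilogram.

Moment identities used (bolus; T_inf = 0):

    CL   = Dose / AUC(0-inf)
    MRT  = AUMC/AUC - T_inf/2
    V_ss = CL * MRT = Dose * AUMC/AUC^2 - Dose * T_inf / (2 * AUC)

The trapezoid variant defaults to linear up/down on the observed grid;
a log-down ("log-trapezoid") option is available for steeply declining
segments. The terminal slope lambda_z is an ordinary least-squares fit of
ln(C) on t over the last ``n_terminal`` positive-concentration points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConcentrationTimeSeries", "NcaResult", "auc_aumc", "vd_ss", "run_nca"]


@dataclass(frozen=True)
class ConcentrationTimeSeries:
    """Sampled plasma curve for one subject and drug.

    times in hours (strictly increasing, >= 3 points), concentrations in
    mg/L, dose in mg, infusion_duration in hours (0 for an i.v. bolus),
    body_weight in kg (used only for the per-kg V_ss).
    """

    times: np.ndarray
    concentrations: np.ndarray
    dose: float
    infusion_duration: float = 0.0
    body_weight: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if t.size < 3:
            raise ValueError("need at least 3 sampling points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.infusion_duration < 0:
            raise ValueError("infusion_duration must be non-negative")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")


@dataclass(frozen=True)
class NcaResult:
    auc_0_inf: float  # mg*h/L
    aumc_0_inf: float  # mg*h^2/L
    mrt: float  # h
    cl_total: float  # L/h
    vd_ss: float  # L/kg
    terminal_slope: float  # 1/h (lambda_z, positive)
    n_terminal_points: int
    auc_extrapolated_fraction: float

    def to_dict(self) -> dict:
        return {
            "auc_0_inf": self.auc_0_inf,
            "aumc_0_inf": self.aumc_0_inf,
            "mrt": self.mrt,
            "cl_total": self.cl_total,
            "vd_ss": self.vd_ss,
            "terminal_slope": self.terminal_slope,
            "n_terminal_points": self.n_terminal_points,
            "auc_extrapolated_fraction": self.auc_extrapolated_fraction,
        }


def _trapezoid_moments(t: np.ndarray, c: np.ndarray, method: str) -> tuple[float, float]:
    """AUC and AUMC over the observed grid."""
    if method == "linear":
        auc = float(np.trapezoid(c, t))
        aumc = float(np.trapezoid(c * t, t))
        return auc, aumc
    if method != "log":
        raise ValueError("method must be 'linear' or 'log'")
    # Log-trapezoid on declining segments with both endpoints positive;
    # linear elsewhere. Exact for mono-exponential decline within a segment.
    auc = aumc = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c1 > c2 > 0:
            k = np.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            # integral of t*C over the segment for C = c1*exp(-k(t-t1))
            aumc += (t[i] * c1 - t[i + 1] * c2) / k + (c1 - c2) / k**2
        else:
            auc += 0.5 * (c1 + c2) * dt
            aumc += 0.5 * (t[i] * c1 + t[i + 1] * c2) * dt
    return float(auc), float(aumc)


def _terminal_slope(t: np.ndarray, c: np.ndarray, n_terminal: int) -> tuple[float, int]:
    """lambda_z by OLS on ln(C) over the last ``n_terminal`` positive points."""
    pos = c > 0
    if pos.sum() < 2:
        raise ValueError("need at least 2 positive concentrations for the terminal fit")
    idx = np.flatnonzero(pos)[-n_terminal:]
    if idx.size < 2:
        raise ValueError("fewer than 2 positive points available for the terminal fit")
    slope, _ = np.polyfit(t[idx], np.log(c[idx]), 1)
    lam = -float(slope)
    if lam <= 0:
        raise ValueError(
            f"terminal slope non-positive (lambda_z={lam:.4g}/h): "
            "curve is not declining; cannot extrapolate to infinity"
        )
    return lam, int(idx.size)


def auc_aumc(
    series: ConcentrationTimeSeries,
    n_terminal: int = 3,
    method: str = "linear",
) -> tuple[float, float, float]:
    """AUC(0-inf), AUMC(0-inf) and the terminal slope lambda_z.

    Observed-range moments by the trapezoid rule plus the tail terms

        AUC_tail  = C_last / lambda_z
        AUMC_tail = t_last * C_last / lambda_z + C_last / lambda_z^2.

    A zero final concentration gives a zero tail (extrapolated fraction 0)
    and the terminal slope is fitted on the trailing positive points.
    """
    t, c = series.times, series.concentrations
    auc_obs, aumc_obs = _trapezoid_moments(t, c, method)
    lam, _ = _terminal_slope(t, c, n_terminal)
    c_last = c[-1]
    t_last = t[-1]
    auc = auc_obs + c_last / lam
    aumc = aumc_obs + t_last * c_last / lam + c_last / lam**2
    return auc, aumc, lam


def run_nca(
    series: ConcentrationTimeSeries,
    n_terminal: int = 3,
    method: str = "linear",
) -> NcaResult:
    """Full moment analysis of one concentration-time series."""
    t, c = series.times, series.concentrations
    auc_obs, _ = _trapezoid_moments(t, c, method)
    lam, n_used = _terminal_slope(t, c, n_terminal)
    auc, aumc, _ = auc_aumc(series, n_terminal=n_terminal, method=method)
    mrt = aumc / auc - series.infusion_duration / 2.0
    cl = series.dose / auc
    vss = cl * mrt / series.body_weight
    return NcaResult(
        auc_0_inf=auc,
        aumc_0_inf=aumc,
        mrt=mrt,
        cl_total=cl,
        vd_ss=vss,
        terminal_slope=lam,
        n_terminal_points=n_used,
        auc_extrapolated_fraction=1.0 - auc_obs / auc,
    )


def vd_ss(
    series: ConcentrationTimeSeries,
    n_terminal: int = 3,
    method: str = "linear",
) -> float:
    """Steady-state volume of distribution, L/kg.

    V_ss = Dose * AUMC/AUC^2 - Dose * T_inf/(2*AUC), divided by body
    weight; for a bolus this is the plain Dose*AUMC/AUC^2.
    """
    return run_nca(series, n_terminal=n_terminal, method=method).vd_ss
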