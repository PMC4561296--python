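"""Real-time cell analysis (impedance) growth metrics.

The xCELLigence RTCA system reports a dimensionless cell index (CI)
proportional to electrode surface occupancy.  This module implements the
standard derived measures: CI normalized to the time of treatment (CI(t) /
CI(t0), equal to 1 at t0 by construction), ordinary least-squares slopes over
a chosen post-treatment window, four-parameter logistic (4PL) dose-response
fits, and the time-dependent IC50 series with its arithmetic (or geometric)
mean.  IC50s reported are *relative*: the dose at the midpoint between the
fitted top and bottom asymptotes.

Input tables are long-format CSV (time_h, well, ci) plus a per-well metadata
CSV (well, cell_line, treatment, dose_M, glucose_g_per_L, t0_h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GrowthCurve",
    "DoseResponse",
    "NormalizationError",
    "WindowError",
    "normalize_ci",
    "slope",
    "fit_4pl",
    "four_pl",
    "time_dependent_ic50",
    "average_replicates",
    "read_curves_csv",
]


class NormalizationError(ValueError):
    """Raised when CI at treatment time is nonpositive."""


class WindowError(ValueError):
    """Raised when a slope window contains fewer than two samples."""


@dataclass(frozen=True)
class GrowthCurve:
    """A single well's cell-index trace.

    ``times`` (hours) must be strictly increasing and the same length as
    ``ci``; ``t0`` is the treatment time and must lie inside the sampled
    range.  Negative CI values (possible before attachment) are flagged with
    a warning but kept.
    """

    times: np.ndarray
    ci: np.ndarray
    well: str = ""
    condition: dict = field(default_factory=dict)
    t0: float = 0.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ci = np.asarray(self.ci, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ci", ci)
        if times.ndim != 1 or times.shape != ci.shape or times.size < 2:
            raise ValueError("times and ci must be 1-D arrays of equal length >= 2")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (times[0] <= self.t0 <= times[-1]):
            raise ValueError(f"t0={self.t0} outside sampled range [{times[0]}, {times[-1]}]")
        if not np.all(np.isfinite(ci)):
            raise ValueError("ci values must be finite")
        if np.any(ci[times >= self.t0] < 0):
            warnings.warn(f"well {self.well!r}: negative cell index after treatment time")

    def ci_at(self, t: float) -> float:
        """CI at time t; linear interpolation between bracketing samples."""
        if not (self.times[0] <= t <= self.times[-1]):
            raise ValueError(f"time {t} outside sampled range")
        return float(np.interp(t, self.times, self.ci))


def normalize_ci(curve: GrowthCurve) -> GrowthCurve:
    """Divide the whole trace by CI at treatment time t0.

    The normalized value at t0 is exactly 1; normalizing an already-normalized
    curve with the same t0 is the identity.  If t0 falls between samples the
    divisor is linearly interpolated.
    """
    c0 = curve.ci_at(curve.t0)
    if c0 <= 0:
        raise NormalizationError(f"well {curve.well!r}: CI at t0 is {c0}, cannot normalize")
    return replace(curve, ci=curve.ci / c0)


def slope(curve: GrowthCurve, window: tuple[float, float]) -> float:
    """OLS slope of CI versus time (CI units per hour) inside a closed window."""
    t_start, t_end = window
    mask = (curve.times >= t_start) & (curve.times <= t_end)
    if mask.sum() < 2:
        raise WindowError(f"window [{t_start}, {t_end}] contains {int(mask.sum())} samples, need >= 2")
    t, y = curve.times[mask], curve.ci[mask]
    if np.ptp(y) == 0.0:
        return 0.0
    return float(stats.linregress(t, y).slope)


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------


def four_pl(dose: np.ndarray, bottom: float, top: float, log10_ic50: float, hill: float) -> np.ndarray:
    """4PL response: bottom + (top - bottom) / (1 + (d/ic50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (np.log10(dose) - log10_ic50)))


@dataclass
class DoseResponse:
    """A per-dose response series with its 4PL fit.

    ``ic50`` is the relative IC50 (midpoint of the fitted asymptotes) in the
    same molar units as ``doses``; after canonicalization bottom <= top, with
    the hill sign carrying the response direction.  ``extrapolated`` marks an
    IC50 outside the tested dose range.
    """

    doses: np.ndarray
    responses: np.ndarray
    bottom: float = np.nan
    top: float = np.nan
    hill: float = np.nan
    ic50: float = np.nan
    fit_ok: bool = False
    extrapolated: bool = False
    residual_norm: float = np.nan
    message: str = ""


def fit_4pl(doses: np.ndarray, responses: np.ndarray) -> DoseResponse:
    """Fit a four-parameter logistic on log-dose by nonlinear least squares.

    Initialization is deterministic, from data quantiles (asymptotes from the
    response extremes, IC50 from the median log dose, hill sign from the
    dose-response rank correlation).  Non-convergence or a flat response never
    raises: the result comes back with ``fit_ok=False`` and a diagnostic
    message.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape or doses.ndim != 1:
        raise ValueError("doses and responses must be 1-D arrays of equal length")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive (molar)")
    order = np.argsort(doses)
    doses, responses = doses[order], responses[order]
    n_distinct = np.unique(doses).size
    if n_distinct < 4:
        warnings.warn(f"only {n_distinct} distinct doses; 4PL fit is under-determined")
    span = np.log10(doses.max() / doses.min()) if n_distinct > 1 else 0.0
    if span < 1.0:
        warnings.warn(f"dose range spans {span:.2f} decades; >= 1 recommended")

    dr = DoseResponse(doses=doses, responses=responses)
    if np.ptp(responses) == 0.0:
        dr.bottom = dr.top = float(responses[0])
        dr.hill = 0.0
        dr.message = "flat responses; ic50 undefined"
        return dr
    if doses.size < 4:
        dr.message = f"{doses.size} points cannot constrain 4 parameters"
        return dr

    rho = stats.spearmanr(doses, responses).statistic
    hill0 = 1.0 if rho < 0 else -1.0  # response falls with dose -> positive hill
    p0 = (
        float(np.quantile(responses, 0.05)),
        float(np.quantile(responses, 0.95)),
        float(np.median(np.log10(doses))),
        hill0,
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(four_pl, doses, responses, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        dr.message = f"4PL fit did not converge: {exc}"
        return dr

    bottom, top, log_ic50, hill = (float(v) for v in popt)
    if bottom > top:  # canonical form: bottom <= top, direction in the hill sign
        bottom, top, hill = top, bottom, -hill
    ic50 = 10.0 ** log_ic50
    resid = responses - four_pl(doses, *popt)
    dr.bottom, dr.top, dr.hill, dr.ic50 = bottom, top, hill, ic50
    dr.residual_norm = float(np.linalg.norm(resid))
    dr.extrapolated = not (doses.min() < ic50 < doses.max())
    # an IC50 outside the tested range is a flagged extrapolation, not a usable fit
    dr.fit_ok = bool(
        np.isfinite(ic50) and ic50 > 0 and abs(top - bottom) > 1e-12 and not dr.extrapolated
    )
    if dr.extrapolated:
        dr.message = "ic50 outside tested dose range (extrapolated)"
    return dr


# ---------------------------------------------------------------------------
# time-dependent IC50
# ---------------------------------------------------------------------------


def average_replicates(curves: list[GrowthCurve], by: str = "dose_M") -> list[GrowthCurve]:
    """Average replicate wells per condition after normalization.

    Curves must share a time grid.  The returned curves carry
    ``condition['sem']`` arrays (standard error of the mean across wells).
    """
    groups: dict[float, list[GrowthCurve]] = {}
    for c in curves:
        groups.setdefault(c.condition.get(by), []).append(c)
    out = []
    for key in sorted(groups, key=lambda v: (v is None, v)):
        members = [normalize_ci(c) for c in groups[key]]
        grid = members[0].times
        for m in members[1:]:
            if not np.array_equal(m.times, grid):
                raise ValueError("replicate wells must share one time grid")
        stack = np.vstack([m.ci for m in members])
        mean = stack.mean(axis=0)
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(members)) if len(members) > 1 else np.zeros_like(mean)
        cond = dict(members[0].condition)
        cond["n_wells"] = len(members)
        cond["sem"] = sem
        out.append(
            GrowthCurve(times=grid, ci=mean, well=f"mean[{by}={key}]", condition=cond, t0=members[0].t0)
        )
    return out


def time_dependent_ic50(
    curves: list[GrowthCurve],
    times: np.ndarray,
    response: str = "normalized_ci",
    slope_window_h: float | None = None,
    mean: str = "arithmetic",
) -> tuple[pd.DataFrame, float]:
    """Fit a dose-response at each evaluation time and average the IC50s.

    At each time point, the response per dose is the normalized CI at that
    time (default) or the slope over the ``slope_window_h`` hours ending
    there.  Times whose 4PL fit fails are excluded and reported with
    ``fit_ok=False`` rows.  Returns (per-time table, mean IC50); the mean is
    arithmetic on the molar scale by default, geometric on request (IC50s are
    log-normally distributed in practice).

    Each input curve must carry its dose in ``condition['dose_M']``.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    doses = np.array([c.condition.get("dose_M") for c in curves], dtype=float)
    if np.any(~np.isfinite(doses)) or np.any(doses <= 0):
        raise ValueError("every curve needs a positive condition['dose_M']")
    if np.unique(doses).size < 4:
        raise ValueError("need >= 4 distinct doses for a time-dependent IC50")
    normalized = [normalize_ci(c) for c in curves]

    rows = []
    fitted: list[float] = []
    for t in times:
        if response == "normalized_ci":
            resp = np.array([c.ci_at(t) for c in normalized])
        elif response == "slope":
            if slope_window_h is None:
                raise ValueError("slope response requires slope_window_h")
            resp = np.array([slope(c, (t - slope_window_h, t)) for c in normalized])
        else:
            raise ValueError(f"unknown response {response!r}; use 'normalized_ci' or 'slope'")
        dr = fit_4pl(doses, resp)
        rows.append(
            {
                "time_h": float(t),
                "ic50_M": dr.ic50 if dr.fit_ok else np.nan,
                "hill": dr.hill,
                "fit_ok": dr.fit_ok,
                "extrapolated": dr.extrapolated,
                "message": dr.message,
            }
        )
        if dr.fit_ok:
            fitted.append(dr.ic50)
    table = pd.DataFrame(rows)
    if not fitted:
        raise RuntimeError("no evaluation time yielded a successful dose-response fit")
    if mean == "arithmetic":
        mean_ic50 = float(np.mean(fitted))
    elif mean == "geometric":
        mean_ic50 = float(np.exp(np.mean(np.log(fitted))))
    else:
        raise ValueError(f"unknown mean {mean!r}; use 'arithmetic' or 'geometric'")
    return table, mean_ic50


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_curves_csv(curves_path: str | Path, wells_path: str | Path) -> list[GrowthCurve]:
    """Load long-format curve data (time_h, well, ci) + per-well metadata CSV."""
    data = pd.read_csv(curves_path)
    meta = pd.read_csv(wells_path).set_index("well")
    for col in ("time_h", "well", "ci"):
        if col not in data.columns:
            raise ValueError(f"{curves_path}: missing column {col!r}")
    curves = []
    for well, group in data.groupby("well", sort=True):
        group = group.sort_values("time_h")
        if well not in meta.index:
            raise ValueError(f"well {well!r} missing from metadata table")
        info = meta.loc[well].to_dict()
        t0 = float(info.pop("t0_h", group["time_h"].iloc[0]))
        curves.append(
            GrowthCurve(
                times=group["time_h"].to_numpy(),
                ci=group["ci"].to_numpy(),
                well=str(well),
                condition=info,
                t0=t0,
            )
        )
    return curves
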