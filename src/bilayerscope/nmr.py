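"""Barotropic NMR analysis.

High-pressure NMR follows peak intensities and chemical shifts along a
hydrostatic pressure ramp at fixed temperature.  A lipid fluid-to-gel
transition shows up as a sigmoidal drop of lipid (and membrane-facing
protein) peak intensities, as a sigmoidal inflection of chemical shifts,
and — for slow-exchange protein conformers — as a two-state splitting
into a fluid-phase peak (If) and a gel-phase peak (Ig) whose relative
populations cross at the transition midpoint Pm.

This module normalizes intensity series to the ambient-pressure point,
fits four-parameter logistic (Boltzmann) transitions, computes two-state
populations p_g = Ig/(If+Ig), and compares linear vs sigmoidal models of
chemical-shift evolution by small-sample-corrected AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError


@dataclass
class PressureSeries:
    """One peak's intensity (and optionally shift) along a pressure ramp.

    Pressures in bar, strictly increasing, with the ambient point first;
    intensities in arbitrary units, shifts in ppm.
    """

    pressures: np.ndarray
    intensity: np.ndarray
    shift: np.ndarray | None = None
    peak_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.shift is not None:
            self.shift = np.asarray(self.shift, dtype=float)
        if self.pressures.size != self.intensity.size:
            raise ValueError("pressures and intensity lengths differ")
        if self.pressures.size > 1 and np.any(np.diff(self.pressures) <= 0):
            raise ValueError("pressures must be strictly increasing")


@dataclass
class TwoStateSeries:
    """If/Ig intensities of a slow-exchange conformational pair."""

    pressures: np.ndarray
    intensity_f: np.ndarray
    intensity_g: np.ndarray
    sd_f: np.ndarray | None = None
    sd_g: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.intensity_f = np.asarray(self.intensity_f, dtype=float)
        self.intensity_g = np.asarray(self.intensity_g, dtype=float)
        n = self.pressures.size
        if self.intensity_f.size != n or self.intensity_g.size != n:
            raise ValueError("state intensities must match pressures")


@dataclass
class SigmoidFit:
    """Four-parameter logistic fit of a transition along a ramp.

    ``y(x) = low + (high - low) / (1 + exp(-(x - Pm)/width))`` — ``low``
    is the plateau approached on the low-x side.  A fit is flagged
    ``rejected`` when the midpoint falls outside the sampled range, the
    width exceeds it, or the amplitude is not significant.
    """

    Pm: float
    width: float
    plateau_low: float
    plateau_high: float
    stderr: dict = field(default_factory=dict)
    rss: float = math.nan
    r_squared: float = math.nan
    rejected: bool = False
    reason: str = ""

    @property
    def amplitude(self) -> float:
        return self.plateau_high - self.plateau_low


def _logistic4(x, pm, width, low, high):
    z = np.clip((x - pm) / width, -500.0, 500.0)
    return low + (high - low) / (1.0 + np.exp(-z))


def fit_sigmoid(x, y) -> SigmoidFit:
    """Least-squares logistic fit of y vs x.

    Handles both ascending and descending transitions (the plateaus are
    free parameters).  Never raises on a poor fit: pathological results
    come back with ``rejected=True`` and a reason.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise FitError("need at least 5 points for a 4-parameter sigmoid")
    span = float(x.max() - x.min())
    guess_mid = 0.5 * (y[0] + y[-1])
    x0 = float(x[np.argmin(np.abs(y - guess_mid))])
    p0 = [x0, span / 10.0, float(y[0]), float(y[-1])]
    bounds = ([-np.inf, 1e-9, -np.inf, -np.inf],
              [np.inf, np.inf, np.inf, np.inf])
    try:
        popt, pcov = curve_fit(_logistic4, x, y, p0=p0, bounds=bounds,
                               maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return SigmoidFit(math.nan, math.nan, math.nan, math.nan,
                          rejected=True, reason=f"fit failed: {exc}")
    pm, width, low, high = (float(v) for v in popt)
    resid = y - _logistic4(x, *popt)
    rss = float(np.sum(resid ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    stderr = dict(zip(("Pm", "width", "plateau_low", "plateau_high"), se))
    se_amp = math.hypot(se[2], se[3]) if np.all(np.isfinite(se[2:])) \
        else math.inf
    fit = SigmoidFit(pm, width, low, high, stderr=stderr, rss=rss,
                     r_squared=r2)
    if not (x.min() <= pm <= x.max()):
        fit.rejected, fit.reason = True, "midpoint outside sampled range"
    elif width > span:
        fit.rejected, fit.reason = True, "width exceeds sampled range"
    elif abs(high - low) < 3.0 * se_amp or abs(high - low) < 1e-12:
        fit.rejected, fit.reason = True, "no significant transition"
    return fit


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def normalize_intensity(series: PressureSeries) -> PressureSeries:
    """Scale a peak's intensities to 1 at ambient pressure.

    The ambient point is the lowest sampled pressure (nominally 1 bar).
    Normalization is per peak and idempotent; the shift columns are left
    untouched.
    """
    ambient = series.intensity[0]
    if not np.isfinite(ambient) or ambient <= 0:
        raise ValueError(
            "ambient-pressure intensity must be positive for normalization")
    out = replace(series, intensity=series.intensity / ambient,
                  metadata={**series.metadata, "normalized": True})
    return out


def two_state_populations(series: TwoStateSeries
                          ) -> tuple[np.ndarray, np.ndarray | None]:
    """Gel-state population p_g = Ig/(If+Ig) at each pressure.

    Assumes equal observability of the two states (same methyl, same
    experiment).  When per-point intensity uncertainties are present,
    the propagated standard deviation of p_g is returned alongside.
    """
    total = series.intensity_f + series.intensity_g
    if np.any(total == 0):
        raise ValueError("If + Ig must be nonzero at every pressure")
    p_g = series.intensity_g / total
    sigma = None
    if series.sd_f is not None and series.sd_g is not None:
        sf = np.asarray(series.sd_f, dtype=float)
        sg = np.asarray(series.sd_g, dtype=float)
        # d p_g / d Ig = If / T^2 ; d p_g / d If = -Ig / T^2
        sigma = np.sqrt((series.intensity_f * sg) ** 2
                        + (series.intensity_g * sf) ** 2) / total ** 2
    return p_g, sigma


def fit_transition(series: PressureSeries | TwoStateSeries) -> SigmoidFit:
    """Logistic transition fit of an intensity or population series.

    A :class:`PressureSeries` is fitted on its (raw or normalized)
    intensities; a :class:`TwoStateSeries` on its gel-state population.
    At least 5 pressures are required.
    """
    if isinstance(series, TwoStateSeries):
        y, _ = two_state_populations(series)
        x = series.pressures
    else:
        x, y = series.pressures, series.intensity
    if x.size < 5:
        raise FitError("need at least 5 pressure points")
    return fit_sigmoid(x, y)


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelComparison:
    preferred: str                # "linear" | "sigmoidal" | "indeterminate"
    aicc_linear: float
    aicc_sigmoidal: float
    delta: float                  # aicc_linear - aicc_sigmoidal
    diagnostics: str = ""


def shift_model_compare(pressures, shifts, tie_threshold: float = 2.0
                        ) -> ModelComparison:
    """Decide whether a chemical-shift curve is linear or sigmoidal.

    Fits a 2-parameter line and a 4-parameter logistic by least squares
    and compares them with the small-sample-corrected AIC; a margin below
    ``tie_threshold`` (or a failed sigmoid fit) yields "indeterminate".
    Requires at least 6 points (the sigmoid has 4 parameters).
    """
    x = np.asarray(pressures, dtype=float)
    y = np.asarray(shifts, dtype=float)
    n = x.size
    if n < 6:
        raise ValueError("need at least 6 points to compare the models")
    coef = np.polyfit(x, y, 1)
    rss_lin = float(np.sum((y - np.polyval(coef, x)) ** 2))
    aicc_lin = _aicc(rss_lin, n, 2)
    sig = fit_sigmoid(x, y)
    if not np.isfinite(sig.rss):
        return ModelComparison("indeterminate", aicc_lin, math.nan,
                               math.nan, diagnostics=sig.reason)
    aicc_sig = _aicc(sig.rss, n, 4)
    delta = aicc_lin - aicc_sig
    if abs(delta) < tie_threshold:
        preferred = "indeterminate"
    else:
        preferred = "sigmoidal" if delta > 0 else "linear"
    return ModelComparison(preferred, aicc_lin, aicc_sig, delta)


def series_from_peak_table(table) -> dict[str, PressureSeries]:
    """Split a peak table (pandas DataFrame) into per-peak series.

    Rows are grouped by ``peak_id`` (and ``state_label`` when present and
    non-empty, as ``"peak/state"``); each group must form a strictly
    increasing pressure ramp after sorting.
    """
    out: dict[str, PressureSeries] = {}
    has_state = "state_label" in table.columns
    keys = ["peak_id", "state_label"] if has_state else ["peak_id"]
    for key, grp in table.groupby(keys, dropna=False, sort=True):
        if has_state:
            peak, state = key
            name = f"{peak}/{state}" if state not in ("", None) \
                and not (isinstance(state, float) and math.isnan(state)) \
                else str(peak)
        else:
            name = str(key[0] if isinstance(key, tuple) else key)
        grp = grp.sort_values("pressure")
        shift = None
        if "shift_1H" in grp.columns and grp["shift_1H"].notna().any():
            shift = grp["shift_1H"].to_numpy(dtype=float)
        out[name] = PressureSeries(
            pressures=grp["pressure"].to_numpy(dtype=float),
            intensity=grp["intensity"].to_numpy(dtype=float),
            shift=shift, peak_id=name)
    return out
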