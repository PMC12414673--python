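"""Phase classification and P/T phase-diagram assembly.

A bilayer condition (one pressure/temperature point, possibly several
replica runs) is summarized by its windowed order metrics — gauche
fraction, area per lipid, box volume, headgroup hydration — and labeled
liquid, gel, or metastable.  The primary signal is the gauche fraction:
fluid bilayers sit near ~28–36%, gel bilayers near ~10–14%, so the
default thresholds (gel below 0.20, liquid above 0.24) bracket the two
regimes; a point is metastable when its value falls between them, when
replicas straddle the band, or when the windowed series still drifts.
Transition midpoints along a pressure ramp are extracted with the same
four-parameter logistic used for the barotropic NMR fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import FitError
from . import chain_order, solvation
from .model import ROLE_GLYCEROL, ROLE_WATER_O, Trajectory, as_trajectory
from .nmr import SigmoidFit, fit_sigmoid

LIQUID = "liquid"
GEL = "gel"
METASTABLE = "metastable"


@dataclass(frozen=True)
class PhaseThresholds:
    """Classification thresholds on the gauche fraction (and APL check).

    ``gel_below``/``liquid_above`` bracket the printed gel (~10–14%) and
    fluid (~28–36%) gauche fractions.  ``apl_gel_max`` is a consistency
    check only: a gel call additionally requires the area per lipid
    below this value when an APL is available.
    """

    gel_below: float = 0.20
    liquid_above: float = 0.24
    apl_gel_max: float = 55.0


@dataclass
class PhasePoint:
    """Metrics and label of one (P, T) condition."""

    pressure: float                    # bar
    temperature: float                 # °C
    metrics: dict                      # name -> (mean, sd or None)
    label: str | None = None


@dataclass
class PhaseDiagram:
    points: list
    boundary: list = field(default_factory=list)  # (T, P_liquid, P_gel)


def condition_summary(replicas, pressure: float = np.nan,
                      temperature: float = np.nan,
                      window_ns: float | None = chain_order.DEFAULT_WINDOW_NS
                      ) -> PhasePoint:
    """Windowed metric means per replica, aggregated across replicas.

    ``replicas`` is one trajectory or a list of replica trajectories;
    their analysis windows must span equal lengths.  Each metric is the
    replica-mean with the across-replica standard deviation (absent for
    a single replica).
    """
    reps = replicas if isinstance(replicas, (list, tuple)) else [replicas]
    reps = [as_trajectory(r) for r in reps]
    windows = [r.last_window(window_ns) for r in reps]
    spans = np.array([w.times[-1] - w.times[0] for w in windows])
    if not np.allclose(spans, spans[0], atol=1e-6):
        raise ValueError("replica analysis windows disagree in length")

    per_rep: dict[str, list[float]] = {}
    for w in windows:
        per_rep.setdefault("f_gauche", []).append(
            chain_order.gauche_fraction(w, window_ns=None).f_g)
        apl = np.mean([chain_order.area_per_lipid(f) for f in w])
        per_rep.setdefault("apl", []).append(float(apl))
        vol = np.mean([float(np.prod(f.box)) for f in w])
        per_rep.setdefault("volume", []).append(float(vol))
        f0 = w.frames[0]
        if f0.has_role(ROLE_GLYCEROL) and f0.has_role(ROLE_WATER_O):
            per_rep.setdefault("hydration", []).append(
                solvation.hydration_number(w))

    metrics = {}
    for name, vals in per_rep.items():
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        metrics[name] = (mean, sd)
    return PhasePoint(pressure=pressure, temperature=temperature,
                      metrics=metrics)


def classify_phase(metrics, thresholds: PhaseThresholds = PhaseThresholds(),
                   replica_values: Sequence[float] | None = None,
                   series: Sequence[float] | None = None) -> str:
    """Label a condition liquid, gel, or metastable.

    ``metrics`` maps metric names to means (or (mean, sd) pairs as
    produced by :func:`condition_summary`); ``f_gauche`` is required.
    ``replica_values`` are per-replica gauche fractions (straddling the
    threshold band marks the point metastable); ``series`` is the
    windowed gauche time series (a split-half mean difference above 3×
    the pooled standard error marks drift → metastable).
    """
    def _mean(v):
        return float(v[0]) if isinstance(v, (tuple, list)) else float(v)

    if "f_gauche" not in metrics:
        raise ValueError("classification requires the gauche fraction")
    f = _mean(metrics["f_gauche"])
    apl = _mean(metrics["apl"]) if "apl" in metrics else None

    if replica_values is not None and len(replica_values) > 1:
        vals = np.asarray(replica_values, dtype=float)
        if vals.min() < thresholds.gel_below \
                and vals.max() > thresholds.liquid_above:
            return METASTABLE
    if series is not None:
        s = np.asarray(series, dtype=float)
        if s.size >= 4:
            half = s.size // 2
            a, b = s[:half], s[half:]
            se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
            if se > 0 and abs(a.mean() - b.mean()) > 3.0 * se:
                return METASTABLE

    if f < thresholds.gel_below:
        if apl is not None and apl >= thresholds.apl_gel_max:
            return METASTABLE
        return GEL
    if f > thresholds.liquid_above:
        return LIQUID
    return METASTABLE


def transition_midpoint(pressures, values) -> SigmoidFit:
    """Logistic transition fit of a metric along a pressure ramp.

    Needs at least 5 points; fits with a midpoint outside the sampled
    range or a width wider than it come back flagged ``rejected``.
    """
    x = np.asarray(pressures, dtype=float)
    if x.size < 5:
        raise FitError("need at least 5 pressure points")
    return fit_sigmoid(x, values)


def phase_diagram(points: Sequence[PhasePoint]) -> PhaseDiagram:
    """Assemble labeled (P, T) points into a diagram with boundaries.

    For each temperature with both liquid and gel points, the boundary
    is bracketed by the highest-pressure liquid point and the
    lowest-pressure gel point (metastable points are ignored).  A liquid
    point at higher pressure than a gel point at the same temperature
    violates boundary monotonicity and emits a warning, not an error.
    """
    seen = set()
    for p in points:
        key = (p.pressure, p.temperature)
        if key in seen:
            raise ValueError(f"duplicate (P, T) entry {key}")
        seen.add(key)
    boundary = []
    for T in sorted({p.temperature for p in points}):
        liq = [p.pressure for p in points
               if p.temperature == T and p.label == LIQUID]
        gel = [p.pressure for p in points
               if p.temperature == T and p.label == GEL]
        if liq and gel:
            if max(liq) > min(gel):
                warnings.warn(
                    f"boundary monotonicity violated at T={T}: liquid at "
                    f"{max(liq)} bar above gel at {min(gel)} bar",
                    stacklevel=2)
            boundary.append((T, max(liq), min(gel)))
    return PhaseDiagram(points=list(points), boundary=boundary)
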