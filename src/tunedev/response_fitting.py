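"""Hill-function characterization of device response curves.

A device response function maps input promoter activity x (RPU) to output
fluorescence y (a.u.).  Activating devices (the TES itself) follow

    y = y_min + (y_max - y_min) * x^n / (K^n + x^n)

and repressing devices (NOT/NOR gates)

    y = y_min + (y_max - y_min) * K^n / (K^n + x^n)

with K the transition point (input at half-maximal output) and n the Hill
coefficient.  Fits are by nonlinear least squares on log10(y) residuals —
cytometry medians span decades and are plotted on log axes, so equal
weight per decade is the natural choice.  This module also computes the
device performance metrics (dynamic range, fold change, distribution
intersection, K range) and the sensor calibration that maps inducer
concentration to RPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import spearmanr

from tunedev.cytometry_stats import HistogramPair, intersection_fraction

__all__ = [
    "ResponseCurve",
    "HillFit",
    "DeviceMetrics",
    "KRange",
    "SensorCalibration",
    "fit_hill_activation",
    "fit_hill_repression",
    "device_metrics",
    "k_range",
    "sensor_calibration",
]


@dataclass(frozen=True)
class ResponseCurve:
    """Observed (input, output) points for one device at one tuner level.

    ``inputs`` and ``outputs`` are aligned observation vectors; replicates
    appear as repeated input values.  At least 4 distinct input levels are
    required (the Hill function has 4 free parameters).
    """

    inputs: np.ndarray
    outputs: np.ndarray
    tuner_activity: float | None = None
    design: str | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.inputs, dtype=float)
        y = np.asarray(self.outputs, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("inputs and outputs must be matching 1-D vectors")
        if np.any(x <= 0):
            raise ValueError("input activities must be positive")
        if np.any(y < 0):
            raise ValueError("outputs must be non-negative")
        if np.unique(x).size < 4:
            raise ValueError("need >= 4 distinct input levels to fit 4 parameters")
        object.__setattr__(self, "inputs", x)
        object.__setattr__(self, "outputs", y)

    @classmethod
    def from_replicates(
        cls,
        inputs: Sequence[float],
        replicate_outputs: np.ndarray,
        tuner_activity: float | None = None,
        design: str | None = None,
    ) -> "ResponseCurve":
        """Build from a (n_inputs, n_replicates) output matrix."""
        reps = np.asarray(replicate_outputs, dtype=float)
        x = np.repeat(np.asarray(inputs, dtype=float), reps.shape[1])
        return cls(x, reps.ravel(), tuner_activity=tuner_activity, design=design)


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with a reliability flag.

    ``reliable`` is False when the optimizer failed, K left the
    identifiable window [min(x)/10, 10*max(x)], the curve's monotonic
    trend contradicts the requested orientation, or the output range is
    too flat to constrain K.
    """

    y_min: float
    y_max: float
    K: float
    n: float
    orientation: str  # "activation" | "repression"
    residual_norm: float
    reliable: bool = True
    message: str = ""

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.orientation == "activation":
            frac = x**self.n / (self.K**self.n + x**self.n)
        else:
            frac = self.K**self.n / (self.K**self.n + x**self.n)
        return self.y_min + (self.y_max - self.y_min) * frac


@dataclass(frozen=True)
class KRange:
    """Span of Hill transition points across tuner levels."""

    K_min: float
    K_max: float
    ratio: float
    n_used: int
    excluded: tuple = ()


@dataclass(frozen=True)
class DeviceMetrics:
    """Table-style device performance metrics (replicate mean +/- SD)."""

    dynamic_range: float
    dynamic_range_sd: float
    fold_change: float
    fold_change_sd: float
    intersection: float
    intersection_sd: float
    n_replicates: int


_EPS = 1e-12


def _hill_residuals(theta, x, logy, orientation):
    y_min, y_max, K, n = theta
    if orientation == "activation":
        frac = x**n / (K**n + x**n)
    else:
        frac = K**n / (K**n + x**n)
    pred = y_min + (y_max - y_min) * frac
    return np.log10(np.maximum(pred, _EPS)) - logy


def _fit_hill(curve: ResponseCurve, orientation: str) -> HillFit:
    x, y = curve.inputs, curve.outputs
    logy = np.log10(np.maximum(y, _EPS))

    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    span_ok = y_hi > 0 and (y_hi - y_lo) > 1e-6 * max(y_hi, 1.0)
    if not span_ok:
        # flat curve: y_min = y_max, K unidentifiable
        med = float(np.median(y))
        return HillFit(
            y_min=med, y_max=med, K=float(np.sqrt(x.min() * x.max())), n=1.0,
            orientation=orientation, residual_norm=0.0, reliable=False,
            message="flat response: K unidentifiable",
        )

    K0 = float(np.exp(np.mean(np.log(x))))  # geometric mean of inputs
    theta0 = np.array([max(y_lo, _EPS), y_hi, K0, 1.0])
    lb = np.array([0.0, 0.0, x.min() / 10.0, 0.3])
    ub = np.array([10.0 * y_hi, 10.0 * y_hi, 10.0 * x.max(), 6.0])
    theta0 = np.clip(theta0, lb + _EPS, ub - _EPS)
    try:
        res = least_squares(
            _hill_residuals, theta0, bounds=(lb, ub), args=(x, logy, orientation),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
        )
        ok = res.success
        theta = res.x
        rnorm = float(np.sqrt(2 * res.cost))
    except Exception as err:  # pragma: no cover - optimizer failure path
        return HillFit(*theta0, orientation=orientation, residual_norm=np.inf,
                       reliable=False, message=f"optimizer failed: {err}")

    y_min_f, y_max_f, K, n = (float(v) for v in theta)
    if y_max_f < y_min_f:
        y_min_f, y_max_f = y_max_f, y_min_f
    reliable, message = bool(ok), "" if ok else "optimizer did not converge"

    if not (x.min() / 10.0 < K < 10.0 * x.max()) or np.isclose(K, x.min() / 10.0) or np.isclose(K, 10.0 * x.max()):
        reliable, message = False, f"K = {K:.4g} at the edge of the identifiable window"

    # orientation sanity: the observed trend must match the requested shape
    rho = spearmanr(x, y).statistic
    if np.isfinite(rho):
        if orientation == "activation" and rho < 0:
            reliable, message = False, "decreasing data fitted with an activation Hill"
        if orientation == "repression" and rho > 0:
            reliable, message = False, "increasing data fitted with a repression Hill"

    return HillFit(y_min_f, y_max_f, K, n, orientation, rnorm, reliable, message)


def fit_hill_activation(curve: ResponseCurve) -> HillFit:
    """Fit an activating Hill response (output rises with input)."""
    return _fit_hill(curve, "activation")


def fit_hill_repression(curve: ResponseCurve) -> HillFit:
    """Fit a repressing Hill response (output falls with input)."""
    return _fit_hill(curve, "repression")


def device_metrics(
    on_medians: Sequence[float],
    off_medians: Sequence[float],
    on_events: Sequence[np.ndarray] | None = None,
    off_events: Sequence[np.ndarray] | None = None,
    n_bins: int = 256,
) -> DeviceMetrics:
    """Dynamic range, fold change, and distribution intersection.

    ``on_medians``/``off_medians`` are per-replicate corrected medians at
    the on/off input states; ``on_events``/``off_events`` (optional) are
    the per-replicate event vectors used for the intersection statistic.
    Per replicate: dynamic range = |median_on - median_off|, fold change =
    larger/smaller median, intersection = normalized histogram overlap;
    reported as mean +/- SD over replicates.
    """
    on = np.asarray(on_medians, dtype=float)
    off = np.asarray(off_medians, dtype=float)
    if on.size != off.size or on.size == 0:
        raise ValueError("on/off medians must be non-empty and matched per replicate")
    dr = np.abs(on - off)
    with np.errstate(divide="ignore"):
        fc = np.maximum(on, off) / np.minimum(on, off)
    if on_events is not None and off_events is not None:
        if len(on_events) != on.size or len(off_events) != on.size:
            raise ValueError("event lists must have one entry per replicate")
        from tunedev.cytometry_stats import histogram_pair

        inter = np.array([
            intersection_fraction(histogram_pair(np.asarray(a), np.asarray(b), n_bins))
            for a, b in zip(off_events, on_events)
        ])
    else:
        inter = np.full(on.size, np.nan)
    sd = (lambda v: float(np.std(v, ddof=1)) if v.size > 1 else 0.0)
    return DeviceMetrics(
        dynamic_range=float(np.mean(dr)), dynamic_range_sd=sd(dr),
        fold_change=float(np.mean(fc)), fold_change_sd=sd(fc),
        intersection=float(np.mean(inter)), intersection_sd=sd(inter),
        n_replicates=int(on.size),
    )


def k_range(fits: Mapping[float, HillFit]) -> KRange:
    """Span of transition points K over tuner levels (reliable fits only)."""
    used, excluded = {}, []
    for tuner, fit in fits.items():
        if fit.reliable:
            used[tuner] = fit.K
        else:
            excluded.append((tuner, fit.message))
    if len(used) < 2:
        raise ValueError(
            f"K range needs >= 2 reliable fits, got {len(used)} "
            f"(excluded: {excluded})"
        )
    ks = np.array(list(used.values()))
    return KRange(
        K_min=float(ks.min()), K_max=float(ks.max()),
        ratio=float(ks.max() / ks.min()), n_used=ks.size, excluded=tuple(excluded),
    )


@dataclass(frozen=True)
class SensorCalibration:
    """Hill mapping between inducer concentration and promoter activity (RPU)."""

    fit: HillFit
    concentrations: np.ndarray
    rpu_values: np.ndarray

    def to_rpu(self, concentration) -> np.ndarray:
        """Forward map: inducer concentration -> promoter activity (RPU)."""
        return self.fit.predict(concentration)

    def to_concentration(self, rpu) -> np.ndarray:
        """Inverse map (activation Hill inverted analytically)."""
        y = np.asarray(rpu, dtype=float)
        f = self.fit
        frac = np.clip((y - f.y_min) / max(f.y_max - f.y_min, _EPS), _EPS, 1 - _EPS)
        return f.K * (frac / (1.0 - frac)) ** (1.0 / f.n)


def sensor_calibration(
    inducer_conc: Sequence[float],
    sensor_medians: Sequence[float],
    rpu_standard_median: float,
) -> SensorCalibration:
    """Calibrate a small-molecule sensor in relative promoter units.

    Per concentration, RPU = sensor median / RPU-standard median; an
    activating Hill function is then fitted over concentration.  Zero
    concentrations are shifted onto a pseudo-concentration two decades
    below the smallest positive grid point so the basal point constrains
    y_min.
    """
    if rpu_standard_median <= 0:
        raise ValueError("RPU standard median must be > 0")
    conc = np.asarray(inducer_conc, dtype=float)
    med = np.asarray(sensor_medians, dtype=float)
    if conc.shape != med.shape:
        raise ValueError("concentration and median vectors must match")
    rpu = med / rpu_standard_median
    x = conc.copy()
    if np.any(x <= 0):
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("need at least one positive concentration")
        x[x <= 0] = positive.min() / 100.0
    curve = ResponseCurve(x, rpu)
    return SensorCalibration(fit=fit_hill_activation(curve), concentrations=conc, rpu_values=rpu)
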