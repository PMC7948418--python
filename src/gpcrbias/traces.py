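"""Kinetic trace processing.

Plate readers record luminescence/fluorescence serially per well; every
downstream quantity here (fold-of-vehicle signal, AUC, half-time) is computed
on those per-well time series. Conventions follow common practice for
NanoBiT / BRET / DERET assays: each well is first normalized to its own
pre-agonist baseline, then to the time-matched mean of vehicle wells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

log = logging.getLogger("gpcrbias")

__all__ = [
    "KineticTrace",
    "TraceSummary",
    "BaselineError",
    "normalize_trace",
    "ratiometric",
    "trace_auc",
    "response_t_half",
    "normalize_to_control",
    "delta_ct_expression",
]


class BaselineError(ValueError):
    """Raised when a well's baseline segment is unusable (mean <= 0)."""


@dataclass
class KineticTrace:
    """Time-indexed signal(s) for one well, with plate-map annotations.

    ``baseline_end`` is the time (min) at which agonist was added; reads at
    ``t < baseline_end`` form the pre-agonist baseline segment.
    """

    well_id: str
    times: np.ndarray
    channels: dict[str, np.ndarray]
    receptor: str | None = None
    ligand: str | None = None
    concentration: float = 0.0
    is_vehicle: bool = False
    block_id: str | None = None
    baseline_end: float = 0.0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, sig in self.channels.items():
            if sig.shape != self.times.shape:
                raise ValueError(f"channel {name!r} length differs from times")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def single_channel(self) -> np.ndarray:
        if len(self.channels) != 1:
            raise ValueError(
                f"well {self.well_id!r}: expected a single channel, "
                f"got {sorted(self.channels)}"
            )
        return next(iter(self.channels.values()))

    def baseline_mask(self) -> np.ndarray:
        return self.times < self.baseline_end

    def baseline_mean(self) -> float:
        sig = self.single_channel()
        mask = self.baseline_mask()
        if not mask.any():
            return float(sig[0])
        return float(np.nanmean(sig[mask]))


@dataclass(frozen=True)
class TraceSummary:
    """Scalar summaries of one processed trace."""

    well_id: str
    auc: float
    peak: float
    t_half: float | None
    baseline_mean: float


def _check_shared_timebase(traces: list[KineticTrace]) -> np.ndarray:
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise ValueError(
                f"mismatched timebases: well {tr.well_id!r} vs {traces[0].well_id!r}"
            )
    return t0


def normalize_trace(trace: KineticTrace, vehicle_traces: list[KineticTrace]) -> KineticTrace:
    """Normalize a well to its own baseline, then to the vehicle mean.

    Each time point is divided by the well's pre-agonist baseline mean, then
    by the mean of the identically baseline-normalized vehicle wells at the
    matching time point. A vehicle trace processed against identical peers
    returns 1.0 everywhere.
    """
    if not vehicle_traces:
        raise ValueError("at least one vehicle trace is required")
    _check_shared_timebase([trace, *vehicle_traces])

    def _baseline_normed(tr: KineticTrace) -> np.ndarray:
        b = tr.baseline_mean()
        if b <= 0 or not math.isfinite(b):
            raise BaselineError(f"well {tr.well_id!r}: baseline mean {b} <= 0")
        return tr.single_channel() / b

    vehicle_mean = np.mean([_baseline_normed(v) for v in vehicle_traces], axis=0)
    if np.any(vehicle_mean <= 0):
        raise BaselineError("vehicle mean signal <= 0 at some time point")
    normed = _baseline_normed(trace) / vehicle_mean
    return replace(trace, channels={"normalized": normed})


def ratiometric(
    trace: KineticTrace,
    numerator_channel: str,
    denominator_channel: str,
    blank: dict[str, float] | None = None,
) -> KineticTrace:
    """Per-time-point channel ratio with optional per-channel blank subtraction.

    Used for BRET (575/460) and DERET (620/520, after subtracting
    fluorescein-only blank wells). Points where the blanked denominator is
    <= 0 are masked to NaN and the well is flagged, not discarded: transient
    instrument artifacts should not throw away a whole well.
    """
    for name in (numerator_channel, denominator_channel):
        if name not in trace.channels:
            raise ValueError(f"well {trace.well_id!r}: channel {name!r} absent")
    blank = blank or {}
    num = trace.channels[numerator_channel] - blank.get(numerator_channel, 0.0)
    den = trace.channels[denominator_channel] - blank.get(denominator_channel, 0.0)
    bad = den <= 0
    flags = list(trace.flags)
    if bad.any():
        flags.append(f"masked {int(bad.sum())} points with denominator <= 0")
        log.warning("well %s: %s", trace.well_id, flags[-1])
    ratio = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    name = f"{numerator_channel}/{denominator_channel}"
    return replace(trace, channels={name: ratio}, flags=flags)


def trace_auc(trace: KineticTrace, baseline_correct: bool = False) -> float:
    """Trapezoidal area under the post-agonist signal (response * min).

    Integrates on the native time grid over ``t >= baseline_end``. With
    ``baseline_correct`` the pre-agonist baseline mean is subtracted first,
    so a flat trace integrates to zero.
    """
    sig = trace.single_channel()
    post = trace.times >= trace.baseline_end
    t, y = trace.times[post], sig[post]
    if len(t) < 2:
        raise ValueError("AUC requires at least 2 post-agonist time points")
    if baseline_correct:
        y = y - trace.baseline_mean()
    return float(np.trapezoid(y, t))


def _exp_association(t, baseline, span, k):
    return baseline + span * (1.0 - np.exp(-k * t))


def response_t_half(trace: KineticTrace, method: str = "interpolate") -> float | None:
    """Time (min, from agonist addition) to half the peak rise above baseline.

    ``method="interpolate"`` (default) takes the first linear-interpolated
    crossing of baseline + (peak - baseline)/2 — assumption-free.
    ``method="fit"`` fits a one-phase exponential association and returns
    ln2/k. Returns None for traces with no rise above baseline.
    """
    sig = trace.single_channel()
    post = trace.times >= trace.baseline_end
    t = trace.times[post] - trace.baseline_end
    y = sig[post]
    baseline = trace.baseline_mean()
    peak = float(np.nanmax(y))
    span = peak - baseline
    if span <= 0 or np.isclose(span, 0.0, atol=1e-12 * max(abs(peak), 1.0)):
        return None
    if method == "fit":
        try:
            popt, _ = curve_fit(
                _exp_association, t, y,
                p0=[baseline, span, 1.0 / max(t[-1] / 4, 1e-6)],
                maxfev=10000,
            )
        except RuntimeError:
            return None
        return float(np.log(2) / popt[2]) if popt[2] > 0 else None
    if method != "interpolate":
        raise ValueError(f"unknown method {method!r}")
    half = baseline + span / 2.0
    above = y >= half
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    # linear interpolation between the bracketing samples
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    return float(t0 + (half - y0) * (t1 - t0) / (y1 - y0))


def normalize_to_control(
    responses: pd.DataFrame,
    control_key: str,
    value_col: str = "response",
    condition_col: str = "condition",
    block_col: str = "block",
    mode: str = "fold",
) -> pd.DataFrame:
    """Express responses relative to each block's control-condition mean.

    ``mode="fold"`` divides by the control mean (ERK fold-of-unstimulated,
    insulin fold-of-glucose-only); ``mode="percent"`` additionally scales by
    100 (%FSK-style cAMP normalization). Blocks whose control mean is <= 0
    are excluded with a log entry.
    """
    if mode not in ("fold", "percent"):
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for block, grp in responses.groupby(block_col, sort=False):
        ctrl = grp.loc[grp[condition_col] == control_key, value_col]
        if ctrl.empty:
            raise ValueError(f"block {block!r}: no {control_key!r} control wells")
        cmean = float(ctrl.mean())
        if cmean <= 0:
            log.warning("block %r excluded: control mean %.3g <= 0", block, cmean)
            continue
        g = grp.copy()
        g[value_col] = g[value_col] / cmean * (100.0 if mode == "percent" else 1.0)
        out.append(g)
    if not out:
        raise ValueError("all blocks excluded: no usable controls")
    return pd.concat(out, ignore_index=True)


def delta_ct_expression(ct_target: float, ct_reference: float) -> float:
    """Relative expression by the 2^-dCt method vs an endogenous control gene."""
    if ct_target is None or ct_reference is None:
        return float("nan")
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        return float("nan")
    return 2.0 ** (-(ct_target - ct_reference))
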