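"""Event-locked response statistics with bootstrap nulls.

The biosonar response to a target escape is quantified by the proportion of
positive ICI changes (deltaICI > 0, i.e. outward depth-of-field
adjustments) in short time bins spanning 500 ms either side of the event;
the kinematic response by the RMS norm-jerk in the same bins.  Chance
association is assessed with a buzz-pair bootstrap: the event offset from
one buzz is transplanted onto another, the statistic recomputed, and a bin
is flagged significant when the observed aggregate exceeds the criterion
quantile of the replicate aggregates.

Analytic helpers relate the ICI to the acoustic depth of field
(dof = ICI * c / 2) and compare the information bandwidth 1/(2*ICI) with
the control bandwidth ~1/(4*latency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .click_buzz import ClickTrain
from .errors import InsufficientDataError, ParameterError
from .trial_io import SensorStream

__all__ = [
    "BinnedResponse",
    "BootstrapResult",
    "event_bins",
    "delta_ici_proportions",
    "norm_jerk",
    "jerk_rms_bins",
    "bootstrap_null",
    "ici_to_dof",
    "dof_to_ici",
    "bandwidth_ratio",
    "clicks_per_latency",
]

WINDOW = 0.5  # s either side of the event


def event_bins(bin_width: float, window: float = WINDOW) -> np.ndarray:
    """Contiguous bin edges (s, event-relative) from -window to +window.

    The event falls exactly on the edge between the pre and post bins.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    n = int(round(window / bin_width))
    return np.linspace(-n * bin_width, n * bin_width, 2 * n + 1)


@dataclass
class BinnedResponse:
    """Per-trial per-bin values of an event-locked statistic."""

    bin_edges: np.ndarray
    values: np.ndarray  # (n_trials, n_bins); NaN where a bin had no data
    bin_width: float
    statistic: str  # "prop_positive_dici" or "rms_jerk"


@dataclass
class BootstrapResult:
    """Observed aggregate, null replicates, and per-bin significance."""

    bin_edges: np.ndarray
    observed: np.ndarray  # (n_bins,) aggregate across trials
    replicates: np.ndarray  # (n_rep, n_bins) aggregate under the null
    significant: np.ndarray  # (n_bins,) bool
    criterion: float
    statistic: str


def delta_ici_proportions(
    train: ClickTrain, event: float, bin_width: float
) -> np.ndarray:
    """Proportion of positive deltaICI per event-locked bin.

    deltaICI_k = ici_{k+1} - ici_k is assigned to the time of click k+1
    (the change only becomes observable when the later click is emitted);
    zero changes count as non-positive.  Bins with no deltaICI are NaN.
    """
    if len(train) < 3:
        raise InsufficientDataError("need >= 3 clicks for deltaICI proportions")
    edges = event_bins(bin_width)
    lo, hi = event + edges[0], event + edges[-1]
    if train.times[-1] < lo or train.times[0] > hi:
        raise InsufficientDataError("click train does not overlap the event window")
    ici = train.ici
    dici = np.diff(ici)
    t_dici = train.times[1:-1] - event  # time of click k+1, event-relative
    nbins = edges.size - 1
    out = np.full(nbins, np.nan)
    idx = np.searchsorted(edges, t_dici, side="right") - 1
    ok = (idx >= 0) & (idx < nbins)
    for b in range(nbins):
        sel = dici[ok & (idx == b)]
        if sel.size:
            out[b] = np.count_nonzero(sel > 0) / sel.size
    return out


def norm_jerk(motion: SensorStream) -> tuple[np.ndarray, np.ndarray]:
    """Norm-jerk: vector magnitude of the acceleration change rate (m/s^3).

    First difference scaled by the sampling rate, no smoothing; returned
    with midpoint times.  Length n-1.
    """
    j = np.linalg.norm(np.diff(motion.accel, axis=1), axis=0) * motion.fs
    t = (np.arange(j.size) + 0.5) / motion.fs
    return t, j


def jerk_rms_bins(motion: SensorStream, event: float, bin_width: float
                  ) -> np.ndarray:
    """RMS norm-jerk (m/s^3) per event-locked bin; NaN for sparse bins."""
    edges = event_bins(bin_width)
    t, j = norm_jerk(motion)
    if t[-1] < event + edges[0] or t[0] > event + edges[-1]:
        raise InsufficientDataError("motion stream does not overlap the event window")
    rel = t - event
    nbins = edges.size - 1
    out = np.full(nbins, np.nan)
    idx = np.searchsorted(edges, rel, side="right") - 1
    ok = (idx >= 0) & (idx < nbins)
    for b in range(nbins):
        sel = j[ok & (idx == b)]
        if sel.size >= 2:
            out[b] = np.sqrt(np.mean(sel**2))
    return out


def _trial_statistic(data, event: float, bin_width: float) -> np.ndarray:
    if isinstance(data, ClickTrain):
        return delta_ici_proportions(data, event, bin_width)
    if isinstance(data, SensorStream):
        return jerk_rms_bins(data, event, bin_width)
    raise ParameterError(f"unsupported trial data type {type(data).__name__}")


def _record_start(data) -> float:
    return float(data.times[0]) if isinstance(data, ClickTrain) else 0.0


def binned_response(
    trials: Sequence[tuple[object, float]], bin_width: float
) -> BinnedResponse:
    """Per-trial event-locked statistic matrix for a cohort of trials.

    Each trial is a ``(ClickTrain, event_time)`` or ``(SensorStream,
    event_time)`` pair; all trials must be of the same kind.
    """
    edges = event_bins(bin_width)
    values = np.vstack(
        [_trial_statistic(data, ev, bin_width) for data, ev in trials]
    )
    stat = (
        "prop_positive_dici"
        if isinstance(trials[0][0], ClickTrain)
        else "rms_jerk"
    )
    return BinnedResponse(
        bin_edges=edges, values=values, bin_width=bin_width, statistic=stat
    )


def bootstrap_null(
    trials: Sequence[tuple[object, float]],
    bin_width: float,
    n_rep: int = 1000,
    rng_seed: int = 0,
    criterion: float = 0.95,
    aggregate: str = "median",
) -> BootstrapResult:
    """Buzz-pair bootstrap null for an event-locked statistic.

    For each replicate, one random ordered pair of trials (with
    replacement) is drawn per trial slot; the event offset of the first
    trial (event time minus record start) is applied at the second trial's
    record start to give a mock event, the per-bin statistic is recomputed
    there, and replicate values are aggregated across slots.  A bin is
    flagged significant when the fraction of replicate aggregates lying
    below the observed aggregate exceeds ``criterion``.

    ``aggregate`` is ``"median"`` (robust, default) or ``"mean"`` (pooled
    average), covering both plausible cross-trial pooling conventions.
    """
    if n_rep < 1:
        raise ParameterError("n_rep must be >= 1")
    if len(trials) < 2:
        raise ParameterError("need >= 2 trials for the pair bootstrap")
    if aggregate not in ("median", "mean"):
        raise ParameterError("aggregate must be 'median' or 'mean'")
    agg = np.nanmedian if aggregate == "median" else np.nanmean
    edges = event_bins(bin_width)
    resp = binned_response(trials, bin_width)
    observed = agg(resp.values, axis=0)

    starts = np.array([_record_start(d) for d, _ in trials])
    offsets = np.array([ev - s for (_, ev), s in zip(trials, starts)])
    n = len(trials)
    rng = np.random.default_rng(rng_seed)
    replicates = np.full((n_rep, edges.size - 1), np.nan)
    for r in range(n_rep):
        donors = rng.integers(0, n, size=n)
        receivers = rng.integers(0, n, size=n)
        vals = np.full((n, edges.size - 1), np.nan)
        for s, (i, j) in enumerate(zip(donors, receivers)):
            mock_event = starts[j] + offsets[i]
            try:
                vals[s] = _trial_statistic(trials[j][0], mock_event, bin_width)
            except InsufficientDataError:
                continue
        replicates[r] = agg(vals, axis=0)
    # mid-p tie handling: aggregates of binned proportions have atoms, and
    # counting ties as non-exceedances would make the criterion conservative
    exceed = np.nanmean(replicates < observed[None, :], axis=0) + 0.5 * np.nanmean(
        replicates == observed[None, :], axis=0
    )
    significant = exceed > criterion
    stat = resp.statistic
    return BootstrapResult(
        bin_edges=edges,
        observed=observed,
        replicates=replicates,
        significant=significant,
        criterion=criterion,
        statistic=stat,
    )


# ---------------------------------------------------------------------------
# analytic helpers


def ici_to_dof(ici: "float | np.ndarray", c: float = 1500.0):
    """Acoustic depth of field (m): the ICI times half the sound speed."""
    ici = np.asarray(ici, dtype=np.float64)
    if np.any(ici < 0) or c <= 0:
        raise ParameterError("require ici >= 0 and c > 0")
    out = ici * c / 2.0
    return float(out) if out.ndim == 0 else out


def dof_to_ici(dof: "float | np.ndarray", c: float = 1500.0):
    """Inverse of :func:`ici_to_dof`: the ICI giving a depth of field."""
    dof = np.asarray(dof, dtype=np.float64)
    if np.any(dof < 0) or c <= 0:
        raise ParameterError("require dof >= 0 and c > 0")
    out = 2.0 * dof / c
    return float(out) if out.ndim == 0 else out


def bandwidth_ratio(ici: float, latency: float) -> float:
    """Information bandwidth over control bandwidth.

    Information flows at up to 1/(2*ICI) Hz (Nyquist); a feedback loop with
    pure delay tau responds at up to ~1/(4*tau) Hz.  The ratio reduces to
    2*latency/ici.
    """
    if ici <= 0 or latency <= 0:
        raise ParameterError("require ici > 0 and latency > 0")
    return (1.0 / (2.0 * ici)) / (1.0 / (4.0 * latency))


def clicks_per_latency(latency: float, ici: float) -> int:
    """Number of clicks emitted during one response latency: floor(lat/ici)."""
    if ici <= 0:
        raise ParameterError("require ici > 0")
    if latency < 0:
        raise ParameterError("require latency >= 0")
    return int(np.floor(latency / ici))
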