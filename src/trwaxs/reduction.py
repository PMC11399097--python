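"""Train filtering, normalization, light-dark differencing and merging.

Order of operations follows the acquisition narrative: filter unstable trains
by profile correlation, average within the light/dark classes, normalize each
curve over the q-window, subtract to get the difference matrix dS(q, t), and
finally merge datasets (e.g. two sample concentrations) by a weighted average
after a scale-and-offset alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .geometry import QGrid
from .synthetic import TrainSeries

log = logging.getLogger(__name__)

__all__ = [
    "DifferenceSeries",
    "TrainCorrelationFilter",
    "filter_trains",
    "normalize_profile",
    "compute_difference",
    "merge_concentrations",
]

#: Correlation threshold below which a train is considered low quality.
DEFAULT_CORRELATION_THRESHOLD = 0.99995


@dataclass
class DifferenceSeries:
    """Light-minus-dark difference matrix dS(q, t) with its grids."""

    q: QGrid
    time_us: np.ndarray
    delta_S: np.ndarray            # (n_q, n_t)
    n_light_frames: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.delta_S = np.asarray(self.delta_S, dtype=float)
        if self.delta_S.shape != (len(self.q), len(self.time_us)):
            raise ValueError("delta_S must have shape (n_q, n_t)")
        if not np.all(np.isfinite(self.delta_S)):
            raise ValueError("delta_S must be finite")
        if self.n_light_frames <= 0:
            raise ValueError("n_light_frames must be positive")


class TrainCorrelationFilter(BaseEstimator):
    """Drop trains whose pulse-averaged profile decorrelates from the run mean.

    For each train the Pearson correlation between its pulse-averaged q-profile
    and the run-average profile of trains with the same light/dark flag is
    computed; trains below ``threshold`` (default 0.99995) are flagged as
    low quality (intermittent jet instability changes the *shape* of the
    curve, which a profile correlation detects while being insensitive to the
    overall multiplicative jitter).

    Attributes after ``fit``: ``correlations_``, ``keep_mask_``, ``report_``.
    """

    def __init__(self, threshold: float = DEFAULT_CORRELATION_THRESHOLD):
        self.threshold = threshold

    def fit(self, X: TrainSeries, y=None):
        if X.n_trains < 2:
            raise ValueError("need at least two trains to filter")
        means = X.train_means()
        keep = np.ones(X.n_trains, bool)

        def correlations(mask):
            corr = np.full(X.n_trains, np.nan)
            for flag in (True, False):
                sel = X.light_flag == flag
                if not (sel & mask).any():
                    continue
                ref = means[sel & mask].mean(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    for i in np.flatnonzero(sel):
                        corr[i] = np.corrcoef(means[i], ref)[0, 1]
            return corr

        # greedy refinement: a distorted train also contaminates the run
        # average it is compared against, so remove the worst offender and
        # recompute the reference until every kept train clears the threshold
        while True:
            corr = correlations(keep)
            # NaN correlations (degenerate profiles) count as failing
            below = keep & ~(corr >= self.threshold)
            if not below.any():
                break
            candidates_ = np.flatnonzero(below)
            ranked = corr[candidates_]
            worst = candidates_[np.nanargmin(ranked)] if np.isfinite(ranked).any() else candidates_[0]
            keep[worst] = False
            if not keep.any():
                raise ValueError("correlation filter would drop every train")
        self.correlations_ = corr
        self.keep_mask_ = keep
        if not self.keep_mask_.any():
            raise ValueError("correlation filter would drop every train")
        n_pulses = X.profiles.shape[1]
        self.report_ = {
            "threshold": self.threshold,
            "per_train_correlation": corr.copy(),
            "n_trains_kept": int(self.keep_mask_.sum()),
            "n_trains_dropped": int((~self.keep_mask_).sum()),
            "n_images_kept": int(self.keep_mask_.sum()) * n_pulses,
            "n_images_dropped": int((~self.keep_mask_).sum()) * n_pulses,
            "dropped_ids": np.flatnonzero(~self.keep_mask_),
        }
        return self

    def transform(self, X: TrainSeries) -> TrainSeries:
        keep = self.keep_mask_
        return TrainSeries(
            profiles=X.profiles[keep],
            light_flag=X.light_flag[keep],
            time_us=X.time_us.copy(),
            q=X.q,
            truth=dict(X.truth) if X.truth is not None else None,
        )

    def fit_transform(self, X: TrainSeries, y=None) -> TrainSeries:
        return self.fit(X).transform(X)


def filter_trains(
    series: TrainSeries, threshold: float = DEFAULT_CORRELATION_THRESHOLD
) -> tuple[TrainSeries, dict]:
    """Functional wrapper over :class:`TrainCorrelationFilter`."""
    flt = TrainCorrelationFilter(threshold=threshold)
    kept = flt.fit_transform(series)
    return kept, flt.report_


def normalize_profile(
    intensity: np.ndarray, q: QGrid, q_lo: float = 0.08, q_hi: float = 2.1
) -> np.ndarray:
    """Divide a curve by its summed intensity over the [q_lo, q_hi] window.

    The window sum of the result is exactly one; scaling the input leaves the
    output unchanged, which is what makes this the jitter-removing step.
    """
    window = q.window(q_lo, q_hi)
    if not window.any():
        raise ValueError("normalization window contains no q bins")
    total = np.sum(np.asarray(intensity, dtype=float)[..., window], axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("non-positive window sum; cannot normalize")
    return np.asarray(intensity, dtype=float) / total


def compute_difference(
    series: TrainSeries,
    pairing: str = "mean",
    normalize: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> DifferenceSeries:
    """Light-minus-dark difference matrix from a (filtered) train series.

    ``pairing='mean'`` averages all light trains and all dark trains, then
    (optionally) normalizes each time-point curve over the given q-window
    before subtracting.  ``pairing='adjacent'`` subtracts each light train
    from its neighbouring dark train and averages the pair differences, which
    additionally suppresses slowly drifting train-level jitter; a trailing
    unpaired train is dropped with a log line.  ``pairing='shuffled'`` pairs
    light and dark trains at random (diagnostic baseline for the adjacent
    strategy; requires ``rng``).
    """
    light = series.profiles[series.light_flag]
    dark = series.profiles[~series.light_flag]
    if len(light) == 0 or len(dark) == 0:
        raise ValueError("need at least one light and one dark train")

    def _norm(block):  # block: (..., n_q) curves per time point
        if normalize is None:
            return block
        return normalize_profile(block, series.q, *normalize)

    if pairing == "mean":
        s_light = _norm(light.mean(axis=0))    # (n_pulses, n_q)
        s_dark = _norm(dark.mean(axis=0))
        delta = s_light - s_dark
    elif pairing in ("adjacent", "shuffled"):
        order = np.flatnonzero(series.light_flag), np.flatnonzero(~series.light_flag)
        n_pairs = min(len(order[0]), len(order[1]))
        if len(order[0]) != len(order[1]):
            log.info("dropping %d unpaired trailing train(s)", abs(len(order[0]) - len(order[1])))
        light_idx = order[0][:n_pairs]
        dark_idx = order[1][:n_pairs]
        if pairing == "shuffled":
            if rng is None:
                raise ValueError("shuffled pairing requires an rng")
            dark_idx = rng.permutation(dark_idx)
        deltas = _norm(series.profiles[light_idx]) - _norm(series.profiles[dark_idx])
        delta = deltas.mean(axis=0)
    else:
        raise ValueError(f"unknown pairing strategy {pairing!r}")

    n_light_frames = int(series.light_flag.sum()) * series.profiles.shape[1]
    return DifferenceSeries(
        q=series.q,
        time_us=series.time_us.copy(),
        delta_S=delta.T,
        n_light_frames=n_light_frames,
        provenance={"pairing": pairing, "normalize_window": normalize},
    )


def merge_concentrations(ds_high: DifferenceSeries, ds_low: DifferenceSeries) -> DifferenceSeries:
    """Scale-and-offset align the low-concentration set, then weighted-average.

    The scalar pair (a, b) minimizing ``sum (a dS_low + b - dS_high)^2`` aligns
    the low set to the high one; the merge weights are the numbers of light
    frames in each dataset.
    """
    if len(ds_high.q) != len(ds_low.q) or not np.allclose(ds_high.q.values, ds_low.q.values):
        raise ValueError("q grids differ; cannot merge")
    if ds_high.delta_S.shape != ds_low.delta_S.shape or not np.allclose(
        ds_high.time_us, ds_low.time_us
    ):
        raise ValueError("time grids differ; cannot merge")
    x = ds_low.delta_S.ravel()
    ymat = np.column_stack([x, np.ones_like(x)])
    (a, b), *_ = np.linalg.lstsq(ymat, ds_high.delta_S.ravel(), rcond=None)
    aligned = a * ds_low.delta_S + b
    w_h, w_l = ds_high.n_light_frames, ds_low.n_light_frames
    merged = (w_h * ds_high.delta_S + w_l * aligned) / (w_h + w_l)
    return DifferenceSeries(
        q=ds_high.q,
        time_us=ds_high.time_us.copy(),
        delta_S=merged,
        n_light_frames=w_h + w_l,
        provenance={
            "merge": {"scale_a": float(a), "offset_b": float(b), "weights": (w_h, w_l)},
            "high": ds_high.provenance,
            "low": ds_low.provenance,
        },
    )
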