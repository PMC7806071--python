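"""Cross-partner reconstruction-error traces and the slope synchrony statistic.

For each dyad, the autoencoder trained on speaker A reconstructs speaker
B's frames in order (and vice versa), yielding two per-frame RMSE traces.
A linear trend fitted to each trace over session-normalized time is the
synchrony statistic: a negative slope means the test speaker's features
reconstruct increasingly well under the partner's model, i.e. the partners'
acoustic distributions are converging. Group-level aggregation reports the
mean slope over all subjects in a group and the Pearson correlation of the
two partners' slopes across the group's sessions (positive: partners move
together; negative: one partner dominates the adaptation).

Slopes are expressed per unit *normalized* session time (t in [0, 1]), so
the statistic is invariant to session length; magnitudes are therefore not
directly comparable to analyses that regress on raw seconds or frame index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .autoencoder import TrainedAutoencoder, TrainingConfig, default_architecture, reconstruct, train_autoencoder
from .features_io import FeatureSequence
from .segmentation import DyadSession

SlopeMethod = Literal["ols", "mean_first_difference"]


class DegenerateRegressionError(ValueError):
    """Slope is undefined (constant time axis or < 2 frames)."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (zero variance or < 2 observations)."""


@dataclass
class ReconstructionTrace:
    """Per-frame RMSE of one test speaker under the partner-trained model."""

    rmse: np.ndarray
    times: np.ndarray
    test_speaker_id: str = ""
    model_speaker_id: str = ""

    def __post_init__(self) -> None:
        self.rmse = np.asarray(self.rmse, dtype=np.float64).ravel()
        self.times = np.asarray(self.times, dtype=np.float64).ravel()
        if self.rmse.shape != self.times.shape:
            raise ValueError("rmse and times must have equal length")
        if np.any(self.rmse < 0):
            raise ValueError("rmse values must be non-negative")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.rmse)

    def smoothed(self, window: int) -> "ReconstructionTrace":
        """Centered moving average (exploratory; off by default in pipelines)."""
        if window < 1:
            raise ValueError("window must be >= 1")
        kernel = np.ones(window) / window
        sm = np.convolve(self.rmse, kernel, mode="same")
        return ReconstructionTrace(sm, self.times, self.test_speaker_id, self.model_speaker_id)


@dataclass(frozen=True)
class SlopeResult:
    """Fitted linear trend of an RMSE trace over normalized session time."""

    slope: float
    method: str
    intercept: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")


@dataclass(frozen=True)
class GroupSummary:
    """Per-group aggregate: mean subject slope and PCC of partner slope pairs."""

    group_id: str
    average_slope: float
    pcc_of_pairs: float  # NaN when n_sessions < 2
    n_sessions: int


def frame_rmse(
    original: FeatureSequence,
    reconstructed: FeatureSequence,
    test_speaker_id: str = "",
    model_speaker_id: str = "",
) -> ReconstructionTrace:
    """Per-frame RMSE across dimensions between original and reconstruction."""
    if original.values.shape != reconstructed.values.shape:
        raise ValueError(
            f"shape mismatch: {original.values.shape} vs {reconstructed.values.shape}"
        )
    diff = original.values - reconstructed.values
    rmse = np.sqrt(np.mean(diff * diff, axis=1))
    return ReconstructionTrace(rmse, original.times, test_speaker_id, model_speaker_id)


def _normalized_times(times: np.ndarray) -> np.ndarray:
    span = times[-1] - times[0]
    if span <= 0:
        raise DegenerateRegressionError("constant time axis: slope undefined")
    return (times - times[0]) / span


def fit_slope(trace: ReconstructionTrace, method: SlopeMethod = "ols") -> SlopeResult:
    """Fit the trend of an RMSE trace over session-normalized time.

    ``"ols"`` (default) is ordinary least squares of rmse against
    t in [0, 1]. ``"mean_first_difference"`` averages consecutive rmse
    differences — for evenly spaced frames this telescopes to
    ``(rmse[-1] - rmse[0]) / (n - 1)`` per frame step, and is rescaled here
    to the same normalized-time axis (where it equals ``rmse[-1] - rmse[0]``).
    """
    y = trace.rmse
    if len(y) < 2:
        raise DegenerateRegressionError("need >= 2 frames to fit a slope")
    t = _normalized_times(trace.times)
    if method == "ols":
        tc = t - t.mean()
        yc = y - y.mean()
        slope = float(tc @ yc / (tc @ tc))
        intercept = float(y.mean() - slope * t.mean())
        return SlopeResult(slope=slope, method="ols", intercept=intercept)
    if method == "mean_first_difference":
        # mean of consecutive differences telescopes exactly to the endpoints;
        # dividing by the mean normalized step (1/(n-1) when evenly spaced)
        # re-expresses it per unit normalized time.
        per_step = (y[-1] - y[0]) / (len(y) - 1)
        mean_dt = 1.0 / (len(y) - 1)
        return SlopeResult(slope=float(per_step / mean_dt), method="mean_first_difference")
    raise ValueError(f"unknown slope method {method!r}")


def mean_first_difference_per_step(trace: ReconstructionTrace) -> float:
    """Mean consecutive rmse difference per frame step (telescoped form)."""
    y = trace.rmse
    if len(y) < 2:
        raise DegenerateRegressionError("need >= 2 frames")
    return float((y[-1] - y[0]) / (len(y) - 1))


@dataclass
class SessionAnalysis:
    """Full per-session result: traces, slopes and the trained models."""

    session: DyadSession
    ae_a: TrainedAutoencoder
    ae_b: TrainedAutoencoder
    trace_b_under_a: ReconstructionTrace
    trace_a_under_b: ReconstructionTrace
    slope_b_under_a: SlopeResult
    slope_a_under_b: SlopeResult

    @property
    def slope_pair(self) -> tuple[float, float]:
        """(slope of A's trace, slope of B's trace) — subject order A, B."""
        return self.slope_a_under_b.slope, self.slope_b_under_a.slope


def analyse_session(
    session: DyadSession,
    cfg: TrainingConfig = TrainingConfig(),
    slope_method: SlopeMethod = "ols",
    smoothing_window: Optional[int] = None,
) -> SessionAnalysis:
    """Train the two partner autoencoders and fit both cross-partner slopes.

    AE_A is trained on speaker A's frames and evaluated on B's (and vice
    versa); both RMSE traces keep the original frame times. The two models'
    seeds are derived from ``cfg.seed`` so the partners are trained
    independently but reproducibly.
    """
    fa, fb = session.features_a, session.features_b
    for name, f in (("a", fa), ("b", fb)):
        if f.n_frames < 2:
            raise ValueError(f"speaker {name} has fewer than 2 frames")
    arch = default_architecture(fa.n_dims)
    cfg_a = replace(cfg, seed=cfg.seed * 2)
    cfg_b = replace(cfg, seed=cfg.seed * 2 + 1)
    ae_a = train_autoencoder(fa, arch, cfg_a)
    ae_b = train_autoencoder(fb, arch, cfg_b)
    trace_b = frame_rmse(fb, reconstruct(ae_a, fb), session.speaker_b_id, session.speaker_a_id)
    trace_a = frame_rmse(fa, reconstruct(ae_b, fa), session.speaker_a_id, session.speaker_b_id)
    if smoothing_window:
        trace_b = trace_b.smoothed(smoothing_window)
        trace_a = trace_a.smoothed(smoothing_window)
    return SessionAnalysis(
        session=session,
        ae_a=ae_a,
        ae_b=ae_b,
        trace_b_under_a=trace_b,
        trace_a_under_b=trace_a,
        slope_b_under_a=fit_slope(trace_b, slope_method),
        slope_a_under_b=fit_slope(trace_a, slope_method),
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on zero variance or length < 2."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d of equal length")
    if len(x) < 2:
        raise UndefinedCorrelationError("need >= 2 observations")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    return float(np.clip(xc @ yc / denom, -1.0, 1.0))


def summarize_group(
    group_id: str,
    session_slopes: Sequence[tuple[float, float]],
    require_pcc: bool = False,
) -> GroupSummary:
    """Aggregate a group's per-session (slope_A, slope_B) pairs.

    ``average_slope`` is the mean over all 2n individual subject slopes;
    ``pcc_of_pairs`` correlates partner slopes across sessions (NaN with a
    warning for a single session unless ``require_pcc`` forces the error).
    """
    if not session_slopes:
        raise ValueError("need at least one session")
    pairs = np.asarray(session_slopes, dtype=np.float64)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("session_slopes must be (n_sessions, 2)")
    avg = float(pairs.mean())
    if len(pairs) >= 2:
        pcc = pearson_correlation(pairs[:, 0], pairs[:, 1])
    elif require_pcc:
        raise UndefinedCorrelationError("PCC of pairs requires >= 2 sessions")
    else:
        warnings.warn(f"group {group_id!r}: PCC undefined with a single session")
        pcc = float("nan")
    return GroupSummary(
        group_id=group_id, average_slope=avg, pcc_of_pairs=pcc, n_sessions=len(pairs)
    )
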