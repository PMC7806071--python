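"""Frame-level feature tables: reading, standardization, delta augmentation.

Acoustic analyses of conversational speech typically start from per-frame
low-level descriptors (LLDs) sampled every 10 ms — e.g. the 65-dimensional
ComParE set, augmented to 130 dimensions with first-order deltas — or from
high-dimensional embeddings of Mel-spectrogram excerpts (4,096-dim "Deep
Spectrum" vectors from a pretrained image CNN). This module consumes such
tables from delimited text or openSMILE ARFF output, standardizes them per
recording, appends deltas, and provides the Mel-spectrogram utility plus a
pluggable embedding-backend contract. LLD extraction itself and CNN weights
are out of scope: feature tables arrive precomputed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.fft
import scipy.signal

#: Dimensions whose per-recording standard deviation falls below this are
#: mapped to all-zeros instead of being divided by a near-zero sigma.
DEGENERATE_SIGMA = 1e-8

#: Additive floor inside the log so silent frames land on a finite value.
LOG_POWER_FLOOR = 1e-10

COMPARE_LLDS = "compare_llds"
DEEP_SPECTRUM = "deep_spectrum"


class FeatureTableError(ValueError):
    """Malformed feature table (ragged rows, non-numeric cells, empty file)."""


class InsufficientDataError(ValueError):
    """Input too short for the requested operation."""


@dataclass
class FeatureSequence:
    """Time-ordered matrix of per-frame feature vectors.

    Frame ``i`` covers the half-open interval
    ``[start_time + i*frame_step, start_time + (i+1)*frame_step)``.
    """

    values: np.ndarray  # (n_frames, n_dims), float64
    frame_step: float = 0.010
    start_time: float = 0.0
    feature_set_name: str = "unknown"
    dim_names: Optional[list[str]] = None
    #: Per-frame start times in seconds. Regular by default; after speaker
    #: splitting they retain the original recording times (irregular).
    times: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.size == 0:
            raise InsufficientDataError("feature sequence must have >= 1 frame and dim")
        if not np.all(np.isfinite(self.values)):
            raise FeatureTableError("feature values must be finite")
        if self.frame_step <= 0:
            raise ValueError("frame_step must be positive")
        if self.times is None:
            self.times = self.start_time + self.frame_step * np.arange(self.n_frames)
        else:
            self.times = np.asarray(self.times, dtype=np.float64)
            if self.times.shape != (self.n_frames,):
                raise ValueError("times length must equal n_frames")
        if self.dim_names is not None and len(self.dim_names) != self.n_dims:
            raise ValueError("dim_names length must equal n_dims")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, dim_names: Optional[list[str]] = None) -> "FeatureSequence":
        """Copy of this sequence with new values but identical timing metadata."""
        return FeatureSequence(
            values=values,
            frame_step=self.frame_step,
            start_time=self.start_time,
            feature_set_name=self.feature_set_name,
            dim_names=dim_names,
            times=self.times.copy(),
        )


@dataclass(frozen=True)
class SpectrogramConfig:
    """Short-time Mel-spectrogram parameters.

    The default hop of 10 ms with a 500 ms Hann window (490 ms overlap)
    matches the 10 ms LLD frame rate; set ``hop_seconds=0.49`` for a literal
    10 ms overlap between consecutive windows.
    """

    window_seconds: float = 0.5
    hop_seconds: float = 0.010
    n_mel_bands: int = 128
    window_function: str = "hann"

    def __post_init__(self) -> None:
        if not (self.window_seconds > self.hop_seconds > 0):
            raise ValueError("require window_seconds > hop_seconds > 0")
        if self.n_mel_bands < 1:
            raise ValueError("n_mel_bands must be >= 1")


@dataclass
class EmbeddingBackend:
    """Contract for mapping a spectrogram excerpt to a fixed-length vector.

    The reference backend (penultimate fully-connected layer of a pretrained
    VGG16, output_dim=4096) is not shipped; any deterministic callable with a
    constant output dimension satisfies the contract.
    """

    embed: Callable[[np.ndarray], np.ndarray]
    output_dim: int

    def __call__(self, spectrogram: np.ndarray) -> np.ndarray:
        out = np.asarray(self.embed(spectrogram), dtype=np.float64)
        if out.shape != (self.output_dim,):
            raise ValueError(
                f"backend returned shape {out.shape}, expected ({self.output_dim},)"
            )
        return out


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _parse_delimited(text: str, path: str) -> tuple[np.ndarray, Optional[list[str]]]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise InsufficientDataError(f"{path}: empty feature table")
    delim = "\t" if "\t" in lines[0] else (";" if ";" in lines[0] and "," not in lines[0] else ",")
    rows = [ln.split(delim) for ln in lines]

    def _numeric(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    names: Optional[list[str]] = None
    if not all(_numeric(c) for c in rows[0]):
        names = [c.strip().strip('"') for c in rows[0]]
        rows = rows[1:]
        if not rows:
            raise InsufficientDataError(f"{path}: header but no data rows")

    width = len(rows[0])
    data = np.empty((len(rows), width), dtype=np.float64)
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FeatureTableError(
                f"{path}: ragged row {i}: {len(row)} fields, expected {width}"
            )
        for j, cell in enumerate(row):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise FeatureTableError(
                    f"{path}: non-numeric cell at row {i}, column {j}: {cell!r}"
                ) from None
    return data, names


def _parse_arff(text: str, path: str) -> tuple[np.ndarray, Optional[list[str]]]:
    """openSMILE-style ARFF: @attribute declarations, then the @data section."""
    attr_names: list[str] = []
    numeric_cols: list[int] = []
    data_lines: list[str] = []
    in_data = False
    for ln in text.splitlines():
        s = ln.strip()
        if not s or s.startswith("%"):
            continue
        low = s.lower()
        if low.startswith("@attribute"):
            parts = s.split(None, 2)
            if len(parts) >= 3:
                if parts[2].strip().lower() in ("numeric", "real", "integer"):
                    numeric_cols.append(len(attr_names))
                attr_names.append(parts[1])
        elif low.startswith("@data"):
            in_data = True
        elif in_data:
            data_lines.append(s)
    if not data_lines:
        raise InsufficientDataError(f"{path}: ARFF file has no data rows")
    data, _ = _parse_delimited_mixed(data_lines, numeric_cols, path)
    names = [attr_names[c] for c in numeric_cols]
    return data, names


def _parse_delimited_mixed(lines: list[str], keep_cols: list[int], path: str) -> tuple[np.ndarray, None]:
    out = np.empty((len(lines), len(keep_cols)), dtype=np.float64)
    for i, ln in enumerate(lines):
        cells = ln.split(",")
        for k, c in enumerate(keep_cols):
            try:
                out[i, k] = float(cells[c])
            except (ValueError, IndexError):
                raise FeatureTableError(
                    f"{path}: bad numeric cell at data row {i}, column {c}"
                ) from None
    return out, None


def read_feature_table(
    path: str | Path,
    frame_step: float = 0.010,
    feature_set_name: str = "unknown",
    start_time: float = 0.0,
) -> FeatureSequence:
    """Read a delimited numeric table (or openSMILE ARFF), one row per frame.

    Comma- and tab-delimited text with an optional single header row is
    accepted; ARFF files contribute their numeric ``@attribute`` columns, with
    attribute names recorded as dimension names.
    """
    path = Path(path)
    text = path.read_text()
    if "@data" in text.lower() and "@attribute" in text.lower():
        data, names = _parse_arff(text, str(path))
    else:
        data, names = _parse_delimited(text, str(path))
    return FeatureSequence(
        values=data,
        frame_step=frame_step,
        start_time=start_time,
        feature_set_name=feature_set_name,
        dim_names=names,
    )


def write_feature_table(seq: FeatureSequence, path: str | Path, fmt: str = "%.8g") -> None:
    """Write a sequence as a comma-delimited table (round-trips via read)."""
    path = Path(path)
    buf = io.StringIO()
    if seq.dim_names is not None:
        buf.write(",".join(seq.dim_names) + "\n")
    np.savetxt(buf, seq.values, fmt=fmt, delimiter=",")
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Standardization and deltas
# ---------------------------------------------------------------------------

def standardize_per_recording(seq: FeatureSequence) -> FeatureSequence:
    """Zero-mean, unit-sd scale each dimension across the recording's frames.

    Uses the population (1/N) standard deviation. Dimensions with sigma below
    ``DEGENERATE_SIGMA`` are mapped to all-zeros. Recording-level (rather than
    corpus-level) scaling removes static channel/environment differences
    between recordings while preserving within-recording dynamics.
    """
    if seq.n_frames < 2:
        raise InsufficientDataError("standardization requires >= 2 frames")
    if seq.feature_set_name == DEEP_SPECTRUM:
        raise ValueError(
            "deep_spectrum features are used raw: standardization is disabled "
            "for this feature set"
        )
    mu = seq.values.mean(axis=0)
    sigma = seq.values.std(axis=0)  # population estimator
    out = np.where(sigma < DEGENERATE_SIGMA, 0.0, (seq.values - mu) / np.where(sigma < DEGENERATE_SIGMA, 1.0, sigma))
    return seq.with_values(out, dim_names=seq.dim_names)


def append_deltas(seq: FeatureSequence) -> FeatureSequence:
    """Append first-order frame differences, doubling the dimensionality.

    ``delta[i] = x[i] - x[i-1]`` with ``delta[0] = 0``; a 65-dim LLD table
    becomes the standard 130-dim delta-augmented representation. This is the
    plain first difference, not a regression-window delta, so tables already
    delta-augmented upstream should skip this step.
    """
    deltas = np.zeros_like(seq.values)
    deltas[1:] = np.diff(seq.values, axis=0)
    names = None
    if seq.dim_names is not None:
        names = seq.dim_names + [f"delta_{n}" for n in seq.dim_names]
    return seq.with_values(np.hstack([seq.values, deltas]), dim_names=names)


# ---------------------------------------------------------------------------
# Mel spectrogram
# ---------------------------------------------------------------------------

def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_bands: int, n_fft: int, sample_rate: float) -> np.ndarray:
    """Triangular Mel filters (HTK scale) over the one-sided DFT bins."""
    f_max = sample_rate / 2.0
    mel_pts = np.linspace(0.0, _hz_to_mel(f_max), n_bands + 2)
    hz_pts = np.asarray(_mel_to_hz(mel_pts))
    bin_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    fb = np.zeros((n_bands, len(bin_freqs)))
    for b in range(n_bands):
        lo, ctr, hi = hz_pts[b], hz_pts[b + 1], hz_pts[b + 2]
        up = (bin_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - bin_freqs) / max(hi - ctr, 1e-12)
        fb[b] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mel_band_center_frequencies(n_bands: int, sample_rate: float) -> np.ndarray:
    """Center frequency (Hz) of each triangular Mel filter."""
    mel_pts = np.linspace(0.0, _hz_to_mel(sample_rate / 2.0), n_bands + 2)
    return np.asarray(_mel_to_hz(mel_pts))[1:-1]


def mel_spectrogram(
    samples: Sequence[float] | np.ndarray,
    sample_rate: float,
    cfg: SpectrogramConfig = SpectrogramConfig(),
) -> np.ndarray:
    """Log-power Mel spectrogram, shape ``(n_windows, n_mel_bands)``.

    Windows of ``window_seconds`` are placed every ``hop_seconds``;
    ``n_windows = floor((n_samples - window) / hop) + 1``. Each window's
    power spectrum is pooled through triangular Mel filters and log10-scaled
    with an additive floor so silence maps to a finite constant.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    win_len = int(round(cfg.window_seconds * sample_rate))
    hop = int(round(cfg.hop_seconds * sample_rate))
    if hop < 1 or win_len < 2:
        raise ValueError("window/hop too small for this sample rate")
    if len(x) < win_len:
        raise InsufficientDataError(
            f"signal of {len(x)} samples shorter than one window ({win_len})"
        )
    n_windows = (len(x) - win_len) // hop + 1
    window = scipy.signal.get_window(cfg.window_function, win_len, fftbins=True)
    fb = mel_filterbank(cfg.n_mel_bands, win_len, sample_rate)
    out = np.empty((n_windows, cfg.n_mel_bands))
    for w in range(n_windows):
        seg = x[w * hop : w * hop + win_len] * window
        spec = np.abs(scipy.fft.rfft(seg)) ** 2
        out[w] = np.log10(fb @ spec + LOG_POWER_FLOOR)
    return out


def read_wav_mono(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file as float64 in [-1, 1]; stereo is averaged to mono."""
    import scipy.io.wavfile

    rate, data = scipy.io.wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(np.float64), int(rate)
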