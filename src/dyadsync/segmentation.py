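"""Split a recording's frame stream into per-speaker subsequences.

A dyadic recording carries one interleaved feature stream for two speakers.
The speaker-labeled, time-stamped turns of the transcript attribute each
10 ms frame to the speaker whose turn interval contains the frame's start
time; frames in silence belong to nobody and frames inside overlapping turns
are dropped by default (the cleanest attribution when each speaker's frames
train that speaker's autoencoder).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np

from .features_io import FeatureSequence

OverlapPolicy = Literal["drop", "both"]


class TranscriptFormatError(ValueError):
    """Transcript violates the two-speaker, sorted-turn contract."""


class EmptySubsequenceError(ValueError):
    """A speaker received zero frames after splitting."""


@dataclass(frozen=True)
class Turn:
    """One speaker turn: half-open interval [start, end) in seconds."""

    speaker_id: str
    start: float
    end: float
    text: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise TranscriptFormatError(
                f"turn for {self.speaker_id!r} must satisfy 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )


@dataclass
class Transcript:
    """Ordered speaker turns of one session; exactly two distinct speakers."""

    turns: list[Turn]
    session_id: str = ""

    def __post_init__(self) -> None:
        if not self.turns:
            raise TranscriptFormatError("transcript has no turns")
        self.turns = sorted(self.turns, key=lambda t: (t.start, t.end))
        if len(self.speaker_ids) != 2:
            raise TranscriptFormatError(
                f"transcript must have exactly two speakers, got {self.speaker_ids}"
            )

    @property
    def speaker_ids(self) -> list[str]:
        """Distinct speakers in order of first appearance."""
        seen: list[str] = []
        for t in self.turns:
            if t.speaker_id not in seen:
                seen.append(t.speaker_id)
        return seen

    @property
    def span(self) -> tuple[float, float]:
        return self.turns[0].start, max(t.end for t in self.turns)


@dataclass
class DyadSession:
    """One dyadic recording: two speakers with their feature subsequences."""

    session_id: str
    group_id: str
    speaker_a_id: str
    speaker_b_id: str
    features_a: FeatureSequence
    features_b: FeatureSequence
    transcript: Optional[Transcript] = field(default=None, repr=False)


def split_by_speaker(
    seq: FeatureSequence,
    transcript: Transcript,
    overlap_policy: OverlapPolicy = "drop",
) -> tuple[FeatureSequence, FeatureSequence]:
    """Assign frames to the two speakers by turn intervals.

    Frame ``i`` goes to a speaker iff its start time lies inside one of that
    speaker's ``[start, end)`` turn intervals. Under ``"drop"`` a frame
    claimed by both speakers (overlapping speech) is excluded from both;
    under ``"both"`` it is kept in both subsequences. Within-speaker frame
    order and original frame times are preserved.

    Returns the subsequences in transcript speaker order (first-appearing
    speaker first). Raises :class:`EmptySubsequenceError` if a speaker ends
    with no frames.
    """
    spk_a, spk_b = transcript.speaker_ids
    t = seq.times
    in_a = np.zeros(seq.n_frames, dtype=bool)
    in_b = np.zeros(seq.n_frames, dtype=bool)
    for turn in transcript.turns:
        mask = (t >= turn.start) & (t < turn.end)
        if turn.speaker_id == spk_a:
            in_a |= mask
        else:
            in_b |= mask
    if overlap_policy == "drop":
        both = in_a & in_b
        in_a &= ~both
        in_b &= ~both
    elif overlap_policy != "both":
        raise ValueError(f"unknown overlap policy {overlap_policy!r}")

    out = []
    for spk, mask in ((spk_a, in_a), (spk_b, in_b)):
        if not mask.any():
            raise EmptySubsequenceError(f"speaker {spk!r} has zero frames after splitting")
        out.append(
            FeatureSequence(
                values=seq.values[mask],
                frame_step=seq.frame_step,
                start_time=float(t[mask][0]),
                feature_set_name=seq.feature_set_name,
                dim_names=seq.dim_names,
                times=t[mask],
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Transcript I/O: tab-delimited session_id, speaker_id, start, end, text
# ---------------------------------------------------------------------------

TRANSCRIPT_COLUMNS = ("session_id", "speaker_id", "start", "end", "text")


def read_transcript(path: str | Path) -> Transcript:
    """Read a tab-delimited transcript (five columns, optional header)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise TranscriptFormatError(f"{path}: empty transcript")
    if lines[0].split("\t")[0].strip() == "session_id":
        lines = lines[1:]
    turns: list[Turn] = []
    session_id = ""
    for i, ln in enumerate(lines):
        cells = ln.split("\t")
        if len(cells) < 4:
            raise TranscriptFormatError(f"{path}: row {i} has {len(cells)} fields, expected 5")
        session_id = cells[0]
        text = cells[4] if len(cells) > 4 else ""
        try:
            turns.append(Turn(cells[1], float(cells[2]), float(cells[3]), text))
        except ValueError as exc:
            raise TranscriptFormatError(f"{path}: row {i}: {exc}") from None
    return Transcript(turns=turns, session_id=session_id)


def write_transcript(transcript: Transcript, path: str | Path) -> None:
    rows = ["\t".join(TRANSCRIPT_COLUMNS)]
    for t in transcript.turns:
        rows.append(
            f"{transcript.session_id}\t{t.speaker_id}\t{t.start:.3f}\t{t.end:.3f}\t{t.text}"
        )
    Path(path).write_text("\n".join(rows) + "\n")
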