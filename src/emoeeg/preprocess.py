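"""Raw-recording preprocessing: re-referencing, band decomposition, segmentation.

The experimental protocol modelled here presents blocks of emotional
pictures (three categories: HVLA, LVLA, LVHA — high/low valence crossed
with low/high arousal) while midline EEG (Fz, Cz, Pz, earlobe references
A1/A2) is recorded at 256 Hz.  Each stimulation unit shows five pictures
for 3 s each (15 s) and is followed by 10 s of rest; every emotion
category appears three times, giving nine units and a 225-s session.

Analysis proceeds per frequency band: the classical θ/α bands plus a
three-way split of β (β1 12–15, β2 15–18, β3 18–30 Hz), each isolated
with a Butterworth band-pass applied forward–backward (zero phase, so
fragment boundaries are not smeared by filter delay).  The band-limited
signal is then cut into the nine 15-s stimulation fragments; rest
periods are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "EMOTIONS",
    "DEFAULT_BANDS",
    "REFERENCE_LABELS",
    "RawRecording",
    "BandDefinition",
    "StimulusBlock",
    "StimulusTimeline",
    "Fragment",
    "rereference",
    "design_paper_timeline",
    "bandpass",
    "segment",
]

EMOTIONS = ("HVLA", "LVLA", "LVHA")
REFERENCE_LABELS = ("A1", "A2")


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz (0 < low < high)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise PreprocessError(f"invalid band edges {self.low}-{self.high} Hz")

    @property
    def center(self) -> float:
        """Geometric-mean center frequency in Hz."""
        return float(np.sqrt(self.low * self.high))


DEFAULT_BANDS = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta1", 12.0, 15.0),
    BandDefinition("beta2", 15.0, 18.0),
    BandDefinition("beta3", 18.0, 30.0),
)


@dataclass
class RawRecording:
    """Labelled multichannel recording (µV) at a common sampling rate."""

    channels: dict[str, np.ndarray]
    fs: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise PreprocessError(f"sampling rate must be positive, got {self.fs}")
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise PreprocessError(f"channels differ in length: {lengths}")
        self.channels = {
            k: np.asarray(v, dtype=np.float64) for k, v in self.channels.items()
        }

    @property
    def n_samples(self) -> int:
        return 0 if not self.channels else len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def scalp_labels(self) -> tuple[str, ...]:
        return tuple(k for k in self.channels if k not in REFERENCE_LABELS)


@dataclass(frozen=True)
class StimulusBlock:
    """One 5-picture stimulation unit of a single emotion category."""

    emotion: str
    onset: float       # s from session start
    duration: float    # s
    section: int       # 1-based repetition index of this emotion


@dataclass(frozen=True)
class StimulusTimeline:
    blocks: tuple[StimulusBlock, ...]
    total_duration: float

    def __post_init__(self) -> None:
        prev_end = 0.0
        for b in self.blocks:
            if b.onset < prev_end - 1e-9:
                raise PreprocessError("timeline blocks overlap or are out of order")
            prev_end = b.onset + b.duration


@dataclass(frozen=True)
class Fragment:
    """One band-limited 15-s stimulation excerpt of one electrode."""

    subject_id: str
    electrode: str
    emotion: str
    section: int
    band: str  # band name or "broadband"
    samples: np.ndarray = field(repr=False)


def design_paper_timeline() -> StimulusTimeline:
    """The default 225-s session timeline.

    Nine 15-s stimulation units (five 3-s pictures each), each followed
    by 10 s of rest; the emotion order HVLA, LVLA, LVHA repeats three
    times, and the section number counts each emotion's occurrences.
    Block onsets therefore fall at 0, 25, 50, …, 200 s.
    """
    blocks = []
    for rep in range(3):
        for k, emotion in enumerate(EMOTIONS):
            onset = (rep * 3 + k) * 25.0
            blocks.append(StimulusBlock(emotion, onset, 15.0, rep + 1))
    return StimulusTimeline(tuple(blocks), 225.0)


def rereference(
    recording: RawRecording,
    scheme: Literal["A1", "A2", "linked_ears"] = "linked_ears",
) -> RawRecording:
    """Subtract an earlobe reference from every scalp channel.

    ``"A1"`` and ``"A2"`` use the single earlobe, ``"linked_ears"`` the
    average (A1 + A2)/2.  Reference channels are dropped from the output.
    """
    if scheme == "linked_ears":
        needed = ("A1", "A2")
    elif scheme in ("A1", "A2"):
        needed = (scheme,)
    else:
        raise PreprocessError(f"unknown reference scheme {scheme!r}")
    missing = [ch for ch in needed if ch not in recording.channels]
    if missing:
        raise PreprocessError(
            f"reference scheme {scheme!r} needs channel(s) {missing}; "
            f"available: {sorted(recording.channels)}"
        )
    ref = sum(recording.channels[ch] for ch in needed) / len(needed)
    out = {
        label: sig - ref
        for label, sig in recording.channels.items()
        if label not in REFERENCE_LABELS
    }
    return RawRecording(out, recording.fs, recording.subject_id)


def bandpass(
    signal: Sequence[float] | np.ndarray,
    fs: float,
    band: BandDefinition,
    order: int = 6,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the given total order.

    ``order`` is the order of the band-pass transfer function (so an
    order-6 band-pass has three conjugate pole pairs per edge and must be
    even).  The filter is applied forward and backward (``sosfiltfilt``),
    which cancels phase distortion and doubles the effective roll-off.
    """
    x = np.asarray(signal, dtype=np.float64)
    if band.high >= fs / 2:
        raise PreprocessError(
            f"band edge {band.high} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    if order < 2 or order % 2:
        raise PreprocessError(f"band-pass order must be a positive even number, got {order}")
    if x.size <= 3 * order:
        raise PreprocessError(
            f"signal too short ({x.size} samples) for an order-{order} filter"
        )
    sos = butter(order // 2, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def _block_slice(block: StimulusBlock, fs: float) -> slice:
    # Half-open [onset, onset + duration) in samples, 0-based.
    start = int(round(block.onset * fs))
    stop = int(round((block.onset + block.duration) * fs))
    return slice(start, stop)


def segment(
    recording: RawRecording,
    timeline: StimulusTimeline,
    bands: Iterable[BandDefinition | None] = DEFAULT_BANDS,
    filter_order: int = 6,
    artifact_mask: np.ndarray | None = None,
) -> list[Fragment]:
    """Cut a (re-referenced) recording into per-band stimulation fragments.

    Every scalp electrode is band-filtered over the full recording and
    then sliced at the timeline's stimulation blocks; rest periods are
    excluded.  ``None`` in ``bands`` yields unfiltered "broadband"
    fragments.  ``artifact_mask`` (boolean, one entry per sample, True =
    keep) lets a caller blank externally detected artifacts; masked
    samples are set to NaN so downstream feature code rejects them
    explicitly rather than silently absorbing them.

    Returns electrodes × bands × blocks fragments.
    """
    if recording.duration < timeline.total_duration - 1e-9:
        raise PreprocessError(
            f"recording lasts {recording.duration:.2f} s but the timeline "
            f"needs {timeline.total_duration:.2f} s"
        )
    if artifact_mask is not None and len(artifact_mask) != recording.n_samples:
        raise PreprocessError("artifact mask length does not match the recording")
    fragments: list[Fragment] = []
    for electrode in recording.scalp_labels:
        raw = recording.channels[electrode]
        if artifact_mask is not None:
            raw = np.where(artifact_mask, raw, np.nan)
        for band in bands:
            if band is None:
                filtered, band_name = raw, "broadband"
            else:
                filtered, band_name = bandpass(raw, recording.fs, band, filter_order), band.name
            for block in timeline.blocks:
                fragments.append(
                    Fragment(
                        recording.subject_id,
                        electrode,
                        block.emotion,
                        block.section,
                        band_name,
                        filtered[_block_slice(block, recording.fs)],
                    )
                )
    return fragments
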