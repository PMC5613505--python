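"""Synthetic emotion-session EEG cohorts with a planted severity effect.

No public dataset exists for the protocol this package analyses, so the
generator manufactures cohorts carrying exactly the statistical
structure the downstream analysis is supposed to detect:

* 10 controls, 17 moderately ill and 17 markedly ill subjects by
  default, each with a 225-s five-channel session (Fz, Cz, Pz plus
  earlobe references A1/A2) at 256 Hz following the default stimulus
  timeline;
* each scalp signal is a sum over the five analysis bands of band
  processes; a band process is a mixture of band-filtered white Gaussian
  noise (irregular) and a sinusoid at the band's geometric center
  (regular), weighted by a noise-mixing fraction c in [0, 1].  ApEn/PE
  of the band fragment increase monotonically in c — approximately
  linearly in ln c until saturating above c ≈ 0.5 — so c is the
  generator's "complexity" knob without pretending to model cortical
  physiology;
* the markedly ill group's c in β1/β2 is raised by ``beta_effect``, and
  its subject-to-subject complexity spread is narrower, mirroring the
  published group summaries (marked ≈ 0.61 with small SD vs moderate
  ≈ 0.54 with large SD for β2 Fz ApEn);
* each patient's PANSS total is coupled to the latent complexity
  deviation that drives their β-band entropy, so that the pooled
  entropy–PANSS correlation lands near the published r ≈ 0.55.

Everything is deterministic given the master seed: per-subject integer
seeds are derived by ``numpy.random.SeedSequence(master).generate_state``
(a stable, documented splitting rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .preprocess import (
    DEFAULT_BANDS,
    BandDefinition,
    RawRecording,
    StimulusTimeline,
    design_paper_timeline,
)
from .reference import PANSS_GROUP_PARAMS, REFERENCE_BETA_CORRELATION
from .stats import GROUPS, SubjectMetadata

__all__ = ["CohortSpec", "SyntheticCohort", "generate_subject", "generate_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters of a synthetic cohort.

    ``complexity_base`` gives each band's noise-mixing fraction c;
    ``beta_effect`` is added to c in the ``effect_bands`` for the
    markedly ill group.  Subject-level variation multiplies c by a
    log-normal factor: ``complexity_sd`` (log scale, identical across
    groups, so a zero ``beta_effect`` leaves the groups exchangeable) in
    the effect bands — driven by the subject's severity latent — and
    ``band_jitter_sd`` elsewhere (independent noise).  The saturating
    entropy response to c turns the common log spread into a wide
    entropy spread for the moderate group and a narrow one for the
    marked group, as in the published summaries.  ``panss_coupling``
    is the within-group correlation between the severity latent and the
    PANSS total, calibrated so the pooled feature–PANSS correlation
    matches ``r_target`` under the default complexity settings.
    """

    n_normal: int = 10
    n_moderate: int = 17
    n_marked: int = 17
    fs: float = 256.0
    electrodes: tuple[str, ...] = ("Fz", "Cz", "Pz", "A1", "A2")
    timeline: StimulusTimeline = field(default_factory=design_paper_timeline)
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    band_power: Mapping[str, float] = field(
        default_factory=lambda: {
            "theta": 1.0, "alpha": 0.8, "beta1": 0.35, "beta2": 0.30, "beta3": 0.25
        }
    )
    complexity_base: Mapping[str, float] = field(
        default_factory=lambda: {
            "theta": 0.5, "alpha": 0.3, "beta1": 0.18, "beta2": 0.18, "beta3": 0.8
        }
    )
    effect_bands: tuple[str, ...] = ("beta1", "beta2")
    beta_effect: float = 0.47
    complexity_sd: float = 0.6
    band_jitter_sd: float = 0.10
    panss_moderate: tuple[float, float] = PANSS_GROUP_PARAMS["moderately_ill"]
    panss_marked: tuple[float, float] = PANSS_GROUP_PARAMS["markedly_ill"]
    r_target: float = REFERENCE_BETA_CORRELATION
    panss_coupling: float = 0.25
    amplitude: float = 10.0      # overall scalp RMS, µV
    ref_amplitude: float = 1.0   # reference-channel noise RMS, µV
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_normal, self.n_moderate, self.n_marked) < 0:
            raise ValueError("group sizes must be nonnegative")
        for name, c in self.complexity_base.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"complexity_base[{name!r}]={c} outside [0, 1]")
        if not -1.0 < self.r_target < 1.0:
            raise ValueError(f"r_target must lie in (-1, 1), got {self.r_target}")
        if not 0.0 <= self.panss_coupling <= 1.0:
            raise ValueError("panss_coupling must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.timeline.total_duration * self.fs))


@dataclass
class SyntheticCohort:
    recordings: list[RawRecording]
    metadata: list[SubjectMetadata]
    truth: dict[str, dict]  # subject_id -> generating parameters

    def labels(self) -> dict[str, str]:
        return {m.subject_id: m.group for m in self.metadata}


def _subject_complexities(
    spec: CohortSpec, group: str, z: float, rng: np.random.Generator
) -> dict[str, float]:
    """Per-band noise-mixing fractions for one subject.

    The group's base fraction (plus ``beta_effect`` for the marked group
    in the effect bands) is jittered multiplicatively on the log scale:
    by the severity latent ``z`` in the effect bands (same spread in
    every group), independently elsewhere.  Clipped to [0.005, 1] so the band never becomes exactly
    deterministic by accident (c = 0 remains reachable by setting the
    base to 0 with zero spread).
    """
    out = {}
    for band in spec.bands:
        base = float(spec.complexity_base.get(band.name, 0.5))
        if group == "markedly_ill" and band.name in spec.effect_bands:
            base = base + spec.beta_effect
        if base <= 0.0:
            out[band.name] = 0.0
            continue
        if band.name in spec.effect_bands:
            log_jitter = spec.complexity_sd * z
        else:
            log_jitter = spec.band_jitter_sd * rng.standard_normal()
        out[band.name] = float(np.clip(base * math.exp(log_jitter), 0.005, 1.0))
    return out


def _band_process(
    band: BandDefinition, c: float, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance band process: √c · filtered noise + √(1−c) · sinusoid."""
    sos = butter(3, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    parts = []
    if c > 0.0:
        noise = sosfiltfilt(sos, rng.standard_normal(n))
        noise /= noise.std()
        parts.append(math.sqrt(c) * noise)
    if c < 1.0:
        t = np.arange(n) / fs
        phase = rng.uniform(0.0, 2.0 * math.pi)
        parts.append(math.sqrt(1.0 - c) * math.sqrt(2.0) * np.sin(2 * math.pi * band.center * t + phase))
    return sum(parts)


def _panss_scores(
    spec: CohortSpec, group: str, z: float, rng: np.random.Generator
) -> tuple[float, float, float, float]:
    """PANSS (positive, negative, global, total) for one subject.

    The total is the group mean plus the group SD times a standardized
    score correlated (``panss_coupling``) with the severity latent z.
    Subscores partition the total roughly 1:1:2 plus noise, summing to
    it exactly.
    """
    if group == "normal":
        return 0.0, 0.0, 0.0, 0.0
    mu, sd = spec.panss_moderate if group == "moderately_ill" else spec.panss_marked
    rho = spec.panss_coupling
    std_score = rho * z + math.sqrt(1.0 - rho**2) * rng.standard_normal()
    total = max(mu + sd * std_score, 30.0)  # PANSS floor (30 items scored >= 1)
    positive = 0.25 * total + 1.5 * rng.standard_normal()
    negative = 0.25 * total + 1.5 * rng.standard_normal()
    glob = total - positive - negative
    return positive, negative, glob, total


def generate_subject(
    spec: CohortSpec, group: str, subject_seed: int, subject_id: str = ""
) -> tuple[RawRecording, SubjectMetadata, dict]:
    """One subject's recording, metadata and generating truth."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    rng = np.random.default_rng(subject_seed)
    z = float(rng.standard_normal())  # severity latent
    complexities = _subject_complexities(spec, group, z, rng)
    n = spec.n_samples

    total_power = sum(float(spec.band_power.get(b.name, 0.0)) for b in spec.bands)
    scale = spec.amplitude / math.sqrt(total_power) if total_power > 0 else 0.0
    channels: dict[str, np.ndarray] = {}
    for electrode in spec.electrodes:
        if electrode in ("A1", "A2"):
            channels[electrode] = spec.ref_amplitude * rng.standard_normal(n)
            continue
        sig = np.zeros(n)
        for band in spec.bands:
            power = float(spec.band_power.get(band.name, 0.0))
            if power <= 0:
                continue
            sig += math.sqrt(power) * _band_process(
                band, complexities[band.name], n, spec.fs, rng
            )
        channels[electrode] = scale * sig

    positive, negative, glob, total = _panss_scores(spec, group, z, rng)
    meta = SubjectMetadata(subject_id, group, positive, negative, glob, total)
    truth = {
        "group": group,
        "severity_latent": z,
        "complexity": complexities,
        "subject_seed": int(subject_seed),
    }
    return RawRecording(channels, spec.fs, subject_id), meta, truth


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """A full cohort, deterministic given ``spec.seed``.

    Subjects are ordered controls, moderate, marked with ids
    ``norm01…``, ``mod01…``, ``marked01…``; subject seeds come from the
    master seed's ``SeedSequence`` state expansion.
    """
    plan = (
        [("normal", f"norm{i + 1:02d}") for i in range(spec.n_normal)]
        + [("moderately_ill", f"mod{i + 1:02d}") for i in range(spec.n_moderate)]
        + [("markedly_ill", f"marked{i + 1:02d}") for i in range(spec.n_marked)]
    )
    if not plan:
        return SyntheticCohort([], [], {})
    seeds = np.random.SeedSequence(spec.seed).generate_state(len(plan))
    recordings, metadata, truth = [], [], {}
    for (group, sid), seed in zip(plan, seeds):
        rec, meta, info = generate_subject(spec, group, int(seed), sid)
        recordings.append(rec)
        metadata.append(meta)
        truth[sid] = info
    return SyntheticCohort(recordings, metadata, truth)
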