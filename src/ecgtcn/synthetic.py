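"""Synthetic ECG5000-like heartbeat generator.

Generates 140-point, five-class beat datasets with class-distinct
P-QRS-T morphology and the archive's class imbalance, so the full
pipeline (augmentation, training, evaluation) is exercisable with no
download.  A beat is a sum of Gaussian bumps — one per wave — with a
shared timing jitter and additive Gaussian noise, optionally
z-normalized:

    beat(t) = sum_w  A_w * exp(-(t - c_w - jitter)^2 / (2 * s_w^2)) + noise

The default archetypes are caricatures chosen for separability, not
claims about real pathology: N is a textbook P-QRS-T; R-on-T adds a
premature wide R over the T-wave region; PVC drops the P wave and has a
wide, large QRS with inverted T; SP is an early, compressed complex; UB
is a low-amplitude irregular morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import HeartbeatDataset, HeartbeatRecord
from .ecg5000 import BEAT_LENGTH, CLASS_LABELS, class_proportions

__all__ = [
    "BeatArchetype",
    "DEFAULT_ARCHETYPES",
    "generate_beat",
    "generate_dataset",
    "largest_remainder",
]


@dataclass(frozen=True)
class BeatArchetype:
    """Per-class beat template: one (amplitude, center, width) Gaussian per wave."""

    label: int
    waves: tuple[tuple[float, float, float], ...]  # (amplitude, center, width)
    noise_sd: float = 0.05
    jitter_sd: float = 1.5

    def __post_init__(self):
        for amp, center, width in self.waves:
            if not 0 <= center < BEAT_LENGTH:
                raise ValueError(f"wave center {center} outside [0, {BEAT_LENGTH})")
            if width <= 0:
                raise ValueError(f"wave width must be positive, got {width}")


# (amplitude, center sample, width in samples) per wave; order P, Q, R, S, T
# where the wave exists.  Centers/widths loosely follow textbook timing at
# the 140-sample-per-beat scale.
DEFAULT_ARCHETYPES: dict[int, BeatArchetype] = {
    1: BeatArchetype(1, (  # N: textbook P-QRS-T
        (0.18, 30, 5.0), (-0.20, 57, 2.0), (1.00, 62, 2.5),
        (-0.28, 67, 2.0), (0.40, 98, 8.0))),
    2: BeatArchetype(2, (  # R-on-T: premature wide R superimposed on the T region
        (0.15, 28, 5.0), (-0.18, 55, 2.0), (0.85, 60, 2.5),
        (-0.25, 65, 2.0), (0.35, 92, 7.0), (0.90, 103, 4.0))),
    3: BeatArchetype(3, (  # PVC: no P, wide large QRS, inverted T
        (1.30, 60, 6.0), (-0.45, 70, 3.5), (-0.50, 100, 9.0))),
    4: BeatArchetype(4, (  # SP: early, compressed complex
        (0.15, 18, 3.5), (-0.18, 40, 1.5), (0.95, 44, 1.8),
        (-0.25, 48, 1.5), (0.30, 72, 6.0))),
    5: BeatArchetype(5, (  # UB: low-amplitude irregular morphology
        (0.30, 35, 12.0), (-0.25, 75, 10.0), (0.20, 110, 8.0))),
}


def generate_beat(archetype: BeatArchetype, rng: np.random.Generator,
                  length: int = BEAT_LENGTH, normalize: bool = True
                  ) -> HeartbeatRecord:
    """Draw one beat from an archetype (jitter + noise), z-normalized by default."""
    t = np.arange(length, dtype=np.float64)
    jitter = rng.normal(0.0, archetype.jitter_sd) if archetype.jitter_sd > 0 else 0.0
    beat = np.zeros(length)
    for amp, center, width in archetype.waves:
        beat += amp * np.exp(-((t - center - jitter) ** 2) / (2.0 * width ** 2))
    if archetype.noise_sd > 0:
        beat += rng.normal(0.0, archetype.noise_sd, length)
    if normalize:
        sd = beat.std()
        if sd > 0:
            beat = (beat - beat.mean()) / sd
    return HeartbeatRecord(beat, archetype.label)


def largest_remainder(n_total: int, proportions: np.ndarray) -> np.ndarray:
    """Apportion ``n_total`` integer counts to fractional shares.

    Each share gets the floor of its quota; leftover units go to the
    largest remainders (ties to the earlier index).  Counts always sum to
    ``n_total`` exactly.
    """
    proportions = np.asarray(proportions, dtype=np.float64)
    quotas = n_total * proportions
    counts = np.floor(quotas).astype(int)
    remainder = n_total - counts.sum()
    if remainder:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def generate_dataset(n_total: int, class_proportions_: dict[int, float] | None = None,
                     seed: int | None = None, *,
                     archetypes: dict[int, BeatArchetype] | None = None,
                     noise_sd: float | None = None, jitter_sd: float | None = None,
                     normalize: bool = True) -> HeartbeatDataset:
    """Generate a shuffled synthetic dataset with given class mix.

    Default proportions mirror the archive's totals (2919, 1767, 96, 194,
    24 of 5000); per-class counts follow largest-remainder apportionment.
    ``noise_sd``/``jitter_sd`` override every archetype's values when given.
    """
    props = class_proportions_ or class_proportions()
    labels = sorted(props)
    p = np.array([props[l] for l in labels], dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()}, expected 1")
    n_nonzero = int((p > 0).sum())
    if n_total < n_nonzero:
        raise ValueError(
            f"n_total={n_total} smaller than the {n_nonzero} populated classes")
    counts = largest_remainder(n_total, p)
    archetypes = archetypes or DEFAULT_ARCHETYPES
    rng = np.random.default_rng(seed)
    records = []
    for label, count in zip(labels, counts):
        arch = archetypes[label]
        if noise_sd is not None or jitter_sd is not None:
            arch = BeatArchetype(arch.label, arch.waves,
                                 noise_sd if noise_sd is not None else arch.noise_sd,
                                 jitter_sd if jitter_sd is not None else arch.jitter_sd)
        for _ in range(count):
            records.append(generate_beat(arch, rng, normalize=normalize))
    order = rng.permutation(len(records))
    ds = HeartbeatDataset.from_records([records[i] for i in order],
                                       provenance=f"synthetic:seed={seed}")
    return ds
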