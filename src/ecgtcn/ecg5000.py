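"""Published ECG5000 study constants: class alphabet and sample counts.

ECG5000 holds 5000 interpolated 140-sample heartbeats in five classes,
derived from the BIDMC Congestive Heart Failure Database.  The tables
below record the published per-class sample distribution for the 90:10
split used with the default augmentation plan, before and after
augmenting the training portions of the PVC, SP and UB classes.

Erratum kept verbatim from the source tables: the UB row lists 2
training beats before augmentation but 550 after (550 = 22 x 25) and a
total of 24 with 20 test beats; the before-augmentation figure is
internally inconsistent with the others and is reproduced here
unchanged rather than silently corrected.
"""

from __future__ import annotations

__all__ = [
    "CLASS_NAMES",
    "CLASS_LABELS",
    "BEAT_LENGTH",
    "N_BEATS",
    "TEST_COUNTS",
    "TRAIN_COUNTS_BEFORE",
    "TRAIN_COUNTS_AFTER",
    "TOTAL_COUNTS",
    "class_proportions",
]

#: Integer label -> class name.
CLASS_NAMES: dict[int, str] = {
    1: "N",          # normal
    2: "R-on-T PVC",  # premature ventricular contraction on the preceding T wave
    3: "PVC",        # premature ventricular contraction
    4: "SP",         # supraventricular premature or ectopic beat
    5: "UB",         # unclassified beat
}

CLASS_LABELS: tuple[int, ...] = tuple(CLASS_NAMES)

#: Samples per beat (about 0.56 s).
BEAT_LENGTH: int = 140

#: Beats in the full archive.
N_BEATS: int = 5000

#: Per-class test-set counts of the published 90:10 split.
TEST_COUNTS: dict[int, int] = {1: 292, 2: 177, 3: 10, 4: 19, 5: 20}

#: Per-class training counts before augmentation (see module erratum for UB).
TRAIN_COUNTS_BEFORE: dict[int, int] = {1: 2627, 2: 1590, 3: 86, 4: 175, 5: 2}

#: Per-class training counts after the default augmentation plan
#: (PVC x25, SP x13, UB x25 including originals); they sum to 9204.
TRAIN_COUNTS_AFTER: dict[int, int] = {1: 2627, 2: 1590, 3: 2150, 4: 2287, 5: 550}

#: Per-class totals of the full 5000-beat archive.
TOTAL_COUNTS: dict[int, int] = {1: 2919, 2: 1767, 3: 96, 4: 194, 5: 24}


def class_proportions() -> dict[int, float]:
    """Class proportions of the full archive (counts / 5000)."""
    return {k: v / N_BEATS for k, v in TOTAL_COUNTS.items()}
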