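"""Heartbeat dataset containers and readers for the UCR text dialects.

Two on-disk dialects are supported: plain delimited text (one beat per
row, integer class label in the first column, comma- or
whitespace-separated) and the sktime-style ``.ts`` format (``@``-prefixed
header directives, series and label separated by ``:``).  Datasets can
also be exported as CSV with a ``label,s0..s139`` header.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HeartbeatRecord",
    "HeartbeatDataset",
    "ParseError",
    "read_delimited",
    "write_delimited",
    "read_ts",
    "write_ts",
    "write_csv",
    "make_split",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed dataset file; the message names the offending line."""


@dataclass(frozen=True)
class HeartbeatRecord:
    """One fixed-length beat (amplitude samples) with its class label."""

    samples: np.ndarray
    label: int

    def __post_init__(self):
        object.__setattr__(self, "samples",
                           np.asarray(self.samples, dtype=np.float64))

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class HeartbeatDataset:
    """An ordered collection of equal-length beats.

    ``X`` is ``(n_records, length)`` float64; ``y`` is ``(n_records,)``
    integer labels.  ``split`` tags whether the collection is a training
    or testing partition.
    """

    X: np.ndarray
    y: np.ndarray
    split: str = "unsplit"  # "train" | "test" | "unsplit"
    provenance: str = ""

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"{self.X.shape[0]} records but {self.y.shape[0]} labels")
        if self.split not in ("train", "test", "unsplit"):
            raise ValueError(f"unknown split tag {self.split!r}")

    def __len__(self) -> int:
        return self.X.shape[0]

    def __getitem__(self, i: int) -> HeartbeatRecord:
        return HeartbeatRecord(self.X[i], int(self.y[i]))

    @property
    def length(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    @classmethod
    def from_records(cls, records, **kw) -> "HeartbeatDataset":
        records = list(records)
        if not records:
            return cls(np.empty((0, 0)), np.empty(0, dtype=np.int64), **kw)
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"records of mixed lengths {sorted(lengths)}")
        return cls(np.stack([r.samples for r in records]),
                   np.array([r.label for r in records]), **kw)


def _parse_row(fields: list[str], lineno: int, expected: int | None) -> tuple[int, list[float]]:
    if expected is not None and len(fields) != expected:
        raise ParseError(
            f"line {lineno}: expected {expected} fields, got {len(fields)}")
    try:
        values = [float(f) for f in fields]
    except ValueError as e:
        raise ParseError(f"line {lineno}: non-numeric field ({e})") from None
    label_f = values[0]
    label = int(round(label_f))
    if abs(label_f - label) > 1e-9:
        raise ParseError(f"line {lineno}: non-integer label {fields[0]!r}")
    return label, values[1:]


def read_delimited(path, label_column_first: bool = True) -> HeartbeatDataset:
    """Read UCR-style delimited text: one beat per line, label first.

    The delimiter (comma vs. whitespace) is sniffed per file.  Ragged
    rows, non-numeric fields and non-integer labels raise
    :class:`ParseError` naming the line.
    """
    if not label_column_first:
        raise NotImplementedError("only label-first rows are supported")
    rows_x, rows_y = [], []
    expected = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",") if "," in line else line.split()
            label, values = _parse_row(fields, lineno, expected)
            expected = expected or len(fields)
            rows_y.append(label)
            rows_x.append(values)
    if not rows_x:
        raise ParseError(f"{path}: no records")
    return HeartbeatDataset(np.array(rows_x), np.array(rows_y),
                            provenance=f"delimited:{path}")


def write_delimited(ds: HeartbeatDataset, path, delimiter: str = ",") -> None:
    with open(path, "w") as fh:
        for i in range(len(ds)):
            fh.write(delimiter.join([str(int(ds.y[i]))]
                                    + [repr(float(v)) for v in ds.X[i]]) + "\n")


def write_csv(ds: HeartbeatDataset, path) -> None:
    """Export with header ``label,s0..s{L-1}``."""
    with open(path, "w") as fh:
        fh.write(",".join(["label"] + [f"s{i}" for i in range(ds.length)]) + "\n")
        for i in range(len(ds)):
            fh.write(",".join([str(int(ds.y[i]))] + [repr(float(v)) for v in ds.X[i]]) + "\n")


_KNOWN_TS_DIRECTIVES = {
    "problemname", "timestamps", "missing", "univariate", "equallength",
    "serieslength", "classlabel", "dimension", "targetlabel", "data",
}


def read_ts(path) -> HeartbeatDataset:
    """Read a sktime-style ``.ts`` file (univariate, equal-length).

    Header metadata (``@seriesLength``, ``@classLabel``) is validated
    against the rows; unknown ``@`` directives are ignored with a warning.
    """
    series_length = None
    class_labels: set[int] | None = None
    in_data = False
    rows_x, rows_y = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@"):
                parts = line[1:].split()
                key = parts[0].lower()
                if key == "data":
                    in_data = True
                elif key == "serieslength":
                    series_length = int(parts[1])
                elif key == "classlabel":
                    if parts[1].lower() == "true":
                        class_labels = {int(round(float(p))) for p in parts[2:]}
                elif key not in _KNOWN_TS_DIRECTIVES:
                    logger.warning("%s line %d: ignoring unknown directive @%s",
                                   path, lineno, key)
                    warnings.warn(f"ignoring unknown .ts directive @{key}",
                                  stacklevel=2)
                continue
            if not in_data:
                raise ParseError(f"line {lineno}: data before @data directive")
            if ":" not in line:
                raise ParseError(f"line {lineno}: missing ':' label separator")
            series_part, label_part = line.rsplit(":", 1)
            try:
                values = [float(v) for v in series_part.split(",")]
                label = int(round(float(label_part)))
            except ValueError as e:
                raise ParseError(f"line {lineno}: non-numeric field ({e})") from None
            if series_length is not None and len(values) != series_length:
                raise ParseError(
                    f"line {lineno}: series length {len(values)} disagrees "
                    f"with header @seriesLength {series_length}")
            if class_labels is not None and label not in class_labels:
                raise ParseError(
                    f"line {lineno}: label {label} not in header alphabet "
                    f"{sorted(class_labels)}")
            rows_x.append(values)
            rows_y.append(label)
    if not rows_x:
        raise ParseError(f"{path}: no records")
    lengths = {len(r) for r in rows_x}
    if len(lengths) != 1:
        raise ParseError(f"{path}: rows of mixed lengths {sorted(lengths)}")
    return HeartbeatDataset(np.array(rows_x), np.array(rows_y),
                            provenance=f"ts:{path}")


def write_ts(ds: HeartbeatDataset, path, problem_name: str = "Heartbeats") -> None:
    labels = sorted(set(ds.y.tolist()))
    with open(path, "w") as fh:
        fh.write(f"@problemName {problem_name}\n")
        fh.write("@timeStamps false\n@missing false\n@univariate true\n")
        fh.write(f"@equalLength true\n@seriesLength {ds.length}\n")
        fh.write("@classLabel true " + " ".join(str(l) for l in labels) + "\n")
        fh.write("@data\n")
        for i in range(len(ds)):
            fh.write(",".join(repr(float(v)) for v in ds.X[i]) + f":{int(ds.y[i])}\n")


def make_split(dataset: HeartbeatDataset, train_fraction: float = 0.9,
               seed: int | None = None, stratify: bool = False
               ) -> tuple[HeartbeatDataset, HeartbeatDataset]:
    """Partition an unsplit dataset into disjoint train/test subsets.

    The test share is ``floor(n * (1 - train_fraction))`` with the
    remainder going to training (5000 records at 0.9 give 4500/500).  The
    training subset is shuffled once with ``seed``; with ``stratify`` the
    test share is apportioned per class by largest remainder.
    """
    if dataset.split != "unsplit":
        raise ValueError(f"dataset already tagged {dataset.split!r}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(dataset)
    rng = np.random.default_rng(seed)
    n_test = int(np.floor(n * (1.0 - train_fraction) + 1e-9))
    perm = rng.permutation(n)
    if stratify:
        from .synthetic import largest_remainder  # shared apportionment rule
        labels, counts = np.unique(dataset.y, return_counts=True)
        shares = largest_remainder(n_test, counts / n)
        test_idx = []
        for lab, share in zip(labels, shares):
            members = perm[dataset.y[perm] == lab]
            test_idx.extend(members[:share].tolist())
        test_idx = np.array(sorted(test_idx))
    else:
        test_idx = np.sort(perm[:n_test])
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    train_order = rng.permutation(np.flatnonzero(~mask))  # shuffled once before use
    train = HeartbeatDataset(dataset.X[train_order], dataset.y[train_order],
                             split="train", provenance=dataset.provenance)
    test = HeartbeatDataset(dataset.X[mask], dataset.y[mask],
                            split="test", provenance=dataset.provenance)
    return train, test
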