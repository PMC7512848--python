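"""Observed multinomial count vectors: parsing, fixtures, frequencies.

Cells are identified positionally — category labels are carried as metadata
only, because the parametric families bind probabilities to cell positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np

from .divergences import ProbabilityVector

__all__ = [
    "CountVector",
    "read_counts",
    "write_counts",
    "fixture",
    "available_fixtures",
    "relative_frequencies",
]


@dataclass(frozen=True)
class CountVector:
    """Observed counts ``X = (X_1, ..., X_k)`` with ``n = sum X_i``."""

    counts: np.ndarray
    labels: Optional[List[str]] = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size < 2:
            raise ValueError("counts must be 1-D with k >= 2 cells")
        if not np.issubdtype(c.dtype, np.integer):
            as_int = c.astype(np.int64)
            if not np.array_equal(as_int, c):
                raise ValueError("counts must be exact integers")
            c = as_int
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if c.sum() < 1:
            raise ValueError("total count n must be >= 1")
        object.__setattr__(self, "counts", c.astype(np.int64))
        if self.labels is not None:
            labels = [str(x) for x in self.labels]
            if len(labels) != c.size:
                raise ValueError("labels length must match counts length")
            if len(set(labels)) != len(labels):
                raise ValueError("duplicate cell labels")
            object.__setattr__(self, "labels", labels)

    @property
    def k(self) -> int:
        return int(self.counts.size)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return self.k


def _parse_count(token: str, where: str) -> int:
    token = token.strip()
    if token == "":
        raise ValueError(f"missing count at {where}")
    try:
        value = float(token)
    except ValueError:
        raise ValueError(f"unparseable count {token!r} at {where}") from None
    if value != int(value):
        raise ValueError(f"fractional count {token!r} at {where}")
    if value < 0:
        raise ValueError(f"negative count {token!r} at {where}")
    return int(value)


def read_counts(
    source: Union[str, Path], format: Optional[str] = None
) -> CountVector:
    """Read a count table from a file or an inline comma-separated string.

    Files are two-column (label, count) TSV/CSV with a header row, or a JSON
    object mapping label to count.  A string containing commas and naming no
    existing file is parsed as inline unlabeled counts, e.g. ``"165,13,7,0"``.
    Parse errors carry the offending line number.
    """
    text_source = isinstance(source, str)
    path = Path(source)
    if text_source and "," in source and not path.exists():
        tokens = source.split(",")
        counts = [
            _parse_count(t, f"inline position {i + 1}")
            for i, t in enumerate(tokens)
        ]
        return CountVector(np.asarray(counts), labels=None)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {source}")

    fmt = format
    if fmt is None:
        fmt = {".tsv": "tsv", ".csv": "csv", ".json": "json"}.get(
            path.suffix.lower(), "tsv"
        )
    if fmt == "json":
        with open(path) as fh:
            obj = json.load(fh)
        if not isinstance(obj, dict):
            raise ValueError(f"{path}: JSON count table must be an object")
        labels = list(obj)
        counts = [
            _parse_count(str(v), f"{path} key {k!r}") for k, v in obj.items()
        ]
        return CountVector(np.asarray(counts), labels=labels)

    sep = "\t" if fmt == "tsv" else ","
    labels, counts = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno == 1 or not line.strip():
                continue  # header / blank
            parts = line.split(sep)
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            labels.append(parts[0].strip())
            counts.append(_parse_count(parts[1], f"{path}:{lineno}"))
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate cell labels")
    return CountVector(np.asarray(counts), labels=labels)


def write_counts(cv: CountVector, path: Union[str, Path],
                 format: Optional[str] = None) -> None:
    """Write a two-column TSV/CSV (header ``label<sep>count``) or JSON."""
    path = Path(path)
    fmt = format or {".tsv": "tsv", ".csv": "csv", ".json": "json"}.get(
        path.suffix.lower(), "tsv"
    )
    labels = cv.labels or [f"cell{i + 1}" for i in range(cv.k)]
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(
                {l: int(c) for l, c in zip(labels, cv.counts)}, fh, indent=1
            )
        return
    sep = "\t" if fmt == "tsv" else ","
    with open(path, "w") as fh:
        fh.write(f"label{sep}count\n")
        for l, c in zip(labels, cv.counts):
            fh.write(f"{l}{sep}{int(c)}\n")


# Thematic classification of the Evergreen Broadleaf Trees (EBL) class in two
# global land-cover maps: correct assignments and confusions with Deciduous
# Broadleaf (DBL), Evergreen Needleleaf (ENL) and Urban (U).
_EBL_LABELS = ["EBL", "DBL", "ENL", "U"]
_FIXTURES = {
    "globcover-ebl": ([165, 13, 7, 0], _EBL_LABELS),
    "lccci-ebl": ([172, 5, 5, 0], _EBL_LABELS),
}


def fixture(name: str) -> CountVector:
    """Built-in count vectors from the land-cover worked example."""
    try:
        counts, labels = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return CountVector(np.asarray(counts), labels=list(labels))


def available_fixtures() -> list:
    return sorted(_FIXTURES)


def relative_frequencies(cv: CountVector) -> ProbabilityVector:
    """Relative frequencies ``pi_hat_i = X_i / n``, with the support mask
    taken from ``X_i > 0`` exactly."""
    if cv.n < 1:
        raise ValueError("n must be >= 1")
    return ProbabilityVector.from_array(cv.counts / cv.n, check=False)


def as_count_vector(x: "Sequence | CountVector") -> CountVector:
    return x if isinstance(x, CountVector) else CountVector(np.asarray(x))
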