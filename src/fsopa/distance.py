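"""Normalized compression distance (NCD) over serialized feature columns.

Each feature column of a sample subset becomes one byte object: the cell
strings joined by newlines in subset order, missing cells emitted as the
``NA`` token.  NCD(x, y) = (C(xy) - min(C(x), C(y))) / max(C(x), C(y)),
where C is the compressed length in bytes.  Concatenation is always done in
canonical (lexicographic name) order so the distance is exactly symmetric
regardless of compressor asymmetries.
"""

from __future__ import annotations

import bz2
import lzma
import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .table import MISSING_TOKEN, FeatureTable

# gzip output is zlib (DEFLATE) plus a fixed-size header, so the two are
# interchangeable for NCD; both names resolve to DEFLATE at maximum level.
_COMPRESSORS: dict[str, Callable[[bytes], int]] = {
    "zlib": lambda b: len(zlib.compress(b, 9)),
    "gzip": lambda b: len(zlib.compress(b, 9)),
    "bz2": lambda b: len(bz2.compress(b, 9)),
    "lzma": lambda b: len(lzma.compress(b)),
}

DEFAULT_COMPRESSOR = "zlib"


def compressed_size(payload: bytes, compressor: str = DEFAULT_COMPRESSOR) -> int:
    try:
        fn = _COMPRESSORS[compressor]
    except KeyError:
        raise ConfigError(
            f"unknown compressor {compressor!r}; choose from {sorted(_COMPRESSORS)}"
        ) from None
    return fn(payload)


@dataclass(frozen=True)
class ByteObject:
    """A named byte payload — one serialized feature column of one subset."""

    name: str
    payload: bytes

    def __post_init__(self) -> None:
        if not self.payload:
            raise DataError(f"byte object {self.name!r} has an empty payload")


def serialize_column(table: FeatureTable, column: str,
                     subset: Sequence[int]) -> ByteObject:
    """Serialize a column over the given subset rows, in subset rank order."""
    subset = list(subset)
    if not subset:
        raise DataError(f"cannot serialize column {column!r} over an empty subset")
    values = table.values(column)
    mask = table.is_missing(column)
    parts = [MISSING_TOKEN if mask[i] else str(values[i]) for i in subset]
    return ByteObject(column, "\n".join(parts).encode("utf-8"))


def ncd(x: ByteObject, y: ByteObject, compressor: str = DEFAULT_COMPRESSOR,
        cx: int | None = None, cy: int | None = None) -> float:
    """Pairwise NCD; exactly symmetric by canonical concatenation order."""
    if cx is None:
        cx = compressed_size(x.payload, compressor)
    if cy is None:
        cy = compressed_size(y.payload, compressor)
    a, ca, b, cb = (x, cx, y, cy) if x.name <= y.name else (y, cy, x, cx)
    cab = compressed_size(a.payload + b.payload, compressor)
    value = (cab - min(ca, cb)) / max(ca, cb)
    return max(value, 0.0)


@dataclass
class DistanceMatrix:
    """Symmetric NCD matrix with a zero diagonal over named objects."""

    names: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.names)
        if self.d.shape != (k, k):
            raise DataError("distance matrix shape does not match names")
        if not np.isfinite(self.d).all():
            raise DataError("distance matrix has non-finite entries")
        if (self.d < 0).any() or not np.array_equal(self.d, self.d.T):
            raise DataError("distance matrix must be symmetric and non-negative")
        if np.diag(self.d).any():
            raise DataError("distance matrix diagonal must be zero")

    def to_phylip(self) -> str:
        """PHYLIP square-format serialization."""
        lines = [f"{len(self.names)}"]
        for name, row in zip(self.names, self.d):
            lines.append(name + "  " + "  ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def ncd_matrix(objects: Sequence[ByteObject],
               compressor: str = DEFAULT_COMPRESSOR) -> DistanceMatrix:
    """All pairwise NCDs; each C(x) is computed once and cached."""
    if len(objects) < 2:
        raise DataError("NCD matrix needs at least 2 objects")
    names = [o.name for o in objects]
    if len(set(names)) != len(names):
        raise DataError("byte object names must be unique")
    sizes = [compressed_size(o.payload, compressor) for o in objects]
    k = len(objects)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = ncd(objects[i], objects[j], compressor,
                                    cx=sizes[i], cy=sizes[j])
    return DistanceMatrix(names, d)
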