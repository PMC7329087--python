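"""Salient-sample selection: criterion ranking and best/worst subsets.

Samples are ranked by the criterion (a stable sort: ties keep original row
order).  Three selection-pressure levels s in {2, 4, 8} cut the head and
tail of the rank into six subsets — B2C/W2C (best/worst halves), B4C/W4C
(quarters) and B8C/W8C (eighths) — nested by construction: B8C within B4C
within B2C, and likewise for the worst tails.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .distance import serialize_column
from .errors import ConfigError, DataError
from .table import FeatureTable

PRESSURE_LEVELS = (2, 4, 8)
SUBSET_LABELS = ("B2C", "W2C", "B4C", "W4C", "B8C", "W8C")


@dataclass
class RankedSubsets:
    """The rank R (best -> worst row indices) and the six head/tail subsets."""

    rank: np.ndarray
    subsets: dict[str, np.ndarray]
    n_ranked: int
    n_dropped_missing: int
    criterion: str
    direction: str
    levels: tuple[int, ...] = PRESSURE_LEVELS

    def __getitem__(self, label: str) -> np.ndarray:
        return self.subsets[label]

    def category_pair(self, level: int) -> tuple[np.ndarray, np.ndarray]:
        return self.subsets[f"B{level}C"], self.subsets[f"W{level}C"]


def ss_sample(table: FeatureTable, criterion: str,
              direction: str = "minimize", min_subset: int = 10) -> RankedSubsets:
    """Rank rows by the criterion and emit the six best/worst subsets.

    Rows with a missing criterion are dropped from the rank (counted in the
    result).  ``direction='minimize'`` means smaller criterion values are
    better (e.g. a shorter stay).  Subset sizes are floor(n/s); the guard
    ``floor(n/8) >= min_subset`` rejects tables too small for a meaningful
    highest-pressure model.
    """
    if direction not in ("minimize", "maximize"):
        raise ConfigError(f"direction must be minimize|maximize, got {direction!r}")
    info = table.column_info(criterion)
    if info.kind != "numeric":
        raise DataError(f"criterion column {criterion!r} must be numeric")
    values = table.numeric(criterion)
    present = ~np.isnan(values)
    rows = np.flatnonzero(present)
    n_dropped = int(table.n - len(rows))
    keys = values[rows]
    if direction == "maximize":
        keys = -keys
    order = np.argsort(keys, kind="stable")  # stable: ties keep row order
    rank = rows[order]
    n = len(rank)
    if n // 8 < min_subset:
        raise DataError(
            f"insufficient data: floor({n}/8) < min_subset={min_subset}")
    subsets: dict[str, np.ndarray] = {}
    for s in PRESSURE_LEVELS:
        size = n // s
        subsets[f"B{s}C"] = rank[:size].copy()
        subsets[f"W{s}C"] = rank[n - size:].copy()
    return RankedSubsets(rank=rank, subsets=subsets, n_ranked=n,
                         n_dropped_missing=n_dropped, criterion=criterion,
                         direction=direction)


def export_subsets(table: FeatureTable, subsets: RankedSubsets, outdir: str | Path,
                   objects: list[str] | None = None) -> dict:
    """Write one serialized file per feature under each subset directory.

    Mirrors the directory layout used during model construction (directory
    per subset, file per feature) and returns the manifest written alongside.
    """
    outdir = Path(outdir)
    names = objects if objects is not None else [c.name for c in table.columns
                                                 if c.role != "id"]
    for label in SUBSET_LABELS:
        sub = outdir / label
        sub.mkdir(parents=True, exist_ok=True)
        for name in names:
            obj = serialize_column(table, name, subsets[label])
            (sub / f"{name}.txt").write_bytes(obj.payload)
    manifest = {
        "criterion": subsets.criterion,
        "direction": subsets.direction,
        "n_ranked": subsets.n_ranked,
        "n_dropped_missing": subsets.n_dropped_missing,
        "rank": subsets.rank.tolist(),
        "subsets": {label: subsets[label].tolist() for label in SUBSET_LABELS},
    }
    (outdir / "rank_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
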