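"""Phylogram model construction for one sample subset.

One model = serialize every feature column over the subset, compute the
pairwise NCD matrix, build the neighbor-joining phylogram and annotate
greedy-modularity communities on the tree graph.  Deterministic for fixed
inputs: same table, subset, object list and compressor always yield the
same Newick string byte-for-byte.
"""

from __future__ import annotations

from typing import Sequence

from .community import fast_newman
from .distance import DEFAULT_COMPRESSOR, DistanceMatrix, ncd_matrix, serialize_column
from .errors import DataError
from .table import FeatureTable
from .tree import Phylogram, neighbor_joining


def model_object_columns(table: FeatureTable,
                         exclude: Sequence[str] = ()) -> list[str]:
    """Columns used as phylogram objects: every non-id column not excluded."""
    drop = set(exclude)
    return [c.name for c in table.columns if c.role != "id" and c.name not in drop]


def build_distance_matrix(table: FeatureTable, subset: Sequence[int],
                          objects: Sequence[str] | None = None,
                          compressor: str = DEFAULT_COMPRESSOR) -> DistanceMatrix:
    if objects is None:
        objects = model_object_columns(table)
    if len(objects) < 2:
        raise DataError("phylogram construction needs at least 2 feature columns")
    byte_objects = [serialize_column(table, name, subset) for name in objects]
    return ncd_matrix(byte_objects, compressor)


def build_model(table: FeatureTable, subset: Sequence[int],
                compressor: str = DEFAULT_COMPRESSOR,
                objects: Sequence[str] | None = None) -> Phylogram:
    """NCD + neighbor joining + community annotation for one subset."""
    if len(list(subset)) == 0:
        raise DataError("cannot build a model from an empty subset")
    dm = build_distance_matrix(table, subset, objects, compressor)
    tree = neighbor_joining(dm)
    tree.communities, tree.modularity = fast_newman(tree.graph)
    return tree
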