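"""Non-dominated (Pareto) comparison of Cox models and elbow suggestion.

Models are points in the bi-objective space (number of features, normalized
AIC), both minimized.  p dominates q when p is no worse in both coordinates
and strictly better in at least one; the front is the non-dominated subset
(duplicates of a front point stay in the front).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataError
from .survival import ModelPoint


def _coords(points: Sequence) -> np.ndarray:
    out = []
    for p in points:
        if isinstance(p, ModelPoint):
            a = p.normalized_aic if p.normalized_aic is not None else p.aic
            out.append((p.n_features, a))
        else:
            k, a = p
            out.append((float(k), float(a)))
    return np.asarray(out, dtype=float)


@dataclass
class ParetoFront:
    """Input points, the non-dominated mask, and per-point dominator lists."""

    points: list
    coords: np.ndarray
    non_dominated: np.ndarray  # boolean mask over points

    @property
    def front(self) -> list:
        return [p for p, keep in zip(self.points, self.non_dominated) if keep]

    def dominators(self, i: int) -> list[int]:
        """Indices of points dominating point i (empty for front members)."""
        k, a = self.coords[i]
        better_eq = (self.coords[:, 0] <= k) & (self.coords[:, 1] <= a)
        strict = (self.coords[:, 0] < k) | (self.coords[:, 1] < a)
        out = np.flatnonzero(better_eq & strict)
        return [int(j) for j in out if j != i]

    def to_json(self) -> str:
        payload = []
        for i, p in enumerate(self.points):
            entry = {"k": self.coords[i, 0], "value": self.coords[i, 1],
                     "non_dominated": bool(self.non_dominated[i]),
                     "dominated_by": self.dominators(i)}
            if isinstance(p, ModelPoint):
                entry["label"] = p.label
            payload.append(entry)
        return json.dumps(payload, indent=2)


def pareto_front(points: Sequence) -> ParetoFront:
    """Extract the non-dominated set by a sort-and-sweep over (k, value).

    Within each k group only the minimal value survives, and only if it is
    strictly below the best value at any smaller k (a tie with a smaller-k
    point means that point dominates through the strict k coordinate).
    """
    points = list(points)
    if not points:
        raise DataError("pareto front needs at least one point")
    coords = _coords(points)
    if not np.isfinite(coords).all():
        raise DataError("non-finite model coordinates")
    mask = np.zeros(len(points), dtype=bool)
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    best_prev = np.inf  # best value among strictly smaller k
    i = 0
    while i < len(order):
        j = i
        k = coords[order[i], 0]
        while j < len(order) and coords[order[j], 0] == k:
            j += 1
        group = order[i:j]
        group_min = coords[group, 1].min()
        if group_min < best_prev:
            mask[group[coords[group, 1] == group_min]] = True
        best_prev = min(best_prev, group_min)
        i = j
    return ParetoFront(points=points, coords=coords, non_dominated=mask)


def elbow(front: ParetoFront):
    """Front point closest to the ideal corner after [0,1] normalization.

    Both coordinates are min-max scaled over the front; the member with the
    smallest Euclidean distance to (0, 0) wins, ties going to fewer features
    and then to the smaller objective value.
    """
    idx = np.flatnonzero(front.non_dominated)
    if len(idx) == 0:
        raise DataError("empty front")
    coords = front.coords[idx]
    spans = coords.max(axis=0) - coords.min(axis=0)
    spans[spans == 0] = 1.0
    scaled = (coords - coords.min(axis=0)) / spans
    dist = np.hypot(scaled[:, 0], scaled[:, 1])
    keys = sorted(range(len(idx)),
                  key=lambda i: (dist[i], coords[i, 0], coords[i, 1]))
    return front.points[idx[keys[0]]]
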