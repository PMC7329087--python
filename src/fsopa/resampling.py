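"""Column-constrained resamplings and the common/novelty/union lists.

RS1 drops columns with more than a threshold fraction of missing cells
(strictly greater than 85% by default).  RS2 drops columns whose declared
role marks them as redundant (dates, codes).  RS3 drops features whose
clades stayed stable across the previous datasets' phylograms.  RS4/RS5
compare the selected sets: features selected in at least two of the three
resamplings split into those also selected from the full dataset (common)
and those not (novelty); RS6 is their union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .errors import DataError
from .sampling import SUBSET_LABELS, ss_sample
from .sensitivity import SelectionResult, select_features
from .table import FeatureTable

log = logging.getLogger(__name__)

PROTECTED_ROLES = ("criterion", "duration", "event")


def rs1_missing_filter(table: FeatureTable, threshold: float = 0.85) -> FeatureTable:
    """Drop columns whose missing fraction is strictly above the threshold."""
    dropped = [c.name for c in table.columns
               if c.role not in PROTECTED_ROLES
               and table.missing_fraction(c.name) > threshold]
    if dropped:
        log.info("RS1 dropped %d columns over %.0f%% missing: %s",
                 len(dropped), 100 * threshold, dropped)
    kept = table.drop_columns(dropped)
    if all(c.role != "feature" for c in kept.columns):
        raise DataError("RS1 filter removed every feature column")
    return kept


def rs2_role_filter(table: FeatureTable,
                    drop_roles: Sequence[str] = ("date", "code")) -> FeatureTable:
    """Drop columns with redundant roles; criterion/duration/event are kept."""
    drop_roles = set(drop_roles) - set(PROTECTED_ROLES)
    dropped = [c.name for c in table.columns if c.role in drop_roles]
    if dropped:
        log.info("RS2 dropped %d columns with roles %s: %s",
                 len(dropped), sorted(drop_roles), dropped)
    return table.drop_columns(dropped)


def stable_features(selections: Sequence[SelectionResult]) -> frozenset[str]:
    """Features whose clades were preserved across every dataset's phylograms.

    A feature is stable when (a) no dataset's SM1 ever selected it and
    (b) for every subset label, the leaf set of its middle-split clade —
    restricted to the features shared by all datasets — is identical across
    datasets.  Stable features carried no best-vs-worst signal anywhere and
    are candidates for removal.
    """
    if len(selections) < 2:
        raise DataError("stability needs at least 2 datasets")
    universes = [frozenset().union(*(c1 | c2 for c1, c2 in sel.splits.values()))
                 for sel in selections]
    shared = frozenset.intersection(*universes)
    if not shared:
        raise DataError("datasets share no candidate features")

    ever_selected = frozenset().union(*(sel.s_clade for sel in selections))
    stable = set()
    for feat in shared - ever_selected:
        ok = True
        for label in SUBSET_LABELS:
            sides = []
            for sel in selections:
                c1, c2 = sel.splits[label]
                side = c1 if feat in c1 else c2
                sides.append(frozenset(side & shared))
            if any(side != sides[0] for side in sides[1:]):
                ok = False
                break
        if ok:
            stable.add(feat)
    return frozenset(stable)


def common_novelty(full_r: frozenset[str],
                   resampled_rs: Sequence[frozenset[str]]
                   ) -> tuple[frozenset[str], frozenset[str]]:
    """RS4 (common) and RS5 (novelty) from the full-dataset r and the resamplings.

    A feature selected in at least two resamplings is common when the full
    dataset also selected it, novelty otherwise.
    """
    counts: dict[str, int] = {}
    for rset in resampled_rs:
        for feat in rset:
            counts[feat] = counts.get(feat, 0) + 1
    recurrent = {feat for feat, c in counts.items() if c >= 2}
    rs4 = frozenset(feat for feat in recurrent if feat in full_r)
    rs5 = frozenset(feat for feat in recurrent if feat not in full_r)
    return rs4, rs5


@dataclass
class ResamplingSuite:
    """Datasets, per-dataset selections and the derived RS4/RS5/RS6 lists."""

    tables: dict[str, FeatureTable]
    selections: dict[str, SelectionResult]
    stable: frozenset[str]
    rs4: frozenset[str]
    rs5: frozenset[str]

    @property
    def rs6(self) -> frozenset[str]:
        return self.rs4 | self.rs5

    def feature_lists(self) -> dict[str, frozenset[str]]:
        lists = {name: sel.r for name, sel in self.selections.items()}
        lists.update(rs4=self.rs4, rs5=self.rs5, rs6=self.rs6)
        return lists

    def membership_table(self) -> "pd.DataFrame":
        """Features x datasets boolean membership matrix (report style)."""
        import pandas as pd

        lists = self.feature_lists()
        feats = sorted(frozenset().union(*lists.values())) if lists else []
        return pd.DataFrame({name: [f in sel for f in feats]
                             for name, sel in lists.items()}, index=feats)


def run_suite(table: FeatureTable, criterion: str, direction: str = "minimize",
              targets: Sequence[str] = (), compressor: str = "zlib",
              missing_threshold: float = 0.85,
              drop_roles: Sequence[str] = ("date", "code"),
              min_subset: int = 10,
              extra_stable_drop: Sequence[str] = ()) -> ResamplingSuite:
    """Full + RS1 + RS2 + RS3 selections and the derived common/novelty lists.

    ``extra_stable_drop`` lets a caller extend the RS3 drop list explicitly
    (the stability criterion is a checkable operationalization; human
    judgment may add to it).
    """
    def run(tab: FeatureTable) -> SelectionResult:
        subs = ss_sample(tab, criterion, direction, min_subset)
        tgts = [t for t in targets if t in tab.column_names]
        return select_features(tab, subs, tgts, compressor)

    tables = {"full": table}
    tables["rs1"] = rs1_missing_filter(table, missing_threshold)
    tables["rs2"] = rs2_role_filter(tables["rs1"], drop_roles)
    selections = {name: run(tab) for name, tab in tables.items()}

    stable = stable_features([selections["full"], selections["rs1"],
                              selections["rs2"]])
    protected = {c.name for c in table.columns if c.role in PROTECTED_ROLES}
    drop = (stable | set(extra_stable_drop)) - protected - {criterion}
    rs3_table = tables["rs2"].drop_columns(
        d for d in drop if d in tables["rs2"].column_names)
    if rs3_table.l < 2:
        raise DataError("RS3 stable-feature removal left fewer than 2 columns")
    tables["rs3"] = rs3_table
    selections["rs3"] = run(rs3_table)

    rs4, rs5 = common_novelty(selections["full"].r,
                              [selections["rs1"].r, selections["rs2"].r,
                               selections["rs3"].r])
    return ResamplingSuite(tables=tables, selections=selections,
                           stable=stable, rs4=rs4, rs5=rs5)
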