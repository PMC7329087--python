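"""Mixed-type feature tables with column roles and an explicit missing mask.

This is the single entry point for every downstream stage.  Cells are kept
as their raw string representation: the compression-distance stage works on
serialized cell text, so the table never coerces, imputes or normalizes
values.  Row order is significant everywhere — it is the alignment key that
lets per-column byte objects share sample order.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError

ROLES = ("feature", "criterion", "duration", "event", "id", "date", "code")
KINDS = ("numeric", "categorical")

#: Token used when a missing cell must be serialized into a byte object.
MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class ColumnInfo:
    """Descriptor of one table column: declared role and inferred kind."""

    name: str
    role: str = "feature"
    kind: str = "categorical"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"unknown column role {self.role!r} for {self.name!r}")
        if self.kind not in KINDS:
            raise ConfigError(f"unknown column kind {self.kind!r} for {self.name!r}")


@dataclass
class ColumnRoleConfig:
    """Names the criterion/duration/event columns plus per-column role overrides.

    ``direction`` states whether a *better* sample has a smaller
    (``minimize``, the default — e.g. a shorter hospital stay) or larger
    (``maximize``) criterion value.  ``sentinels`` are the cell strings read
    as missing.
    """

    criterion: str | None = None
    direction: str = "minimize"
    duration: str | None = None
    event: str | None = None
    roles: dict[str, str] = field(default_factory=dict)
    sentinels: tuple[str, ...] = ("", "NA")
    include_criterion_in_model: bool = True

    def __post_init__(self) -> None:
        if self.direction not in ("minimize", "maximize"):
            raise ConfigError(f"direction must be minimize|maximize, got {self.direction!r}")
        for name, role in self.roles.items():
            if role not in ROLES:
                raise ConfigError(f"unknown role {role!r} for column {name!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "ColumnRoleConfig":
        """Load from a YAML or JSON mapping."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {"criterion", "direction", "duration", "event", "roles", "sentinels",
                 "include_criterion_in_model"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "sentinels" in data:
            data["sentinels"] = tuple(data["sentinels"])
        return cls(**data)


class FeatureTable:
    """An n x l mixed-type table with per-cell missing mask and column metadata."""

    def __init__(self, cells: pd.DataFrame, missing: pd.DataFrame,
                 columns: Sequence[ColumnInfo]):
        names = [c.name for c in columns]
        if len(set(names)) != len(names):
            raise DataError("duplicate column names")
        if list(cells.columns) != names or list(missing.columns) != names:
            raise DataError("cell/mask frames must share the column descriptor order")
        if cells.shape != missing.shape:
            raise DataError("cell and mask shapes differ")
        n_crit = sum(c.role == "criterion" for c in columns)
        if n_crit > 1:
            raise ConfigError("at most one column may carry role=criterion")
        self.cells = cells.reset_index(drop=True)
        self.missing = missing.reset_index(drop=True)
        self.columns = list(columns)
        self._by_name = {c.name: c for c in self.columns}
        for c in self.columns:
            if c.role == "event":
                vals = self.values(c.name)[~self.is_missing(c.name)]
                ok = np.isin(vals, ("0", "1", "0.0", "1.0"))
                if not ok.all():
                    raise DataError(f"event column {c.name!r} has values outside {{0,1}}")

    # -- basic shape -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def l(self) -> int:
        """Number of feature-like columns (everything that is not an id)."""
        return sum(c.role != "id" for c in self.columns)

    def column_info(self, name: str) -> ColumnInfo:
        try:
            return self._by_name[name]
        except KeyError:
            raise ConfigError(f"unknown column {name!r}") from None

    # -- cell access -------------------------------------------------------
    def values(self, name: str) -> np.ndarray:
        self.column_info(name)
        return self.cells[name].to_numpy(dtype=object)

    def is_missing(self, name: str) -> np.ndarray:
        self.column_info(name)
        return self.missing[name].to_numpy(dtype=bool)

    def numeric(self, name: str) -> np.ndarray:
        """Column as floats with NaN at missing cells (numeric kind required)."""
        info = self.column_info(name)
        if info.kind != "numeric":
            raise DataError(f"column {name!r} is not numeric")
        out = np.full(self.n, np.nan)
        mask = ~self.is_missing(name)
        out[mask] = [float(v) for v in self.values(name)[mask]]
        return out

    def missing_fraction(self, name: str) -> float:
        """Fraction of masked cells in a column; invariant under row order."""
        if self.n == 0:
            return 0.0
        return float(self.is_missing(name).sum()) / self.n

    # -- derived tables ----------------------------------------------------
    def take_rows(self, indices: Iterable[int]) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(self.cells.iloc[idx], self.missing.iloc[idx], self.columns)

    def select_columns(self, names: Sequence[str]) -> "FeatureTable":
        infos = [self.column_info(n) for n in names]
        return FeatureTable(self.cells[list(names)], self.missing[list(names)], infos)

    def drop_columns(self, names: Iterable[str]) -> "FeatureTable":
        drop = set(names)
        keep = [n for n in self.column_names if n not in drop]
        return self.select_columns(keep)

    # -- IO ----------------------------------------------------------------
    def write_csv(self, path_or_buf) -> None:
        """Canonical RFC-4180 writer; missing cells emitted as the empty string."""
        own = isinstance(path_or_buf, (str, Path))
        handle = open(path_or_buf, "w", newline="") if own else path_or_buf
        try:
            writer = csv.writer(handle, lineterminator="\n")
            writer.writerow(self.column_names)
            miss = self.missing.to_numpy(dtype=bool)
            vals = self.cells.to_numpy(dtype=object)
            for i in range(self.n):
                writer.writerow(["" if miss[i, j] else str(vals[i, j])
                                 for j in range(len(self.columns))])
        finally:
            if own:
                handle.close()

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.write_csv(buf)
        return buf.getvalue()

    def equals(self, other: "FeatureTable") -> bool:
        """Cell-exact equality on string representations and masks."""
        if self.columns != other.columns or self.n != other.n:
            return False
        if not (self.missing.to_numpy() == other.missing.to_numpy()).all():
            return False
        a, b = self.cells.to_numpy(object), other.cells.to_numpy(object)
        mask = ~self.missing.to_numpy(bool)
        return all(str(x) == str(y) for x, y in zip(a[mask], b[mask]))


def _infer_kind(values: np.ndarray, mask: np.ndarray) -> str:
    present = values[~mask]
    if len(present) == 0:
        return "categorical"
    try:
        for v in present:
            float(v)
    except (TypeError, ValueError):
        return "categorical"
    return "numeric"


def build_table(header: Sequence[str], rows: Sequence[Sequence[object]],
                config: ColumnRoleConfig | None = None) -> FeatureTable:
    """Assemble a FeatureTable from in-memory records (shared by read_table/synth)."""
    config = config or ColumnRoleConfig()
    header = list(header)
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise DataError(f"duplicate header names: {dupes}")
    width = len(header)
    str_rows = []
    for i, row in enumerate(rows):
        if len(row) != width:
            raise DataError(f"ragged input: row {i + 1} has {len(row)} cells, expected {width}")
        str_rows.append(["" if v is None else str(v) for v in row])
    cells = pd.DataFrame(str_rows, columns=header, dtype=object) if str_rows else \
        pd.DataFrame({h: pd.Series(dtype=object) for h in header})
    sentinels = set(config.sentinels)
    missing = cells.isin(sentinels) if len(cells) else cells.astype(bool)

    role_map = dict(config.roles)
    for name, role in ((config.duration, "duration"), (config.event, "event"),
                       (config.criterion, "criterion")):
        if name is not None:
            if name not in header:
                raise ConfigError(f"configured {role} column {name!r} not in table")
            role_map[name] = role
    for name in config.roles:
        if name not in header:
            raise ConfigError(f"role override names unknown column {name!r}")

    infos = []
    for name in header:
        kind = _infer_kind(cells[name].to_numpy(object), missing[name].to_numpy(bool))
        infos.append(ColumnInfo(name, role_map.get(name, "feature"), kind))
    return FeatureTable(cells, missing, infos)


def read_table(path_or_buf, config: ColumnRoleConfig | None = None) -> FeatureTable:
    """Read a delimited text table (header row required) into a FeatureTable.

    Ragged rows are rejected with the offending row number; duplicate header
    names and a missing configured criterion column are errors.
    """
    own = isinstance(path_or_buf, (str, Path))
    handle = open(path_or_buf, newline="") if own else path_or_buf
    try:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise DataError("empty input: no header row") from None
        rows = list(reader)
    finally:
        if own:
            handle.close()
    return build_table(header, rows, config)


def write_table(table: FeatureTable, path) -> None:
    table.write_csv(path)
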