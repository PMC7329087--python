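"""End-to-end run: read -> rank -> six models -> SM1/SM2 -> Cox -> Pareto.

Artifacts (Newick trees, selection JSON, model CSV, front JSON) are written
to an output directory together with a manifest carrying content hashes, so
a rerun on identical inputs is checkable byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .decision import elbow, pareto_front
from .errors import ConfigError
from .model import model_object_columns
from .resampling import run_suite
from .sampling import SUBSET_LABELS, ss_sample
from .sensitivity import select_features
from .survival import CoxSpec, ModelPoint, forward_aic, model_table, normalize_aic
from .table import ColumnRoleConfig, FeatureTable, read_table


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]
    outputs: dict[str, str] = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    version: str = __version__

    def to_json(self, include_timings: bool = True) -> str:
        payload = {"version": self.version, "config": self.config,
                   "inputs": self.inputs, "outputs": self.outputs,
                   "stages": self.stages}
        if include_timings:
            payload["timings"] = self.timings
        return json.dumps(payload, indent=2, sort_keys=True)


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _write(outdir: Path, relpath: str, text: str, manifest: RunManifest) -> None:
    path = outdir / relpath
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)
    manifest.outputs[relpath] = _sha256(text.encode())


def candidate_order(selection, exclude: Sequence[str]) -> list[str]:
    """Forward-scan order: SM1-selected features first, then SM2-only ones.

    Alphabetical within each group; outcome columns are excluded (the
    criterion cannot covary with itself).
    """
    drop = {e for e in exclude if e}
    sm1_feats = sorted(selection.s_clade - drop)
    sm2_only = sorted(selection.s_criterion - selection.s_clade - drop)
    return sm1_feats + sm2_only


def run_pipeline(config: dict, outdir: str | Path,
                 table: FeatureTable | None = None) -> RunManifest:
    """Execute the full pipeline from a config mapping.

    Config keys: ``input`` (CSV path; optional when a table is passed),
    ``criterion``, ``direction``, ``duration``, ``event``, ``roles``,
    ``targets``, ``compressor``, ``exclude_columns``, ``min_subset``,
    ``resampling`` (bool), ``missing_threshold``, ``drop_roles``, ``cox``
    (bool).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    criterion = config.get("criterion")
    if not criterion:
        raise ConfigError("config must name the criterion column")
    direction = config.get("direction", "minimize")
    duration = config.get("duration", criterion)
    event = config.get("event")
    compressor = config.get("compressor", "zlib")
    min_subset = int(config.get("min_subset", 10))
    want_cox = bool(config.get("cox", True))
    if want_cox and not duration:
        raise ConfigError("Cox stage requested but no duration column configured")

    manifest = RunManifest(config=dict(config), inputs={})
    t0 = time.perf_counter()

    if table is None:
        path = config.get("input")
        if not path:
            raise ConfigError("config must provide an input path or a table")
        manifest.inputs[str(path)] = _sha256(Path(path).read_bytes())
        role_config = ColumnRoleConfig(
            criterion=criterion, direction=direction, duration=duration,
            event=event, roles=dict(config.get("roles", {})))
        table = read_table(path, role_config)
    manifest.stages["read"] = {"n": table.n, "columns": table.column_names}

    exclude = list(config.get("exclude_columns", []))
    if event and event not in exclude:
        exclude.append(event)  # the censoring flag is outcome, not feature
    if not config.get("include_criterion_in_model", True):
        exclude.append(criterion)
    objects = model_object_columns(table, exclude)
    targets = list(config.get("targets", [criterion]))
    targets = [t for t in targets if t in objects]

    subsets = ss_sample(table, criterion, direction, min_subset)
    manifest.stages["ss"] = {
        "n_ranked": subsets.n_ranked,
        "n_dropped_missing": subsets.n_dropped_missing,
        "sizes": {label: len(subsets[label]) for label in SUBSET_LABELS}}

    selection = select_features(table, subsets, targets, compressor, objects)
    for label in SUBSET_LABELS:
        _write(outdir, f"trees/{label}.nwk",
               selection.models[label].to_newick() + "\n", manifest)
    _write(outdir, "selection.json", selection.to_json(), manifest)
    manifest.stages["selection"] = {"r": sorted(selection.r),
                                    "s_clade": sorted(selection.s_clade),
                                    "s_criterion": sorted(selection.s_criterion)}

    feature_lists: dict[str, frozenset] = {"full": selection.r}
    if config.get("resampling", False):
        suite = run_suite(table, criterion, direction, targets, compressor,
                          missing_threshold=float(config.get("missing_threshold", 0.85)),
                          drop_roles=tuple(config.get("drop_roles", ("date", "code"))),
                          min_subset=min_subset)
        feature_lists = suite.feature_lists()
        _write(outdir, "suite.json", json.dumps(
            {name: sorted(sel) for name, sel in feature_lists.items()},
            indent=2, sort_keys=True), manifest)
        _write(outdir, "membership.csv",
               suite.membership_table().to_csv(), manifest)
        manifest.stages["resampling"] = {"stable": sorted(suite.stable)}

    if want_cox:
        spec = CoxSpec(duration=duration, event=event)
        points: list[ModelPoint] = []
        logs = {}
        # outcome columns cannot covary with themselves; date strings and
        # free-form codes are identifiers, not model covariates
        unusable = {c.name for c in table.columns if c.role in ("date", "code", "id")}
        outcome_cols = tuple(unusable | {criterion, duration} |
                             ({event} if event else set()))
        for label, feats in sorted(feature_lists.items()):
            cands = [f for f in sorted(feats) if f not in outcome_cols]
            if label == "full" or label in ("rs1", "rs2", "rs3"):
                sel = (selection if label == "full"
                       else suite.selections[label])
                cands = candidate_order(sel, outcome_cols)
            if not cands:
                continue
            point, steps = forward_aic(table, spec, cands, label=label)
            points.append(point)
            logs[label] = [{"candidate": s.candidate, "aic_before": s.aic_before,
                            "aic_after": s.aic_after, "kept": s.kept,
                            "reason": s.reason} for s in steps]
        points = normalize_aic(points, reference="max")
        _write(outdir, "models.csv", model_table(points).to_csv(index=False),
               manifest)
        _write(outdir, "forward_logs.json",
               json.dumps(logs, indent=2, sort_keys=True), manifest)
        front = pareto_front(points)
        best = elbow(front)
        _write(outdir, "front.json", front.to_json(), manifest)
        manifest.stages["cox"] = {
            "models": [p.label for p in points],
            "front": [p.label for p in front.front],
            "elbow": best.label}

    manifest.timings["total_s"] = time.perf_counter() - t0
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
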