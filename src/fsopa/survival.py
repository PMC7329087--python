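"""Cox proportional-hazards modeling of the criterion with forward-AIC selection.

The hazard for covariates X is h(t, X) = h0(t) * exp(X @ beta); models are
scored by AIC = -2 logPL + 2k with k the number of estimated coefficients
after encoding.  Fitting goes through lifelines (Efron tie handling — stay
durations are day-granular, so ties are certain).  The covariate-free null
model's log partial likelihood has the closed form
-sum_t sum_{l<d_t} log(n_risk(t) - l), which is what the Efron denominators
reduce to at beta = 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, NumericError
from .table import FeatureTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoxSpec:
    """Duration/event column names for the survival outcome.

    ``event=None`` means every duration is an observed event (no censoring
    column, as for discharge-complete stay records).
    """

    duration: str
    event: str | None = None


@dataclass
class ModelPoint:
    """One fitted Cox model: feature set, fit summary and AIC coordinates."""

    label: str
    features: tuple[str, ...]
    coefficients: dict[str, float]
    log_partial_likelihood: float
    k: int
    aic: float
    n_obs: int
    standard_errors: dict[str, float] = field(default_factory=dict)
    normalized_aic: float | None = None

    @property
    def n_features(self) -> int:
        return len(self.features)


@dataclass
class ForwardStep:
    candidate: str
    aic_before: float
    aic_after: float | None
    kept: bool
    reason: str = ""


def encode_covariates(table: FeatureTable, features: Sequence[str],
                      rows: np.ndarray | None = None
                      ) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Design matrix for the named features over complete-case rows.

    Numeric columns pass through; categorical columns are one-hot encoded
    with the most frequent level (ties: lexicographically first) as the
    reference.  Rows with any missing value among the used columns are
    dropped.  Returns (X, kept row indices, notes about dropped features).
    """
    features = list(features)
    for f in features:
        table.column_info(f)
    mask = np.ones(table.n, dtype=bool)
    if rows is not None:
        keep = np.zeros(table.n, dtype=bool)
        keep[rows] = True
        mask &= keep
    for f in features:
        mask &= ~table.is_missing(f)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise DataError("no usable rows after complete-case filtering")

    notes: list[str] = []
    cols: dict[str, np.ndarray] = {}
    for f in features:
        info = table.column_info(f)
        if info.kind == "numeric":
            cols[f] = table.numeric(f)[idx]
        else:
            values = table.values(f)[idx]
            levels, counts = np.unique(values.astype(str), return_counts=True)
            if len(levels) < 2:
                notes.append(f"dropped {f!r}: single level after row filtering")
                continue
            order = np.lexsort((levels, -counts))
            reference = levels[order[0]]
            for lev in levels:
                if lev != reference:
                    cols[f"{f}={lev}"] = (values.astype(str) == lev).astype(float)
    X = pd.DataFrame(cols, index=idx)
    if X.shape[1] and len(idx) < 10 * X.shape[1]:
        log.warning("only %d complete-case rows for %d encoded columns "
                    "(10 per column recommended)", len(idx), X.shape[1])
    return X, idx, notes


def encoded_width(table: FeatureTable, feature: str,
                  rows: np.ndarray | None = None) -> int:
    """Number of design-matrix columns a feature contributes (0 if degenerate)."""
    info = table.column_info(feature)
    if info.kind == "numeric":
        return 1
    values = table.values(feature)
    mask = ~table.is_missing(feature)
    if rows is not None:
        sel = np.zeros(table.n, dtype=bool)
        sel[rows] = True
        mask &= sel
    n_levels = len(np.unique(values[mask].astype(str)))
    return max(n_levels - 1, 0)


def _outcome(table: FeatureTable, spec: CoxSpec,
             rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    durations = table.numeric(spec.duration)[rows]
    if np.isnan(durations).any():
        raise DataError("missing durations among complete-case rows")
    if (durations <= 0).any():
        raise DataError("durations must be positive")
    if spec.event is None:
        events = np.ones(len(rows))
    else:
        events = table.numeric(spec.event)[rows]
        if np.isnan(events).any():
            raise DataError("missing event indicators among complete-case rows")
    return durations, events


def _complete_rows(table: FeatureTable, spec: CoxSpec,
                   columns: Sequence[str]) -> np.ndarray:
    mask = ~table.is_missing(spec.duration)
    if spec.event is not None:
        mask &= ~table.is_missing(spec.event)
    for c in columns:
        mask &= ~table.is_missing(c)
    return np.flatnonzero(mask)


def null_log_partial_likelihood(durations: np.ndarray,
                                events: np.ndarray) -> float:
    """Efron log partial likelihood at beta = 0 (closed form)."""
    durations = np.asarray(durations, float)
    events = np.asarray(events, float)
    order = np.argsort(-durations, kind="stable")
    t_sorted = durations[order]
    e_sorted = events[order]
    total = 0.0
    at_risk = 0
    i = 0
    n = len(t_sorted)
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        at_risk += j - i
        d = int(e_sorted[i:j].sum())
        for l in range(d):
            total -= np.log(at_risk - l)
        i = j
    return float(total)


def cox_fit(table: FeatureTable, spec: CoxSpec, features: Sequence[str] = (),
            label: str = "", rows: np.ndarray | None = None) -> ModelPoint:
    """Maximize the Cox partial likelihood (Efron ties) over the feature set.

    An empty feature set yields the null model (k = 0, AIC = -2 logPL0).
    ``rows`` optionally restricts to a pre-chosen row subset (the forward
    search uses this to keep AIC values comparable across candidate models).
    """
    table.column_info(spec.duration)
    if spec.event is not None:
        table.column_info(spec.event)
    features = [f for f in features if f not in (spec.duration, spec.event)]

    if not features:
        idx = rows if rows is not None else _complete_rows(table, spec, ())
        durations, events = _outcome(table, spec, idx)
        ll = null_log_partial_likelihood(durations, events)
        return ModelPoint(label=label, features=(), coefficients={},
                          log_partial_likelihood=ll, k=0, aic=-2 * ll,
                          n_obs=len(idx))

    base_rows = rows if rows is not None else _complete_rows(table, spec, features)
    X, idx, notes = encode_covariates(table, features, rows=base_rows)
    for note in notes:
        log.info("%s", note)
    if X.shape[1] == 0:
        return cox_fit(table, spec, (), label=label, rows=idx)
    durations, events = _outcome(table, spec, idx)

    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = X.copy()
    df["__T"] = durations
    df["__E"] = events
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="__T", event_col="__E")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        raise NumericError(f"Cox fit failed for {features}: {exc}") from exc

    ll = float(cph.log_likelihood_)
    k = int(len(cph.params_))
    kept = tuple(f for f in features
                 if f in X.columns or any(c.startswith(f + "=") for c in X.columns))
    return ModelPoint(label=label, features=kept,
                      coefficients=dict(cph.params_),
                      log_partial_likelihood=ll, k=k, aic=-2 * ll + 2 * k,
                      n_obs=len(idx),
                      standard_errors=dict(cph.standard_errors_))


def forward_aic(table: FeatureTable, spec: CoxSpec, candidates: Sequence[str],
                label: str = "") -> tuple[ModelPoint, list[ForwardStep]]:
    """Single-pass forward selection: keep a candidate iff AIC strictly drops.

    Starts from the null model and scans candidates in the given order.  The
    complete-case row set is fixed over all candidates for the whole run so
    every AIC is computed on the same observations.  Candidates that fail to
    fit are skipped with a logged reason.
    """
    candidates = [c for c in candidates if c not in (spec.duration, spec.event)]
    if not candidates:
        raise ConfigError("forward selection needs at least one candidate")
    rows = _complete_rows(table, spec, candidates)
    if len(rows) == 0:
        raise DataError("no complete-case rows over the candidate set")

    current = cox_fit(table, spec, (), label=label, rows=rows)
    kept: list[str] = []
    steps: list[ForwardStep] = []
    for cand in candidates:
        width = current.k + encoded_width(table, cand, rows)
        if width > max(len(rows) // 10, 1):
            steps.append(ForwardStep(cand, current.aic, None, False,
                                     f"design too wide: {width} encoded columns "
                                     f"for {len(rows)} rows"))
            continue
        try:
            trial = cox_fit(table, spec, kept + [cand], label=label, rows=rows)
        except NumericError as exc:
            steps.append(ForwardStep(cand, current.aic, None, False, str(exc)))
            continue
        if trial.aic < current.aic:
            steps.append(ForwardStep(cand, current.aic, trial.aic, True))
            current = trial
            kept.append(cand)
        else:
            steps.append(ForwardStep(cand, current.aic, trial.aic, False,
                                     "no AIC decrease"))
    return replace(current, label=label), steps


def normalize_aic(points: Sequence[ModelPoint],
                  reference: float | str = "max") -> list[ModelPoint]:
    """Divide each AIC by the reference (a positive value or the max AIC)."""
    if reference == "max":
        reference = max(p.aic for p in points)
    reference = float(reference)
    if reference <= 0:
        raise NumericError(f"normalization reference must be positive, got {reference}")
    return [replace(p, normalized_aic=p.aic / reference) for p in points]


def model_table(points: Sequence[ModelPoint]) -> pd.DataFrame:
    """Report frame: label, features, k, logPL, AIC, normalized AIC."""
    return pd.DataFrame([
        {"label": p.label, "features": ";".join(p.features),
         "n_features": p.n_features, "k": p.k, "n_obs": p.n_obs,
         "log_partial_likelihood": p.log_partial_likelihood,
         "aic": p.aic, "normalized_aic": p.normalized_aic}
        for p in points])
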