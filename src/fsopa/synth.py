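"""Synthetic EHR-like tables with Cox-structured outcomes, and toy fixtures.

The generator emulates the structure of a hospital-stay registry: mixed
numeric/categorical features, date-like and code-like distractor columns,
missing-value blocks, and a length-of-stay outcome drawn from a
proportional-hazards law over a known informative subset — so every stage
of the pipeline is testable with known ground truth.  Event times follow
T = -log(U) / (lambda * exp(X @ beta)); censoring is independent
exponential, its rate calibrated to the requested censoring fraction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import optimize

from .errors import ConfigError, DataError
from .table import ColumnRoleConfig, FeatureTable, build_table
from .tree import Phylogram


@dataclass
class SynthSpec:
    """Study conditions for one synthetic table.

    ``beta`` is the log-hazard coefficient shared by informative numeric
    columns (per-level contrasts for informative categoricals are spaced
    over [-beta, beta]).  ``baseline_rate`` is the exponential baseline
    hazard in 1/day: 0.1 gives a mean uncensored stay of 10 days.
    Durations are rounded up to whole days (stay records are day-granular);
    the criterion column is the duration itself.
    """

    n: int = 2000
    n_informative_numeric: int = 5
    n_informative_categorical: int = 0
    n_noise_numeric: int = 10
    n_noise_categorical: int = 5
    n_date: int = 2
    n_code: int = 2
    beta: float = 1.0
    baseline_rate: float = 0.1
    censoring: float = 0.2
    missingness: float = 0.0
    categorical_levels: int = 3
    day_granularity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.censoring < 1:
            raise ConfigError("censoring fraction must be in [0, 1)")
        if not 0 <= self.missingness < 1:
            raise ConfigError("missingness fraction must be in [0, 1)")
        if self.n_informative_numeric + self.n_informative_categorical + \
                self.n_noise_numeric + self.n_noise_categorical < 2:
            raise ConfigError("need at least 2 covariate columns")


def calibrate_censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c + h_i) = target."""
    if target <= 0:
        return 0.0
    lo, hi = 1e-12, 1e12

    def frac(c: float) -> float:
        return float(np.mean(c / (c + hazards))) - target

    if frac(lo) > 0 or frac(hi) < 0:
        raise DataError("censoring calibration infeasible for these hazards")
    return float(optimize.brentq(frac, lo, hi, xtol=1e-12))


def simulate_survival(log_hazard: np.ndarray, baseline_rate: float,
                      censoring: float, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Continuous event/censoring times under the proportional-hazards law.

    Returns (duration, event indicator, calibrated censor rate).  This is
    the exact generative model; the table generator applies day rounding on
    top of it.
    """
    hazards = baseline_rate * np.exp(np.asarray(log_hazard, float))
    t_event = rng.exponential(1.0 / hazards)
    if censoring <= 0:
        return t_event, np.ones(len(t_event)), 0.0
    c_rate = calibrate_censoring_rate(hazards, censoring)
    t_cens = rng.exponential(1.0 / c_rate, size=len(t_event))
    duration = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(float)
    return duration, event, c_rate


_LEVEL_NAMES = "abcdefghij"


def generate_table(spec: SynthSpec
                   ) -> tuple[FeatureTable, dict, ColumnRoleConfig]:
    """Draw one table; returns (table, ground truth, matching role config).

    Covariates are i.i.d. (numeric standard normal, categorical uniform over
    the levels).  The criterion column ``los`` is the simulated duration;
    ``event`` flags uncensored stays.  Date/code columns are
    outcome-independent distractors; missingness is applied completely at
    random per feature column.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    columns: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    informative: dict[str, float | dict[str, float]] = {}
    log_hazard = np.zeros(n)

    for i in range(spec.n_informative_numeric):
        name = f"inf_num_{i + 1}"
        x = rng.standard_normal(n)
        log_hazard += spec.beta * x
        columns[name] = np.round(x, 2)
        informative[name] = spec.beta
    for i in range(spec.n_informative_categorical):
        name = f"inf_cat_{i + 1}"
        levels = list(_LEVEL_NAMES[:spec.categorical_levels])
        codes = rng.integers(0, len(levels), size=n)
        level_beta = np.linspace(-spec.beta, spec.beta, len(levels))
        log_hazard += level_beta[codes]
        columns[name] = np.array([levels[c] for c in codes], dtype=object)
        informative[name] = {lev: float(b) for lev, b in zip(levels, level_beta)}
    for i in range(spec.n_noise_numeric):
        columns[f"noise_num_{i + 1}"] = np.round(rng.standard_normal(n), 2)
    for i in range(spec.n_noise_categorical):
        levels = list(_LEVEL_NAMES[:spec.categorical_levels])
        codes = rng.integers(0, len(levels), size=n)
        columns[f"noise_cat_{i + 1}"] = np.array([levels[c] for c in codes],
                                                 dtype=object)
    for i in range(spec.n_date):
        name = f"admission_date_{i + 1}"
        days = rng.integers(0, 3650, size=n)
        base = np.datetime64("2008-01-01") + days.astype("timedelta64[D]")
        columns[name] = base.astype(str).astype(object)
        roles[name] = "date"
    for i in range(spec.n_code):
        name = f"patient_code_{i + 1}"
        columns[name] = np.array([f"P{v:06d}" for v in
                                  rng.integers(0, 10 ** 6, size=n)], dtype=object)
        roles[name] = "code"

    duration, event, c_rate = simulate_survival(
        log_hazard, spec.baseline_rate, spec.censoring, rng)
    if spec.day_granularity:
        duration = np.maximum(np.ceil(duration), 1.0)
    columns["los"] = np.round(duration, 6)
    columns["event"] = event.astype(int)

    if spec.missingness > 0:
        feature_names = [c for c in columns if c not in ("los", "event")]
        for name in feature_names:
            drop = rng.random(n) < spec.missingness
            col = columns[name].astype(object)
            col[drop] = None
            columns[name] = col

    header = list(columns)
    rows = list(zip(*(columns[h] for h in header)))
    config = ColumnRoleConfig(criterion="los", direction="minimize",
                              duration="los", event="event", roles=roles)
    table = build_table(header, rows, config)
    truth = {
        "informative": sorted(informative),
        "beta": informative,
        "baseline_rate": spec.baseline_rate,
        "censor_rate": c_rate,
        "requested_censoring": spec.censoring,
        "observed_censoring": float(1 - event.mean()),
        "seed": spec.seed,
    }
    return table, truth, config


def write_dataset(spec: SynthSpec, outdir: str | Path) -> dict:
    """CSV + ground-truth JSON + the spec used, for CLI `simulate`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth, config = generate_table(spec)
    table.write_csv(outdir / "dataset.csv")
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    (outdir / "synth_spec.json").write_text(json.dumps(asdict(spec), indent=2))
    return truth


# ---------------------------------------------------------------------------
# Toy phylogram fixtures
# ---------------------------------------------------------------------------

@dataclass
class ToyFixture:
    best: Phylogram
    worst: Phylogram
    target: str | None
    expected: frozenset[str]


def _balanced_best() -> Phylogram:
    # ((A,B),(C,D)) -- ((E,F),(G,H)); central edge splits the two halves
    edges = [(0, 8, 1), (1, 8, 1), (2, 9, 1), (3, 9, 1), (8, 10, 1), (9, 10, 1),
             (4, 11, 1), (5, 11, 1), (6, 12, 1), (7, 12, 1), (11, 13, 1),
             (12, 13, 1), (10, 13, 1)]
    leaves = dict(enumerate("ABCDEFGH"))
    return Phylogram.from_edges(edges, leaves)


def toy_phylograms(which: str) -> ToyFixture:
    """Hand-built best/worst tree pairs with known sensitivity outputs.

    ``clade`` (SM1): the best model keeps the cherry (A, B) whose
    arrangement the worst model breaks up, so exactly A and B change
    sibling sets and the clade-based list is {A, B}.  ``criterion`` (SM2):
    with target A, the best-model clade pairs A with sibling B while the
    worst-model clade hangs the subtree {B, C} off A's parent, so the
    criterion-based list is {A, B, C}.
    """
    best = _balanced_best()
    if which in ("clade", "fig7"):
        # worst: caterpillar (A,(B,(C,D))) on the A-side, other half unchanged
        edges = [(0, 8, 1), (8, 9, 1), (1, 9, 1), (9, 10, 1), (2, 10, 1),
                 (3, 10, 1), (4, 11, 1), (5, 11, 1), (6, 12, 1), (7, 12, 1),
                 (11, 13, 1), (12, 13, 1), (8, 13, 1)]
        worst = Phylogram.from_edges(edges, dict(enumerate("ABCDEFGH")))
        return ToyFixture(best, worst, None, frozenset("AB"))
    if which in ("criterion", "fig8"):
        # worst: ((A,(B,C)),D) on the A-side — A's sibling subtree is {B, C}
        edges = [(3, 8, 1), (8, 9, 1), (0, 9, 1), (9, 10, 1), (1, 10, 1),
                 (2, 10, 1), (4, 11, 1), (5, 11, 1), (6, 12, 1), (7, 12, 1),
                 (11, 13, 1), (12, 13, 1), (8, 13, 1)]
        worst = Phylogram.from_edges(edges, dict(enumerate("ABCDEFGH")))
        return ToyFixture(best, worst, "A", frozenset("ABC"))
    raise ConfigError(f"unknown toy fixture {which!r} (use 'clade' or 'criterion')")


def random_phylogram(n_leaves: int, rng: np.random.Generator,
                     min_length: float = 0.1, max_length: float = 1.0,
                     prefix: str = "L") -> Phylogram:
    """Random unrooted binary tree with uniform branch lengths (test oracle aid)."""
    if n_leaves < 2:
        raise DataError("need at least 2 leaves")
    leaves = {i: f"{prefix}{i + 1}" for i in range(n_leaves)}
    if n_leaves == 2:
        return Phylogram.from_edges(
            [(0, 1, rng.uniform(min_length, max_length))], leaves)
    edges = {(0, 1): rng.uniform(min_length, max_length)}
    next_internal = n_leaves
    for leaf in range(2, n_leaves):
        split = list(edges)[rng.integers(0, len(edges))]
        length = edges.pop(split)
        u, v = split
        w = next_internal
        next_internal += 1
        edges[(u, w)] = length * 0.5
        edges[(w, v)] = length * 0.5
        edges[(leaf, w)] = rng.uniform(min_length, max_length)
    triples = [(u, v, l) for (u, v), l in edges.items()]
    return Phylogram.from_edges(triples, leaves)
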