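import pytest

from fsopa.errors import DataError
from fsopa.resampling import (common_novelty, rs1_missing_filter,
                              rs2_role_filter, run_suite, stable_features)
from fsopa.sampling import ss_sample
from fsopa.sensitivity import select_features
from fsopa.synth import SynthSpec, generate_table
from fsopa.table import ColumnRoleConfig

from conftest import make_table


def table_with_missing(fracs: dict):
    n = 20
    cols = {}
    for name, frac in fracs.items():
        k = int(round(frac * n))
        cols[name] = [""] * k + [str(i) for i in range(n - k)]
    return make_table(cols)


class TestMissingFilter:
    def test_strictly_above_threshold_dropped(self):
        t = table_with_missing({"a": 0.9, "b": 0.0})
        assert rs1_missing_filter(t).column_names == ["b"]

    def test_boundary_085_kept(self):
        t = table_with_missing({"a": 0.85, "b": 0.0})
        assert rs1_missing_filter(t).column_names == ["a", "b"]

    def test_identity_when_no_missing(self):
        t = table_with_missing({"a": 0.0, "b": 0.0})
        assert rs1_missing_filter(t).column_names == ["a", "b"]

    def test_idempotent(self):
        t = table_with_missing({"a": 0.9, "b": 0.3, "c": 0.0})
        once = rs1_missing_filter(t)
        twice = rs1_missing_filter(once)
        assert once.column_names == twice.column_names

    def test_all_features_dropped_is_error(self):
        t = table_with_missing({"a": 0.95, "b": 0.9})
        with pytest.raises(DataError):
            rs1_missing_filter(t)


class TestRoleFilter:
    def test_declared_roles_dropped(self):
        cfg = ColumnRoleConfig(roles={"birth_date": "date", "pid": "code"})
        t = make_table({"birth_date": ["2001-02-03"] * 3, "pid": ["p1", "p2", "p3"],
                        "age": [1, 2, 3]}, cfg)
        assert rs2_role_filter(t).column_names == ["age"]

    def test_identity_without_matching_roles(self):
        t = make_table({"a": [1], "b": [2]})
        assert rs2_role_filter(t).column_names == ["a", "b"]

    def test_protected_roles_never_dropped(self):
        cfg = ColumnRoleConfig(duration="d", roles={"a": "date"})
        t = make_table({"d": [1, 2], "a": ["x", "y"]}, cfg)
        filtered = rs2_role_filter(t, drop_roles=("date", "duration"))
        assert "d" in filtered.column_names
        assert "a" not in filtered.column_names


class TestCommonNovelty:
    def test_worked_example(self):
        rs4, rs5 = common_novelty(frozenset("abc"),
                                  [frozenset("ab"), frozenset("ad"),
                                   frozenset("bd")])
        assert rs4 == {"a", "b"}
        assert rs5 == {"d"}
        assert rs4 | rs5 == {"a", "b", "d"}

    def test_empty_resamplings(self):
        rs4, rs5 = common_novelty(frozenset("abc"), [frozenset()] * 3)
        assert rs4 == rs5 == frozenset()

    def test_single_occurrence_excluded(self):
        rs4, rs5 = common_novelty(frozenset("a"),
                                  [frozenset("a"), frozenset(), frozenset()])
        assert rs4 == rs5 == frozenset()

    def test_disjointness_invariant(self, rng):
        for _ in range(20):
            universe = list("abcdefgh")
            pick = lambda: frozenset(rng.choice(universe, rng.integers(0, 8),
                                                replace=False))
            rs4, rs5 = common_novelty(pick(), [pick(), pick(), pick()])
            assert not (rs4 & rs5)


@pytest.fixture(scope="module")
def selection():
    table, _, _ = generate_table(SynthSpec(n=400, seed=11))
    table = table.drop_columns([c.name for c in table.columns
                                if c.role in ("date", "code")] + ["event"])
    subs = ss_sample(table, "los")
    return select_features(table, subs, targets=["los"])


class TestStability:

    def test_same_dataset_twice_marks_unselected_stable(self, selection):
        stable = stable_features([selection, selection])
        universe = frozenset().union(*(c1 | c2
                                       for c1, c2 in selection.splits.values()))
        assert stable == universe - selection.s_clade

    def test_selected_features_never_stable(self, selection):
        stable = stable_features([selection, selection])
        assert not (stable & selection.s_clade)

    def test_fewer_than_two_datasets_rejected(self, selection):
        with pytest.raises(DataError):
            stable_features([selection])


class TestSuite:
    def test_suite_invariants_on_synthetic_registry(self):
        table, _, _ = generate_table(SynthSpec(
            n=480, seed=2, missingness=0.02, n_noise_numeric=6,
            n_noise_categorical=2, n_date=1, n_code=1))
        # a nearly-empty column for RS1 to drop
        import io

        from fsopa.table import read_table

        cells = table.to_csv_string().splitlines()
        header = cells[0] + ",mostly_empty"
        rows = [line + (",1" if i % 12 == 0 else ",")
                for i, line in enumerate(cells[1:])]
        cfg = ColumnRoleConfig(criterion="los", duration="los", event="event",
                               roles={"admission_date_1": "date",
                                      "patient_code_1": "code"})
        table2 = read_table(io.StringIO("\n".join([header] + rows)), cfg)
        suite = run_suite(table2, "los", targets=["los"], min_subset=10)
        names = {k: set(t.column_names) for k, t in suite.tables.items()}
        assert names["rs1"] <= names["full"]
        assert names["rs2"] <= names["rs1"]
        assert names["rs3"] <= names["rs2"]
        assert "mostly_empty" not in names["rs1"]
        assert "admission_date_1" not in names["rs2"]
        assert suite.rs6 == suite.rs4 | suite.rs5
        assert not (suite.rs4 & suite.rs5)
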