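import math

import networkx as nx
import pandas as pd
import pytest

from painnma.exceptions import (
    DisconnectedNetworkError,
    SchemaError,
    ValidationError,
)
from painnma.trial_data import (
    ArmOutcome,
    OutcomeRecord,
    Study,
    comparison_graph,
    fixture_path,
    graph_to_frame,
    load_network,
    select_timepoint,
    summarize,
    write_network,
)


def _write_csv(tmp_path, rows, name="trials.csv"):
    p = tmp_path / name
    cols = [
        "study_id", "treatment", "role", "n", "outcome_id", "followup_weeks",
        "kind", "events", "mean_change", "sd", "scale_name", "direction",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(p, index=False)
    return p


def _arm_row(study, treatment, n, role=None, **kw):
    return {"study_id": study, "treatment": treatment, "n": n, "role": role, **kw}


class TestLoadNetwork:
    def test_fixture_composition(self, fixture_ds):
        assert len(fixture_ds.studies) == 20
        assert len(fixture_ds.treatments) == 12
        assert fixture_ds.reference == "placebo"

    def test_minimal_two_arm_study(self, tmp_path):
        p = _write_csv(tmp_path, [_arm_row("s1", "A", 10), _arm_row("s1", "B", 12)])
        ds = load_network(p)
        assert ds.treatment_ids == ("A", "B")
        assert len(ds.studies) == 1
        assert ds.reference == "A"  # alphabetical fallback without placebo

    def test_disconnected_network_rejected(self, tmp_path):
        p = _write_csv(
            tmp_path,
            [
                _arm_row("s1", "A", 10), _arm_row("s1", "B", 10),
                _arm_row("s2", "C", 10), _arm_row("s2", "D", 10),
            ],
        )
        with pytest.raises(DisconnectedNetworkError):
            load_network(p)

    def test_missing_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"study_id": ["s1"], "treatment": ["A"]}).to_csv(p, index=False)
        with pytest.raises(SchemaError, match="missing required columns"):
            load_network(p)

    def test_duplicate_arm_rejected(self, tmp_path):
        p = _write_csv(
            tmp_path,
            [_arm_row("s1", "A", 10), _arm_row("s1", "A", 10), _arm_row("s1", "B", 10)],
        )
        with pytest.raises(ValidationError, match="duplicate"):
            load_network(p)

    def test_non_numeric_n_rejected(self, tmp_path):
        p = _write_csv(tmp_path, [_arm_row("s1", "A", "ten"), _arm_row("s1", "B", 10)])
        with pytest.raises(ValidationError, match="n"):
            load_network(p)

    def test_row_order_invariance(self, tmp_path, fixture_ds):
        df = pd.read_csv(fixture_path(), dtype=str)
        shuffled = df.sample(frac=1.0, random_state=42)
        p = tmp_path / "shuffled.csv"
        shuffled.to_csv(p, index=False)
        assert load_network(p) == fixture_ds

    def test_roundtrip_via_writer(self, tmp_path, fixture_ds):
        p = tmp_path / "out.csv"
        write_network(fixture_ds, p)
        assert load_network(p) == fixture_ds


class TestInvariants:
    def test_study_needs_two_arms(self):
        with pytest.raises(ValidationError):
            Study(study_id="s", arms=(("A", 10),))

    def test_arm_outcome_kind_fields(self):
        with pytest.raises(ValidationError):
            ArmOutcome(kind="dichotomous", n=10, events=11)
        with pytest.raises(ValidationError):
            ArmOutcome(kind="continuous", n=10, mean_change=1.0)  # missing sd
        with pytest.raises(ValidationError):
            ArmOutcome(kind="continuous", n=10, mean_change=1.0, sd=2.0, events=1)

    def test_record_rejects_mixed_kinds(self):
        with pytest.raises(ValidationError, match="mixes kinds"):
            OutcomeRecord(
                outcome_id="pain4w",
                followup_weeks=4.0,
                arm_outcomes={
                    "A": ArmOutcome(kind="continuous", n=10, mean_change=0.0, sd=1.0),
                    "B": ArmOutcome(kind="dichotomous", n=10, events=2),
                },
            )


def _rec(weeks):
    return OutcomeRecord(
        outcome_id="pain4w",
        followup_weeks=weeks,
        arm_outcomes={
            "A": ArmOutcome(kind="continuous", n=10, mean_change=0.0, sd=1.0),
            "B": ArmOutcome(kind="continuous", n=10, mean_change=0.0, sd=1.0),
        },
    )


class TestSelectTimepoint:
    def test_closest_wins(self):
        assert select_timepoint([_rec(3), _rec(7)], 4, (3, 17)).followup_weeks == 3

    def test_exact_match(self):
        assert select_timepoint([_rec(4)], 4, (3, 17)).followup_weeks == 4

    def test_tie_breaks_earlier(self):
        assert select_timepoint([_rec(3), _rec(5)], 4, (3, 17)).followup_weeks == 3

    def test_none_outside_window(self):
        assert select_timepoint([_rec(20)], 4, (3, 17)) is None

    def test_idempotent_and_in_window(self):
        recs = [_rec(w) for w in (3.5, 6, 9, 12)]
        chosen = select_timepoint(recs, 4, (3, 17))
        assert 3 <= chosen.followup_weeks <= 17
        assert select_timepoint([chosen], 4, (3, 17)) is chosen


class TestSummarize:
    def test_fixture_counts(self, fixture_ds):
        s = summarize(fixture_ds)
        assert s.total_participants == 1198
        assert s.intervention_participants == 622
        assert s.comparison_participants == 576
        assert s.total_participants == s.intervention_participants + s.comparison_participants
        assert s.n_two_arm + s.n_three_arm == s.n_studies == 20
        assert (s.n_placebo_controlled, s.n_head_to_head) == (14, 5)
        assert s.n_treatments == 11

    def test_fixture_moments(self, fixture_ds):
        s = summarize(fixture_ds)
        assert s.mean_study_size == pytest.approx(1198 / 20)
        sizes = [st.total_n for st in fixture_ds.studies]
        mean = sum(sizes) / 20
        sd = math.sqrt(sum((x - mean) ** 2 for x in sizes) / 19)
        assert s.sd_study_size == pytest.approx(sd)
        assert (s.mean_study_size_rounded, s.sd_study_size_rounded) == (60, 55)

    def test_single_study_convention(self, tmp_path):
        p = _write_csv(
            tmp_path, [_arm_row("s1", "A", 10), _arm_row("s1", "placebo", 10)]
        )
        s = summarize(load_network(p))
        assert s.total_participants == 20
        assert s.mean_study_size == 20
        assert s.sd_study_size == 0.0


class TestComparisonGraph:
    def test_three_arm_contributes_three_edges(self, tmp_path):
        p = _write_csv(
            tmp_path,
            [
                _arm_row("s1", "A", 10),
                _arm_row("s1", "B", 10),
                _arm_row("s1", "placebo", 10),
            ],
        )
        g = comparison_graph(load_network(p))
        assert g.number_of_edges() == 3
        assert all(d["n_studies"] == 1 for _, _, d in g.edges(data=True))

    def test_repeat_studies_stack_on_edge(self, tmp_path):
        rows = []
        for sid in ("s1", "s2"):
            rows += [_arm_row(sid, "A", 10), _arm_row(sid, "placebo", 10)]
        g = comparison_graph(load_network(_write_csv(tmp_path, rows)))
        assert g.number_of_edges() == 1
        assert g["A"]["placebo"]["n_studies"] == 2

    def test_fixture_placebo_largest(self, fixture_ds):
        g = comparison_graph(fixture_ds)
        totals = nx.get_node_attributes(g, "n_randomized")
        assert max(totals, key=totals.get) == "placebo"

    def test_empty_outcome_flagged(self, fixture_ds):
        g = comparison_graph(fixture_ds, "pain4w")  # fixture carries no outcome rows
        assert g.graph["empty"]

    def test_edge_frame(self, fixture_ds):
        df = graph_to_frame(comparison_graph(fixture_ds))
        assert set(df.columns) == {"treat_a", "treat_b", "n_studies"}
        assert df["n_studies"].sum() >= 20
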