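"""ToxPi weighted-slice scoring: transforms, scaling, slices, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bindrisk.refdata import reference_metric_table
from bindrisk.synthetic import SimConfig, gen_metric_table
from bindrisk.toxpi import (
    MetricSpec,
    MetricTable,
    ToxPiScorer,
    minmax_scale,
    rank_profiles,
    toxpi_scores,
    transform_metric,
)


class TestTransforms:
    def test_negate_flips_docking_score(self):
        out = transform_metric({"BPAF": -8.6}, "negate")
        assert out["BPAF"] == 8.6

    def test_absdiff_vs_control(self):
        out = transform_metric({"BPAF": 11.20}, "absdiff_vs_control", control_value=31.55)
        assert out["BPAF"] == pytest.approx(20.35)

    def test_identity(self):
        vals = {"A": 1.5, "B": -2.0}
        assert transform_metric(vals, "identity") == vals

    def test_absdiff_requires_control(self):
        with pytest.raises(ValueError, match="control"):
            transform_metric({"A": 1.0}, "absdiff_vs_control")


class TestMinMaxScale:
    def test_docking_example(self):
        negated = {"BPA": 7.8, "BPS": 7.6, "BPE": 7.6, "BPF": 7.6, "BPB": 7.9, "BPAF": 8.6}
        scaled = minmax_scale(negated)
        assert scaled == pytest.approx(
            {"BPA": 0.2, "BPS": 0.0, "BPE": 0.0, "BPF": 0.0, "BPB": 0.3, "BPAF": 1.0},
            abs=1e-9,
        )

    def test_degenerate_metric_scores_zero(self):
        assert minmax_scale({"A": 3.0, "B": 3.0}) == {"A": 0.0, "B": 0.0}

    def test_two_chemicals_hit_endpoints(self):
        assert minmax_scale({"A": 1.0, "B": 2.0}) == {"A": 0.0, "B": 1.0}

    def test_single_chemical_rejected(self):
        with pytest.raises(ValueError):
            minmax_scale({"A": 1.0})


def simple_table(values: dict[str, dict[str, float]], classes=None) -> MetricTable:
    df = pd.DataFrame(values)
    specs = {
        m: MetricSpec(class_name=(classes or {}).get(m, "all")) for m in df.columns
    }
    return MetricTable(values=df, specs=specs)


class TestScorer:
    def test_dominant_chemical_scores_one_and_ranks_first(self):
        table = gen_metric_table(5, dominant="XX", cfg=SimConfig(seed=2))
        results = toxpi_scores(table)
        top = next(r for r in results if r.chemical == "XX")
        assert top.rank == 1
        assert top.overall == pytest.approx(1.0)

    def test_all_degenerate_metrics_score_zero(self):
        table = simple_table({"m1": {"A": 1.0, "B": 1.0}, "m2": {"A": 2.0, "B": 2.0}})
        assert all(r.overall == 0.0 for r in toxpi_scores(table))

    def test_weights_must_cover_classes_and_sum_to_one(self):
        table = simple_table(
            {"m1": {"A": 1.0, "B": 2.0}, "m2": {"A": 2.0, "B": 1.0}},
            classes={"m1": "c1", "m2": "c2"},
        )
        with pytest.raises(ValueError, match="sum to 1"):
            toxpi_scores(table, weights={"c1": 0.5, "c2": 0.6})
        with pytest.raises(ValueError, match="missing"):
            toxpi_scores(table, weights={"c1": 1.0})

    def test_scores_bounded_and_ranks_permutation(self):
        table = gen_metric_table(8, cfg=SimConfig(seed=9))
        results = toxpi_scores(table)
        assert sorted(r.rank for r in results) == list(range(1, 9))
        for r in results:
            assert 0.0 <= r.overall <= 1.0
            assert all(0.0 <= v <= 1.0 for v in r.slice_scores.values())

    def test_metric_insertion_order_irrelevant(self):
        table = gen_metric_table(6, cfg=SimConfig(seed=4))
        cols = list(table.values.columns)
        perm = list(reversed(cols))
        table2 = MetricTable(values=table.values[perm], specs={c: table.specs[c] for c in perm})
        r1 = {r.chemical: r.overall for r in toxpi_scores(table)}
        r2 = {r.chemical: r.overall for r in toxpi_scores(table2)}
        assert r1 == pytest.approx(r2)

    def test_improving_one_metric_never_lowers_overall(self):
        table = gen_metric_table(6, cfg=SimConfig(seed=12))
        chem = table.chemicals[2]
        metric = "metric_01"  # identity transform
        assert table.specs[metric].transform == "identity"
        before = {r.chemical: r.overall for r in toxpi_scores(table)}
        bumped = table.values.copy()
        bumped.loc[chem, metric] = bumped[metric].max() + 5.0
        after = {
            r.chemical: r.overall
            for r in toxpi_scores(MetricTable(values=bumped, specs=table.specs))
        }
        assert after[chem] >= before[chem] - 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
    )
    def test_positive_affine_scale_invariance(self, a, b):
        """Rescaling a raw identity metric by a·v+b (a>0) leaves scores unchanged."""
        table = gen_metric_table(5, cfg=SimConfig(seed=21))
        metric = "metric_02"
        assert table.specs[metric].transform == "identity"
        scaled = table.values.copy()
        scaled[metric] = a * scaled[metric] + b
        r1 = {r.chemical: r.overall for r in toxpi_scores(table)}
        r2 = {
            r.chemical: r.overall
            for r in toxpi_scores(MetricTable(values=scaled, specs=table.specs))
        }
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestRankProfiles:
    def test_descending_order_with_lexicographic_ties(self):
        from bindrisk.toxpi import ToxPiResult

        results = [
            ToxPiResult("B", {}, 0.5, 0),
            ToxPiResult("A", {}, 0.9, 0),
            ToxPiResult("C", {}, 0.5, 0),
        ]
        ranked = rank_profiles(results)
        assert [r.chemical for r in ranked] == ["A", "B", "C"]
        assert [r.rank for r in ranked] == [1, 2, 3]


class TestReferenceFixture:
    def test_thirteen_metrics_in_five_classes(self):
        table = reference_metric_table()
        assert len(table.values.columns) == 13
        assert len(table.classes) == 5

    def test_uniform_weights_sum_to_one(self):
        scorer = ToxPiScorer().fit(reference_metric_table())
        assert sum(scorer.weights_.values()) == pytest.approx(1.0)
        assert all(w == pytest.approx(0.2) for w in scorer.weights_.values())

    def test_bpaf_ranks_first(self):
        """The fluorinated analog dominates the integrated risk ranking."""
        scorer = ToxPiScorer().fit(reference_metric_table())
        assert scorer.ranks_["BPAF"] == 1

    def test_full_order_reported(self):
        # Soft check: the full six-way order depends on unverified fixture
        # slots; only report that it is a valid permutation topped by BPAF.
        scorer = ToxPiScorer().fit(reference_metric_table())
        order = scorer.ranks_.sort_values().index.tolist()
        assert order[0] == "BPAF"
        assert sorted(order) == sorted(scorer.ranks_.index)

    def test_sklearn_transform_output_shape(self):
        table = reference_metric_table()
        out = ToxPiScorer().fit(table).transform(table)
        assert list(out.columns)[-2:] == ["overall", "rank"]
        assert out.shape == (6, 7)
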