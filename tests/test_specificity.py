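"""JS specificity scores, exclusive isoforms, KS comparison, trend clusters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

from pegsplice.simulate import (
    STAGES,
    SimulationConfig,
    generate_annotation,
    generate_genome,
    simulate_expression,
)
from pegsplice.specificity import (
    ExpressionMatrix,
    compare_score_distributions,
    exclusive_isoforms,
    js_divergence,
    js_specificity,
    select_differential,
    stage_specific,
    timecourse_clusters,
)

from _oracles import oracle_ks_d


class TestJsSpecificity:
    def test_single_tissue_expression_scores_one(self):
        result = js_specificity({"t1": 10.0, "t2": 0.0, "t3": 0.0})
        assert result.max_score == pytest.approx(1.0)
        assert result.argmax_tissue == "t1"

    def test_uniform_two_tissue_closed_form(self):
        # 1 - sqrt(H(0.75, 0.25) - 0.5) = 0.4421 to four decimals
        result = js_specificity({"t1": 1.0, "t2": 1.0})
        expected = 1.0 - np.sqrt(
            -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25)) - 0.5
        )
        assert result.max_score == pytest.approx(expected, abs=1e-12)
        assert round(result.max_score, 4) == 0.4421

    def test_all_zero_vector_is_flagged_undefined(self):
        result = js_specificity({"t1": 0.0, "t2": 0.0})
        assert result.undefined and result.max_score is None

    def test_matches_scipy_jensenshannon(self, rng):
        for _ in range(25):
            p = rng.random(5)
            q = rng.random(5)
            p, q = p / p.sum(), q / q.sum()
            ours = np.sqrt(js_divergence(p, q))
            assert ours == pytest.approx(jensenshannon(p, q, base=2), abs=1e-12)

    @given(
        vec=st.lists(
            st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=6
        ),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance_and_bounds(self, vec, scale):
        labels = [f"t{i}" for i in range(len(vec))]
        base = js_specificity(dict(zip(labels, vec)))
        scaled = js_specificity(dict(zip(labels, [v * scale for v in vec])))
        assert np.allclose(base.scores, scaled.scores, atol=1e-9)
        assert ((base.scores >= 0) & (base.scores <= 1 + 1e-12)).all()

    def test_max_score_one_iff_single_tissue(self):
        mixed = js_specificity({"a": 5.0, "b": 0.01})
        assert mixed.max_score < 1.0
        pure = js_specificity({"a": 5.0, "b": 0.0})
        assert pure.max_score == pytest.approx(1.0)

    def test_argmax_tie_breaks_lexicographically(self):
        result = js_specificity({"b": 1.0, "a": 1.0})
        assert result.argmax_tissue == "a"


class TestKsComparison:
    def test_identical_samples_have_zero_d(self):
        d, _ = compare_score_distributions([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert d == 0.0

    def test_disjoint_supports_have_d_one(self):
        d, p = compare_score_distributions([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert d == 1.0 and p < 0.05

    def test_matches_brute_force_ecdf_sweep(self, rng):
        a = rng.normal(0, 1, size=80)
        b = rng.normal(0.5, 1, size=60)
        d, _ = compare_score_distributions(a, b)
        assert d == pytest.approx(oracle_ks_d(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_score_distributions([], [0.1])


def _matrix(values: dict, groups: dict) -> ExpressionMatrix:
    df = pd.DataFrame(values).T
    df.columns = list(groups)
    return ExpressionMatrix(df, sample_tissue=groups)


class TestExclusiveIsoforms:
    def setup_method(self):
        self.groups = {"s1": "root", "s2": "leaf", "s3": "peg"}

    def test_single_tissue_isoform_is_exclusive(self):
        matrix = _matrix({"i1": [5.0, 0.0, 0.0], "i2": [1.0, 1.0, 1.0]}, self.groups)
        result = exclusive_isoforms(matrix)
        assert result.exclusive["root"] == {"i1"}
        assert result.exclusive["leaf"] == set()

    def test_everywhere_present_isoform_in_full_overlap(self):
        matrix = _matrix({"i1": [5.0, 4.0, 3.0]}, self.groups)
        result = exclusive_isoforms(matrix)
        assert result.combination_counts[frozenset(["root", "leaf", "peg"])] == 1

    def test_exclusive_sets_are_pairwise_disjoint(self, rng):
        values = {f"i{k}": list(rng.random(3) * 2) for k in range(50)}
        result = exclusive_isoforms(_matrix(values, self.groups))
        sets = list(result.exclusive.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])

    def test_below_threshold_everywhere_is_nowhere_present(self):
        matrix = _matrix({"i1": [0.05, 0.01, 0.0]}, self.groups)
        result = exclusive_isoforms(matrix, presence_threshold=0.1)
        assert all("i1" not in s for s in result.exclusive.values())

    def test_zero_sample_group_rejected(self):
        matrix = _matrix({"i1": [1.0, 1.0, 1.0]}, self.groups)
        with pytest.raises(ValueError):
            exclusive_isoforms(matrix, groups={**self.groups, "missing": "x"}, )


@pytest.fixture(scope="module")
def sim():
    config = SimulationConfig(seed=55)
    genome = generate_genome(config)
    annotation, _ = generate_annotation(config, genome)
    matrix, truth = simulate_expression(config, annotation)
    return config, matrix, truth


class TestSimulatedExpression:

    def test_planted_tissue_exclusives_recovered_exactly(self, sim):
        config, matrix, truth = sim
        result = exclusive_isoforms(matrix)
        planted = {
            tissue: {
                iso
                for iso, rec in truth.expression.items()
                if rec == {"label": "tissue_exclusive", "group": tissue}
            }
            for tissue in ("root", "leaf", "shoot_tip", "flower")
        }
        for tissue, ids in planted.items():
            assert result.exclusive[tissue] == ids
        # peg exclusives = all stage-exclusive isoforms
        peg = {
            iso
            for iso, rec in truth.expression.items()
            if rec["label"] == "stage_exclusive"
        }
        assert result.exclusive["peg"] == peg

    def test_planted_stage_exclusives_and_gene_counts(self, sim):
        config, matrix, truth = sim
        excl, gene_counts = stage_specific(matrix, STAGES)
        for stage in STAGES:
            planted = {
                iso
                for iso, rec in truth.expression.items()
                if rec == {"label": "stage_exclusive", "group": stage}
            }
            assert excl.exclusive[stage] == planted
            expected_genes = {matrix.gene_map[i] for i in planted}
            assert gene_counts[stage] == len(expected_genes)

    def test_trend_labels_recovered_above_95_percent(self, sim):
        config, matrix, truth = sim
        selected = select_differential(matrix, STAGES)
        profiles = matrix.stage_means().loc[selected, list(STAGES)]
        clusters = timecourse_clusters(profiles, seed=config.seed)
        truth_labels = {
            iso: rec["label"].removeprefix("trend_")
            for iso, rec in truth.expression.items()
            if rec["label"].startswith("trend_")
        }
        labelled = [c for c in clusters if c.isoform_id in truth_labels]
        assert len(labelled) == len(truth_labels)  # all trends pass selection
        agreement = np.mean(
            [c.label == truth_labels[c.isoform_id] for c in labelled]
        )
        assert agreement >= 0.95


class TestTimecourseClusters:
    def test_monotone_profiles_get_expected_labels(self):
        profiles = pd.DataFrame(
            {"S1": [1, 8], "S2": [2, 4], "S3": [3, 2], "S4": [4, 1]},
            index=["up_iso", "down_iso"],
        )
        clusters = {c.isoform_id: c.label for c in timecourse_clusters(profiles)}
        assert clusters == {"up_iso": "up", "down_iso": "down"}

    def test_constant_profiles_are_excluded(self):
        profiles = pd.DataFrame(
            {"S1": [1, 5, 8], "S2": [2, 5, 4], "S3": [3, 5, 2], "S4": [4, 5, 1]},
            index=["up_iso", "flat", "down_iso"],
        )
        clusters = timecourse_clusters(profiles)
        assert {c.isoform_id for c in clusters} == {"up_iso", "down_iso"}

    def test_single_stage_rejected(self):
        with pytest.raises(ValueError):
            timecourse_clusters(pd.DataFrame({"S1": [1.0, 2.0]}))
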