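import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

from chromdelta import (
    BackgroundFreqs,
    EmissionMatrix,
    SampleGroup,
    ScoreMatrix,
    StateAlphabet,
    ValidationError,
    build_dataset,
    build_score_matrix,
    check_assumptions,
    empirical_state_freqs,
    jsd,
    shannon_entropy,
)
from conftest import make_map


def ref_jsd(a, b):
    """Independent oracle: twice the conventional JSD via scipy."""
    return 2.0 * jensenshannon(a, b, base=math.e) ** 2


dist6 = st.lists(st.floats(0.01, 1.0), min_size=6, max_size=6).map(
    lambda xs: np.array(xs) / np.sum(xs)
)


class TestEntropy:
    @pytest.mark.parametrize(
        "dist, expected",
        [
            ([1, 0, 0, 0, 0, 0], 0.0),
            ([1 / 6.0] * 6, math.log(6)),
            ([0.5, 0.5, 0, 0, 0, 0], math.log(2)),
        ],
    )
    def test_closed_forms(self, dist, expected):
        assert shannon_entropy(dist) == pytest.approx(expected, abs=1e-12)

    def test_invalid_distributions_rejected(self):
        with pytest.raises(ValidationError):
            shannon_entropy([-0.1, 1.1])
        with pytest.raises(ValidationError):
            shannon_entropy([0.7, 0.7])


class TestJSD:
    def test_identity_is_zero(self):
        e = np.array([0.2, 0.3, 0.5])
        assert jsd(e, e) == 0.0

    def test_disjoint_support_attains_upper_bound(self):
        a = np.array([1.0, 0, 0, 0])
        b = np.array([0, 1.0, 0, 0])
        assert jsd(a, b) == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            jsd([0.5, 0.5], [1.0, 0.0, 0.0])

    @settings(max_examples=50, derandomize=True)
    @given(a=dist6, b=dist6)
    def test_symmetric_bounded_and_matches_reference(self, a, b):
        v = jsd(a, b)
        assert v == pytest.approx(jsd(b, a), abs=1e-12)
        assert -1e-12 <= v <= 2 * math.log(2) + 1e-12
        assert v == pytest.approx(ref_jsd(a, b), abs=1e-9)


class TestScoreMatrix:
    def test_identical_rows_score_minus_mean(self):
        # two identical emission rows: raw JSD 0, shifted score -round(10*mean)
        alphabet = StateAlphabet(("E1", "E2", "E3"))
        probs = np.array([[0.9, 0.1], [0.9, 0.1], [0.1, 0.9]])
        em = EmissionMatrix(alphabet, ("a", "b"), probs)
        matrix = build_score_matrix(em, background_state=None)
        rows = probs / probs.sum(axis=1, keepdims=True)
        jsds = [ref_jsd(rows[i], rows[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        mean = np.mean(jsds)
        expected = int(np.sign(-mean) * np.floor(abs(10 * mean) + 0.5))
        assert matrix.scores[0, 1] == expected
        assert expected < 0

    def test_background_rule_sets_matrix_minimum(self, toy_emissions):
        matrix = build_score_matrix(toy_emissions)
        minimum = matrix.scores.min()
        assert np.all(matrix.scores[3, :] == minimum)
        assert np.all(matrix.scores[:, 3] == minimum)

    def test_symmetric_integer_output(self, toy_emissions):
        matrix = build_score_matrix(toy_emissions)
        assert np.array_equal(matrix.scores, matrix.scores.T)
        assert matrix.scores.dtype == np.int64

    def test_background_rule_idempotent(self, toy_emissions):
        matrix = build_score_matrix(toy_emissions)
        scores = matrix.scores.copy()
        minimum = scores.min()
        scores[3, :] = minimum
        scores[:, 3] = minimum
        assert np.array_equal(scores, matrix.scores)

    def test_per_state_mean_mode_is_symmetric(self, toy_emissions):
        matrix = build_score_matrix(toy_emissions, mean_mode="per_state")
        assert np.array_equal(matrix.scores, matrix.scores.T)

    def test_tsv_roundtrip(self, tmp_path, toy_emissions):
        matrix = build_score_matrix(toy_emissions)
        path = tmp_path / "scores.tsv"
        matrix.to_tsv(path)
        back = ScoreMatrix.from_tsv(path, background_state=3)
        assert np.array_equal(back.scores, matrix.scores)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            ScoreMatrix(np.array([[0, 1], [2, 0]]), ("E1", "E2"))


class TestAssumptions:
    def test_all_negative_matrix_fails_positive_score(self):
        matrix = ScoreMatrix(-np.ones((2, 2), dtype=int), ("E1", "E2"))
        freqs = BackgroundFreqs([0.5, 0.5], [0.5, 0.5])
        report = check_assumptions(matrix, freqs)
        assert not report.positive_score_possible
        assert not report.passed

    def test_all_positive_matrix_fails_expected_score(self):
        matrix = ScoreMatrix(np.ones((2, 2), dtype=int), ("E1", "E2"))
        freqs = BackgroundFreqs([0.5, 0.5], [0.5, 0.5])
        report = check_assumptions(matrix, freqs)
        assert report.expected_score == pytest.approx(1.0)
        assert not report.passed

    def test_zero_expected_score_fails_strict_negativity(self):
        scores = np.array([[-1, 1], [1, -1]])
        matrix = ScoreMatrix(scores, ("E1", "E2"))
        freqs = BackgroundFreqs([0.5, 0.5], [0.5, 0.5])
        report = check_assumptions(matrix, freqs)
        assert report.expected_score == pytest.approx(0.0)
        assert not report.expected_score_negative

    def test_identical_emission_rows_make_scoring_unusable(self):
        alphabet = StateAlphabet(("E1", "E2", "E3"))
        em = EmissionMatrix(alphabet, ("a", "b"), np.tile([0.6, 0.4], (3, 1)))
        matrix = build_score_matrix(em, background_state=None)
        freqs = BackgroundFreqs(np.ones(3) / 3, np.ones(3) / 3)
        assert not check_assumptions(matrix, freqs).positive_score_possible


class TestEmpiricalFreqs:
    def test_counts_states_over_bins(self, toy_emissions):
        maps = [make_map("a", {"chr1": [0, 0, 1]})]
        ds = build_dataset(maps, toy_emissions, {"G": SampleGroup("G", ("a",))})
        freqs = empirical_state_freqs(ds, ds.group("G"))
        assert freqs.tolist() == [2 / 3, 1 / 3, 0.0, 0.0]

    def test_identical_replicates_do_not_change_freqs(self, toy_emissions):
        maps = [
            make_map("a", {"chr1": [0, 0, 1]}),
            make_map("b", {"chr1": [0, 0, 1]}),
        ]
        ds = build_dataset(
            maps, toy_emissions,
            {"G": SampleGroup("G", ("a", "b")), "S": SampleGroup("S", ("a",))},
        )
        both = empirical_state_freqs(ds, ds.group("G"))
        single = empirical_state_freqs(ds, ds.group("S"))
        assert np.allclose(both, single)

    def test_all_background_map(self, toy_emissions):
        maps = [make_map("a", {"chr1": [3, 3, 3]})]
        ds = build_dataset(maps, toy_emissions, {"G": SampleGroup("G", ("a",))})
        freqs = empirical_state_freqs(ds, ds.group("G"))
        assert freqs.tolist() == [0.0, 0.0, 0.0, 1.0]
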