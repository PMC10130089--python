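import itertools

import numpy as np
import pandas as pd
import pytest

from sibamod import (
    Biosignature,
    apparition_histogram,
    group_counts,
    hsic,
    median_heuristic_bandwidth,
    select_biosignature,
    select_by_pearson,
)
from sibamod.cohort_io import FEATURE_GROUPS
from sibamod.signature import SignatureEntry


def hsic_summation_oracle(x, y):
    """Explicit summation form of the biased estimator (independent of the
    trace-form implementation): builds H and the kernels element by element."""
    n = len(x)
    sx = median_heuristic_bandwidth(x)
    sy = median_heuristic_bandwidth(y)
    K = [[np.exp(-((x[i] - x[j]) ** 2) / (2 * sx * sx)) for j in range(n)] for i in range(n)]
    L = [[np.exp(-((y[i] - y[j]) ** 2) / (2 * sy * sy)) for j in range(n)] for i in range(n)]
    H = [[(1.0 if i == j else 0.0) - 1.0 / n for j in range(n)] for i in range(n)]
    total = 0.0
    for i, j, k, l in itertools.product(range(n), repeat=4):
        total += K[i][j] * H[j][k] * L[k][l] * H[l][i]
    return total / (n - 1) ** 2


class TestBandwidth:
    def test_small_example_enumerating_pairs(self):
        # pairs of [0,1,2]: |0-1|, |0-2|, |1-2| -> {1, 2, 1}, median 1
        assert median_heuristic_bandwidth(np.array([0.0, 1.0, 2.0])) == 1.0

    def test_single_pair(self):
        assert median_heuristic_bandwidth(np.array([0.0, 10.0])) == 10.0

    def test_constant_input_falls_back_to_one(self):
        assert median_heuristic_bandwidth(np.array([4.0, 4.0, 4.0])) == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            median_heuristic_bandwidth(np.array([1.0]))


class TestHsic:
    def test_constant_input_gives_zero(self, rng):
        # centering annihilates a constant kernel row space (up to fp dust)
        assert hsic(np.full(10, 3.0), rng.normal(size=10)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert hsic(x, y) == pytest.approx(hsic(y, x), abs=1e-12)

    def test_matches_quadruple_sum_oracle_n4(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        assert hsic(x, x) == pytest.approx(hsic_summation_oracle(x, x), abs=1e-12)

    def test_matches_oracle_on_random_inputs(self, rng):
        for _ in range(5):
            n = int(rng.integers(3, 9))  # the O(n^4) oracle limits n here
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert hsic(x, y) == pytest.approx(hsic_summation_oracle(x, y), abs=1e-10)

    def test_invariant_under_joint_permutation(self, rng):
        x, y = rng.normal(size=25), rng.normal(size=25)
        perm = rng.permutation(25)
        assert hsic(x[perm], y[perm]) == pytest.approx(hsic(x, y), abs=1e-10)

    def test_dependent_pair_exceeds_independent_decoys(self, rng):
        n = 200
        s = rng.uniform(size=n)
        planted = np.sin(3 * s) + 0.05 * rng.normal(size=n)
        decoy_scores = [hsic(rng.normal(size=n), s) for _ in range(200)]
        assert hsic(planted, s) > np.quantile(decoy_scores, 0.95) * 1.5

    def test_length_mismatch_and_short_input_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            hsic(np.arange(3.0), np.arange(4.0))
        with pytest.raises(ValueError, match="at least 2"):
            hsic(np.array([1.0]), np.array([2.0]))


def _feature_frame(rng, n=30, n_feats=8, signal_col=2, monotone=True):
    X = rng.normal(size=(n, n_feats))
    s = np.linspace(0, 1, n)
    X[:, signal_col] = s if monotone else (s - 0.5) ** 2
    names = [f"hrv_{i:02d}" for i in range(n_feats)]
    groups = {name: "hrv" for name in names}
    return pd.DataFrame(X, columns=names), 40 * s, groups


class TestSelection:
    def test_noiseless_driver_feature_ranked_first(self, rng):
        X, y, groups = _feature_frame(rng)
        sig = select_biosignature(X, y, 3, groups)
        assert sig.feature_names[0] == "hrv_02"

    def test_nonmonotone_dependence_found_by_hsic_not_pearson(self, rng):
        # the label is a symmetric (V-shaped) function of the driver feature,
        # so linear correlation is ~0 while kernel dependence is strong
        X, _, groups = _feature_frame(rng, monotone=True)
        s = X["hrv_02"].to_numpy()
        y = 40 * (s - 0.5) ** 2
        hs = select_biosignature(X, y, 1, groups)
        pe = select_by_pearson(X, y, 1, groups)
        assert hs.feature_names == ["hrv_02"]
        assert pe.feature_names != ["hrv_02"]

    def test_full_and_empty_signature_sizes(self, rng):
        X, y, groups = _feature_frame(rng)
        assert len(select_biosignature(X, y, X.shape[1], groups).entries) == X.shape[1]
        with pytest.raises(ValueError):
            select_biosignature(X, y, 0, groups)
        with pytest.raises(ValueError):
            select_biosignature(X, y, X.shape[1] + 1, groups)

    def test_selection_is_deterministic(self, rng):
        X, y, groups = _feature_frame(rng)
        a = select_biosignature(X, y, 5, groups)
        b = select_biosignature(X, y, 5, groups)
        assert [e.feature_name for e in a.entries] == [e.feature_name for e in b.entries]
        scores = [e.hsic_score for e in a.entries]
        assert scores == sorted(scores, reverse=True)

    def test_too_few_labeled_days_rejected(self, rng):
        X, y, groups = _feature_frame(rng, n=1)
        with pytest.raises(ValueError):
            select_biosignature(X.iloc[:1], y[:1], 2, groups)


def _sig(names, groups):
    entries = [SignatureEntry(n, 1.0, groups.get(n, "sleep")) for n in names]
    return Biosignature(nu=len(names), entries=entries, fit_day_set=[0, 1])


class TestSummaries:
    def test_group_counts_sum_to_nu_and_report_empty_groups(self):
        groups = {"sleep_00": "sleep", "sleep_01": "sleep", "hrv_00": "hrv"}
        counts = group_counts(_sig(["sleep_00", "sleep_01", "hrv_00"], groups))
        assert counts["sleep"] == 2 and counts["hrv"] == 1
        assert set(counts) == set(FEATURE_GROUPS)
        assert counts["activity"] == 0
        assert sum(counts.values()) == 3

    def test_apparition_identical_signatures(self):
        sigs = [_sig(["a", "b"], {}) for _ in range(4)]
        assert apparition_histogram(sigs) == {"a": 4, "b": 4}

    def test_apparition_disjoint_signatures(self):
        hist = apparition_histogram([_sig(["a"], {}), _sig(["b"], {})])
        assert max(hist.values()) == 1

    def test_apparition_requires_signatures(self):
        with pytest.raises(ValueError):
            apparition_histogram([])
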