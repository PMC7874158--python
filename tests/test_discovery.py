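"""mRMR, BER, CV framework, size selection, signature distance, consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from imlnc import (
    DiscoveryConfig,
    SignatureCandidate,
    balanced_error_rate,
    mrmr_select,
    pick_representative,
    run_cv_framework,
    select_signature_size,
    signature_distance,
    stratified_folds,
)
from imlnc.discovery import discretize_features, mutual_information


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def mi_oracle(a, b):
    """Plug-in MI from an explicitly built joint table (nats)."""
    a, b = np.asarray(a), np.asarray(b)
    mi = 0.0
    n = len(a)
    for va in np.unique(a):
        for vb in np.unique(b):
            pab = np.mean((a == va) & (b == vb))
            if pab > 0:
                mi += pab * np.log(pab / (np.mean(a == va) * np.mean(b == vb)))
    return mi


def mrmr_oracle(codes, y, n_select, feature_ids):
    """Greedy MID mRMR by exhaustive argmax scan at every step."""
    selected = []
    remaining = list(range(codes.shape[1]))
    while len(selected) < n_select:
        best, best_score = None, -np.inf
        for j in remaining:
            rel = mi_oracle(codes[:, j], y)
            red = np.mean([mi_oracle(codes[:, j], codes[:, s]) for s in selected]) if selected else 0.0
            score = rel - red
            if score > best_score + 1e-12:
                best, best_score = j, score
        selected.append(best)
        remaining.remove(best)
    return [feature_ids[j] for j in selected]


class TestMutualInformation:
    def test_matches_plugin_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 200)
        b = (a + rng.integers(0, 2, 200)) % 3
        assert mutual_information(a, b, 3, 3) == pytest.approx(mi_oracle(a, b))

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 5000)
        b = rng.integers(0, 2, 5000)
        assert mutual_information(a, b, 3, 2) < 0.005


class TestMrmrSelect:
    @staticmethod
    def _frame(X, ids):
        return pd.DataFrame(X.T, index=ids, columns=[f"s{i}" for i in range(X.shape[0])])

    def test_single_pick_is_max_relevance(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 120)
        X = rng.normal(size=(120, 5))
        X[:, 3] += 2.5 * y  # strongly informative
        z = self._frame(X, [f"f{i}" for i in range(5)])
        assert mrmr_select(z, pd.Series(y, index=z.columns), 1) == ["f3"]

    def test_redundancy_beats_raw_relevance(self):
        """A duplicated informative feature loses to a weaker independent one."""
        rng = np.random.default_rng(3)
        n = 400
        y = rng.integers(0, 2, n)
        strong = 2.0 * y + rng.normal(0, 0.3, n)
        dup = strong + rng.normal(0, 0.01, n)  # near-duplicate
        weak = 0.8 * y + rng.normal(0, 1.0, n)  # independent, weaker
        z = self._frame(np.column_stack([strong, dup, weak]), ["strong", "dup", "weak"])
        picked = mrmr_select(z, pd.Series(y, index=z.columns), 2)
        assert picked[0] in {"strong", "dup"}
        assert picked[1] == "weak"

    def test_matches_exhaustive_oracle(self):
        """Greedy path identical to the brute-force scan on <= 8 features."""
        rng = np.random.default_rng(4)
        n = 150
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 8))
        X[:, 0] += 1.5 * y
        X[:, 1] += X[:, 0] * 0.8
        X[:, 5] += 0.7 * y
        ids = [f"f{i}" for i in range(8)]
        z = self._frame(X, ids)
        picked = mrmr_select(z, pd.Series(y, index=z.columns), 4)
        codes = discretize_features(X)
        expected = mrmr_oracle(codes, y, 4, ids)
        assert picked == expected

    def test_permuted_labels_give_near_zero_relevance(self):
        rng = np.random.default_rng(5)
        n = 500
        X = rng.normal(size=(n, 6))
        X[:, 2] += 2.0 * rng.integers(0, 2, n)  # informative for *some* labels
        y_perm = rng.permutation(rng.integers(0, 2, n))
        z = self._frame(X, [f"f{i}" for i in range(6)])
        top = mrmr_select(z, pd.Series(y_perm, index=z.columns), 1)[0]
        codes = discretize_features(X)
        j = int(top[1])
        assert mi_oracle(codes[:, j], y_perm) < 0.01

    def test_constant_feature_excluded_with_warning(self):
        z = self._frame(np.column_stack([np.ones(40), np.linspace(0, 1, 40)]), ["const", "ok"])
        y = pd.Series([0, 1] * 20, index=z.columns)
        with pytest.warns(UserWarning, match="constant"):
            assert mrmr_select(z, y, 1) == ["ok"]


class TestBalancedErrorRate:
    def test_perfect_prediction(self):
        assert balanced_error_rate([0, 0, 1, 1], [0, 0, 1, 1]) == 0.0

    def test_majority_guess_is_half(self):
        y = [0] * 9 + [1]
        assert balanced_error_rate(y, [0] * 10) == 0.5

    def test_per_class_miscount(self):
        """8/10 right in class A, 6/10 in class B -> (0.2 + 0.4) / 2 = 0.3."""
        y = ["A"] * 10 + ["B"] * 10
        pred = ["A"] * 8 + ["B"] * 2 + ["B"] * 6 + ["A"] * 4
        assert balanced_error_rate(y, pred) == pytest.approx(0.3)

    def test_missing_class_raises(self):
        with pytest.raises(ValueError, match="2 classes"):
            balanced_error_rate([1, 1, 1], [1, 0, 1])


class TestSelectSignatureSize:
    def test_first_plateau_point(self):
        profile = dict(zip([1, 2, 3, 4, 5], [0.40, 0.25, 0.10, 0.10, 0.10]))
        assert select_signature_size(profile, tolerance=0.0) == 3

    def test_strictly_decreasing_selects_largest(self):
        profile = dict(zip([1, 2, 3], [0.4, 0.3, 0.2]))
        assert select_signature_size(profile, tolerance=0.0) == 3

    def test_flat_profile_selects_smallest(self):
        profile = {s: 0.2 for s in (1, 2, 3, 4)}
        assert select_signature_size(profile, tolerance=0.0) == 1

    def test_tolerance_absorbs_small_gains(self):
        profile = dict(zip([1, 2, 3], [0.30, 0.10, 0.095]))
        assert select_signature_size(profile, tolerance=0.01) == 2
        assert select_signature_size(profile, tolerance=0.0) == 3

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError):
            select_signature_size({})


def _toy_z(n_samples=6, seed=0, ids=("a", "b", "c", "d", "e", "f")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(len(ids), n_samples)),
        index=list(ids),
        columns=[f"s{i}" for i in range(n_samples)],
    )


def _cand(features, importances=None, ber=0.1, repeat=0, fold=0):
    k = len(features)
    imps = importances if importances is not None else tuple(np.linspace(1, 0.1, k))
    return SignatureCandidate(
        feature_ids=tuple(features), importances=tuple(imps), test_ber=ber,
        repeat_idx=repeat, fold_idx=fold,
    )


class TestSignatureDistance:
    def test_self_distance_zero(self):
        z = _toy_z()
        sig = _cand(["a", "b", "c"])
        assert signature_distance(sig, sig, z) == pytest.approx(0.0)

    def test_anticorrelated_partner_gives_two(self):
        z = _toy_z(ids=("a", "b", "c"))
        neg = -z.iloc[::-1]  # reversed order, negated values
        neg.index = ["na", "nb", "nc"]
        both = pd.concat([z, neg])
        s1 = _cand(["a", "b", "c"])
        s2 = _cand(["na", "nb", "nc"])
        # pair a<->na etc: na is -c... align explicitly: na rows are -c,-b,-a
        s2 = _cand(["nc", "nb", "na"])
        assert signature_distance(s1, s2, both) == pytest.approx(2.0)

    def test_matches_hand_spearman_sum(self):
        """3-feature toy distance equals the hand-ranked Spearman average."""
        z = _toy_z(seed=3)
        s1 = _cand(["a", "b", "c"], importances=(0.5, 0.3, 0.2))
        s2 = _cand(["d", "e", "f"], importances=(0.9, 0.5, 0.1))
        total = 0.0
        for f1, f2 in zip(["a", "b", "c"], ["d", "e", "f"]):
            r1 = rankdata(z.loc[f1])
            r2 = rankdata(z.loc[f2])
            total += np.corrcoef(r1, r2)[0, 1]
        assert signature_distance(s1, s2, z) == pytest.approx(1 - total / 3)

    def test_unsorted_importances_rejected(self):
        """Candidates must arrive Gini-sorted; the pairing relies on it."""
        with pytest.raises(ValueError, match="descending"):
            SignatureCandidate(("a", "b"), (0.2, 0.5), 0.1, 0, 0)

    def test_size_mismatch_raises(self):
        z = _toy_z()
        with pytest.raises(ValueError, match="size"):
            signature_distance(_cand(["a", "b"]), _cand(["a", "b", "c"]), z)

    def test_matching_pairing_bounds_gini_pairing(self):
        """Optimal assignment can only increase the paired Rho sum."""
        z = _toy_z(seed=9)
        s1 = _cand(["a", "b", "c"])
        s2 = _cand(["d", "e", "f"])
        d_gini = signature_distance(s1, s2, z)
        d_match = signature_distance(s1, s2, z, pairing="matching")
        assert d_match <= d_gini + 1e-12


class TestPickRepresentative:
    def test_identical_pair_beats_outlier(self):
        z = _toy_z(n_samples=8, seed=5)
        a = _cand(["a", "b", "c"], ber=0.2)
        b = _cand(["a", "b", "c"], ber=0.1, repeat=1)
        c = _cand(["d", "e", "f"], ber=0.05, repeat=2)
        res = pick_representative([a, b, c], z)
        assert res.representative_idx in (0, 1)
        # enumerate: D(a,b)=0 so their sums are D(a,c)=D(b,c); tie -> lower BER
        assert res.representative_idx == 1
        np.testing.assert_allclose(np.diag(res.distances), 0.0)
        np.testing.assert_allclose(res.distances, res.distances.T)
        assert (res.distances >= 0).all() and (res.distances <= 2).all()

    def test_two_candidates_tie_breaks_on_ber(self):
        z = _toy_z(seed=6)
        a = _cand(["a", "b", "c"], ber=0.3)
        b = _cand(["d", "e", "f"], ber=0.1, repeat=1)
        res = pick_representative([a, b], z)
        assert res.representative_idx == 1

    def test_all_identical_tie_breaks_on_index(self):
        z = _toy_z(seed=7)
        cands = [_cand(["a", "b", "c"], ber=0.2, repeat=r) for r in range(3)]
        res = pick_representative(cands, z)
        assert res.representative_idx == 0
        np.testing.assert_allclose(res.summed, 0.0, atol=1e-12)

    def test_matches_pairwise_signature_distance(self):
        """Vectorized matrix agrees with the per-pair function."""
        z = _toy_z(n_samples=10, seed=8)
        cands = [
            _cand(["a", "b", "c"], importances=(3.0, 2.0, 1.0)),
            _cand(["b", "d", "f"], importances=(5.0, 1.0, 0.5), repeat=1),
            _cand(["e", "c", "a"], importances=(2.0, 1.5, 0.2), repeat=2),
        ]
        res = pick_representative(cands, z)
        for i, j in itertools.combinations(range(3), 2):
            assert res.distances[i, j] == pytest.approx(
                signature_distance(cands[i], cands[j], z)
            )


class TestCvFramework:
    @staticmethod
    def _dataset(n=36, n_feat=20, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array(["IH", "IL"])[rng.integers(0, 2, n)]
        X = rng.normal(size=(n_feat, n))
        X[0] += 2.0 * (y == "IH")
        X[1] += 2.0 * (y == "IH")
        ids = [f"L{i}" for i in range(n_feat)]
        z = pd.DataFrame(X, index=ids, columns=[f"s{i}" for i in range(n)])
        return z, pd.Series(y, index=z.columns)

    def test_candidate_count_and_structure(self):
        z, y = self._dataset()
        cfg = DiscoveryConfig(
            n_repeats=4, rf_trees=16, size_grid=(1, 2, 3), top_frac=0.2,
            n_negative_controls=1, seed=1,
        )
        cv = run_cv_framework(z, y, cfg)
        assert len(cv.candidates) == 4 * 3
        assert all(c.size == cv.selected_size for c in cv.candidates)
        assert {(c.repeat_idx, c.fold_idx) for c in cv.candidates} == {
            (r, f) for r in range(4) for f in range(3)
        }
        assert set(cv.ber_by_size["size"]) == {1, 2, 3}
        assert (cv.ber_by_size["n"] == 12).all()

    def test_deterministic_given_seed(self):
        z, y = self._dataset(seed=2)
        cfg = DiscoveryConfig(n_repeats=2, rf_trees=16, size_grid=(1, 2), top_frac=0.2, seed=5)
        cv1 = run_cv_framework(z, y, cfg)
        cv2 = run_cv_framework(z, y, cfg)
        assert [c.feature_ids for c in cv1.candidates] == [c.feature_ids for c in cv2.candidates]
        pd.testing.assert_frame_equal(cv1.ber_by_size, cv2.ber_by_size)

    def test_small_class_rejected(self):
        z, y = self._dataset(n=10)
        y[:] = "IH"
        y.iloc[:2] = "IL"
        with pytest.raises(ValueError, match="n_folds"):
            run_cv_framework(z, y, DiscoveryConfig(n_repeats=1))

    def test_negative_control_near_chance(self):
        """Label-permuted runs hover at BER 0.5 regardless of signal."""
        z, y = self._dataset(n=48, seed=3)
        cfg = DiscoveryConfig(
            n_repeats=12, rf_trees=16, size_grid=(2,), top_frac=0.2,
            n_negative_controls=3, seed=7,
        )
        cv = run_cv_framework(z, y, cfg)
        assert len(cv.control_bers) >= 100
        assert 0.45 <= cv.control_bers.mean() <= 0.55


class TestStratifiedFolds:
    def test_three_fold_partition_sizes(self):
        """144 samples under 3-fold CV: train 96, test 48, disjoint, stratified."""
        y = np.array(["IH"] * 60 + ["IL"] * 84)
        folds = stratified_folds(y, 3, seed=0)
        assert len(folds) == 3
        for train, test in folds:
            assert len(train) == 96
            assert len(test) == 48
            assert set(train) & set(test) == set()
            assert set(y[train]) == {"IH", "IL"}
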