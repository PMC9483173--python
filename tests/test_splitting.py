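import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem
from rdkit.Chem import AllChem

from hergml.splitting import (
    SplitError,
    maxmin_pick,
    maxmin_split,
    morgan_fingerprint,
    pca_coverage_check,
    tanimoto,
)
from hergml.synthetic import fixture_smiles


class TestMorgan:
    def test_deterministic(self):
        assert np.array_equal(morgan_fingerprint("CCO"), morgan_fingerprint("CCO"))

    def test_different_molecules_differ(self):
        assert not np.array_equal(morgan_fingerprint("CCO"), morgan_fingerprint("CCCCCCCC"))

    def test_popcount_matches_toolkit_oracle(self):
        smi = "CC(=O)Oc1ccccc1C(=O)O"
        fp = morgan_fingerprint(smi, radius=2, nbits=2048)
        oracle = AllChem.GetMorganFingerprintAsBitVect(
            Chem.MolFromSmiles(smi), radius=2, nBits=2048
        )
        assert int(fp.sum()) == oracle.GetNumOnBits()

    def test_unparseable_raises(self):
        with pytest.raises(SplitError):
            morgan_fingerprint("not-a-smiles")


class TestTanimoto:
    def test_identical(self):
        v = np.array([1, 0, 1, 1], dtype=np.uint8)
        assert tanimoto(v, v) == 1.0

    def test_disjoint(self):
        assert tanimoto(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0

    def test_hand_counted(self):
        assert tanimoto(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0])) == pytest.approx(1 / 3)

    def test_both_empty_convention(self):
        z = np.zeros(8, dtype=np.uint8)
        assert tanimoto(z, z) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(SplitError):
            tanimoto(np.zeros(4), np.zeros(5))

    @given(st.lists(st.booleans(), min_size=1, max_size=64),
           st.lists(st.booleans(), min_size=1, max_size=64))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_symmetric(self, a, b):
        n = min(len(a), len(b))
        va, vb = np.array(a[:n]), np.array(b[:n])
        t = tanimoto(va, vb)
        assert 0.0 <= t <= 1.0
        assert t == tanimoto(vb, va)


def _naive_maxmin(fps, n_pick, start):
    """Independent reference: plain-python greedy MaxMin."""
    def dist(a, b):
        inter = sum(1 for x, y in zip(a, b) if x and y)
        union = sum(1 for x, y in zip(a, b) if x or y)
        return 1.0 - (1.0 if union == 0 else inter / union)

    picked = [start]
    while len(picked) < n_pick:
        best, best_d = None, -1.0
        for i in range(len(fps)):
            if i in picked:
                continue
            d = min(dist(fps[i], fps[j]) for j in picked)
            if d > best_d:
                best, best_d = i, d
        picked.append(best)
    return picked


class TestMaxMin:
    def test_colinear_triple_picks_extremes(self):
        a = np.array([1, 1, 1, 1, 0, 0, 0], dtype=np.uint8)
        b = np.array([0, 0, 1, 1, 1, 0, 0], dtype=np.uint8)
        c = np.array([0, 0, 0, 0, 1, 1, 1], dtype=np.uint8)
        picked = maxmin_pick([a, b, c], 2)
        assert set(picked) == {0, 2}  # a starts (max popcount), c is farthest

    @pytest.mark.parametrize("trial", range(5))
    def test_agrees_with_naive_implementation_small(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(3, 7))
        fps = [rng.integers(0, 2, 16).astype(np.uint8) for _ in range(n)]
        n_pick = int(rng.integers(2, n + 1))
        got = maxmin_pick(fps, n_pick)
        assert got == _naive_maxmin([list(f) for f in fps], n_pick, got[0])

    def test_order_invariance_of_selected_set(self):
        smiles = fixture_smiles(20)
        fps = [morgan_fingerprint(s) for s in smiles]
        picked = maxmin_pick(fps, 8, ids=smiles)
        perm = list(reversed(range(20)))
        picked_perm = maxmin_pick([fps[i] for i in perm], 8, ids=[smiles[i] for i in perm])
        assert {smiles[i] for i in picked} == {smiles[perm[i]] for i in picked_perm}


class TestSplit:
    def test_balanced_80_20_arithmetic(self):
        smiles = fixture_smiles(100)
        labels = ["ACT"] * 50 + ["INA"] * 50
        s = maxmin_split(smiles, labels, fraction=0.8)
        by = dict(zip(smiles, labels))
        assert len(s.train_ids) == 80 and len(s.valid_ids) == 20
        assert sum(by[i] == "ACT" for i in s.train_ids) == 40
        assert sum(by[i] == "ACT" for i in s.valid_ids) == 10

    def test_five_to_one_ratio_preserved(self):
        smiles = fixture_smiles(120)
        labels = ["ACT"] * 20 + ["INA"] * 100
        s = maxmin_split(smiles, labels, fraction=0.8)
        by = dict(zip(smiles, labels))
        train_act = sum(by[i] == "ACT" for i in s.train_ids)
        train_ina = len(s.train_ids) - train_act
        assert (train_act, train_ina) == (16, 80)  # 5:1 in the training half
        assert set(s.train_ids) | set(s.valid_ids) == set(smiles)
        assert not set(s.train_ids) & set(s.valid_ids)

    def test_determinism(self):
        smiles = fixture_smiles(40)
        labels = (["ACT"] * 20 + ["INA"] * 20)
        a = maxmin_split(smiles, labels, fraction=0.8)
        b = maxmin_split(smiles, labels, fraction=0.8)
        assert a.train_ids == b.train_ids and a.valid_ids == b.valid_ids

    def test_tiny_class_raises(self):
        with pytest.raises(SplitError):
            maxmin_split(["CCO", "CCN"], ["ACT", "INA"])


class TestPCACoverage:
    def test_rank_two_data_fully_explained(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(0, 1, (2, 6))
        train = rng.normal(0, 1, (30, 2)) @ basis
        valid = rng.normal(0, 1, (10, 2)) @ basis
        rep = pca_coverage_check(train, valid)
        assert rep["variance_explained_pc1_2"] == pytest.approx(1.0, abs=1e-9)

    def test_interior_validation_box_contained(self):
        rng = np.random.default_rng(1)
        train = rng.uniform(-1, 1, (50, 4))
        valid = 0.1 * rng.uniform(-1, 1, (10, 4))  # strictly interior
        rep = pca_coverage_check(train, valid)
        tr, va = rep["score_ranges"]["train"], rep["score_ranges"]["valid"]
        for pc in ("pc1", "pc2"):
            assert tr[pc][0] <= va[pc][0] and va[pc][1] <= tr[pc][1]

    def test_duplicate_sets_identical_ranges(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (20, 5))
        rep = pca_coverage_check(X, X.copy())
        assert rep["score_ranges"]["train"] == rep["score_ranges"]["valid"]

    def test_too_few_descriptors(self):
        with pytest.raises(SplitError):
            pca_coverage_check(np.ones((5, 1)), np.ones((3, 1)))
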