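"""Alpha diversity, Bray-Curtis, NMDS, and ANOSIM against closed forms and
independent oracles (hand formulas, scipy distance, skbio ANOSIM)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import rankdata
from scipy.stats import t as t_dist

import rumenomics as rm
from rumenomics.diversity import anosim_r, welch_t_test
from conftest import GROUPS, SAMPLES, make_abundance, make_otu_table


class TestAlphaDiversity:
    def test_uniform_closed_form(self):
        a = make_abundance(np.full((6, 4), 0.25))
        alpha = rm.alpha_diversity(a)
        assert np.allclose(alpha["shannon"], np.log(4), atol=1e-12)
        assert np.allclose(alpha["simpson"], 0.75, atol=1e-12)

    def test_single_taxon_zero_diversity(self):
        a = make_abundance(np.ones((6, 1)))
        alpha = rm.alpha_diversity(a)
        assert np.allclose(alpha, 0.0, atol=1e-12)

    def test_direct_evaluation(self):
        a = make_abundance(np.tile([0.5, 0.3, 0.2], (6, 1)))
        assert rm.alpha_diversity(a)["shannon"].iloc[0] == pytest.approx(1.02965, abs=1e-5)

    def test_within_taxon_renormalises_and_flags_absent(self):
        counts = np.array([[2, 0, 2, 6]] * 5 + [[0, 0, 5, 5]])
        t = make_otu_table(counts)  # genus_0: OTU_0, OTU_2; genus_1: OTU_1, OTU_3
        a = rm.relative_abundance(t)
        alpha = rm.alpha_diversity(a, rank="genus", taxon="Genus_0")
        # within Genus_0 the first five samples split 0.5/0.5
        assert alpha["shannon"].iloc[0] == pytest.approx(np.log(2))
        alpha1 = rm.alpha_diversity(a, rank="genus", taxon="Genus_1")
        assert not alpha1.isna().any().any()
        # sample with no Genus_0 members... OTU_0 zero but OTU_2 present: present
        assert not np.isnan(alpha["shannon"].iloc[5])


class TestWelch:
    def test_hand_computed_oracle(self):
        x, y = np.array([1.0, 2, 3]), np.array([2.0, 4, 6])
        t, p = welch_t_test(x, y)
        # textbook arithmetic: vx=1, vy=4, se2=5/3, df from Welch-Satterthwaite
        se2 = 1 / 3 + 4 / 3
        t_exp = (2 - 4) / np.sqrt(se2)
        df_exp = se2**2 / ((1 / 3) ** 2 / 2 + (4 / 3) ** 2 / 2)
        assert t == pytest.approx(t_exp)
        assert p == pytest.approx(2 * t_dist.sf(abs(t_exp), df_exp))

    def test_identical_groups(self):
        assert welch_t_test([1, 1, 1], [1, 1, 1]) == (0.0, 1.0)

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        x = 1 + rng.normal(0, 1e-9, 3)
        y = 2 + rng.normal(0, 1e-9, 3)
        _, p = welch_t_test(x, y)
        assert p < 0.01

    def test_group_test_requires_two_per_group(self):
        alpha = pd.DataFrame({"shannon": [1.0, 2.0], "simpson": [0.5, 0.6]},
                             index=["LC1", "MC1"])
        with pytest.raises(rm.ValidationError):
            rm.diversity_group_test(alpha, GROUPS.loc[["LC1", "MC1"]])


class TestBrayCurtis:
    def test_hand_value(self):
        a = make_abundance(np.array([[0.6, 0.2, 0.2], [0.2, 0.6, 0.2]] * 3))
        d = rm.bray_curtis(a)
        assert d.values[0, 1] == pytest.approx(0.4)

    def test_identical_and_disjoint(self):
        a = make_abundance(np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]] * 2))
        d = rm.bray_curtis(a)
        assert d.values[0, 1] == pytest.approx(0.0)
        assert d.values[0, 2] == pytest.approx(1.0)

    @given(arrays(np.float64, (4, 6), elements=st.floats(0.01, 1.0)))
    def test_properties_and_scipy_oracle(self, raw):
        frac = raw / raw.sum(axis=1, keepdims=True)
        a = make_abundance(frac)
        d = rm.bray_curtis(a).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()
        for i, j in itertools.combinations(range(4), 2):
            assert d[i, j] == pytest.approx(scipy_braycurtis(frac[i], frac[j]))


class TestNmds:
    def test_exactly_embeddable_triangle(self):
        d = rm.DistanceMatrix(
            ids=("a", "b", "c"),
            values=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
        )
        res = rm.nmds(d, k=2, seed=0)
        assert res.stress < 1e-3

    def test_seed_reproducible(self):
        rng = np.random.default_rng(1)
        x = rng.random((5, 3))
        a = make_abundance(x / x.sum(axis=1, keepdims=True))
        d = rm.bray_curtis(a)
        r1 = rm.nmds(d, seed=42)
        r2 = rm.nmds(d, seed=42)
        pd.testing.assert_frame_equal(r1.coordinates, r2.coordinates)
        assert r1.stress == r2.stress

    def test_stress_non_increasing_within_start(self):
        rng = np.random.default_rng(2)
        x = rng.random((7, 4))
        a = make_abundance(x / x.sum(axis=1, keepdims=True),
                           groups=pd.Series(["g"] * 7, index=[f"s{i}" for i in range(7)]))
        d = rm.bray_curtis(a)
        res = rm.nmds(d, n_starts=3, seed=5)
        diffs = np.diff(res.stress_history)
        assert (diffs <= 1e-12).all()

    def test_k_must_be_smaller_than_n(self):
        d = rm.DistanceMatrix(ids=("a", "b"), values=np.array([[0, 1], [1, 0]], float))
        with pytest.raises(rm.ValidationError):
            rm.nmds(d, k=2)

    def test_non_symmetric_rejected(self):
        with pytest.raises(rm.ValidationError, match="symmetric"):
            rm.DistanceMatrix(ids=("a", "b"), values=np.array([[0, 1], [2, 0]], float))


def _naive_anosim_r(dist: np.ndarray, labels: list) -> float:
    """Independent oracle: explicit pair enumeration + average ranks."""
    pairs = []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append((dist[i, j], labels[i] != labels[j]))
    values = [p[0] for p in pairs]
    ranks = rankdata(values)
    between = [r for r, p in zip(ranks, pairs) if p[1]]
    within = [r for r, p in zip(ranks, pairs) if not p[1]]
    m = len(pairs)
    return (np.mean(between) - np.mean(within)) / (m / 2)


class TestAnosim:
    def _separated(self):
        v = np.array(
            [[0.0, 0.1, 0.1, 0.9, 0.8, 0.9],
             [0.1, 0.0, 0.2, 0.9, 0.9, 0.8],
             [0.1, 0.2, 0.0, 0.8, 0.9, 0.9],
             [0.9, 0.9, 0.8, 0.0, 0.1, 0.2],
             [0.8, 0.9, 0.9, 0.1, 0.0, 0.1],
             [0.9, 0.8, 0.9, 0.2, 0.1, 0.0]]
        )
        return rm.DistanceMatrix(ids=tuple(SAMPLES), values=v)

    def test_complete_separation_gives_r_one(self):
        res = rm.anosim(self._separated(), GROUPS, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_all_ties_give_r_zero(self):
        v = np.ones((6, 6)) - np.eye(6)
        d = rm.DistanceMatrix(ids=tuple(SAMPLES), values=v)
        assert anosim_r(d, GROUPS) == pytest.approx(0.0)

    def test_two_plus_two_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        raw = rng.random((4, 4))
        v = (raw + raw.T) / 2
        np.fill_diagonal(v, 0)
        ids = ("s1", "s2", "s3", "s4")
        d = rm.DistanceMatrix(ids=ids, values=v)
        for split in itertools.combinations(range(4), 2):
            labels = ["B"] * 4
            for i in split:
                labels[i] = "A"
            groups = pd.Series(labels, index=list(ids))
            assert anosim_r(d, groups) == pytest.approx(_naive_anosim_r(v, labels))

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        x = rng.dirichlet(np.ones(12), size=8)
        labels = ["A"] * 4 + ["B"] * 4
        ids = [f"s{i}" for i in range(8)]
        a = make_abundance(x, groups=pd.Series(labels, index=ids))
        d = rm.bray_curtis(a)
        ours = rm.anosim(d, a.groups, n_perm=999, seed=0)
        theirs = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d.values, ids), labels, permutations=0
        )
        assert ours.r == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_pvalue_convention_never_zero(self):
        res = rm.anosim(self._separated(), GROUPS, n_perm=9, seed=0)
        assert 0 < res.p_value <= 1

    def test_rejects_singleton_group(self):
        d = self._separated()
        groups = pd.Series(["A"] + ["B"] * 5, index=SAMPLES)
        with pytest.raises(rm.ValidationError):
            rm.anosim(d, groups)
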