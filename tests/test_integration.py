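"""SCFA statistics, molar proportions, the OTU-SCFA screen, and constrained
correspondence analysis against brute-force and external (vegan) oracles."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency
from scipy.stats import f as f_dist

import rumenomics as rm
from rumenomics.integration import SCFAS, one_way_anova
from conftest import GROUPS, SAMPLES


def make_scfa(conc_by_time: dict, groups=None) -> rm.ScfaProfile:
    """conc_by_time: {time_h: array (n_samples x 6)}."""
    g = groups if groups is not None else GROUPS
    rows = []
    for t, conc in conc_by_time.items():
        for i, sid in enumerate(g.index):
            rows.append({"sample": sid, "time_h": t,
                         **{s: conc[i, k] for k, s in enumerate(SCFAS)}, "pH": 6.5})
    return rm.ScfaProfile(data=pd.DataFrame(rows), groups=g)


class TestMolarProportions:
    def test_hand_fractions(self):
        conc = np.tile([60.0, 20, 20, 0, 0, 0], (6, 1))
        s = make_scfa({8: conc})
        props = rm.molar_proportions(s)
        assert np.allclose(props.iloc[0], [0.6, 0.2, 0.2, 0, 0, 0])
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        conc = rng.uniform(1, 50, (6, 6))
        a = rm.molar_proportions(make_scfa({8: conc}))
        b = rm.molar_proportions(make_scfa({8: 2 * conc}))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_total_rejected(self):
        conc = np.tile([60.0, 20, 20, 0, 0, 0], (6, 1))
        conc[2] = 0
        with pytest.raises(rm.ValidationError, match="LC3"):
            rm.molar_proportions(make_scfa({8: conc}))

    def test_missing_time_point(self):
        s = make_scfa({8: np.ones((6, 6))})
        with pytest.raises(rm.ValidationError, match="not present"):
            rm.molar_proportions(s, time_point=2)


class TestScfaGroupStats:
    def test_anova_matches_textbook_sums_of_squares(self):
        f, p = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        # hand arithmetic: SSB = 3*((2-3)^2+(3-3)^2+(4-3)^2) = 6 on 2 df,
        # SSW = 2+2+2 = 6 on 6 df, so F = 3/1 = 3
        assert f == pytest.approx(3.0)
        assert p == pytest.approx(float(f_dist.sf(3.0, 2, 6)))

    def test_identical_means_f_zero(self):
        f, p = one_way_anova([[2, 2, 2], [2, 2, 2]])
        assert (f, p) == (0.0, 1.0)

    def test_between_group_t_on_equal_vectors_is_one(self):
        conc = np.tile([60.0, 20, 10, 2, 1, 2], (6, 1))
        s = make_scfa({0: conc, 2: conc, 5: conc, 8: conc})
        stats = rm.scfa_group_stats(s)
        t_rows = stats[(stats["test"] == "ttest_group") & (stats["analyte"] == "acetate")]
        assert np.allclose(t_rows["p"], 1.0)
        prop_rows = stats[stats["test"] == "ttest_proportion"]
        assert np.allclose(prop_rows["p"].dropna(), 1.0)

    def test_planted_group_effects_detected_in_recovery_mode(self):
        cfg = rm.SyntheticConfig.recovery(seed=3)
        s, _ = rm.simulate_scfa(cfg)
        stats = rm.scfa_group_stats(s)
        but = stats[(stats["test"] == "ttest_proportion") & (stats["analyte"] == "butyrate")]
        assert float(but["p"].iloc[0]) < 0.01
        tot2 = stats[(stats["test"] == "ttest_group") & (stats["analyte"] == "total")
                     & (stats["time_h"] == 2)]
        assert float(tot2["p"].iloc[0]) < 0.01


class TestScreen:
    def _abundance(self, fractions):
        frame = pd.DataFrame(fractions, index=SAMPLES,
                             columns=[f"OTU_{j}" for j in range(fractions.shape[1])])
        return rm.AbundanceTable(fractions=frame, groups=GROUPS)

    def test_rank_equal_otu_retained_with_enumerated_p(self):
        frac = np.column_stack([
            np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.06]),
            np.array([0.99, 0.98, 0.97, 0.96, 0.95, 0.94]),
        ])
        a = self._abundance(frac)
        props = pd.DataFrame(
            {"butyrate": [0.08, 0.09, 0.10, 0.11, 0.12, 0.13]}, index=SAMPLES
        )
        out = rm.otu_scfa_screen(a, props)
        assert "OTU_0" in out.retained
        row = out.best.set_index("otu").loc["OTU_0"]
        assert row["rho"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(2 / 720)
        # the anti-correlated OTU fails the signed rule but passes |rho| mode
        assert "OTU_1" not in out.retained
        out_abs = rm.otu_scfa_screen(a, props, absolute=True)
        assert out_abs.retained == {"OTU_0", "OTU_1"}

    def test_constant_otu_dropped_with_reason(self):
        frac = np.column_stack([np.full(6, 0.5), np.full(6, 0.5)])
        a = self._abundance(frac)
        props = pd.DataFrame({"butyrate": np.linspace(0.1, 0.2, 6)}, index=SAMPLES)
        out = rm.otu_scfa_screen(a, props)
        assert set(out.dropped_constant) == {"OTU_0", "OTU_1"}
        assert out.retained == set()

    def test_empty_table_gives_nan_sentinel(self):
        a = self._abundance(np.zeros((6, 0)))
        props = pd.DataFrame({"butyrate": np.linspace(0.1, 0.2, 6)}, index=SAMPLES)
        out = rm.otu_scfa_screen(a, props)
        assert out.retained == set()
        assert np.isnan(out.removed_fraction)

    def test_null_retention_is_rare(self):
        rng = np.random.default_rng(5)
        kept = 0
        total = 0
        for _ in range(10):
            raw = rng.uniform(0.5, 1.5, (6, 30))
            frac = raw / raw.sum(axis=1, keepdims=True)
            props = pd.DataFrame(
                rng.dirichlet(np.ones(6) * 20, 6), index=SAMPLES, columns=list(SCFAS)
            )
            out = rm.otu_scfa_screen(self._abundance(frac), props)
            kept += out.n_retained
            total += out.n_input
        assert kept / total < 0.1


def _random_case(rng, n=6, m=10, q=3):
    y = pd.DataFrame(
        rng.integers(0, 30, size=(n, m)).astype(float) + 1,
        index=[f"s{i}" for i in range(n)],
        columns=[f"o{j}" for j in range(m)],
    )
    x = pd.DataFrame(rng.normal(size=(n, q)), index=y.index,
                     columns=[f"e{k}" for k in range(q)])
    return y, x


def cca_bruteforce(Y, X):
    """Independent route: QR basis + generalised eigenproblem via eigh."""
    P = Y / Y.sum()
    r, c = P.sum(1), P.sum(0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    Xc = X - r @ X
    Xc = Xc / np.sqrt(r @ (Xc**2))
    Xw = np.sqrt(r)[:, None] * Xc
    Z, _ = np.linalg.qr(Xw)
    M = Z.T @ Q
    w, W = np.linalg.eigh(M @ M.T)
    order = np.argsort(w)[::-1]
    w, W = w[order], W[:, order]
    keep = w > 1e-10
    w, W = w[keep], W[:, keep]
    U = Z @ W
    Qfit = Z @ M
    V = (Qfit.T @ U) / np.sqrt(w)
    species = V / np.sqrt(c)[:, None]
    site_lc = U / np.sqrt(r)[:, None]
    return w, species, site_lc


class TestCca:
    def test_total_inertia_equals_chi2_over_grand_total(self):
        rng = np.random.default_rng(1)
        y, x = _random_case(rng)
        res = rm.cca(y, x)
        chi2 = chi2_contingency(y.to_numpy(), correction=False).statistic
        assert res.total_inertia == pytest.approx(chi2 / y.to_numpy().sum(), abs=1e-10)

    def test_matches_bruteforce_eigenproblem(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y, x = _random_case(rng)
            res = rm.cca(y, x)
            w, species, site_lc = cca_bruteforce(y.to_numpy(), x.to_numpy())
            assert np.allclose(res.eigenvalues, w, atol=1e-10)
            for k in range(len(w)):
                for ours, theirs in ((res.species_scores, species),
                                     (res.site_scores_lc, site_lc)):
                    a = ours.iloc[:, k].to_numpy()
                    b = theirs[:, k]
                    assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_inertia_conserved(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y, x = _random_case(rng, n=7, m=12, q=4)
            res = rm.cca(y, x)
            assert res.constrained_inertia + res.unconstrained_inertia == pytest.approx(
                res.total_inertia, abs=1e-10
            )

    def test_full_rank_constraints_reduce_to_plain_ca(self):
        rng = np.random.default_rng(4)
        y, _ = _random_case(rng, n=5, m=8)
        indicators = pd.DataFrame(np.eye(5), index=y.index,
                                  columns=[f"i{k}" for k in range(5)])
        with pytest.warns(UserWarning):
            res = rm.cca(y, indicators, standardize=False)
        Y = y.to_numpy()
        P = Y / Y.sum()
        r, c = P.sum(1), P.sum(0)
        E = np.outer(r, c)
        Q = (P - E) / np.sqrt(E)
        s = np.linalg.svd(Q, compute_uv=False)
        ca_eig = s[s**2 > 1e-10] ** 2
        assert np.allclose(res.eigenvalues, ca_eig, atol=1e-10)

    def test_single_binary_constraint_gives_one_axis(self):
        rng = np.random.default_rng(5)
        y, _ = _random_case(rng)
        x = pd.DataFrame({"group": [0, 0, 0, 1, 1, 1]}, index=y.index)
        res = rm.cca(y, x)
        assert len(res.eigenvalues) == 1
        assert res.eigenvalues[0] > 0

    def test_constrained_inertia_monotone_in_constraints(self):
        rng = np.random.default_rng(6)
        y, x = _random_case(rng, q=4)
        previous = 0.0
        for q in range(1, 5):
            res = rm.cca(y, x.iloc[:, :q])
            assert res.constrained_inertia >= previous - 1e-12
            previous = res.constrained_inertia

    def test_negative_abundance_rejected(self):
        rng = np.random.default_rng(7)
        y, x = _random_case(rng)
        y.iloc[0, 0] = -1
        with pytest.raises(rm.ValidationError, match="nonnegative"):
            rm.cca(y, x)

    def test_zero_sum_rows_dropped_with_warning(self):
        rng = np.random.default_rng(8)
        y, x = _random_case(rng)
        y.iloc[0] = 0
        with pytest.warns(UserWarning, match="zero-sum"):
            res = rm.cca(y, x)
        assert "s0" not in res.site_scores_lc.index

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_vegan(self, tmp_path):
        rng = np.random.default_rng(9)
        y, x = _random_case(rng)
        res = rm.cca(y, x)
        y.to_csv(tmp_path / "Y.csv")
        x.to_csv(tmp_path / "X.csv")
        script = tmp_path / "cca.R"
        script.write_text(
            'suppressMessages(library(vegan))\n'
            'Y <- read.csv("Y.csv", row.names=1)\n'
            'X <- read.csv("X.csv", row.names=1)\n'
            'm <- cca(Y ~ e0 + e1 + e2, data=X)\n'
            'cat(sprintf("%.12g", m$CCA$eig), sep=",")\ncat("\\n")\n'
            'cat(sprintf("%.12g", m$CA$eig), sep=",")\ncat("\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", "cca.R"], cwd=tmp_path, capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        lines = out.stdout.strip().splitlines()
        veg_constrained = np.array([float(v) for v in lines[0].split(",")])
        veg_unconstrained = np.array([float(v) for v in lines[1].split(",")])
        assert np.allclose(res.eigenvalues, veg_constrained, atol=1e-8)
        assert np.allclose(res.unconstrained_eigenvalues, veg_unconstrained, atol=1e-8)


class TestGenusCentroids:
    def _result(self, species, col_weights):
        axes = [f"CCA{i + 1}" for i in range(species.shape[1])]
        frame = pd.DataFrame(species, index=[f"OTU_{i}" for i in range(len(species))],
                             columns=axes)
        return rm.CcaResult(
            eigenvalues=np.ones(species.shape[1]),
            unconstrained_eigenvalues=np.array([]),
            total_inertia=1.0, constrained_inertia=1.0, unconstrained_inertia=0.0,
            site_scores_lc=pd.DataFrame(), site_scores_wa=pd.DataFrame(),
            species_scores=frame,
            biplot_scores=pd.DataFrame(), rank=species.shape[1],
            row_weights=pd.Series(dtype=float),
            col_weights=pd.Series(col_weights, index=frame.index),
        )

    def test_single_otu_genus_equals_its_score(self):
        res = self._result(np.array([[1.5, -2.0]]), [1.0])
        tax = pd.DataFrame({"genus": ["G"]}, index=["OTU_0"])
        cen = rm.genus_centroids(res, tax)
        assert np.allclose(cen.loc["G"], [1.5, -2.0])

    def test_uniform_weighting_symmetry(self):
        res = self._result(np.array([[1.0, 2.0], [-1.0, -2.0]]), [0.9, 0.1])
        tax = pd.DataFrame({"genus": ["G", "G"]}, index=["OTU_0", "OTU_1"])
        cen = rm.genus_centroids(res, tax, weighting="uniform")
        assert np.allclose(cen.loc["G"], [0.0, 0.0])

    def test_abundance_weighted_mean(self):
        res = self._result(np.array([[0.0, 0.0], [4.0, 0.0]]), [3.0, 1.0])
        tax = pd.DataFrame({"genus": ["G", "G"]}, index=["OTU_0", "OTU_1"])
        cen = rm.genus_centroids(res, tax)
        assert np.allclose(cen.loc["G"], [1.0, 0.0])


class TestAssociationSigns:
    def test_signs_and_consistency(self, study, abundance):
        props = rm.molar_proportions(study.scfa)
        genus = rm.aggregate_taxa(abundance, "genus")
        out = rm.association_signs(
            props, study.expression, genus,
            [("butyrate", "butyrate"), ("butyrate", "HDAC1"),
             ("Clostridium_IV", "GPR1")],
        )
        self_row = out.iloc[0]
        assert self_row["rho"] == pytest.approx(1.0)
        assert self_row["sign"] == 1
        for row in out.itertuples():
            assert row.sign == np.sign(row.rho)

    def test_unknown_variable_lists_candidates(self, study, abundance):
        props = rm.molar_proportions(study.scfa)
        genus = rm.aggregate_taxa(abundance, "genus")
        with pytest.raises(rm.ValidationError, match="candidates"):
            rm.association_signs(props, study.expression, genus, [("nope", "HDAC1")])
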