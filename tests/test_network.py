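"""GGM estimation, SNP-node integration, greedy phenotype-module search."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mqtlnet import network
from mqtlnet.qtl import IndependentSet

from conftest import transformed_from


def _gauss_matrix(cov, n, seed=0, prefix="M"):
    rng = np.random.default_rng(seed)
    p = cov.shape[0]
    X = rng.multivariate_normal(np.zeros(p), cov, size=n)
    vals = pd.DataFrame(X, index=[f"S{i}" for i in range(n)],
                        columns=[f"{prefix}{j}" for j in range(p)])
    return transformed_from(vals)


class TestShrinkagePcor:
    def test_matches_unregularized_inverse_at_large_n(self):
        """With n >> p the shrinkage pcor matrix is within 0.02 elementwise
        of the plain inverse-correlation pcor."""
        rng = np.random.default_rng(3)
        p = 12
        A = rng.normal(0, 1, (p, p))
        cov = A @ A.T + p * np.eye(p)
        m = _gauss_matrix(cov, n=6000, seed=4)
        X = m.values.to_numpy()
        R_star, lam = network.shrinkage_correlation(X)
        pcor_shrunk = network.partial_correlations(R_star)
        R_plain = np.corrcoef(X, rowvar=False)
        pcor_plain = network.partial_correlations(R_plain)
        assert lam < 0.05
        assert np.max(np.abs(pcor_shrunk - pcor_plain)) < 0.02

    def test_identity_input_gives_zero_partial_correlations(self):
        pcor = network.partial_correlations(np.eye(5))
        off = pcor[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)


class TestEstimateGGM:
    def test_chain_recovers_direct_edges_only(self):
        """A -> B -> C chain: marginal corr(A,C) ~ 0.5 but only A-B and
        B-C are edged; pcor(A,C|rest) stays near 0."""
        r = 0.7  # corr(A,C) = r^2 = 0.49
        cov = np.array([[1, r, r * r], [r, 1, r], [r * r, r, 1]])
        # closed-form oracle on the true covariance: pcor(A,C | B) = 0
        pcor_true = network.partial_correlations(cov)
        assert pcor_true[0, 2] == pytest.approx(0.0, abs=1e-12)
        m = _gauss_matrix(cov, n=2000, seed=8)
        G = network.estimate_ggm(m)
        assert G.has_edge("M0", "M1") and G.has_edge("M1", "M2")
        assert not G.has_edge("M0", "M2")
        # empirical pcor(A,C|B) close to the oracle zero
        R_star, _ = network.shrinkage_correlation(m.values.to_numpy())
        assert abs(network.partial_correlations(R_star)[0, 2]) < 0.05

    def test_negative_partial_correlation_never_edged(self):
        cov = np.array([[1.0, -0.45, 0.0], [-0.45, 1.0, 0.0], [0.0, 0.0, 1.0]])
        m = _gauss_matrix(cov, n=3000, seed=9)
        G = network.estimate_ggm(m)
        assert not G.has_edge("M0", "M1")
        # the pair is strongly (negatively) partially correlated, just excluded
        R_star, _ = network.shrinkage_correlation(m.values.to_numpy())
        assert network.partial_correlations(R_star)[0, 1] < -0.3

    def test_independent_metabolites_no_edges(self):
        for seed in range(5):
            m = _gauss_matrix(np.eye(30), n=500, seed=seed)
            G = network.estimate_ggm(m)
            assert G.number_of_edges() == 0

    def test_edge_count_monotone_in_pcor_min_and_alpha(self):
        rng = np.random.default_rng(12)
        A = rng.normal(0, 0.4, (10, 10))
        cov = A @ A.T + np.eye(10)
        m = _gauss_matrix(cov, n=800, seed=13)
        edges = [
            network.estimate_ggm(m, pcor_min=t).number_of_edges()
            for t in (0.0, 0.1, 0.2, 0.4)
        ]
        assert all(b <= a for a, b in zip(edges, edges[1:]))
        edges_alpha = [
            network.estimate_ggm(m, alpha=a, pcor_min=0.0).number_of_edges()
            for a in (1e-6, 1e-3, 0.05)
        ]
        assert all(b >= a for a, b in zip(edges_alpha, edges_alpha[1:]))

    def test_default_denominator_is_squared_count(self):
        m = _gauss_matrix(np.eye(7), n=100, seed=1)
        G = network.estimate_ggm(m)
        assert G.graph["bonferroni_denominator"] == 49
        G2 = network.estimate_ggm(m, pairwise_denominator=True)
        assert G2.graph["bonferroni_denominator"] == 21

    def test_confounder_residualization_removes_spurious_edges(self):
        """Two metabolites driven by the same covariate are connected
        unless the confounder is projected out."""
        rng = np.random.default_rng(21)
        n = 1500
        z = rng.normal(0, 1, n)
        vals = pd.DataFrame(
            {"M0": 0.8 * z + 0.6 * rng.normal(0, 1, n),
             "M1": 0.8 * z + 0.6 * rng.normal(0, 1, n),
             "M2": rng.normal(0, 1, n)},
            index=[f"S{i}" for i in range(n)],
        )
        m = transformed_from(vals)
        conf = pd.DataFrame({"age": z}, index=vals.index)
        G_raw = network.estimate_ggm(m)
        G_adj = network.estimate_ggm(m, conf)
        assert G_raw.has_edge("M0", "M1")
        assert not G_adj.has_edge("M0", "M1")

    def test_too_few_subjects_rejected(self):
        m = _gauss_matrix(np.eye(3), n=20, seed=2)
        with pytest.raises(ValueError, match="30 subjects"):
            network.estimate_ggm(m)


class TestAddSnpNodes:
    def _net(self):
        G = nx.Graph()
        G.add_nodes_from(["M0", "M1"], kind="metabolite")
        G.add_edge("M0", "M1", pcor=0.4, p=1e-8, provenance="ggm")
        return G

    def test_empty_collection_leaves_network_unchanged(self):
        G = self._net()
        out = network.add_snp_nodes(G, {})
        assert nx.utils.graphs_equal(G, out)

    def test_one_snp_two_metabolites_single_node_two_edges(self):
        G = self._net()
        ind = {
            "M0": IndependentSet("M0", ["rs1"], [1e-20], [0.05]),
            "M1": IndependentSet("M1", ["rs1"], [1e-15], [0.05]),
        }
        out = network.add_snp_nodes(G, ind)
        assert network.network_summary(out) == (2, 1, 3)
        assert out.edges[("rs1", "M0")]["provenance"] == "metqtl"

    def test_missing_metabolite_skipped_with_warning(self):
        G = self._net()
        ind = {"M9": IndependentSet("M9", ["rs2"], [1e-9], [0.05])}
        with pytest.warns(RuntimeWarning, match="absent"):
            out = network.add_snp_nodes(G, ind)
        assert "rs2" not in out


class TestScoreProfile:
    def test_null_score_tail_calibrated(self):
        """P(score > 2) ~ 0.01 when profile is independent of the phenotype."""
        rng = np.random.default_rng(31)
        n = 1000
        exceed = 0
        reps = 1000
        x = rng.normal(0, 1, n)
        for _ in range(reps):
            _, s = network.score_profile(rng.normal(0, 1, n), x)
            exceed += s > 2
        assert abs(exceed / reps - 0.01) < 0.01

    def test_perfect_profile_machine_limited_score(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 500)
        _, s = network.score_profile(x.copy(), x)
        assert s > 100

    def test_zero_variance_profile_scores_zero(self):
        rng = np.random.default_rng(2)
        beta, s = network.score_profile(np.ones(50), rng.normal(0, 1, 50))
        assert (beta, s) == (0.0, 0.0)

    def test_module_average_beats_single_members(self):
        """Averaging correlated members reduces noise: the module-mean
        score exceeds every single-member score in >= 90% of replicates."""
        wins = 0
        reps = 100
        rng = np.random.default_rng(77)
        n, k, rho, eff = 1000, 4, 0.5, 0.15
        for _ in range(reps):
            f = rng.normal(0, 1, n)
            pheno = (eff / np.sqrt(rho)) * f + np.sqrt(
                1 - eff**2 / rho
            ) * rng.normal(0, 1, n)
            members = (
                np.sqrt(rho) * f[:, None]
                + np.sqrt(1 - rho) * rng.normal(0, 1, (n, k))
            )
            single = [network.score_profile(members[:, j], pheno)[1] for j in range(k)]
            _, mod = network.score_profile(members.mean(axis=1), pheno)
            wins += mod > max(single)
        assert wins >= 90


def _module_cohort(seed, n=1000, p=20, eff=0.12, rho=0.6, members=(0, 1, 2)):
    """Cohort with one planted phenotype module among independent metabolites."""
    rng = np.random.default_rng(seed)
    f = rng.normal(0, 1, n)
    vals = rng.normal(0, 1, (n, p))
    for j in members:
        vals[:, j] = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.normal(0, 1, n)
    a = eff / np.sqrt(rho)
    pheno = a * f + np.sqrt(1 - a**2) * rng.normal(0, 1, n)
    df = pd.DataFrame(vals, index=[f"S{i}" for i in range(n)],
                      columns=[f"M{j}" for j in range(p)])
    return transformed_from(df), pd.Series(pheno, index=df.index)


class TestGreedyModuleSearch:
    def test_null_cohort_rarely_yields_modules(self):
        """Bonferroni over seeds keeps the family-wise rate near alpha."""
        hits = 0
        for seed in range(40):
            m, pheno = _module_cohort(seed=5000 + seed, eff=0.0, rho=0.5)
            G = network.estimate_ggm(m)
            mods = network.greedy_module_search(G, m, pheno, "fev1pp")
            hits += bool(mods)
        assert hits <= 4  # ~alpha-level family-wise errors over 40 nulls

    def test_planted_module_recovered_when_members_fail_univariate(self):
        """The aggregation-power property: members individually miss the
        single-metabolite Bonferroni bar while the module is significant."""
        recovered = 0
        member_hits = 0
        reps = 100
        thr = 0.05 / 995
        for seed in range(reps):
            m, pheno = _module_cohort(seed=6000 + seed)
            G = network.estimate_ggm(m)
            mods = network.greedy_module_search(G, m, pheno, "fev1pp")
            found = any(
                len(set(mod.members) & {"M0", "M1", "M2"}) >= 2 for mod in mods
            )
            recovered += found
            for j in ("M0", "M1", "M2"):
                _, s = network.score_profile(m.values[j].to_numpy(),
                                             pheno.to_numpy())
                member_hits += (10.0 ** -s) < thr
        assert recovered / reps >= 0.8
        assert member_hits / (3 * reps) < 0.5  # members usually fail alone

    def test_overlapping_optima_merge_to_single_module(self):
        m, pheno = _module_cohort(seed=303, eff=0.2)
        G = network.estimate_ggm(m)
        mods = network.greedy_module_search(G, m, pheno, "fev1pp")
        planted = [mod for mod in mods if set(mod.members) & {"M0", "M1", "M2"}]
        assert len(planted) == 1  # seeds converging on the module deduplicate

    def test_module_score_dominates_members(self):
        m, pheno = _module_cohort(seed=41, eff=0.2)
        G = network.estimate_ggm(m)
        for mod in network.greedy_module_search(G, m, pheno, "fev1pp"):
            for v in mod.members:
                _, s = network.score_profile(m.values[v].to_numpy(), pheno.to_numpy())
                assert mod.score >= s

    def test_column_permutation_leaves_members_unchanged(self):
        m, pheno = _module_cohort(seed=55, eff=0.2)
        G = network.estimate_ggm(m)
        mods1 = network.greedy_module_search(G, m, pheno, "fev1pp")
        shuffled = m.values[list(np.random.default_rng(0).permutation(m.values.columns))]
        m2 = transformed_from(shuffled)
        mods2 = network.greedy_module_search(G, m2, pheno, "fev1pp")
        assert {mod.members for mod in mods1} == {mod.members for mod in mods2}

    def test_empty_network_empty_result(self):
        m, pheno = _module_cohort(seed=1)
        assert network.greedy_module_search(nx.Graph(), m, pheno, "x") == []


class TestModuleVarianceDecomposition:
    def _cohort_with_shared_snp(self, seed=9, n=2000, snp_r2=0.15):
        rng = np.random.default_rng(seed)
        dose = rng.binomial(2, 0.3, n).astype(float)
        g_std = (dose - dose.mean()) / dose.std()
        vals = {}
        for j in range(2):
            vals[f"M{j}"] = np.sqrt(snp_r2) * g_std + np.sqrt(1 - snp_r2) * rng.normal(0, 1, n)
        vals["M2"] = rng.normal(0, 1, n)
        df = pd.DataFrame(vals, index=[f"S{i}" for i in range(n)])
        m = transformed_from(df)
        from mqtlnet.containers import DosageMatrix

        dos = pd.DataFrame({"rs1": dose}, index=df.index)
        info = pd.DataFrame(
            {"chrom": "1", "pos": [1], "effect_allele": "A", "other_allele": "G",
             "eaf": [0.3], "consequence": "", "nearest_gene": ""},
            index=pd.Index(["rs1"], name="snp"),
        )
        cov = pd.DataFrame({"age": rng.normal(65, 8, n)}, index=df.index)
        return m, DosageMatrix(dos, info), cov

    def _module(self, members, phenotype="fev1pp"):
        return network.PhenotypeModule(
            phenotype=phenotype, members=tuple(members), seed=members[0],
            beta=0.1, score=3.0, adjusted_p=0.01, adjusted_score=2.0,
        )

    def test_no_genetic_effect_r2_near_zero(self):
        m, g, cov = self._cohort_with_shared_snp(snp_r2=0.0)
        mod = self._module(["M0", "M1"])
        out = network.module_variance_decomposition(mod, m, g, {}, cov)
        assert out.r2_genetic == 0.0
        assert out.r2_covariates < 2 / 2000 * 10

    def test_shared_planted_snp_recovered_in_pc(self):
        m, g, cov = self._cohort_with_shared_snp(snp_r2=0.15)
        mod = self._module(["M0", "M1"])
        ind = {"M0": IndependentSet("M0", ["rs1"], [1e-30], [0.05])}
        out = network.module_variance_decomposition(mod, m, g, ind, cov)
        # Monte-Carlo oracle (300 reps): PC r2 on the shared SNP concentrates
        # near 4*0.15/2.3 ~ 0.26, 1st-99th percentile [0.23, 0.31]
        assert 0.20 <= out.r2_genetic <= 0.33

    def test_pc_sign_invariance(self):
        m, g, cov = self._cohort_with_shared_snp(snp_r2=0.15)
        flipped = transformed_from(-m.values)
        mod = self._module(["M0", "M1"])
        ind = {"M0": IndependentSet("M0", ["rs1"], [1e-30], [0.05])}
        a = network.module_variance_decomposition(mod, m, g, ind, cov)
        b = network.module_variance_decomposition(mod, flipped, g, ind, cov)
        assert a.r2_genetic == pytest.approx(b.r2_genetic, abs=1e-10)

    def test_single_member_module_rejected(self):
        m, g, cov = self._cohort_with_shared_snp()
        with pytest.raises(ValueError, match=">= 2"):
            network.module_variance_decomposition(self._module(["M0"]), m, g, {}, cov)
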