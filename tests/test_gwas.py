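"""Association machinery: MAF filter, kinship, PCA, the three scan models,
region calling, enrichment and inflation diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alumpanel import gwas
from alumpanel import simulate as sim
from alumpanel.panel import GenotypeMatrix


def _matrix(calls, positions=None, subpops=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    markers = pd.DataFrame({
        "id": [f"m{j}" for j in range(m)],
        "chrom": ["chr1"] * m,
        "pos": positions if positions is not None else list(range(0, 100 * m, 100)),
    })
    lines = pd.DataFrame({"id": [f"l{i}" for i in range(n)]})
    if subpops is not None:
        lines["subpop"] = subpops
    return GenotypeMatrix(calls, markers, lines)


@pytest.fixture(scope="module")
def confounded_panel():
    """Two diverged subpopulations with a trait shift between them."""
    cfg = sim.PanelConfig(K=2, lines_per_subpop=(60, 60),
                          markers_per_chrom=(600,), chrom_lengths=(6_000_000,),
                          fst=0.35, missing_rate=0.0, seed=21)
    panel = sim.simulate_panel(cfg)
    rng = np.random.default_rng(22)
    y = np.where(panel.genotypes.lines["subpop"] == "indica", 0.36, 0.72)
    y = y + rng.normal(0, 0.08, panel.genotypes.n_lines)
    return panel, y


class TestMafFilter:
    def test_monomorphic_removed(self):
        G = _matrix([[0, 0], [0, 2], [0, 2]])
        out = gwas.maf_filter(G, 0.01)
        assert list(out.marker_ids) == ["m1"]

    def test_strict_inequality_at_threshold(self):
        # 10 lines, one alt allele in 20 -> MAF exactly 0.05
        calls = np.zeros((10, 1), dtype=np.int8)
        calls[0, 0] = 1
        G = _matrix(calls)
        assert gwas.maf_filter(G, 0.05).n_markers == 0
        assert gwas.maf_filter(G, 0.049).n_markers == 1

    def test_maf_uses_nonmissing_subset(self):
        calls = np.array([[2], [0], [-1], [-1]], dtype=np.int8)
        G = _matrix(calls)
        assert G.maf()[0] == pytest.approx(0.5)


class TestKinship:
    def test_identical_and_opposite_lines(self):
        G = _matrix([[0, 2, 0], [0, 2, 0], [2, 0, 2]])
        K = gwas.ibs_kinship(G)
        assert K[0, 1] == pytest.approx(1.0)
        assert K[0, 2] == pytest.approx(0.0)
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), 1.0)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([0, 1, 2, -1], size=(3, 4), p=[0.4, 0.1, 0.4, 0.1])
        G = _matrix(calls)
        K = gwas.ibs_kinship(G)
        for i in range(3):
            for j in range(3):
                vals = []
                for m in range(4):
                    a, b = calls[i, m], calls[j, m]
                    if a >= 0 and b >= 0:
                        vals.append(1 - abs(int(a) - int(b)) / 2)
                assert K[i, j] == pytest.approx(np.mean(vals))

    def test_disjoint_missing_pair_is_error(self):
        calls = np.array([[0, -1], [-1, 2]], dtype=np.int8)
        with pytest.raises(ValueError, match="share no observed markers"):
            gwas.ibs_kinship(_matrix(calls))


class TestPca:
    def test_separates_structured_groups(self, confounded_panel):
        panel, _ = confounded_panel
        pcs = gwas.pca_covariates(panel.genotypes, 2)
        labels = panel.genotypes.lines["subpop"].to_numpy()
        from sklearn.metrics import silhouette_score

        assert silhouette_score(pcs[:, :1], labels) > 0.8

    def test_component_variances_nonincreasing(self, small_panel):
        pcs = gwas.pca_covariates(small_panel.genotypes, 5)
        var = pcs.var(axis=0)
        assert np.all(np.diff(var) <= 1e-9)


class TestScan:
    def test_mixed_with_identity_kinship_equals_naive(self):
        rng = np.random.default_rng(7)
        calls = rng.choice([0, 2], size=(40, 30))
        G = _matrix(calls)
        y = rng.normal(0, 1, 40)
        naive = gwas.scan(G, y, model="naive").frame
        mixed = gwas.scan(G, y, model="mixed", kinship=np.eye(40)).frame
        assert np.allclose(mixed["p"], naive["p"], rtol=1e-8)
        assert np.allclose(mixed["effect"], naive["effect"], rtol=1e-8)

    def test_mixed_matches_explicit_gls_oracle(self):
        """Per-marker mixed-model p equals brute-force GLS with V^-1 formed
        explicitly, on a 30-line x 50-marker structured instance."""
        cfg = sim.PanelConfig(K=2, lines_per_subpop=(15, 15),
                              markers_per_chrom=(50,), chrom_lengths=(500_000,),
                              fst=0.3, missing_rate=0.0, seed=31)
        panel = sim.simulate_panel(cfg)
        G = panel.genotypes
        rng = np.random.default_rng(32)
        y = (G.lines["subpop"] == "aus") * 0.5 + rng.normal(0, 0.3, 30)
        y = np.asarray(y, dtype=float)
        model = gwas.AssociationScanModel(G, y, model="mixed")
        res = model.fit()
        s2g, s2e = res.variance_components
        K = model.kinship
        V = s2g * K + s2e * np.eye(30)
        Vinv = np.linalg.inv(V)
        for _, row in res.frame.iloc[::7].iterrows():
            j = G.marker_index(row["marker"])
            X = np.column_stack([np.ones(30), G.calls[:, j].astype(float)])
            XtVX = X.T @ Vinv @ X
            beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
            resid = y - X @ beta
            df = 30 - 2
            sigma2 = float(resid @ Vinv @ resid) / df
            se = np.sqrt(sigma2 * np.linalg.inv(XtVX)[1, 1])
            p = 2 * stats.t.sf(abs(beta[1] / se), df)
            assert row["p"] == pytest.approx(p, abs=1e-6)
            assert row["effect"] == pytest.approx(beta[1], abs=1e-6)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        calls = rng.choice([0, 2], size=(100, 2000))
        G = _matrix(calls, positions=list(range(2000)))
        y = rng.normal(0, 1, 100)
        res = gwas.scan(G, y, model="naive")
        ks = stats.kstest(res.frame["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_scan_invariant_to_block_and_line_order(self):
        rng = np.random.default_rng(9)
        calls = rng.choice([0, 1, 2], size=(25, 12))
        markers = pd.DataFrame({"id": [f"m{j}" for j in range(12)],
                                "chrom": ["chr1"] * 6 + ["chr2"] * 6,
                                "pos": list(range(0, 600, 100)) * 2})
        lines = pd.DataFrame({"id": [f"l{i}" for i in range(25)]})
        G = GenotypeMatrix(calls, markers, lines)
        y = rng.normal(0, 1, 25)
        base = gwas.scan(G, y, model="naive").frame.set_index("marker")["p"]
        # swap chromosome block order (records match up to ordering)
        order = np.r_[np.arange(6, 12), np.arange(6)]
        G2 = G.subset_markers(order)
        out_m = gwas.scan(G2, y, model="naive").frame.set_index("marker")["p"]
        assert np.allclose(base.loc[out_m.index], out_m)
        perm_l = rng.permutation(25)
        G3 = G.subset_lines(perm_l)
        out_l = gwas.scan(G3, y[perm_l], model="naive").frame.set_index("marker")["p"]
        assert np.allclose(base.loc[out_l.index], out_l)

    def test_reml_loglik_at_optimum_dominates_zero_variance(self, confounded_panel):
        panel, y = confounded_panel
        G = gwas.maf_filter(panel.genotypes)
        model = gwas.AssociationScanModel(G, y, model="mixed")
        X0 = np.ones((G.n_lines, 1))
        Q, _ = np.linalg.qr(X0)
        S = np.eye(G.n_lines) - Q @ Q.T
        vals, vecs = np.linalg.eigh(S @ (model.kinship + 1e-9 * np.eye(G.n_lines)) @ S)
        order = np.argsort(vals)[::-1][: G.n_lines - 1]
        lam = np.maximum(vals[order], 0)
        eta2 = (vecs[:, order].T @ y) ** 2
        s2g, s2e, delta = model._fit_variance_components(X0)
        ll_opt = model._reml_loglik(np.log(delta), lam, eta2)
        ll_null = model._reml_loglik(np.log(1e8), lam, eta2)  # sigma_g -> 0 limit
        assert ll_opt >= ll_null - 1e-6


class TestSubpopulationScans:
    def test_subset_maf_refiltering(self):
        # marker m0: polymorphic panel-wide but monomorphic within subpop A
        calls = np.array([[0, 0], [0, 2], [0, 0], [2, 2], [0, 2], [2, 0]] * 6,
                         dtype=np.int8)
        subpops = (["A", "A", "A", "B", "B", "B"] * 6)
        G = _matrix(calls, subpops=subpops)
        y = np.random.default_rng(10).normal(0, 1, 36)
        scans = gwas.subpopulation_scans(G, y, np.asarray(subpops), model="naive",
                                         min_lines=10)
        by_set = {s.germplasm: s for s in scans}
        assert "m0" not in set(by_set["A"].frame["marker"])
        assert "m0" in set(by_set["all"].frame["marker"])
        for s in scans:
            assert len(s.frame) == len(set(s.frame["marker"]))

    def test_small_subset_skipped(self):
        calls = np.random.default_rng(11).choice([0, 2], size=(40, 10))
        subpops = ["A"] * 36 + ["B"] * 4
        G = _matrix(calls, subpops=subpops)
        y = np.random.default_rng(12).normal(0, 1, 40)
        scans = gwas.subpopulation_scans(G, y, np.asarray(subpops), model="naive",
                                         min_lines=30)
        assert {s.germplasm for s in scans} == {"all", "A"}


class TestRegions:
    def test_no_significant_markers(self):
        frame = pd.DataFrame({"marker": ["m0"], "chrom": ["chr1"], "pos": [100],
                              "maf": [0.2], "n": [10], "effect": [0.0],
                              "se": [1.0], "p": [0.5]})
        res = gwas.AssociationResults(frame, "naive")
        assert gwas.call_regions(res) == []

    def test_hand_merge(self):
        pos = [1_000_000, 1_100_000, 1_500_000]
        frame = pd.DataFrame({"marker": [f"m{i}" for i in range(3)],
                              "chrom": ["chr1"] * 3, "pos": pos,
                              "maf": [0.2] * 3, "n": [10] * 3,
                              "effect": [1.0] * 3, "se": [0.1] * 3,
                              "p": [1e-6] * 3})
        res = gwas.AssociationResults(frame, "naive")
        regions = gwas.call_regions(res, 1e-4, 200_000)
        assert len(regions) == 2
        assert (regions[0].start, regions[0].end) == (1_000_000, 1_100_001)
        assert (regions[1].start, regions[1].end) == (1_500_000, 1_500_001)
        assert regions[0].markers == ["m0", "m1"]


class TestEnrichment:
    def test_hand_ratio(self):
        # 2 of 10 window markers vs 1 of 100 background markers significant
        pos = list(range(0, 110 * 1000, 1000))
        p = np.full(110, 0.5)
        p[[0, 1]] = 1e-6      # in-window significants
        p[50] = 1e-6          # background significant
        frame = pd.DataFrame({"marker": [f"m{i}" for i in range(110)],
                              "chrom": ["chr1"] * 110, "pos": pos,
                              "maf": [0.2] * 110, "n": [10] * 110,
                              "effect": [0.0] * 110, "se": [1.0] * 110, "p": p})
        res = gwas.AssociationResults(frame, "naive")
        genes = pd.DataFrame({"chrom": ["chr1"], "pos": [4500]})
        out = gwas.candidate_enrichment(res, genes, window_bp=5000, p_threshold=1e-4)
        assert out["n_window"] == 10
        assert out["n_background"] == 100
        assert out["enrichment"] == pytest.approx((2 / 10) / (1 / 100))
        assert out["fdr_upper"] == pytest.approx(1e-4 * 10 / 2)

    def test_null_enrichment_near_one(self):
        rng = np.random.default_rng(13)
        ratios = []
        for _ in range(200):
            p = rng.uniform(size=400)
            frame = pd.DataFrame({"marker": [f"m{i}" for i in range(400)],
                                  "chrom": ["chr1"] * 400,
                                  "pos": list(range(0, 400_000, 1000)),
                                  "maf": [0.2] * 400, "n": [10] * 400,
                                  "effect": [0.0] * 400, "se": [1.0] * 400, "p": p})
            res = gwas.AssociationResults(frame, "naive")
            genes = pd.DataFrame({"chrom": ["chr1"], "pos": [100_000]})
            out = gwas.candidate_enrichment(res, genes, window_bp=50_000,
                                            p_threshold=0.1)
            ratios.append(out["enrichment"])
        mean = np.nanmean(ratios)
        se = np.nanstd(ratios) / np.sqrt(len(ratios))
        assert abs(mean - 1.0) < 3 * se + 0.05

    def test_no_window_markers_flagged(self):
        frame = pd.DataFrame({"marker": ["m0"], "chrom": ["chr1"], "pos": [100],
                              "maf": [0.2], "n": [10], "effect": [0.0],
                              "se": [1.0], "p": [0.5]})
        res = gwas.AssociationResults(frame, "naive")
        genes = pd.DataFrame({"chrom": ["chr9"], "pos": [0]})
        out = gwas.candidate_enrichment(res, genes)
        assert np.isnan(out["enrichment"])


class TestInflation:
    def test_quantile_oracle_20_pvalues(self):
        p = np.linspace(0.01, 0.96, 20)
        p_full = np.tile(p, 5)  # >= 100 markers required
        lam = gwas.genomic_inflation(p_full)
        chi2 = stats.chi2.isf(p_full, 1)
        expected = np.median(chi2) / stats.chi2.isf(0.5, 1)
        assert lam == pytest.approx(expected, abs=1e-12)

    def test_uniform_null_lambda_near_one(self):
        rng = np.random.default_rng(14)
        lam = gwas.genomic_inflation(rng.uniform(size=5000))
        assert 0.9 < lam < 1.1

    def test_structure_confounding_ordering(self, confounded_panel):
        panel, y = confounded_panel
        G = gwas.maf_filter(panel.genotypes)
        lam_naive = gwas.genomic_inflation(gwas.scan(G, y, model="naive"))
        lam_pca = gwas.genomic_inflation(gwas.scan(G, y, model="pca"))
        lam_mixed = gwas.genomic_inflation(gwas.scan(G, y, model="mixed"))
        assert lam_naive > lam_pca > lam_mixed
        assert lam_naive > 2.0   # uncorrected scan grossly inflated
        assert lam_mixed < 1.3
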