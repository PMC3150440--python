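"""Local-ancestry HMM: emissions, forward-backward vs enumeration, Viterbi
vs brute force, EM behavior, decoding and the introgression machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from alumpanel import ancestry
from alumpanel import simulate as sim
from alumpanel.ancestry import (AncestryHMM, AncestryModel, IntrogressionCall,
                                emission_prob, unique_outlier_introgressions)
from alumpanel.panel import GenotypeMatrix


def _matrix(calls, positions=None, line_ids=None, chrom="chr1"):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    markers = pd.DataFrame({"id": [f"m{j}" for j in range(m)], "chrom": [chrom] * m,
                            "pos": positions if positions is not None
                            else list(range(0, 1000 * m, 1000))})
    lines = pd.DataFrame({"id": line_ids or [f"l{i}" for i in range(n)]})
    return GenotypeMatrix(calls, markers, lines)


def _enumerate_posteriors(calls_row, freqs, f, tau):
    """Exhaustive-path posteriors and likelihood for one line, one chromosome."""
    K, M = freqs.shape
    post = np.zeros((M, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=M):
        p = 1.0 / K
        for j in range(M):
            if j > 0:
                p *= (1 - tau) if path[j] == path[j - 1] else tau / (K - 1)
            p *= emission_prob(calls_row[j], freqs[path[j], j], f)
        total += p
        for j in range(M):
            post[j, path[j]] += p
    return post / total, total


class TestEmission:
    def test_fully_inbred_no_hets(self):
        assert emission_prob(1, 0.5, 1.0) == 0.0

    def test_hardy_weinberg_at_half(self):
        assert emission_prob(0, 0.5, 0.0) == pytest.approx(0.25)
        assert emission_prob(1, 0.5, 0.0) == pytest.approx(0.5)
        assert emission_prob(2, 0.5, 0.0) == pytest.approx(0.25)

    def test_probabilities_sum_to_one_on_grid(self):
        for p in np.linspace(0, 1, 21):
            for f in np.linspace(0, 1, 21):
                s = sum(emission_prob(g, p, f) for g in (0, 1, 2))
                assert s == pytest.approx(1.0, abs=1e-12)

    def test_missing_uninformative(self):
        assert emission_prob(-1, 0.3, 0.7) == 1.0


def _build_hmm(calls, freqs, f, tau, controls=None, positions=None):
    G = _matrix(calls, positions=positions)
    K = freqs.shape[0]
    names = [f"p{k}" for k in range(K)]
    # anchor each state with a dummy control appended to the panel
    if controls is None:
        controls = {}
    hmm = AncestryHMM.__new__(AncestryHMM)
    hmm.G = G
    hmm.control_labels = controls
    hmm.K = K
    hmm.subpop_names = names
    hmm.tau0 = tau
    hmm.estimate_tau = False
    hmm.distance_scaled = False
    hmm._control_state = np.full(G.n_lines, -1, dtype=int)
    for lid, lab in controls.items():
        hmm._control_state[G.line_index(lid)] = names.index(lab)
    hmm._blocks = []
    for chrom, grp in G.markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        hmm._blocks.append((chrom, idx[0], idx[-1] + 1))
    hmm._spacing_scale = np.ones(G.n_markers)
    model = AncestryModel(K, names, freqs, np.asarray(f, dtype=float), tau, G.markers)
    return hmm, model


class TestForwardBackward:
    @pytest.mark.parametrize("seed,K,M,f", [(1, 2, 6, 0.9), (2, 3, 5, 0.8),
                                            (3, 2, 10, 1.0), (4, 3, 8, 0.6),
                                            (5, 2, 8, 0.0)])
    def test_matches_exhaustive_enumeration(self, seed, K, M, f):
        rng = np.random.default_rng(seed)
        freqs = rng.uniform(0.05, 0.95, size=(K, M))
        tau = 0.08
        if f == 1.0:  # heterozygous calls impossible at f=1
            calls = rng.choice([0, 2, -1], size=(1, M), p=[0.45, 0.45, 0.1])
        else:
            calls = rng.choice([0, 1, 2, -1], size=(1, M), p=[0.4, 0.1, 0.4, 0.1])
        hmm, model = _build_hmm(calls, freqs, [f], tau)
        gamma, loglik = hmm.state_posteriors(model)
        expected, total = _enumerate_posteriors(calls[0], freqs, f, tau)
        assert np.allclose(gamma[0], expected, atol=1e-10)
        assert loglik == pytest.approx(np.log(total), abs=1e-10)

    def test_posteriors_normalized(self, small_panel, small_controls):
        Gs = ancestry.select_ancestry_snps(small_panel.genotypes, small_controls,
                                           spacing_bp=5000)
        fit = AncestryHMM(Gs, small_controls).fit(max_iter=5)
        sums = fit.posteriors.sum(axis=2)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestViterbi:
    def test_matches_bruteforce_path(self):
        rng = np.random.default_rng(6)
        K, M = 2, 8
        freqs = rng.uniform(0.05, 0.95, size=(K, M))
        tau = 0.1
        calls = rng.choice([0, 2], size=(1, M))
        hmm, model = _build_hmm(calls, freqs, [0.9], tau)
        res = ancestry.AncestryResults(hmm, model, np.zeros((1, M, K)), np.array([0.0]))
        path = res._decode_line(0)
        best_p, best_path = -1.0, None
        for cand in itertools.product(range(K), repeat=M):
            p = 1.0 / K
            for j in range(M):
                if j > 0:
                    p *= (1 - tau) if cand[j] == cand[j - 1] else tau / (K - 1)
                p *= emission_prob(calls[0, j], freqs[cand[j], j], 0.9)
            if p > best_p + 1e-15:
                best_p, best_path = p, cand
        assert tuple(path.states) == best_path

    def test_uniform_emissions_single_state_path(self):
        K, M = 3, 10
        freqs = np.full((K, M), 0.5)
        calls = np.full((1, M), -1, dtype=np.int8)  # all missing: uniform emissions
        hmm, model = _build_hmm(calls, freqs, [0.9], 0.05)
        res = ancestry.AncestryResults(hmm, model, np.zeros((1, M, K)), np.array([0.0]))
        path = res._decode_line(0)
        assert np.all(path.states == path.states[0])
        assert path.states[0] == 0  # tie broken toward lowest state index

    def test_viterbi_beats_random_paths(self):
        rng = np.random.default_rng(7)
        K, M = 3, 40
        freqs = rng.uniform(0.05, 0.95, size=(K, M))
        calls = rng.choice([0, 1, 2], size=(1, M))
        tau = 0.05
        hmm, model = _build_hmm(calls, freqs, [0.8], tau)
        res = ancestry.AncestryResults(hmm, model, np.zeros((1, M, K)), np.array([0.0]))
        path = res._decode_line(0)

        def logp(states):
            lp = -np.log(K)
            for j in range(M):
                if j > 0:
                    lp += np.log(1 - tau) if states[j] == states[j - 1] else np.log(tau / (K - 1))
                lp += np.log(max(emission_prob(calls[0, j], freqs[states[j], j], 0.8), 1e-300))
            return lp

        best = logp(path.states)
        for _ in range(1000):
            rand = rng.integers(0, K, M)
            assert logp(rand) <= best + 1e-9


class TestEmFit:
    def test_k1_degenerate(self):
        rng = np.random.default_rng(8)
        calls = rng.choice([0, 2], size=(6, 20))
        G = _matrix(calls)
        controls = {"l0": "only"}
        hmm = AncestryHMM(G, controls, K=1)
        fit = hmm.fit(max_iter=10)
        assert np.allclose(fit.posteriors[:, :, 0], 1.0)

    def test_loglik_nondecreasing_over_seeds(self):
        for seed in range(4):
            cfg = sim.PanelConfig(K=2, lines_per_subpop=(12, 12),
                                  markers_per_chrom=(120,), chrom_lengths=(1_200_000,),
                                  fst=0.3, seed=40 + seed)
            panel = sim.simulate_panel(cfg)
            controls = {f"{s}_{j}": s for s in ("indica", "aus") for j in range(4)}
            fit = AncestryHMM(panel.genotypes, controls).fit(max_iter=12, tol=0.0)
            diffs = np.diff(fit.loglik_trace)
            assert np.all(diffs >= -1e-6), f"seed {seed}: {diffs.min()}"

    def test_control_only_panel_recovers_empirical_frequencies(self):
        cfg = sim.PanelConfig(K=2, lines_per_subpop=(15, 15),
                              markers_per_chrom=(150,), chrom_lengths=(1_500_000,),
                              fst=0.4, missing_rate=0.0, inbreeding_dist=1.0, seed=50)
        panel = sim.simulate_panel(cfg)
        G = panel.genotypes
        controls = dict(zip(G.line_ids, G.lines["subpop"]))
        fit = AncestryHMM(G, controls, estimate_tau=False).fit(max_iter=60, tol=1e-10)
        for k, name in enumerate(fit.model.subpop_names):
            idx = np.flatnonzero(G.lines["subpop"].to_numpy() == name)
            emp = G.calls[idx].mean(axis=0) / 2.0
            est = fit.model.freqs[k]
            assert np.allclose(est, np.clip(emp, 1e-4, 1 - 1e-4), atol=1e-6)

    def test_inbreeding_recovery(self):
        for true_f in (0.8, 0.9, 1.0):
            cfg = sim.PanelConfig(K=2, lines_per_subpop=(12, 12),
                                  markers_per_chrom=(2000,), chrom_lengths=(20_000_000,),
                                  fst=0.3, missing_rate=0.0, inbreeding_dist=true_f,
                                  seed=int(true_f * 100))
            panel = sim.simulate_panel(cfg)
            controls = {f"{s}_{j}": s for s in ("indica", "aus") for j in range(4)}
            fit = AncestryHMM(panel.genotypes, controls).fit(max_iter=25)
            est = fit.model.f.mean()
            assert abs(est - true_f) < 0.05


class TestSnpSelection:
    def test_monomorphic_everywhere_removed(self, toy_matrix):
        controls = {"a": "indica", "b": "indica", "c": "aus", "d": "aus"}
        calls = toy_matrix.calls.copy()
        calls[:, 0] = 0  # monomorphic in both groups
        G = GenotypeMatrix(calls, toy_matrix.markers, toy_matrix.lines)
        out = ancestry.select_ancestry_snps(G, controls, spacing_bp=1)
        assert "m0" not in out.marker_ids

    def test_single_group_polymorphism_retained(self):
        calls = np.array([[0, 0], [2, 0], [0, 0], [0, 0]], dtype=np.int8)
        G = _matrix(calls, line_ids=["a", "b", "c", "d"])
        controls = {"a": "p0", "b": "p0", "c": "p1", "d": "p1"}
        out = ancestry.select_ancestry_snps(G, controls, spacing_bp=1)
        assert "m0" in out.marker_ids  # MAF 0.25 in p0, 0 in p1: rule (b) keeps it

    def test_spacing_thinning(self):
        calls = np.array([[0, 0], [2, 2], [0, 2], [2, 0]], dtype=np.int8)
        G = _matrix(calls, positions=[0, 1000], line_ids=["a", "b", "c", "d"])
        controls = {"a": "p0", "b": "p0", "c": "p1", "d": "p1"}
        out = ancestry.select_ancestry_snps(G, controls, spacing_bp=50_000)
        assert out.n_markers == 1


class TestFractionsAndIntrogressions:
    def _fit_small(self, small_panel, small_controls):
        Gs = ancestry.select_ancestry_snps(small_panel.genotypes, small_controls,
                                           spacing_bp=5000)
        return AncestryHMM(Gs, small_controls).fit(max_iter=10)

    def test_pure_line_fraction_one(self, small_panel, small_controls):
        fit = self._fit_small(small_panel, small_controls)
        frac = fit.ancestry_fractions().set_index("line")
        ctrl = list(small_controls)[0]
        assert frac.loc[ctrl, f"frac_{small_controls[ctrl]}"] == pytest.approx(1.0)
        assert frac.loc[ctrl, "classification"] == small_controls[ctrl]

    def test_hand_built_70_30_is_admixed(self, small_panel, small_controls):
        fit = self._fit_small(small_panel, small_controls)
        path = ancestry.AncestryPath(
            "x", np.zeros(1, dtype=int),
            [("chr1", 0, 700_000, "indica"), ("chr1", 700_000, 1_000_000, "aus")],
        )
        frac = fit.ancestry_fractions([path]).iloc[0]
        assert frac["frac_indica"] == pytest.approx(0.7)
        assert frac["classification"] == "admixed"
        # both subpops are Indica-group, so the varietal level stays classified
        assert frac["varietal_group"] == "Indica"

    def test_pure_line_no_introgressions(self, small_panel, small_controls):
        fit = self._fit_small(small_panel, small_controls)
        paths = [fit.decode(lid) for lid in list(small_controls)[:3]]
        assert fit.call_introgressions(paths) == []

    def test_two_runs_not_merged(self, small_panel, small_controls):
        fit = self._fit_small(small_panel, small_controls)
        G = fit.hmm.G
        M = G.n_markers
        states = np.zeros(M, dtype=int)
        # two donor runs split by a single majority-state marker
        states[10:20] = 1
        states[21:31] = 1
        path = ancestry.AncestryPath(G.line_ids[0], states,
                                     fit._states_to_intervals(states))
        calls = fit.call_introgressions([path], min_markers=5, min_bp=1)
        donors = [c for c in calls if c.donor == fit.model.subpop_names[1]]
        assert len(donors) == 2

    def test_planted_introgression_recovered(self):
        cfg = sim.PanelConfig(K=2, lines_per_subpop=(15, 15),
                              markers_per_chrom=(300,), chrom_lengths=(3_000_000,),
                              fst=0.45, missing_rate=0.0, inbreeding_dist=0.95, seed=60)
        panel = sim.simulate_panel(cfg)
        lid = "indica_10"
        panel = sim.inject_introgressions(
            panel, [(lid, "chr1", 1_000_000, 1_780_000, "aus")], seed=61)
        controls = {f"{s}_{j}": s for s in ("indica", "aus") for j in range(5)}
        fit = AncestryHMM(panel.genotypes, controls).fit(max_iter=20)
        calls = fit.call_introgressions([fit.decode(lid)])
        assert len(calls) == 1
        c = calls[0]
        assert c.donor == "aus"
        # boundaries within three 10-kb marker intervals of the planted segment
        # (boundary markers can be uninformative between the two subpopulations)
        assert abs(c.start - 1_000_000) <= 30_000
        assert abs(c.end - 1_780_000) <= 30_000


class TestUniquenessFilter:
    def _call(self, line, start, end, donor="tropical_japonica", chrom="chr7"):
        return IntrogressionCall(line, chrom, start, end, donor, 10, 0.99)

    def test_shared_introgression_removed(self):
        calls = [self._call("out1", 100, 200), self._call("comp1", 150, 250)]
        kept, table = unique_outlier_introgressions(calls, ["out1"], ["comp1"])
        assert kept == []
        assert table.empty

    def test_empty_outlier_set(self):
        kept, table = unique_outlier_introgressions([], [], ["comp1"])
        assert kept == [] and table.empty

    def test_table3_style_scenario(self):
        """Five outliers share a donor segment absent from all comparison
        lines; the filter groups them into one locus listing all carriers."""
        outliers = [f"out{i}" for i in range(5)]
        calls = [self._call(o, 27_050_000, 27_620_000 + 10_000 * i) for i, o in
                 enumerate(outliers)]
        # comparison lines carry an overlapping segment from a different donor
        calls.append(self._call("comp1", 27_000_000, 27_500_000, donor="aus"))
        # and a same-donor segment elsewhere on the chromosome
        calls.append(self._call("comp2", 5_000_000, 5_600_000))
        kept, table = unique_outlier_introgressions(calls, outliers,
                                                    ["comp1", "comp2"])
        assert len(kept) == 5
        assert len(table) == 1
        locus = table.iloc[0]
        assert sorted(locus["carriers"]) == outliers
        assert locus["start"] == 27_050_000
        assert locus["end"] == 27_620_000  # consensus = shared core
        assert locus["size_mb"] == pytest.approx(0.57)
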