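"""EM/HMM local-ancestry inference for inbred lines.

The hidden state at each marker is the subpopulation of origin of the
surrounding chromosomal segment (K single-subpopulation states — lines are
inbred, so admixture appears as an along-chromosome mosaic, not as
heterozygous ancestry).  Emissions are Hardy–Weinberg draws from the state's
subpopulation allele frequency mixed with an identical-by-descent component
governed by a per-line inbreeding coefficient f:

    P(hom-ref) = (1-f)(1-p)^2 + f(1-p)
    P(het)     = (1-f) 2p(1-p)
    P(hom-alt) = (1-f)p^2 + fp

Adjacent markers on a chromosome are linked by a weak-linkage transition
kernel: the state is retained with probability 1 - tau and switches to each
of the other K-1 states with probability tau / (K-1).

Fitting is by EM.  The E-step runs the scaled forward-backward algorithm per
line; a designated set of non-admixed control lines (the anchors for each
subpopulation) have their states clamped to their label, which pins the
frequency estimates and prevents label switching.  The M-step updates
subpopulation allele frequencies, per-line f and (optionally) tau in closed
form by augmenting with an explicit per-(line, marker) identical-by-descent
indicator, so every update is an exact maximizer and the observed-data
log-likelihood is non-decreasing at every iteration.

Decoding is by Viterbi (ties broken toward the lower-indexed state); decoded
paths yield ancestry fractions, the <80% admixture classification,
introgression calls, and the outlier-uniqueness filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix

logger = logging.getLogger(__name__)

ADMIXTURE_THRESHOLD = 0.80
DEFAULT_MIN_MARKERS = 5
DEFAULT_MIN_BP = 100_000


# ----------------------------------------------------------------------
def select_ancestry_snps(G: GenotypeMatrix, control_labels: dict,
                         maf_threshold: float = 0.05,
                         spacing_bp: int = 50_000) -> GenotypeMatrix:
    """Informative-marker subset for ancestry inference.

    A marker is retained if its MAF exceeds ``maf_threshold`` within at
    least one labeled control group, then markers are thinned to at most one
    per ``spacing_bp`` along each chromosome (greedy left-to-right), keeping
    LD between retained markers weak.
    """
    groups: dict = {}
    for lid, lab in control_labels.items():
        groups.setdefault(lab, []).append(G.line_index(lid))
    keep = np.zeros(G.n_markers, dtype=bool)
    for lab, idx in groups.items():
        sub = G.calls[idx]
        obs = sub >= 0
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, sub, 0).sum(axis=0)
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
        maf = np.minimum(p, 1 - p)
        keep |= maf > maf_threshold
    # spacing thinning
    thin = np.zeros(G.n_markers, dtype=bool)
    for chrom, grp in G.markers.groupby("chrom", sort=False):
        last = -np.inf
        for j in grp.index:
            if keep[j] and G.markers["pos"].iloc[j] >= last + spacing_bp:
                thin[j] = True
                last = G.markers["pos"].iloc[j]
    return G.subset_markers(thin)


def emission_prob(genotype: int, p: float, f: float) -> float:
    """Emission probability of one genotype call given allele frequency and f.

    Missing calls (negative codes) are uninformative and return 1.
    """
    if genotype < 0:
        return 1.0
    if genotype == 0:
        return (1 - f) * (1 - p) ** 2 + f * (1 - p)
    if genotype == 1:
        return (1 - f) * 2 * p * (1 - p)
    return (1 - f) * p**2 + f * p


def _emission_parts(calls: np.ndarray, freqs: np.ndarray, f: np.ndarray):
    """Hardy–Weinberg and IBD emission components for all (line, marker, state).

    Returns (hwe, ibd) arrays of shape (n_lines, M, K); missing calls get 1
    in both components so the mixture is 1 (uninformative).
    """
    n, M = calls.shape
    K = freqs.shape[0]
    p = freqs.T[None, :, :]                       # 1 x M x K
    g = calls[:, :, None]                         # n x M x 1
    hwe = np.where(
        g == 0, (1 - p) ** 2, np.where(g == 1, 2 * p * (1 - p), p**2)
    )
    ibd = np.where(g == 0, 1 - p, np.where(g == 1, 0.0, p))
    miss = np.broadcast_to(g < 0, hwe.shape)
    hwe = np.where(miss, 1.0, hwe)
    ibd = np.where(miss, 1.0, ibd)
    return hwe, ibd


@dataclass
class AncestryModel:
    """Fitted HMM parameters."""

    K: int
    subpop_names: list
    freqs: np.ndarray          # K x M alternate-allele frequencies
    f: np.ndarray              # per-line inbreeding coefficient
    tau: float                 # per-adjacent-marker switch probability
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 0.5):
            raise ValueError("tau must lie in (0, 0.5)")
        if np.any(self.freqs < 0) or np.any(self.freqs > 1):
            raise ValueError("frequencies must lie in [0, 1]")


@dataclass
class AncestryPath:
    """Decoded ancestry of one line.

    ``states`` is the per-marker Viterbi state index; ``intervals`` is the
    interval representation: (chrom, start, end, subpop) half-open bp
    intervals tiling each chromosome, with boundaries at midpoints between
    markers of differing states and terminal intervals extended to the
    chromosome ends.
    """

    line_id: str
    states: np.ndarray
    intervals: list


@dataclass
class IntrogressionCall:
    """A contiguous run of non-majority ancestry in one line."""

    line_id: str
    chrom: object
    start: int
    end: int
    donor: str
    n_markers: int
    mean_posterior: float
    unique: bool | None = None

    @property
    def size_mb(self) -> float:
        return (self.end - self.start) / 1e6


class AncestryHMM:
    """K-subpopulation local-ancestry model for an inbred-line panel.

    Parameters
    ----------
    G : GenotypeMatrix
        The (already thinned) informative-marker panel.
    control_labels : dict
        line id -> subpopulation name for the non-admixed anchor lines;
        every subpopulation must have at least one control.
    K : int, optional
        Number of subpopulations (defaults to the number of distinct control
        labels).
    tau : float
        Initial (or fixed) switch probability per adjacent-marker step.
    estimate_tau : bool
        Update tau in the M-step from expected switch counts.
    distance_scaled : bool
        Scale the switch probability by inter-marker distance relative to
        the median spacing (tau is then held fixed).
    """

    def __init__(self, G: GenotypeMatrix, control_labels: dict, K: int | None = None,
                 tau: float = 0.01, estimate_tau: bool = True,
                 distance_scaled: bool = False):
        self.G = G
        self.control_labels = dict(control_labels)
        names = sorted(set(self.control_labels.values()))
        if K is None:
            K = len(names)
        if len(names) != K:
            raise ValueError(f"need controls for all {K} subpopulations, got {len(names)}")
        if not names:
            raise ValueError("empty control set")
        self.K = K
        self.subpop_names = names
        self.tau0 = tau
        self.estimate_tau = estimate_tau and not distance_scaled
        self.distance_scaled = distance_scaled

        self._control_state = np.full(G.n_lines, -1, dtype=int)
        for lid, lab in self.control_labels.items():
            self._control_state[G.line_index(lid)] = names.index(lab)

        # chromosome blocks (contiguous marker index ranges)
        self._blocks = []
        for chrom, grp in G.markers.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            self._blocks.append((chrom, idx[0], idx[-1] + 1))
        self._spacing_scale = self._interval_scales()

    def _interval_scales(self) -> np.ndarray:
        """Per-interval distance scale factors (ones unless distance_scaled)."""
        M = self.G.n_markers
        scale = np.ones(M)  # scale[j] applies to the step j-1 -> j
        if not self.distance_scaled:
            return scale
        pos = self.G.markers["pos"].to_numpy(dtype=float)
        gaps = []
        for (_, s, e) in self._blocks:
            if e - s > 1:
                gaps.append(np.diff(pos[s:e]))
        med = np.median(np.concatenate(gaps)) if gaps else 1.0
        for (_, s, e) in self._blocks:
            if e - s > 1:
                scale[s + 1:e] = np.diff(pos[s:e]) / med
        return scale

    # ------------------------------------------------------------------
    def _init_params(self):
        """Frequencies from control empirical frequencies; f from observed calls."""
        G = self.G
        K, M = self.K, G.n_markers
        freqs = np.full((K, M), 0.5)
        for k in range(K):
            idx = np.flatnonzero(self._control_state == k)
            sub = G.calls[idx]
            obs = sub >= 0
            n_alleles = 2 * obs.sum(axis=0)
            alt = np.where(obs, sub, 0).sum(axis=0)
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.5)
            freqs[k] = np.clip(p, 1e-4, 1 - 1e-4)
        obs = G.calls >= 0
        het = (G.calls == 1).sum(axis=1) / np.maximum(obs.sum(axis=1), 1)
        f0 = np.clip(1.0 - 2.0 * het, 0.05, 0.999)
        return freqs, f0

    def _forward_backward(self, freqs, f, tau):
        """Scaled forward-backward vectorized across lines.

        Returns (gamma, ibd_post, loglik, switch_exp, step_count) where
        gamma is n x M x K state posteriors, ibd_post the per-(line, marker)
        posterior IBD probability (already state-summed), and switch_exp the
        expected number of state switches (for the tau M-step).
        """
        G = self.G
        n, M, K = G.n_lines, G.n_markers, self.K
        hwe, ibd = _emission_parts(G.calls, freqs, f[:, None])
        emis = (1 - f[:, None, None]) * hwe + f[:, None, None] * ibd
        # clamp controls: zero out emissions off their labeled state
        ctrl = self._control_state
        is_ctrl = ctrl >= 0
        if is_ctrl.any():
            mask = np.ones((n, K))
            mask[is_ctrl] = 0.0
            mask[is_ctrl, ctrl[is_ctrl]] = 1.0
            emis = emis * mask[:, None, :]
        emis = np.maximum(emis, 1e-300)

        gamma = np.empty((n, M, K))
        loglik = 0.0
        switch_exp = 0.0
        step_count = 0
        tau_step = np.clip(tau * self._spacing_scale, 1e-12, 0.5)
        if K == 1:  # degenerate chain: no switching
            tau_step = np.zeros_like(tau_step)

        for (_, s, e) in self._blocks:
            Mb = e - s
            alpha = np.empty((Mb, n, K))
            c = np.empty((Mb, n))
            a = emis[:, s, :] / K
            c[0] = a.sum(axis=1)
            alpha[0] = a / c[0][:, None]
            for j in range(1, Mb):
                t = tau_step[s + j]
                stay = 1.0 - t
                other = t / max(K - 1, 1)
                tot = alpha[j - 1].sum(axis=1, keepdims=True)
                pred = alpha[j - 1] * (stay - other) + tot * other
                a = pred * emis[:, s + j, :]
                c[j] = a.sum(axis=1)
                alpha[j] = a / c[j][:, None]
            loglik += float(np.log(c).sum())

            beta = np.ones((n, K))
            gamma[:, e - 1, :] = alpha[Mb - 1]
            for j in range(Mb - 2, -1, -1):
                t = tau_step[s + j + 1]
                stay = 1.0 - t
                other = t / max(K - 1, 1)
                be = beta * emis[:, s + j + 1, :]
                tot = be.sum(axis=1, keepdims=True)
                beta_new = (be * (stay - other) + tot * other) / c[j + 1][:, None]
                # expected switches across step j -> j+1:
                # xi_ii = alpha_i * stay * e_i * beta_i / c; stay prob mass
                stay_mass = (alpha[j] * stay * be / c[j + 1][:, None]).sum()
                switch_exp += alpha[j].sum() * 1.0 - stay_mass  # alpha rows sum to 1
                beta = beta_new
                g = alpha[j] * beta
                gamma[:, s + j, :] = g / g.sum(axis=1, keepdims=True)
            step_count += (Mb - 1) * n

        # posterior IBD probability given the state mixture
        ibd_num = f[:, None, None] * ibd
        denom = (1 - f[:, None, None]) * hwe + ibd_num
        with np.errstate(invalid="ignore", divide="ignore"):
            a_post = np.where(denom > 0, ibd_num / np.maximum(denom, 1e-300), 0.0)
        ibd_post = (gamma * a_post).sum(axis=2)
        return gamma, ibd_post, a_post, loglik, switch_exp, step_count

    def state_posteriors(self, model: "AncestryModel"):
        """Forward-backward posteriors and log-likelihood under given parameters.

        Returns ``(gamma, loglik)`` with gamma of shape (lines, markers, K).
        """
        gamma, _, _, loglik, _, _ = self._forward_backward(
            model.freqs, model.f, model.tau
        )
        return gamma, loglik

    def fit(self, max_iter: int = 50, tol: float = 1e-4, seed: int = 0,
            verbose: bool = False) -> "AncestryResults":
        """Run EM to convergence and return fitted results.

        Stops when the log-likelihood gain drops below ``tol`` or after
        ``max_iter`` iterations.  ``seed`` is reserved for EM restarts
        (deterministic single-restart initialization from control-line
        frequencies is used by default, so the fit itself is deterministic).
        """
        G = self.G
        freqs, f = self._init_params()
        tau = self.tau0
        trace = []
        prev = -np.inf
        for it in range(max_iter):
            gamma, ibd_post, a_post, loglik, switch_exp, steps = self._forward_backward(
                freqs, f, tau
            )
            if not np.isfinite(loglik):
                raise RuntimeError(
                    f"non-finite log-likelihood at EM iteration {it}: {loglik}"
                )
            trace.append(loglik)
            if verbose:
                logger.info("EM iter %d loglik %.4f tau %.5f", it, loglik, tau)
            if loglik - prev < tol and it > 0:
                break
            prev = loglik

            # ---- M-step (closed form via the IBD augmentation) ----
            calls = G.calls.astype(float)
            obsm = calls >= 0
            gdose = np.where(obsm, calls, 0.0)
            # per (line, marker, state): allele-count numerator and draw count
            a1 = a_post                             # P(ibd | state, g)
            num = gamma * (a1 * (gdose[:, :, None] / 2.0) + (1 - a1) * gdose[:, :, None])
            den = gamma * (a1 * 1.0 + (1 - a1) * 2.0)
            num = np.where(obsm[:, :, None], num, 0.0)
            den = np.where(obsm[:, :, None], den, 0.0)
            new_freqs = num.sum(axis=0).T / np.maximum(den.sum(axis=0).T, 1e-12)
            freqs = np.clip(new_freqs, 1e-4, 1 - 1e-4)

            nobs = obsm.sum(axis=1)
            f = np.clip(
                np.where(obsm, ibd_post, 0.0).sum(axis=1) / np.maximum(nobs, 1),
                1e-6, 1 - 1e-6,
            )
            if self.estimate_tau:
                tau = float(np.clip(switch_exp / max(steps, 1), 1e-6, 0.4999))

        model = AncestryModel(self.K, self.subpop_names, freqs, f, tau, G.markers)
        return AncestryResults(self, model, gamma, np.asarray(trace))


class AncestryResults:
    """Fitted local-ancestry model plus per-line state posteriors."""

    def __init__(self, hmm: AncestryHMM, model: AncestryModel,
                 posteriors: np.ndarray, loglik_trace: np.ndarray):
        self.hmm = hmm
        self.model = model
        self.posteriors = posteriors  # n x M x K
        self.loglik_trace = loglik_trace

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    # ------------------------------------------------------------------
    def decode(self, line_id=None, clamp_controls: bool = True
               ) -> list[AncestryPath] | AncestryPath:
        """Viterbi state path(s); ties break toward the lower state index.

        ``clamp_controls=False`` decodes control lines from their genotypes
        alone (ignoring their anchoring label) — the honest way to check
        that controls are assigned to their own subpopulation.
        """
        G = self.hmm.G
        if line_id is not None:
            i = G.line_index(line_id)
            return self._decode_line(i, clamp_controls)
        return [self._decode_line(i, clamp_controls) for i in range(G.n_lines)]

    def _decode_line(self, i: int, clamp_controls: bool = True) -> AncestryPath:
        hmm, model = self.hmm, self.model
        G = hmm.G
        K = model.K
        f = model.f[i]
        hwe, ibd = _emission_parts(G.calls[i:i + 1], model.freqs, np.array([[f]]))
        emis = ((1 - f) * hwe + f * ibd)[0]  # M x K
        cs = hmm._control_state[i] if clamp_controls else -1
        if cs >= 0:
            m = np.zeros(K)
            m[cs] = 1.0
            emis = emis * m[None, :]
        logem = np.log(np.maximum(emis, 1e-300))
        tau_step = np.clip(model.tau * hmm._spacing_scale, 1e-12, 0.5)
        if K == 1:
            tau_step = np.zeros_like(tau_step) + 1e-300

        states = np.empty(G.n_markers, dtype=int)
        for (_, s, e) in hmm._blocks:
            Mb = e - s
            delta = logem[s] - np.log(K)
            back = np.empty((Mb, K), dtype=np.int16)
            for j in range(1, Mb):
                t = tau_step[s + j]
                logT = np.full((K, K), np.log(t / max(K - 1, 1)))
                np.fill_diagonal(logT, np.log(1.0 - t))
                scores = delta[:, None] + logT
                back[j] = np.argmax(scores, axis=0)  # argmax takes lowest index on ties
                delta = scores[back[j], np.arange(K)] + logem[s + j]
            last = int(np.argmax(delta))
            path = np.empty(Mb, dtype=int)
            path[-1] = last
            for j in range(Mb - 1, 0, -1):
                path[j - 1] = back[j, path[j]]
            states[s:e] = path
        intervals = self._states_to_intervals(states)
        return AncestryPath(G.line_ids[i], states, intervals)

    def _states_to_intervals(self, states: np.ndarray) -> list:
        G = self.hmm.G
        model = self.model
        pos = G.markers["pos"].to_numpy()
        intervals = []
        for (chrom, s, e) in self.hmm._blocks:
            chrom_start = 0
            chrom_end = int(pos[e - 1]) + 1
            st = states[s:e]
            p = pos[s:e]
            run_start_idx = 0
            for j in range(1, len(st) + 1):
                if j == len(st) or st[j] != st[run_start_idx]:
                    left = chrom_start if run_start_idx == 0 else int((p[run_start_idx - 1] + p[run_start_idx]) // 2)
                    right = chrom_end if j == len(st) else int((p[j - 1] + p[j]) // 2)
                    intervals.append(
                        (chrom, left, right, model.subpop_names[st[run_start_idx]])
                    )
                    run_start_idx = j
        return intervals

    # ------------------------------------------------------------------
    def ancestry_fractions(self, paths: list[AncestryPath] | None = None) -> pd.DataFrame:
        """bp-weighted genome fraction per subpopulation, with classification.

        A line is classified to a subpopulation (and to a varietal group)
        iff its fraction at that level is >= 0.80; otherwise admixed.
        """
        from .phenotype import varietal_group

        paths = paths if paths is not None else self.decode()
        names = self.model.subpop_names
        rows = []
        for path in paths:
            total = 0
            acc = dict.fromkeys(names, 0)
            for (c, s, e, pop) in path.intervals:
                acc[pop] += e - s
                total += e - s
            frac = {k: v / total for k, v in acc.items()}
            best = max(names, key=lambda k: frac[k])
            sub_class = best if frac[best] >= ADMIXTURE_THRESHOLD else "admixed"
            vg: dict = {}
            for k, v in frac.items():
                vg[varietal_group(k)] = vg.get(varietal_group(k), 0.0) + v
            best_vg = max(vg, key=vg.get)
            vg_class = best_vg if vg[best_vg] >= ADMIXTURE_THRESHOLD else "admixed"
            row = {"line": path.line_id, **{f"frac_{k}": frac[k] for k in names},
                   "classification": sub_class, "varietal_group": vg_class}
            rows.append(row)
        return pd.DataFrame(rows)

    def call_introgressions(self, paths: list[AncestryPath] | None = None,
                            min_markers: int = DEFAULT_MIN_MARKERS,
                            min_bp: int = DEFAULT_MIN_BP) -> list[IntrogressionCall]:
        """Maximal runs of non-majority ancestry meeting both support thresholds.

        The line's majority ancestry is its largest bp-weighted fraction; a
        run must span >= ``min_markers`` markers and >= ``min_bp`` bp.  Runs
        separated by even one majority-state marker stay separate calls.
        """
        paths = paths if paths is not None else self.decode()
        names = self.model.subpop_names
        G = self.hmm.G
        pos = G.markers["pos"].to_numpy()
        calls: list[IntrogressionCall] = []
        frac = self.ancestry_fractions(paths).set_index("line")
        for path in paths:
            i = G.line_index(path.line_id)
            majority = max(names, key=lambda k: frac.loc[path.line_id, f"frac_{k}"])
            maj_idx = names.index(majority)
            st = path.states
            for (chrom, s, e) in self.hmm._blocks:
                j = s
                while j < e:
                    if st[j] != maj_idx:
                        k = j
                        while k < e and st[k] == st[j]:
                            k += 1
                        n_mark = k - j
                        left = 0 if j == s else int((pos[j - 1] + pos[j]) // 2)
                        right = int(pos[e - 1]) + 1 if k == e else int((pos[k - 1] + pos[k]) // 2)
                        if n_mark >= min_markers and right - left >= min_bp:
                            mp = float(self.posteriors[i, j:k, st[j]].mean())
                            calls.append(
                                IntrogressionCall(
                                    path.line_id, chrom, left, right,
                                    names[st[j]], n_mark, mp,
                                )
                            )
                        j = k
                    else:
                        j += 1
        return calls

    def summary(self) -> str:
        model = self.model
        frac = self.ancestry_fractions()
        n_adm = int((frac["classification"] == "admixed").sum())
        return "\n".join([
            f"Ancestry HMM: K={model.K} subpops={model.subpop_names}",
            f"lines={self.hmm.G.n_lines} markers={self.hmm.G.n_markers}",
            f"tau={model.tau:.5f}  mean f={model.f.mean():.3f}",
            f"log-likelihood={self.loglik:.2f} ({len(self.loglik_trace)} EM iterations)",
            f"admixed lines (<{ADMIXTURE_THRESHOLD:.0%} single-subpop ancestry): {n_adm}",
        ])


# ----------------------------------------------------------------------
def unique_outlier_introgressions(
    calls: list[IntrogressionCall], outlier_lines, comparison_lines,
) -> tuple[list[IntrogressionCall], pd.DataFrame]:
    """Uniqueness filter and shared-locus grouping for outlier introgressions.

    An outlier line's call is retained iff no comparison line carries a call
    from the same donor overlapping it by any bp.  Retained calls are then
    grouped across outliers into shared loci: overlapping same-donor calls
    form one locus with the carrier list, the consensus interval (the region
    common to all carriers, or the spanning interval when no common core
    exists) and its size in Mb.
    """
    outlier_lines = set(outlier_lines)
    comparison_lines = set(comparison_lines)
    comp = [c for c in calls if c.line_id in comparison_lines]
    retained = []
    for c in calls:
        if c.line_id not in outlier_lines:
            continue
        clash = any(
            o.donor == c.donor and o.chrom == c.chrom
            and c.start < o.end and o.start < c.end
            for o in comp
        )
        c.unique = not clash
        if not clash:
            retained.append(c)

    # group retained calls into shared loci by overlap (same chrom + donor)
    loci = []
    for c in sorted(retained, key=lambda x: (str(x.chrom), x.start)):
        placed = False
        for locus in loci:
            if (locus["chrom"] == c.chrom and locus["donor"] == c.donor
                    and c.start < locus["span_end"] and locus["span_start"] < c.end):
                locus["members"].append(c)
                locus["span_start"] = min(locus["span_start"], c.start)
                locus["span_end"] = max(locus["span_end"], c.end)
                placed = True
                break
        if not placed:
            loci.append({"chrom": c.chrom, "donor": c.donor, "members": [c],
                         "span_start": c.start, "span_end": c.end})

    rows = []
    for li, locus in enumerate(loci, start=1):
        members = locus["members"]
        core_start = max(m.start for m in members)
        core_end = min(m.end for m in members)
        if core_end <= core_start:
            core_start, core_end = locus["span_start"], locus["span_end"]
        rows.append({
            "locus": f"{locus['chrom']}.{li}",
            "chrom": locus["chrom"],
            "donor": locus["donor"],
            "carriers": sorted({m.line_id for m in members}),
            "n_carriers": len({m.line_id for m in members}),
            "start": core_start,
            "end": core_end,
            "size_mb": (core_end - core_start) / 1e6,
        })
    return retained, pd.DataFrame(
        rows, columns=["locus", "chrom", "donor", "carriers", "n_carriers",
                       "start", "end", "size_mb"])
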