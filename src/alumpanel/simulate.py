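"""Synthetic structured rice panels, introgressions, crosses and phenotypes.

This module generates the inputs every downstream stage consumes, with the
statistical structure those stages assume:

* ``simulate_panel`` — K differentiated subpopulations of highly inbred lines
  under the Balding–Nichols model: each subpopulation's allele frequency at a
  marker is a Beta draw around an ancestral frequency with dispersion set by
  F_st, and each line is homozygous-by-descent at a marker with probability
  equal to its inbreeding coefficient f.
* ``inject_introgressions`` — localized cross-subpopulation donor segments
  (the panel emulates historical indica x japonica admixture, where observed
  donor segments are sub-Mb to Mb scale).
* ``simulate_root_phenotypes`` — replicate-level root-growth records under
  control and Al treatment, with subpopulation offsets (optionally calibrated
  to a target one-way ANOVA R^2), planted causal SNPs, and measurement noise.
* ``simulate_cross`` — bi-parental RIL/BIL populations under the Haldane
  (no-interference) map function.

All randomness flows through a single integer seed per call; repeated calls
with the same arguments are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypeMatrix

__all__ = [
    "PanelConfig",
    "SimulatedPanel",
    "TraitConfig",
    "SimulatedCross",
    "simulate_panel",
    "inject_introgressions",
    "simulate_root_phenotypes",
    "simulate_cross",
    "cross_to_qtl_codes",
]


# ----------------------------------------------------------------------
# distribution specs: a float is a point mass; a tuple names a family
def _draw(dist, size, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` values from a distribution spec.

    Accepted specs: a scalar (point mass), ``("uniform", lo, hi)``,
    ``("beta", a, b)``, ``("beta", a, b, scale)`` (Beta scaled into
    [0, scale]).
    """
    if np.isscalar(dist):
        return np.full(size, float(dist))
    kind = dist[0]
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size=size)
    if kind == "beta":
        x = rng.beta(dist[1], dist[2], size=size)
        if len(dist) > 3:
            x = x * dist[3]
        return x
    raise ValueError(f"unknown distribution spec: {dist!r}")


@dataclass
class PanelConfig:
    """Geometry and population-genetic parameters of a simulated panel.

    Defaults describe a desk-scale version of a five-subpopulation rice
    diversity panel: deep differentiation (F_st in the 0.3-0.5 range reported
    for domesticated rice), highly inbred lines (f ~ Beta(9, 1), mean 0.9),
    and 1% missing calls.
    """

    K: int = 5
    lines_per_subpop: tuple = (40, 40, 40, 40, 40)
    markers_per_chrom: tuple = (500, 500)
    chrom_lengths: tuple = (25_000_000, 25_000_000)
    fst: tuple | float = 0.4
    ancestral_maf_dist: tuple | float = ("uniform", 0.05, 0.5)
    inbreeding_dist: tuple | float = ("beta", 9.0, 1.0)
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if len(self.lines_per_subpop) != self.K:
            raise ValueError("lines_per_subpop must have K entries")
        if any(n < 1 for n in self.lines_per_subpop):
            raise ValueError("lines_per_subpop entries must be positive")
        if len(self.markers_per_chrom) != len(self.chrom_lengths):
            raise ValueError("markers_per_chrom and chrom_lengths must align")
        if any(m < 1 for m in self.markers_per_chrom):
            raise ValueError("marker counts must be positive")
        fst = np.atleast_1d(np.asarray(self.fst, dtype=float))
        if fst.size == 1:
            fst = np.repeat(fst, self.K)
        if fst.size != self.K:
            raise ValueError("fst must be scalar or have K entries")
        if np.any(fst >= 1.0) or np.any(fst < 0.0):
            raise ValueError("fst must lie in [0, 1)")
        self._fst = fst
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def fst_per_subpop(self) -> np.ndarray:
        return self._fst

    @property
    def n_lines(self) -> int:
        return int(sum(self.lines_per_subpop))

    @property
    def n_markers(self) -> int:
        return int(sum(self.markers_per_chrom))

    @property
    def subpop_names(self) -> list:
        default = ["indica", "aus", "tropical_japonica", "temperate_japonica", "aromatic"]
        if self.K <= len(default):
            return default[: self.K]
        return default + [f"pop{i}" for i in range(len(default), self.K)]


@dataclass
class SimulatedPanel:
    """A simulated panel plus its generating truth.

    ``true_ancestry`` maps line id to a list of (chrom, start, end, subpop)
    half-open intervals tiling each chromosome; ``true_f`` is the per-line
    inbreeding coefficient; ``subpop_freqs`` is the K x markers matrix of
    subpopulation alternate-allele frequencies.
    """

    genotypes: GenotypeMatrix
    true_ancestry: dict
    true_f: np.ndarray
    subpop_freqs: np.ndarray
    ancestral_freqs: np.ndarray

    def copy(self) -> "SimulatedPanel":
        return SimulatedPanel(
            self.genotypes.copy(),
            {k: list(v) for k, v in self.true_ancestry.items()},
            self.true_f.copy(),
            self.subpop_freqs.copy(),
            self.ancestral_freqs.copy(),
        )


def _genotype_draw(p, f, rng):
    """Genotypes given allele frequency ``p`` and inbreeding ``f`` (arrays)."""
    ibd = rng.random(p.shape) < f
    hom = 2 * rng.binomial(1, p)
    hwe = rng.binomial(2, p)
    return np.where(ibd, hom, hwe).astype(np.int8)


def simulate_panel(config: PanelConfig) -> SimulatedPanel:
    """Simulate a structured panel under the Balding–Nichols model.

    For subpopulation k with differentiation F_k, the subpopulation allele
    frequency at a marker with ancestral frequency p is drawn from
    ``Beta(p (1-F_k)/F_k, (1-p)(1-F_k)/F_k)`` (mean p, variance
    F_k p (1-p)); F_k = 0 degenerates to the ancestral frequency itself.
    Each line is assigned an inbreeding coefficient f from
    ``config.inbreeding_dist``; at each marker the line is
    homozygous-by-descent (a single allele draw, doubled) with probability f
    and a Hardy–Weinberg draw otherwise.
    """
    rng = np.random.default_rng(config.seed)
    K, M = config.K, config.n_markers

    p_anc = _draw(config.ancestral_maf_dist, M, rng)
    p_anc = np.clip(p_anc, 1e-6, 0.5)

    subpop_freqs = np.empty((K, M))
    for k, F in enumerate(config.fst_per_subpop):
        if F <= 0.0:
            subpop_freqs[k] = p_anc
        else:
            shape = (1.0 - F) / F
            subpop_freqs[k] = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
    subpop_freqs = np.clip(subpop_freqs, 0.0, 1.0)

    # marker map: uniformly spaced positions per chromosome
    rows = []
    idx = 0
    for c, (m, L) in enumerate(zip(config.markers_per_chrom, config.chrom_lengths)):
        spacing = L / m
        for j in range(m):
            rows.append((f"snp{idx}", f"chr{c + 1}", int(j * spacing)))
            idx += 1
    markers = pd.DataFrame(rows, columns=["id", "chrom", "pos"])

    names = config.subpop_names
    line_ids, line_subpops, subpop_of_line = [], [], []
    for k, n in enumerate(config.lines_per_subpop):
        for j in range(n):
            line_ids.append(f"{names[k]}_{j}")
            line_subpops.append(names[k])
            subpop_of_line.append(k)
    subpop_of_line = np.asarray(subpop_of_line)
    lines = pd.DataFrame({"id": line_ids, "subpop": line_subpops})

    true_f = np.clip(_draw(config.inbreeding_dist, len(line_ids), rng), 0.0, 1.0)

    calls = np.empty((len(line_ids), M), dtype=np.int8)
    for i in range(len(line_ids)):
        p = subpop_freqs[subpop_of_line[i]]
        calls[i] = _genotype_draw(p, true_f[i], rng)

    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = MISSING

    ancestry = {}
    for i, lid in enumerate(line_ids):
        own = names[subpop_of_line[i]]
        ancestry[lid] = [
            (f"chr{c + 1}", 0, int(L), own)
            for c, L in enumerate(config.chrom_lengths)
        ]

    return SimulatedPanel(
        GenotypeMatrix(calls, markers, lines),
        ancestry,
        true_f,
        subpop_freqs,
        p_anc,
    )


# ----------------------------------------------------------------------
def _split_intervals(intervals, chrom, start, end, donor):
    """Replace [start, end) on ``chrom`` with a donor interval, keeping a tiling."""
    out = []
    for (c, s, e, pop) in intervals:
        if c != chrom or e <= start or s >= end:
            out.append((c, s, e, pop))
            continue
        if s < start:
            out.append((c, s, start, pop))
        if e > end:
            out.append((c, end, e, pop))
    out.append((chrom, start, end, donor))
    out.sort(key=lambda iv: (str(iv[0]), iv[1]))
    return out


def inject_introgressions(panel: SimulatedPanel, events, seed: int = 0) -> SimulatedPanel:
    """Redraw genotypes inside donor intervals from the donor subpopulation.

    ``events`` is a list of ``(line_id, chrom, start, end, donor_subpop)``
    with 0-based half-open bp intervals.  Calls at markers with positions in
    [start, end) are redrawn from the donor subpopulation's frequencies using
    the line's own inbreeding coefficient; everything else is untouched.
    Overlapping events on the same line are rejected.
    """
    panel = panel.copy()
    if not events:
        return panel
    rng = np.random.default_rng(seed)
    G = panel.genotypes
    chrom_extent = {}
    for c, grp in G.markers.groupby("chrom", sort=False):
        chrom_extent[c] = int(grp["pos"].max()) + 1

    seen = {}
    subpop_names = list(dict.fromkeys(G.lines["subpop"])) if "subpop" in G.lines else []
    for (line_id, chrom, start, end, donor) in events:
        if start < 0 or end <= start:
            raise ValueError(f"bad interval [{start}, {end}) for line {line_id}")
        if chrom not in chrom_extent:
            raise ValueError(f"unknown chromosome {chrom}")
        for (s0, e0) in seen.get((line_id, chrom), []):
            if start < e0 and s0 < end:
                raise ValueError(
                    f"overlapping introgression events on line {line_id} {chrom}"
                )
        seen.setdefault((line_id, chrom), []).append((start, end))

        i = G.line_index(line_id)
        donor_idx = subpop_names.index(donor) if donor in subpop_names else int(donor)
        mask = G.region_mask(chrom, start, end)
        p = panel.subpop_freqs[donor_idx, mask]
        new = _genotype_draw(p, panel.true_f[i], rng)
        was_missing = G.calls[i, mask] == MISSING
        new[was_missing] = MISSING
        G.calls[i, mask] = new
        panel.true_ancestry[line_id] = _split_intervals(
            panel.true_ancestry[line_id], chrom, start, end, donor
        )
    return panel


# ----------------------------------------------------------------------
@dataclass
class TraitConfig:
    """Generating model for the root-growth tolerance trait.

    A line's latent tolerance (its true relative root growth under Al) is
    ``subpop offset + sum(allele count x QTL effect) + N(0, residual_sd)``,
    shifted around ``base_tolerance``.  Replicate-level growth is drawn with
    coefficient of variation ``replicate_cv`` around a common control growth
    mean (``control_growth``) and around ``control_growth x tolerance`` for
    the Al treatment.  When ``target_subpop_r2`` is set, subpopulation
    offsets are rescaled so the realized one-way ANOVA R^2 of the latent
    values on subpopulation matches the target.
    """

    subpop_means: tuple = ()
    qtls: tuple = ()                 # ((marker_id, additive effect per allele), ...)
    residual_sd: float = 0.05
    replicate_count: int = 4
    replicate_cv: float = 0.1
    target_subpop_r2: float | None = None
    base_tolerance: float = 0.6
    control_growth: float = 100.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if self.target_subpop_r2 is not None and not 0.0 <= self.target_subpop_r2 < 1.0:
            raise ValueError("target_subpop_r2 must lie in [0, 1)")


def _anova_r2_arrays(values: np.ndarray, groups: np.ndarray) -> float:
    grand = values.mean()
    ss_tot = ((values - grand) ** 2).sum()
    if ss_tot == 0:
        return float("nan")
    ss_b = 0.0
    for g in np.unique(groups):
        v = values[groups == g]
        ss_b += len(v) * (v.mean() - grand) ** 2
    return float(ss_b / ss_tot)


def simulate_root_phenotypes(
    panel: SimulatedPanel, trait: TraitConfig, seed: int = 0
) -> pd.DataFrame:
    """Replicate-level root-growth records for control and Al treatments.

    Returns a tidy table with columns ``line``, ``treatment`` (control/Al),
    ``replicate``, ``total``, ``primary``, ``longest`` — the three root-class
    growth measurements, all driven by the same latent tolerance.  Also
    attaches the latent per-line tolerance as ``df.attrs['latent']``.
    """
    rng = np.random.default_rng(seed)
    G = panel.genotypes
    subpops = G.lines["subpop"].to_numpy()
    subpop_list = list(dict.fromkeys(subpops))
    if trait.subpop_means and len(trait.subpop_means) != len(subpop_list):
        raise ValueError("subpop_means must have one entry per subpopulation")
    offsets = np.asarray(trait.subpop_means if trait.subpop_means else [0.0] * len(subpop_list))
    offset_of = {s: offsets[i] for i, s in enumerate(subpop_list)}

    genetic = np.zeros(G.n_lines)
    for marker_id, effect in trait.qtls:
        j = G.marker_index(marker_id)
        dose = G.calls[:, j].astype(float)
        dose[dose < 0] = np.nan
        dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
        genetic += dose * effect

    noise = rng.normal(0.0, trait.residual_sd, G.n_lines) if trait.residual_sd > 0 else 0.0
    base_off = np.array([offset_of[s] for s in subpops])
    g_part = genetic + noise

    if trait.target_subpop_r2 is not None:
        # rescale offsets so the realized one-way ANOVA R^2 of the latent
        # tolerance on subpopulation hits the target (monotone in the scale)
        if trait.subpop_means:
            direction = base_off
        else:
            direction = np.array(
                [float(i - (len(subpop_list) - 1) / 2.0) for i in range(len(subpop_list))]
            )
            direction = np.array([direction[subpop_list.index(s)] for s in subpops])
            base_off = direction
        groups = np.asarray(subpops)

        def realized(c):
            return _anova_r2_arrays(base_off * c + g_part, groups)

        lo, hi = 0.0, 1.0
        while realized(hi) < trait.target_subpop_r2 and hi < 1e6:
            hi *= 2.0
        if realized(hi) < trait.target_subpop_r2:
            raise ValueError("cannot reach target_subpop_r2 with these offsets")
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if realized(mid) < trait.target_subpop_r2:
                lo = mid
            else:
                hi = mid
        base_off = base_off * hi

    latent = trait.base_tolerance + base_off + g_part
    latent = np.clip(latent, 0.01, None)

    # per-root-class control growth means (arbitrary length units)
    class_means = {"total": trait.control_growth, "primary": 0.3 * trait.control_growth,
                   "longest": 0.4 * trait.control_growth}
    records = []
    for i, lid in enumerate(G.line_ids):
        for treatment in ("control", "Al"):
            mult = 1.0 if treatment == "control" else latent[i]
            for r in range(trait.replicate_count):
                row = {"line": lid, "treatment": treatment, "replicate": r}
                for cls, mu in class_means.items():
                    mean = mu * mult
                    sd = trait.replicate_cv * mean
                    val = rng.normal(mean, sd) if sd > 0 else mean
                    row[cls] = max(val, 0.0)
                records.append(row)
    df = pd.DataFrame.from_records(records)
    df.attrs["latent"] = pd.Series(latent, index=G.line_ids)
    return df


# ----------------------------------------------------------------------
def _haldane_r(d_cM: np.ndarray) -> np.ndarray:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def ril_recombinant_fraction(r: np.ndarray) -> np.ndarray:
    """Map expansion for selfed RILs: R = 2r / (1 + 2r)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclass
class SimulatedCross:
    """A simulated bi-parental population: calls plus true parental origins.

    ``origins`` is lines x markers in {0 (parent A), 1 (parent B)}.
    """

    genotypes: GenotypeMatrix
    origins: np.ndarray
    design: str


def simulate_cross(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    design: str,
    n_lines: int,
    genetic_map: pd.DataFrame,
    seed: int = 0,
) -> SimulatedCross:
    """Simulate an inbred bi-parental mapping population.

    Parents are homozygous genotype vectors (0/2 per marker) over
    ``genetic_map`` (columns ``id``, ``chrom``, ``cM``, ``pos``).  RIL lines
    descend from an F1 selfed to fixation: each line is a mosaic of the two
    parental genomes with adjacent-marker recombinant fraction expanded to
    ``2r/(1+2r)``; parental origin is a priori 50/50.  BIL lines descend
    from one backcross to parent A followed by selfing, so the marker-wise
    donor (parent B) frequency is 0.25; along the chromosome the origin
    process is a two-state stationary Markov chain with the same expanded
    recombinant fraction.
    """
    parent_a = np.asarray(parent_a)
    parent_b = np.asarray(parent_b)
    for name, par in (("A", parent_a), ("B", parent_b)):
        obs = par[par >= 0]
        if np.any(obs == 1):
            raise ValueError(f"parent {name} has heterozygous calls; parents must be inbred")
    if design not in ("RIL", "BIL"):
        raise ValueError("design must be 'RIL' or 'BIL'")
    rng = np.random.default_rng(seed)

    gmap = genetic_map.reset_index(drop=True)
    pi_b = 0.5 if design == "RIL" else 0.25
    M = len(gmap)
    origins = np.empty((n_lines, M), dtype=np.int8)

    for chrom, grp in gmap.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        cm = grp["cM"].to_numpy(dtype=float)
        R = ril_recombinant_fraction(_haldane_r(np.diff(cm)))
        # stationarity-preserving switch kernel: P(i->j) = (1-s) d_ij + s pi_j
        # with s chosen so the recombinant fraction equals R
        s = np.clip(R / (2.0 * pi_b * (1.0 - pi_b)), 0.0, 1.0)
        state = (rng.random(n_lines) < pi_b).astype(np.int8)
        origins[:, idx[0]] = state
        for j, sj in enumerate(s):
            switch = rng.random(n_lines) < sj
            resample = (rng.random(n_lines) < pi_b).astype(np.int8)
            state = np.where(switch, resample, state)
            origins[:, idx[j + 1]] = state

    calls = np.where(origins == 0, parent_a[None, :], parent_b[None, :]).astype(np.int8)
    lines = pd.DataFrame({"id": [f"{design.lower()}_{i}" for i in range(n_lines)]})
    markers = gmap[["id", "chrom", "pos"]].copy()
    return SimulatedCross(GenotypeMatrix(calls, markers, lines), origins, design)


def cross_to_qtl_codes(cross: SimulatedCross) -> np.ndarray:
    """Parental-origin codes for QTL mapping: 0 = parent A, 1 = parent B."""
    return cross.origins.copy()
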