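"""Window-based haplotype grouping and LD decay for inbred-line panels.

Inbred homozygous calls are treated as haploid alleles, so haplotypes over a
genomic window are simply the distinct allele strings across the member
markers (heterozygous calls count as missing, the inbred-line convention).
Pairwise LD is the squared allele-frequency correlation r^2; the "decay
distance" convention used here is the smallest inter-marker distance at
which the distance-binned mean r^2 first falls below a cutoff (default 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix
from .phenotype import anova_r2

DEFAULT_R2_CUTOFF = 0.2
DEFAULT_MIN_CALL_FRACTION = 0.8


def _haploid_codes(calls: np.ndarray) -> np.ndarray:
    """Homozygous dosage to haploid allele code (0/1); het and missing to -1."""
    out = np.full(calls.shape, -1, dtype=np.int8)
    out[calls == 0] = 0
    out[calls == 2] = 1
    return out


def pairwise_ld(G: GenotypeMatrix, chrom=None, start=None, end=None,
                r2_cutoff: float = DEFAULT_R2_CUTOFF,
                bin_bp: int = 25_000) -> dict:
    """r^2 for all marker pairs in a region, plus an LD decay distance.

    For each pair, r^2 is the squared Pearson correlation of the haploid
    allele codes over lines homozygous and non-missing at both markers
    (pairwise exclusion).  Monomorphic pairs are skipped.  The decay
    distance is the lower edge of the first ``bin_bp`` distance bin whose
    mean r^2 falls below ``r2_cutoff``; NaN (flagged) when LD never decays
    within the region or the region is monomorphic.
    """
    if chrom is not None:
        G = G.subset_markers(G.region_mask(chrom, start, end))
    H = _haploid_codes(G.calls)
    pos = G.markers["pos"].to_numpy()
    ids = G.marker_ids
    rows = []
    for a in range(G.n_markers):
        for b in range(a + 1, G.n_markers):
            ok = (H[:, a] >= 0) & (H[:, b] >= 0)
            if ok.sum() < 2:
                continue
            x, y = H[ok, a].astype(float), H[ok, b].astype(float)
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            rows.append({"marker_a": ids[a], "marker_b": ids[b],
                         "dist_bp": int(abs(pos[b] - pos[a])),
                         "r2": float(r**2), "n": int(ok.sum())})
    table = pd.DataFrame(rows, columns=["marker_a", "marker_b", "dist_bp", "r2", "n"])
    if table.empty:
        return {"table": table, "decay_bp": float("nan"), "flag": "monomorphic region"}

    bins = (table["dist_bp"] // bin_bp).to_numpy()
    decay = float("nan")
    for b in sorted(set(bins)):
        if table["r2"][bins == b].mean() < r2_cutoff:
            decay = float(b * bin_bp)
            break
    return {"table": table, "decay_bp": decay}


@dataclass
class HaplotypeTable:
    """Distinct haplotypes over one window.

    ``haplotypes`` has per haplotype: id (``H1`` is the most common), allele
    string ('0'/'1' per member marker), carrier lines, carrier count and
    subpopulation composition.  ``assignments`` maps every retained line to
    its haplotype id or ``None`` (unassigned).
    """

    chrom: object
    start: int | None
    end: int | None
    marker_ids: list
    haplotypes: pd.DataFrame
    assignments: dict

    def carriers(self, hap_id: str) -> list:
        row = self.haplotypes[self.haplotypes["id"] == hap_id]
        if row.empty:
            raise KeyError(f"unknown haplotype {hap_id}")
        return list(row["carriers"].iloc[0])


def build_haplotypes(G: GenotypeMatrix, chrom=None, start=None, end=None,
                     marker_ids=None,
                     min_call_fraction: float = DEFAULT_MIN_CALL_FRACTION) -> HaplotypeTable:
    """Group lines by exact identity of their window allele strings.

    The window is given either as a region (``chrom``/``start``/``end``) or
    as an explicit ``marker_ids`` list (for sub-haplotypes of named SNPs).
    Lines with fewer than ``min_call_fraction`` callable in-window markers
    are excluded.  Fully called lines define the groups; a line with missing
    calls joins a group iff exactly one group matches its non-missing
    alleles, otherwise it is left unassigned.  Haplotypes are ordered by
    descending carrier count.
    """
    if marker_ids is not None:
        idx = np.asarray([G.marker_index(m) for m in marker_ids])
        Gw = G.subset_markers(idx)
    else:
        Gw = G.subset_markers(G.region_mask(chrom, start, end))
    if Gw.n_markers == 0:
        raise ValueError("window contains no markers")
    H = _haploid_codes(Gw.calls)
    callable_frac = (H >= 0).mean(axis=1)
    retained = np.flatnonzero(callable_frac >= min_call_fraction)

    subpop = Gw.lines["subpop"] if "subpop" in Gw.lines else pd.Series(
        ["?"] * Gw.n_lines)
    complete = [i for i in retained if (H[i] >= 0).all()]
    groups: dict = {}
    for i in complete:
        key = "".join(str(a) for a in H[i])
        groups.setdefault(key, []).append(i)

    assignments: dict = {}
    for i in retained:
        if (H[i] >= 0).all():
            assignments[Gw.line_ids[i]] = "".join(str(a) for a in H[i])
            continue
        obs = H[i] >= 0
        compatible = [
            key for key in groups
            if all(int(key[j]) == H[i, j] for j in np.flatnonzero(obs))
        ]
        if len(compatible) == 1:
            assignments[Gw.line_ids[i]] = compatible[0]
            groups[compatible[0]].append(i)
        else:
            assignments[Gw.line_ids[i]] = None

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    rows = []
    key_to_id = {}
    for rank, (key, members) in enumerate(ordered, start=1):
        hid = f"H{rank}"
        key_to_id[key] = hid
        comp: dict = {}
        for i in members:
            comp[subpop.iloc[i]] = comp.get(subpop.iloc[i], 0) + 1
        rows.append({"id": hid, "alleles": key,
                     "carriers": [Gw.line_ids[i] for i in sorted(members)],
                     "count": len(members), "subpops": comp})
    assignments = {lid: (key_to_id[k] if k is not None else None)
                   for lid, k in assignments.items()}
    return HaplotypeTable(
        chrom, start, end, list(Gw.marker_ids),
        pd.DataFrame(rows, columns=["id", "alleles", "carriers", "count", "subpops"]),
        assignments,
    )


def haplotype_variance_explained(table: HaplotypeTable, phenotype: pd.Series,
                                 focal_haplotype: str,
                                 subset=None) -> float:
    """One-way ANOVA R^2 of phenotype on carrying the focal haplotype.

    ``phenotype`` is indexed by line id.  ``subset`` optionally restricts the
    analysis to a germplasm subset (e.g. one subpopulation's line ids).
    Needs >= 3 carriers and >= 3 non-carriers with phenotypes; degenerate
    splits raise.
    """
    carriers = set(table.carriers(focal_haplotype))
    lines = [l for l in table.assignments if table.assignments[l] is not None]
    if subset is not None:
        subset = set(subset)
        lines = [l for l in lines if l in subset]
    lines = [l for l in lines if l in phenotype.index and not np.isnan(phenotype[l])]
    indicator = np.array([1 if l in carriers else 0 for l in lines])
    if indicator.sum() < 3 or (len(lines) - indicator.sum()) < 3:
        raise ValueError("need >= 3 carriers and >= 3 non-carriers")
    values = np.array([phenotype[l] for l in lines], dtype=float)
    return anova_r2(values, indicator)
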