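"""Bi-parental QTL scans: Haley–Knott interval mapping and composite
interval mapping (CIM) with permutation LOD thresholds.

Populations are inbred (RIL or BIL), coded per marker as parent-A or
parent-B homozygote; residual heterozygous calls are treated as missing.
At each evaluation position the expected parent-B dosage given the nearest
informative flanking markers is computed under the Haldane map function
with the selfed-line map expansion ``R = 2r / (1 + 2r)``, and the phenotype
is regressed on that dosage (plus, for CIM, cofactor markers outside an
exclusion window).  ``LOD = (n/2) log10(RSS0 / RSS1)``.

Genome-wide significance comes from permutation of the phenotype: the
threshold is the (1 - alpha) quantile of the maximum genome-wide LOD over
permuted scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import _haldane_r, ril_recombinant_fraction

DEFAULT_STEP_CM = 1.0
DEFAULT_WINDOW_CM = 10.0
DEFAULT_N_COFACTORS = 5

_CODE = {"A": 0, "B": 1, "H": -1, "-": -1}


@dataclass
class CrossGenotypes:
    """Genotypes of an inbred bi-parental population.

    ``codes``: lines x markers in {0 (parent A), 1 (parent B), -1 (missing;
    residual heterozygotes are recoded to missing)}.  ``gmap`` has columns
    ``id``, ``chrom``, ``cM`` and ``pos`` (bp), monotone in cM within each
    chromosome.  ``design`` is 'RIL' (class frequencies 0.5/0.5) or 'BIL'
    (0.75 parent A / 0.25 donor parent B).
    """

    codes: np.ndarray
    gmap: pd.DataFrame
    design: str = "RIL"
    line_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.design not in ("RIL", "BIL"):
            raise ValueError("design must be RIL or BIL")
        bad = set(np.unique(self.codes)) - {-1, 0, 1}
        if bad:
            raise ValueError(f"invalid codes: {sorted(bad)}")
        self.gmap = self.gmap.reset_index(drop=True)
        for chrom, grp in self.gmap.groupby("chrom", sort=False):
            if np.any(np.diff(grp["cM"].to_numpy()) < 0):
                raise ValueError(f"genetic map not monotone on {chrom}")
        if not self.line_ids:
            self.line_ids = [f"line_{i}" for i in range(self.codes.shape[0])]

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def pi_b(self) -> float:
        """A priori parent-B class frequency."""
        return 0.5 if self.design == "RIL" else 0.25

    @classmethod
    def from_letters(cls, letters: np.ndarray, gmap: pd.DataFrame,
                     design: str = "RIL", line_ids=None) -> "CrossGenotypes":
        """Build from an A/B/H/- letter matrix (H treated as missing)."""
        arr = np.vectorize(lambda s: _CODE[s])(np.asarray(letters, dtype=object))
        return cls(arr.astype(np.int8), gmap, design, list(line_ids or []))


# ----------------------------------------------------------------------
def _chain_params(d_cM: np.ndarray, pi_b: float):
    """Per-interval switch probabilities of the stationary origin chain."""
    R = ril_recombinant_fraction(_haldane_r(d_cM))
    return np.clip(R / (2.0 * pi_b * (1.0 - pi_b)), 0.0, 1.0)


def _transition(s: float, pi_b: float) -> np.ndarray:
    """2x2 transition matrix: stay with prob 1-s, else redraw from (1-pi, pi)."""
    pi = np.array([1.0 - pi_b, pi_b])
    return (1.0 - s) * np.eye(2) + s * np.ones((2, 1)) @ pi[None, :]


def expected_dosage(cross: CrossGenotypes, chrom, cm_positions: np.ndarray) -> np.ndarray:
    """Expected parent-B dosage at evaluation positions on one chromosome.

    For each line and position, conditions on the nearest informative
    (non-missing) flanking markers under the two-state origin chain; with a
    single informative flank the single-marker conditional is used, and with
    none the prior ``pi_b``.
    """
    grp = cross.gmap[cross.gmap["chrom"] == chrom]
    midx = grp.index.to_numpy()
    cm = grp["cM"].to_numpy(dtype=float)
    codes = cross.codes[:, midx]
    pi_b = cross.pi_b
    n, m = codes.shape
    out = np.empty((n, len(cm_positions)))

    for i in range(n):
        obs = np.flatnonzero(codes[i] >= 0)
        ocm = cm[obs]
        og = codes[i, obs].astype(float)
        for t, c in enumerate(cm_positions):
            right = np.searchsorted(ocm, c)
            left = right - 1
            have_l = left >= 0
            have_r = right < len(obs)
            if not have_l and not have_r:
                out[i, t] = pi_b
                continue
            if have_l and ocm[left] == c:
                out[i, t] = og[left]
                continue
            if have_l and have_r:
                s_l = _chain_params(np.array([c - ocm[left]]), pi_b)[0]
                s_r = _chain_params(np.array([ocm[right] - c]), pi_b)[0]
                Tl = _transition(s_l, pi_b)
                Tr = _transition(s_r, pi_b)
                gl, gr = int(og[left]), int(og[right])
                num = Tl[gl, 1] * Tr[1, gr]
                den = Tl[gl, 0] * Tr[0, gr] + num
                out[i, t] = num / den if den > 0 else pi_b
            elif have_l:
                s_l = _chain_params(np.array([c - ocm[left]]), pi_b)[0]
                out[i, t] = _transition(s_l, pi_b)[int(og[left]), 1]
            else:
                s_r = _chain_params(np.array([ocm[right] - c]), pi_b)[0]
                T = _transition(s_r, pi_b)
                gr = int(og[right])
                num = pi_b * T[1, gr]
                den = (1 - pi_b) * T[0, gr] + num
                out[i, t] = num / den if den > 0 else pi_b
    return out


def scan_positions(cross: CrossGenotypes, step_cM: float = DEFAULT_STEP_CM) -> pd.DataFrame:
    """Evaluation grid: every ``step_cM`` along each chromosome plus marker positions."""
    rows = []
    for chrom, grp in cross.gmap.groupby("chrom", sort=False):
        cm = grp["cM"].to_numpy(dtype=float)
        grid = np.arange(cm.min(), cm.max() + 1e-9, step_cM)
        allcm = np.unique(np.round(np.concatenate([grid, cm]), 6))
        pos = np.interp(allcm, cm, grp["pos"].to_numpy(dtype=float))
        for c, p in zip(allcm, pos):
            rows.append({"chrom": chrom, "cM": c, "pos": float(p)})
    return pd.DataFrame(rows)


@dataclass
class QtlScanResult:
    """Genome-scan profile with optional threshold and peak table.

    ``profile`` has per evaluation position: ``chrom``, ``cM``, ``pos`` (bp),
    ``lod``, ``effect`` (additive effect of a parent-B allele substitution),
    ``r2``.
    """

    profile: pd.DataFrame
    design: str
    method: str
    threshold: float | None = None
    peaks: pd.DataFrame | None = None

    @property
    def max_lod(self) -> float:
        return float(self.profile["lod"].max())

    def summary(self) -> str:
        out = [f"QTL scan ({self.method}, {self.design}): "
               f"{len(self.profile)} positions, max LOD = {self.max_lod:.2f}"]
        if self.threshold is not None:
            out.append(f"permutation LOD threshold = {self.threshold:.2f}")
        if self.peaks is not None and len(self.peaks):
            out.append(self.peaks.to_string(index=False))
        elif self.peaks is not None:
            out.append("no significant QTL")
        return "\n".join(out)


def _fit_position(y, dosage, cof=None):
    """Single-position Haley–Knott regression; returns (lod, effect, r2)."""
    n = y.size
    ones = np.ones((n, 1))
    X0 = ones if cof is None else np.hstack([ones, cof])
    X1 = np.hstack([X0, dosage[:, None]])
    b0, _, _, _ = np.linalg.lstsq(X0, y, rcond=None)
    r0 = y - X0 @ b0
    rss0 = float(r0 @ r0)
    b1, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
    r1 = y - X1 @ b1
    rss1 = float(r1 @ r1)
    if rss1 <= 0 or rss0 <= 0:
        lod = 0.0 if rss0 <= 0 else float("inf")
    else:
        lod = (n / 2.0) * np.log10(rss0 / rss1)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = (rss0 - rss1) / tss if tss > 0 else 0.0
    return max(lod, 0.0), float(b1[-1]), float(r2)


class QtlScanModel:
    """Interval-mapping / CIM scan of one phenotype on a bi-parental cross.

    ``fit`` evaluates the LOD profile; ``permutation_threshold`` computes the
    genome-wide significance level; ``peak_summary`` extracts QTL peaks with
    LOD-1 support intervals.
    """

    def __init__(self, cross: CrossGenotypes, phenotype,
                 step_cM: float = DEFAULT_STEP_CM):
        y = np.asarray(phenotype, dtype=float)
        if y.shape[0] != cross.n_lines:
            raise ValueError("phenotype length does not match line count")
        keep = ~np.isnan(y)
        self.cross = CrossGenotypes(
            cross.codes[keep], cross.gmap, cross.design,
            [cross.line_ids[i] for i in np.flatnonzero(keep)],
        )
        self.y = y[keep]
        self.step_cM = step_cM
        self.positions = scan_positions(self.cross, step_cM)
        self._dosage = self._dosage_matrix()

    def _dosage_matrix(self) -> np.ndarray:
        """Expected dosages at all evaluation positions (lines x positions)."""
        cols = []
        for chrom, grp in self.positions.groupby("chrom", sort=False):
            cols.append(expected_dosage(self.cross, chrom, grp["cM"].to_numpy()))
        return np.hstack(cols)

    def _marker_dosages(self) -> np.ndarray:
        """Expected dosage at marker positions (for cofactor selection)."""
        cols = []
        for chrom, grp in self.cross.gmap.groupby("chrom", sort=False):
            cols.append(expected_dosage(self.cross, chrom, grp["cM"].to_numpy()))
        return np.hstack(cols)

    def select_cofactors(self, n_cofactors: int) -> list[int]:
        """Forward stepwise selection of cofactor markers by RSS reduction."""
        if n_cofactors == 0:
            return []
        if n_cofactors >= self.cross.n_lines / 5:
            raise ValueError("n_cofactors must be < n_lines / 5")
        D = self._marker_dosages()
        y = self.y
        chosen: list[int] = []
        for _ in range(n_cofactors):
            best_j, best_rss = None, np.inf
            base = np.hstack([np.ones((y.size, 1))] + [D[:, [j]] for j in chosen])
            for j in range(D.shape[1]):
                if j in chosen:
                    continue
                X = np.hstack([base, D[:, [j]]])
                b, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
                r = y - X @ b
                rss = float(r @ r)
                if rss < best_rss - 1e-12:
                    best_rss, best_j = rss, j
            if best_j is None:
                break
            chosen.append(best_j)
        return chosen

    def fit(self, method: str = "im", n_cofactors: int = DEFAULT_N_COFACTORS,
            window_cM: float = DEFAULT_WINDOW_CM) -> QtlScanResult:
        """Evaluate the LOD profile.

        ``method='im'`` is plain Haley–Knott interval mapping;
        ``method='cim'`` adds forward-selected cofactor markers, dropping any
        cofactor within ``window_cM`` of the evaluated position on the same
        chromosome.  CIM with zero cofactors reduces exactly to interval
        mapping.
        """
        if method not in ("im", "cim"):
            raise ValueError("method must be 'im' or 'cim'")
        cof_idx = self.select_cofactors(n_cofactors) if method == "cim" else []
        D_cof = self._marker_dosages()[:, cof_idx] if cof_idx else None
        cof_map = self.cross.gmap.iloc[cof_idx] if cof_idx else None

        lods, effs, r2s = [], [], []
        for t, row in self.positions.iterrows():
            dosage = self._dosage[:, t]
            if cof_idx:
                keep = []
                for c, (_, crow) in enumerate(cof_map.iterrows()):
                    same = crow["chrom"] == row["chrom"]
                    if not (same and abs(crow["cM"] - row["cM"]) <= window_cM):
                        keep.append(c)
                cof = D_cof[:, keep] if keep else None
            else:
                cof = None
            lod, eff, r2 = _fit_position(self.y, dosage, cof)
            lods.append(lod)
            effs.append(eff)
            r2s.append(r2)
        profile = self.positions.copy()
        profile["lod"] = lods
        profile["effect"] = effs
        profile["r2"] = r2s
        return QtlScanResult(profile, self.cross.design, method)

    # ------------------------------------------------------------------
    def permutation_threshold(self, n_perm: int = 1000, alpha: float = 0.05,
                              seed: int = 0) -> float:
        """(1 - alpha) quantile of the max genome-wide interval-mapping LOD
        over phenotype permutations.

        Vectorized across permutations: with a single dosage regressor the
        LOD is ``-(n/2) log10(1 - r^2)`` for the dosage-phenotype
        correlation, so all positions x permutations reduce to one matrix
        product.
        """
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        rng = np.random.default_rng(seed)
        y = self.y
        n = y.size
        Y = np.empty((n, n_perm))
        for b in range(n_perm):
            Y[:, b] = rng.permutation(y)
        Dc = self._dosage - self._dosage.mean(axis=0, keepdims=True)
        Yc = Y - Y.mean(axis=0, keepdims=True)
        dn = np.linalg.norm(Dc, axis=0)
        yn = np.linalg.norm(Yc, axis=0)
        dn[dn == 0] = np.inf
        r = (Dc.T @ Yc) / np.outer(dn, yn)  # positions x perms
        r2 = np.clip(r**2, 0.0, 1.0 - 1e-15)
        lod = -(n / 2.0) * np.log10(1.0 - r2)
        max_lod = lod.max(axis=0)
        return float(np.quantile(max_lod, 1.0 - alpha))

    def peak_summary(self, result: QtlScanResult, threshold: float) -> pd.DataFrame:
        """QTL peaks above ``threshold`` with LOD-1 support intervals.

        One peak per chromosome exceeding the threshold (the position of
        maximum LOD); the support interval is the contiguous run around the
        peak with LOD >= peak - 1, reported in bp (and Mb) at its outermost
        positions.  The additive effect's sign says which parent's allele
        increases the trait (positive = parent B / donor).
        """
        rows = []
        prof = result.profile
        for chrom, grp in prof.groupby("chrom", sort=False):
            grp = grp.reset_index(drop=True)
            if grp["lod"].max() < threshold:
                continue
            pk = int(grp["lod"].idxmax())
            peak_lod = grp["lod"].iloc[pk]
            lo = pk
            while lo > 0 and grp["lod"].iloc[lo - 1] >= peak_lod - 1.0:
                lo -= 1
            hi = pk
            while hi < len(grp) - 1 and grp["lod"].iloc[hi + 1] >= peak_lod - 1.0:
                hi += 1
            rows.append(
                {
                    "chrom": chrom,
                    "peak_cM": grp["cM"].iloc[pk],
                    "peak_pos": grp["pos"].iloc[pk],
                    "peak_mb": grp["pos"].iloc[pk] / 1e6,
                    "lod1_left_mb": grp["pos"].iloc[lo] / 1e6,
                    "lod1_right_mb": grp["pos"].iloc[hi] / 1e6,
                    "lod": peak_lod,
                    "effect": grp["effect"].iloc[pk],
                    "tolerant_parent": "B" if grp["effect"].iloc[pk] > 0 else "A",
                    "r2": grp["r2"].iloc[pk],
                }
            )
        return pd.DataFrame(
            rows,
            columns=["chrom", "peak_cM", "peak_pos", "peak_mb", "lod1_left_mb",
                     "lod1_right_mb", "lod", "effect", "tolerant_parent", "r2"],
        )


def interval_map(cross: CrossGenotypes, phenotype, step_cM: float = DEFAULT_STEP_CM) -> QtlScanResult:
    """Haley–Knott interval mapping (functional wrapper)."""
    return QtlScanModel(cross, phenotype, step_cM).fit(method="im")


def cim(cross: CrossGenotypes, phenotype, n_cofactors: int = DEFAULT_N_COFACTORS,
        window_cM: float = DEFAULT_WINDOW_CM, step_cM: float = DEFAULT_STEP_CM) -> QtlScanResult:
    """Composite interval mapping (functional wrapper)."""
    return QtlScanModel(cross, phenotype, step_cM).fit(
        method="cim", n_cofactors=n_cofactors, window_cM=window_cM
    )
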