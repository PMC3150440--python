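"""Structure-aware genome-wide association for inbred-line panels.

Three single-marker models over a :class:`~alumpanel.panel.GenotypeMatrix`:

* ``naive`` — ordinary least squares of phenotype on allele dosage;
* ``pca``   — OLS with the leading genotype principal components as fixed
  covariates (default four);
* ``mixed`` — a kinship mixed model ``y = X b + C g + Z u + e`` with
  ``u ~ N(0, s2_g K)`` for an identity-by-state kinship K and
  ``e ~ N(0, s2_e I)``.  Variance components are estimated once per scan by
  REML on the null (no-marker) model via the spectral decomposition of K,
  and each marker is then tested by generalized least squares at those
  components — the standard single-variance-component approximation to
  exact per-marker REML.

Supporting machinery: MAF filtering, IBS kinship, genotype PCA, per-subset
scans, significant-region merging, candidate-window enrichment and the
genomic inflation factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_MAF = 0.05
DEFAULT_P_THRESHOLD = 1.0e-4
DEFAULT_WINDOW_BP = 200_000
DEFAULT_N_PCS = 4


# ----------------------------------------------------------------------
def maf_filter(G: GenotypeMatrix, threshold: float = DEFAULT_MAF) -> GenotypeMatrix:
    """Retain markers with minor-allele frequency strictly greater than ``threshold``.

    MAF is computed on non-missing calls of the lines present in ``G``; the
    comparison is strict (a marker at exactly the threshold is dropped).
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must lie in [0, 0.5]")
    return G.subset_markers(G.maf() > threshold)


def ibs_kinship(G: GenotypeMatrix) -> np.ndarray:
    """Identity-by-state similarity matrix over lines.

    Entry (i, j) is the mean over markers non-missing in both lines of the
    shared-allele proportion ``1 - |g_i - g_j| / 2``.  Symmetric with unit
    diagonal; a line pair with no overlapping markers is an error.
    """
    if G.n_lines < 2:
        raise ValueError("kinship needs >= 2 lines")
    calls = G.calls.astype(np.float64)
    obs = calls >= 0
    callsz = np.where(obs, calls, 0.0)
    obs_f = obs.astype(np.float64)
    # sum over markers of |gi - gj| restricted to jointly observed markers:
    # |gi-gj| expands over the 3x3 dosage table; use one matmul per dosage level
    overlap = obs_f @ obs_f.T
    if np.any(overlap == 0):
        i, j = np.argwhere(overlap == 0)[0]
        raise ValueError(
            f"lines {G.line_ids[i]!r} and {G.line_ids[j]!r} share no observed markers"
        )
    ind = [((calls == d) & obs).astype(np.float64) for d in (0, 1, 2)]
    absdiff = np.zeros_like(overlap)
    for a in range(3):
        for b in range(3):
            if a != b:
                absdiff += abs(a - b) * (ind[a] @ ind[b].T)
    K = 1.0 - absdiff / (2.0 * overlap)
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return K


def pca_covariates(G: GenotypeMatrix, n_components: int = DEFAULT_N_PCS) -> np.ndarray:
    """Leading principal components of the centered, mean-imputed genotype scores.

    Missing calls are imputed with the marker mean before centering; the
    returned (lines x n_components) matrix holds the line coordinates on the
    top eigenvectors of the line-by-line covariance, ordered by decreasing
    explained variance.
    """
    if n_components >= G.n_lines:
        raise ValueError("n_components must be < number of lines")
    X = G.calls.astype(np.float64)
    miss = X < 0
    col_mean = np.where(
        (~miss).sum(axis=0) > 0,
        np.where(miss, 0, X).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
        0.0,
    )
    X = np.where(miss, col_mean[None, :], X)
    X -= X.mean(axis=0)
    cov = (X @ X.T) / max(G.n_markers - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:n_components]
    pcs = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return pcs


# ----------------------------------------------------------------------
@dataclass
class AssociationResults:
    """Per-marker association results from one scan.

    ``frame`` has one row per tested marker: ``marker``, ``chrom``, ``pos``,
    ``maf``, ``n``, ``effect``, ``se``, ``p``.  ``model`` names the
    structure correction and ``germplasm`` the analyzed line set.
    """

    frame: pd.DataFrame
    model: str
    germplasm: str = "all"
    variance_components: tuple | None = None  # (s2_g, s2_e) for the mixed model

    def significant(self, p_threshold: float = DEFAULT_P_THRESHOLD) -> pd.DataFrame:
        return self.frame[self.frame["p"] < p_threshold]

    def summary(self, top: int = 10) -> str:
        lines = [
            f"Association scan: model={self.model} germplasm={self.germplasm} "
            f"markers={len(self.frame)}"
        ]
        if self.variance_components is not None:
            s2g, s2e = self.variance_components
            lines.append(f"REML variance components: s2_g={s2g:.4g} s2_e={s2e:.4g}")
        if len(self.frame) >= 100:
            lines.append(f"genomic inflation lambda = {genomic_inflation(self):.3f}")
        best = self.frame.nsmallest(top, "p")
        lines.append(best.to_string(index=False))
        return "\n".join(lines)


class AssociationScanModel:
    """Single-marker genome scan of a phenotype on a genotype panel.

    Parameters
    ----------
    G : GenotypeMatrix
        Genotypes; apply :func:`maf_filter` beforehand (or use ``maf`` here).
    y : array-like
        Phenotype aligned with the lines of ``G``; NaN lines are dropped.
    model : {'naive', 'pca', 'mixed'}
    covariates : ndarray, optional
        Fixed covariates (without intercept); computed via
        :func:`pca_covariates` when model='pca' and not supplied.
    kinship : ndarray, optional
        IBS kinship for the mixed model; computed via :func:`ibs_kinship`
        when not supplied.
    """

    def __init__(self, G: GenotypeMatrix, y, model: str = "mixed",
                 covariates: np.ndarray | None = None,
                 kinship: np.ndarray | None = None,
                 germplasm: str = "all"):
        if model not in ("naive", "pca", "mixed"):
            raise ValueError("model must be naive, pca or mixed")
        y = np.asarray(y, dtype=float)
        if y.shape[0] != G.n_lines:
            raise ValueError("phenotype length does not match line count")
        keep = ~np.isnan(y)
        if not keep.all():
            G = G.subset_lines(keep)
            y = y[keep]
            if covariates is not None:
                covariates = covariates[keep]
            if kinship is not None:
                kinship = kinship[np.ix_(keep, keep)]
        self.G = G
        self.y = y
        self.model = model
        self.germplasm = germplasm
        if model == "pca" and covariates is None:
            covariates = pca_covariates(G)
        self.covariates = covariates
        if model == "mixed" and kinship is None:
            kinship = ibs_kinship(G)
        self.kinship = kinship

    # -- REML machinery -------------------------------------------------
    @staticmethod
    def _reml_loglik(log_delta: float, lam: np.ndarray, eta2: np.ndarray) -> float:
        """Restricted log-likelihood profile in delta = s2_e / s2_g.

        ``lam`` are the non-trivial eigenvalues of the projected kinship and
        ``eta2`` the squared rotated null-model residuals.
        """
        delta = np.exp(log_delta)
        w = lam + delta
        n = lam.size
        sigma2 = np.sum(eta2 / w) / n
        return -0.5 * (n * np.log(2 * np.pi * sigma2) + np.sum(np.log(w)) + n)

    def _fit_variance_components(self, X0: np.ndarray):
        """EMMA-style null-model REML: eigendecompose S K S on the null design."""
        K = np.asarray(self.kinship, dtype=float)
        n, q = X0.shape
        # project out the null fixed effects
        Q, _ = np.linalg.qr(X0)
        S = np.eye(n) - Q @ Q.T
        vals, vecs = np.linalg.eigh(S @ (K + 1e-9 * np.eye(n)) @ S)
        order = np.argsort(vals)[::-1][: n - q]
        lam = np.maximum(vals[order], 0.0)
        U = vecs[:, order]
        eta = U.T @ self.y
        eta2 = eta**2

        grid = np.linspace(-10, 10, 81)
        lls = [self._reml_loglik(g, lam, eta2) for g in grid]
        i = int(np.argmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda g: -self._reml_loglik(g, lam, eta2), bounds=(lo, hi),
            method="bounded", options={"xatol": 1e-8},
        )
        delta = float(np.exp(res.x))
        w = lam + delta
        s2_g = float(np.sum(eta2 / w) / lam.size)
        s2_e = s2_g * delta
        return s2_g, s2_e, delta

    # -------------------------------------------------------------------
    def fit(self) -> AssociationResults:
        """Run the scan and return per-marker effects and p-values."""
        G, y = self.G, self.y
        n = G.n_lines
        C = self.covariates
        q_cov = 0 if C is None else C.shape[1]
        ones = np.ones((n, 1))
        X0 = ones if C is None else np.hstack([ones, C])

        var_comp = None
        if self.model == "mixed":
            s2_g, s2_e, delta = self._fit_variance_components(X0)
            var_comp = (s2_g, s2_e)
            K = np.asarray(self.kinship, dtype=float)
            vals, vecs = np.linalg.eigh(K)
            vals = np.maximum(vals, 0.0)  # PSD shift: clip spurious negatives
            # whitening transform: rows scaled by 1/sqrt(lam_i + delta)
            scale = 1.0 / np.sqrt(vals + delta)
            W = (vecs * scale[None, :]).T  # W V W' = s2_g I
        else:
            W = None

        calls = G.calls
        maf = G.maf()
        rows = []
        for j in range(G.n_markers):
            g = calls[:, j].astype(float)
            obs = g >= 0
            n_used = int(obs.sum())
            X = np.hstack([X0[obs], g[obs, None]])
            yj = y[obs]
            if W is not None:
                if obs.all():
                    Xt, yt = W @ X, W @ y
                else:
                    # re-whiten on the observed subset
                    Ks = np.asarray(self.kinship, dtype=float)[np.ix_(obs, obs)]
                    v, u = np.linalg.eigh(Ks)
                    v = np.maximum(v, 0.0)
                    Ws = (u * (1.0 / np.sqrt(v + delta))[None, :]).T
                    Xt, yt = Ws @ X, Ws @ yj
            else:
                Xt, yt = X, yj
            df = n_used - X.shape[1]
            if df < 1 or np.linalg.matrix_rank(Xt) < Xt.shape[1]:
                logger.info("marker %s skipped: singular design", G.marker_ids[j])
                continue
            beta, rss, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
            resid = yt - Xt @ beta
            rss = float(resid @ resid)
            XtX_inv = np.linalg.inv(Xt.T @ Xt)
            sigma2 = rss / df
            se = float(np.sqrt(sigma2 * XtX_inv[-1, -1]))
            eff = float(beta[-1])
            if se == 0:
                p = 1.0
            else:
                t = eff / se
                p = float(2.0 * stats.t.sf(abs(t), df))
            rows.append(
                {
                    "marker": G.marker_ids[j],
                    "chrom": G.markers["chrom"].iloc[j],
                    "pos": int(G.markers["pos"].iloc[j]),
                    "maf": float(maf[j]),
                    "n": n_used,
                    "effect": eff,
                    "se": se,
                    "p": max(p, np.nextafter(0, 1)),
                }
            )
        frame = pd.DataFrame(rows)
        return AssociationResults(frame, self.model, self.germplasm, var_comp)


def scan(G: GenotypeMatrix, y, model: str = "mixed", covariates=None,
         kinship=None, germplasm: str = "all") -> AssociationResults:
    """Functional wrapper: build an :class:`AssociationScanModel` and fit it."""
    return AssociationScanModel(G, y, model, covariates, kinship, germplasm).fit()


def subpopulation_scans(
    G: GenotypeMatrix, y, labels, model: str = "mixed",
    maf: float = DEFAULT_MAF, min_lines: int = 30,
) -> list[AssociationResults]:
    """Panel-wide scan plus one scan per subpopulation subset.

    MAF filtering and (for the mixed model) kinship are recomputed within
    each subset; subsets below ``min_lines`` are skipped with a warning.
    The panel-wide scan uses all lines regardless of label.
    """
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    results = [scan(maf_filter(G, maf), y, model=model, germplasm="all")]
    for sub in pd.unique(labels):
        mask = labels == sub
        if mask.sum() < min_lines:
            logger.warning("subset %s has %d lines (< %d); skipped", sub, mask.sum(), min_lines)
            continue
        Gs = maf_filter(G.subset_lines(mask), maf)
        # within a subpopulation there is no main structure axis; drop PCs
        sub_model = "mixed" if model == "mixed" else "naive"
        results.append(scan(Gs, y[mask], model=sub_model, germplasm=str(sub)))
    return results


# ----------------------------------------------------------------------
@dataclass
class RegionCall:
    """A merged run of significant markers (bp, 0-based half-open)."""

    chrom: object
    start: int
    end: int
    markers: list
    best_p: float
    germplasm: str = "all"


def call_regions(result: AssociationResults,
                 p_threshold: float = DEFAULT_P_THRESHOLD,
                 merge_window_bp: int = DEFAULT_WINDOW_BP) -> list[RegionCall]:
    """Merge significant markers into disjoint regions.

    Markers with p < ``p_threshold`` are merged into one region when
    successive significant markers on a chromosome lie within
    ``merge_window_bp``; the region spans min..max member position
    (half-open, end exclusive at max position + 1).
    """
    if p_threshold <= 0 or merge_window_bp <= 0:
        raise ValueError("thresholds must be positive")
    sig = result.significant(p_threshold).sort_values(["chrom", "pos"])
    regions: list[RegionCall] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        cur: list = []
        last_pos = None
        for _, row in grp.iterrows():
            if last_pos is not None and row["pos"] - last_pos > merge_window_bp:
                regions.append(_close_region(chrom, cur, result.germplasm))
                cur = []
            cur.append(row)
            last_pos = row["pos"]
        if cur:
            regions.append(_close_region(chrom, cur, result.germplasm))
    return regions


def _close_region(chrom, rows, germplasm) -> RegionCall:
    pos = [int(r["pos"]) for r in rows]
    return RegionCall(
        chrom=chrom,
        start=min(pos),
        end=max(pos) + 1,
        markers=[r["marker"] for r in rows],
        best_p=float(min(r["p"] for r in rows)),
        germplasm=germplasm,
    )


def candidate_enrichment(
    result: AssociationResults,
    gene_positions: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    exclude_regions: list | None = None,
) -> dict:
    """Enrichment of significant markers near a priori candidate genes.

    ``gene_positions`` has columns ``chrom`` and ``pos``.  Markers within
    ``window_bp`` of any gene are the candidate-window class; the background
    class is everything outside the windows and outside any supplied
    ``exclude_regions`` (list of (chrom, start, end)).  Returns the
    enrichment ratio (significant fraction in windows over significant
    fraction in background) and the upper-limit FDR in the windows
    (expected false positives at the threshold over observed significant
    count).
    """
    frame = result.frame
    in_window = np.zeros(len(frame), dtype=bool)
    pos = frame["pos"].to_numpy()
    for _, gene in gene_positions.iterrows():
        on = (frame["chrom"] == gene["chrom"]).to_numpy()
        in_window |= on & (np.abs(pos - gene["pos"]) <= window_bp)
    excluded = np.zeros(len(frame), dtype=bool)
    for (chrom, start, end) in exclude_regions or []:
        on = (frame["chrom"] == chrom).to_numpy()
        excluded |= on & (pos >= start) & (pos < end)
    background = ~in_window & ~excluded

    sig = (frame["p"] < p_threshold).to_numpy()
    n_win, n_bg = int(in_window.sum()), int(background.sum())
    if n_win == 0:
        return {"enrichment": float("nan"), "fdr_upper": float("nan"),
                "n_window": 0, "n_background": n_bg, "flag": "no markers in windows"}
    sig_win = int((sig & in_window).sum())
    sig_bg = int((sig & background).sum())
    frac_win = sig_win / n_win
    frac_bg = sig_bg / n_bg if n_bg else float("nan")
    enrichment = frac_win / frac_bg if frac_bg else float("inf")
    fdr_upper = (p_threshold * n_win / sig_win) if sig_win else float("nan")
    return {
        "enrichment": float(enrichment),
        "fdr_upper": float(fdr_upper),
        "n_window": n_win,
        "n_background": n_bg,
        "sig_window": sig_win,
        "sig_background": sig_bg,
    }


def genomic_inflation(result: AssociationResults | pd.Series | np.ndarray) -> float:
    """Genomic inflation factor lambda.

    Median of the per-marker association chi-square statistics (1 df,
    obtained from the two-sided p-values) divided by the null median
    ``chi2_1(0.5) ~ 0.4549``.
    """
    if isinstance(result, AssociationResults):
        p = result.frame["p"].to_numpy()
    else:
        p = np.asarray(result, dtype=float)
    if p.size < 100:
        raise ValueError("genomic inflation needs >= 100 tested markers")
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
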