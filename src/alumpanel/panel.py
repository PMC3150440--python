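"""Genotype containers for inbred-line SNP panels.

The central object is :class:`GenotypeMatrix`: biallelic calls for a set of
inbred lines (coded 0/1/2 alternate-allele dosage, ``-1`` for missing), a
marker map sorted by (chromosome, position), and per-line metadata.  All
internal coordinates are 0-based, half-open; 1-based formats (VCF, HapMap)
are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

_VALID_CALLS = frozenset({-1, 0, 1, 2})


@dataclass
class GenotypeMatrix:
    """Lines x markers biallelic genotype calls with map and line metadata.

    Parameters
    ----------
    calls : ndarray of int8, shape (n_lines, n_markers)
        Alternate-allele dosage in {0, 1, 2}; -1 encodes missing.
    markers : DataFrame with columns ``id``, ``chrom``, ``pos``
        Marker map; ``pos`` is the 0-based bp position.  Must be sorted by
        (chrom, pos) with unique ids.
    lines : DataFrame with columns ``id`` and optionally ``subpop``
        One row per line, aligned with ``calls`` rows.
    """

    calls: np.ndarray
    markers: pd.DataFrame
    lines: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D lines x markers array")
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.markers)} markers"
            )
        bad = set(np.unique(self.calls)) - _VALID_CALLS
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        self.markers = self.markers.reset_index(drop=True)
        self.lines = self.lines.reset_index(drop=True)
        if self.markers["id"].duplicated().any():
            dup = self.markers.loc[self.markers["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate marker id: {dup}")
        if self.lines["id"].duplicated().any():
            dup = self.lines.loc[self.lines["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate line id: {dup}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"marker positions out of order on chromosome {chrom}")

    # ------------------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def line_ids(self) -> np.ndarray:
        return self.lines["id"].to_numpy()

    @property
    def marker_ids(self) -> np.ndarray:
        return self.markers["id"].to_numpy()

    @property
    def chroms(self) -> list:
        """Chromosome labels in map order."""
        seen: list = []
        for c in self.markers["chrom"]:
            if c not in seen:
                seen.append(c)
        return seen

    def marker_index(self, marker_id) -> int:
        idx = np.flatnonzero(self.marker_ids == marker_id)
        if idx.size == 0:
            raise KeyError(f"unknown marker id: {marker_id}")
        return int(idx[0])

    def line_index(self, line_id) -> int:
        idx = np.flatnonzero(self.line_ids == line_id)
        if idx.size == 0:
            raise KeyError(f"unknown line id: {line_id}")
        return int(idx[0])

    # ------------------------------------------------------------------
    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker on non-missing calls.

        Markers with no non-missing calls get MAF 0.
        """
        calls = self.calls
        obs = calls >= 0
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
        return np.minimum(p, 1.0 - p)

    def heterozygosity(self) -> float:
        """Fraction of heterozygous calls among non-missing calls."""
        obs = self.calls >= 0
        n = obs.sum()
        return float((self.calls == 1).sum() / n) if n else float("nan")

    # ------------------------------------------------------------------
    def subset_lines(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[index],
            self.markers.copy(),
            self.lines.iloc[index].reset_index(drop=True),
        )

    def subset_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[:, index],
            self.markers.iloc[index].reset_index(drop=True),
            self.lines.copy(),
        )

    def select_lines(self, line_ids) -> "GenotypeMatrix":
        idx = [self.line_index(i) for i in line_ids]
        return self.subset_lines(np.asarray(idx))

    def region_mask(self, chrom, start: int | None = None, end: int | None = None) -> np.ndarray:
        """Boolean marker mask for markers on ``chrom`` with pos in [start, end)."""
        mask = (self.markers["chrom"] == chrom).to_numpy()
        pos = self.markers["pos"].to_numpy()
        if start is not None:
            mask &= pos >= start
        if end is not None:
            mask &= pos < end
        return mask

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.copy(), self.markers.copy(), self.lines.copy())
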