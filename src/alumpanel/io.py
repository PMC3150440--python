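"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based, half-open bp everywhere; 1-based formats
(VCF, HapMap-like TSV) are converted at this boundary.  Emitted BED is
0-based half-open; emitted TSV position columns carry a ``pos0`` name to
mark the convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import MISSING, GenotypeMatrix

GENO_SUFFIX = ".geno.csv"
MAP_SUFFIX = ".map.tsv"


# ----------------------------------------------------------------------
def write_genotypes(G: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write a panel as ``<prefix>.geno.csv`` (lines x markers, -1 missing)
    and ``<prefix>.map.tsv`` (marker, chrom, pos0)."""
    prefix = Path(prefix)
    geno_path = prefix.with_name(prefix.name + GENO_SUFFIX)
    map_path = prefix.with_name(prefix.name + MAP_SUFFIX)
    df = pd.DataFrame(G.calls, columns=G.marker_ids)
    meta_cols = [c for c in G.lines.columns]
    for c in reversed(meta_cols):
        df.insert(0, c, G.lines[c].to_numpy())
    df.to_csv(geno_path, index=False)
    m = G.markers.rename(columns={"pos": "pos0"})
    m.to_csv(map_path, sep="\t", index=False)
    return geno_path, map_path


def read_genotypes(path: str | Path, dialect: str = "csv",
                   map_path: str | Path | None = None) -> GenotypeMatrix:
    """Read genotypes in one of the supported dialects.

    ``csv``: the pair written by :func:`write_genotypes` (``path`` may be
    the prefix or the .geno.csv file).  ``hapmap``: HapMap-like TSV with
    columns marker, alleles (ref/alt), chrom, pos (1-based) then one column
    per line holding two-letter genotype strings (``NN`` missing).
    ``vcf``: biallelic-SNP VCF (heterozygous calls become dosage 1,
    half-missing calls become missing).
    """
    path = Path(path)
    if dialect == "csv":
        return _read_csv_pair(path, map_path)
    if dialect == "hapmap":
        return _read_hapmap(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect: {dialect}")


def _read_csv_pair(path: Path, map_path) -> GenotypeMatrix:
    if path.name.endswith(GENO_SUFFIX):
        geno_path = path
        stem = path.name[: -len(GENO_SUFFIX)]
        map_path = map_path or path.with_name(stem + MAP_SUFFIX)
    else:
        geno_path = path.with_name(path.name + GENO_SUFFIX)
        map_path = map_path or path.with_name(path.name + MAP_SUFFIX)
    df = pd.read_csv(geno_path)
    markers = pd.read_csv(map_path, sep="\t").rename(columns={"pos0": "pos"})
    marker_ids = markers["id"].astype(str).tolist()
    meta_cols = [c for c in df.columns if c not in marker_ids]
    calls_df = df[marker_ids]
    bad = ~calls_df.isin([-1, 0, 1, 2]).to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"unknown genotype code {calls_df.iat[r, c]!r} at row {r + 2} "
            f"column {marker_ids[c]}"
        )
    lines = df[meta_cols].copy()
    return GenotypeMatrix(calls_df.to_numpy(dtype=np.int8), markers, lines)


def _read_hapmap(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["marker", "alleles", "chrom", "pos"]
    for col in fixed:
        if col not in df.columns:
            raise ValueError(f"hapmap file lacks required column {col!r}")
    line_ids = [c for c in df.columns if c not in fixed]
    calls = np.empty((len(line_ids), len(df)), dtype=np.int8)
    for j, (_, row) in enumerate(df.iterrows()):
        try:
            ref, alt = row["alleles"].split("/")
        except ValueError:
            raise ValueError(f"malformed alleles field at line {j + 2}: {row['alleles']!r}")
        for i, lid in enumerate(line_ids):
            g = row[lid]
            if g == "NN":
                calls[i, j] = MISSING
            elif len(g) == 2 and set(g) <= {ref, alt}:
                calls[i, j] = sum(1 for a in g if a == alt)
            else:
                raise ValueError(
                    f"unknown genotype code {g!r} at line {j + 2} for {lid}"
                )
    markers = pd.DataFrame({
        "id": df["marker"], "chrom": df["chrom"],
        "pos": df["pos"].astype(int) - 1,  # 1-based -> 0-based
    })
    return GenotypeMatrix(calls, markers, pd.DataFrame({"id": line_ids}))


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    ids, chroms, pos, rows = [], [], [], []
    for k, rec in enumerate(vcf):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue  # biallelic SNPs only
        ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        chroms.append(rec.CHROM)
        pos.append(rec.POS - 1)  # VCF is 1-based
        gt = rec.genotype.array()
        row = np.empty(len(line_ids), dtype=np.int8)
        for i in range(len(line_ids)):
            a, b = gt[i, 0], gt[i, 1]
            row[i] = MISSING if (a < 0 or b < 0) else int(a) + int(b)
        rows.append(row)
    calls = np.stack(rows, axis=1) if rows else np.empty((len(line_ids), 0), dtype=np.int8)
    markers = pd.DataFrame({"id": ids, "chrom": chroms, "pos": pos})
    return GenotypeMatrix(calls, markers, pd.DataFrame({"id": line_ids}))


def write_vcf(G: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal biallelic-SNP VCF (GT only; A=ref, G=alt placeholders).

    Internal 0-based positions are converted to VCF's 1-based POS.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in G.chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in G.line_ids) + "\n")
        gt_str = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(G.n_markers):
            row = G.markers.iloc[j]
            cells = [gt_str[int(c)] for c in G.calls[:, j]]
            fh.write(f"{row['chrom']}\t{int(row['pos']) + 1}\t{row['id']}\t"
                     f"A\tG\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n")
    return path


# ----------------------------------------------------------------------
def write_bed(intervals, path: str | Path) -> Path:
    """Write (chrom, start, end[, name...]) tuples as 0-based half-open BED."""
    path = Path(path)
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end, *rest = iv
            fields = [str(chrom), str(int(start)), str(int(end))] + [str(r) for r in rest]
            fh.write("\t".join(fields) + "\n")
    return path


def write_ancestry_bed(paths, out_dir: str | Path) -> list[Path]:
    """One BED per line with its decoded ancestry intervals."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for p in paths:
        written.append(write_bed(
            [(c, s, e, pop) for (c, s, e, pop) in p.intervals],
            out_dir / f"{p.line_id}.ancestry.bed",
        ))
    return written


def write_introgressions(calls, tsv_path: str | Path, bed_path: str | Path | None = None):
    """Introgression calls as TSV (pos0 convention) and optional BED."""
    rows = [
        {"line": c.line_id, "chrom": c.chrom, "start_pos0": c.start,
         "end_pos0": c.end, "donor": c.donor, "n_markers": c.n_markers,
         "mean_posterior": c.mean_posterior, "size_mb": c.size_mb,
         "unique": c.unique}
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=["line", "chrom", "start_pos0", "end_pos0",
                                     "donor", "n_markers", "mean_posterior",
                                     "size_mb", "unique"])
    df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        write_bed([(c.chrom, c.start, c.end, f"{c.line_id}:{c.donor}") for c in calls],
                  bed_path)
    return df


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
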