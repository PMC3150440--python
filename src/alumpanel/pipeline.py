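"""End-to-end orchestration: simulate -> rrg -> gwas -> qtl -> ancestry -> haplotype.

``run_pipeline`` executes the enabled stages in order on a YAML-style config
dict, writing per-stage TSV/BED outputs into the output directory plus a
JSON manifest recording inputs, parameters, seeds, package version and
per-stage record counts.  Runs with identical config and seeds are
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ancestry, gwas, haplotypes, io, phenotype, qtl, simulate

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "rrg", "gwas", "qtl", "ancestry", "haplotype")


def default_config(seed: int = 0, out_dir: str = "alumpanel_out") -> dict:
    """A complete runnable configuration with desk-scale defaults."""
    return {
        "out_dir": out_dir,
        "seed": seed,
        "stages": list(STAGE_ORDER),
        "simulate": {"K": 5, "lines_per_subpop": [30, 30, 30, 30, 30],
                     "markers_per_chrom": [400, 400], "chrom_lengths": [20_000_000, 20_000_000],
                     "fst": 0.4, "missing_rate": 0.01},
        "trait": {"target_subpop_r2": 0.57, "residual_sd": 0.08,
                  "replicate_count": 4, "replicate_cv": 0.1},
        "gwas": {"model": "mixed", "maf": 0.05, "pthresh": 1.0e-4, "window_bp": 200_000},
        "qtl": {"design": "RIL", "n_lines": 150, "perms": 300, "alpha": 0.05,
                "n_cofactors": 3, "window_cM": 10.0, "step_cM": 2.0},
        "ancestry": {"controls_per_subpop": 5, "max_iter": 30, "tol": 1e-3,
                     "tau": 0.01, "min_markers": 5, "min_bp": 100_000},
        "haplotype": {"window_kb": 200},
    }


def run_pipeline(config: dict) -> dict:
    """Execute enabled stages and return the manifest (also written to disk)."""
    out_dir = Path(config.get("out_dir", "alumpanel_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", list(STAGE_ORDER))
    manifest: dict = {"version": __version__, "seed": seed,
                      "config": config, "stages": {}}

    panel = None
    pheno = None
    indices = None
    try:
        if "simulate" in stages:
            sim = dict(config.get("simulate", {}))
            for key in ("lines_per_subpop", "markers_per_chrom", "chrom_lengths", "fst"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            panel = simulate.simulate_panel(simulate.PanelConfig(seed=seed, **sim))
            io.write_genotypes(panel.genotypes, out_dir / "panel")
            io.write_bed(
                [(c, s, e, f"{lid}:{pop}")
                 for lid, ivs in panel.true_ancestry.items()
                 for (c, s, e, pop) in ivs],
                out_dir / "true_ancestry.bed",
            )
            manifest["stages"]["simulate"] = {
                "lines": panel.genotypes.n_lines, "markers": panel.genotypes.n_markers,
            }

        if "rrg" in stages:
            if panel is None:
                raise RuntimeError("rrg stage needs the simulate stage (or input genotypes)")
            trait = simulate.TraitConfig(**config.get("trait", {}))
            pheno = simulate.simulate_root_phenotypes(panel, trait, seed=seed + 1)
            pheno.to_csv(out_dir / "root_growth.tsv", sep="\t", index=False)
            indices = phenotype.compute_rrg(pheno)
            indices.to_csv(out_dir / "rrg_indices.tsv", sep="\t", index=False)
            manifest["stages"]["rrg"] = {"lines": len(indices)}

        if "gwas" in stages:
            gcfg = config.get("gwas", {})
            y = indices.set_index("line")["TRG_RRG"].loc[panel.genotypes.line_ids].to_numpy()
            G = gwas.maf_filter(panel.genotypes, gcfg.get("maf", 0.05))
            res = gwas.scan(G, y, model=gcfg.get("model", "mixed"))
            res.frame.rename(columns={"pos": "pos0"}).to_csv(
                out_dir / "gwas_scan.tsv", sep="\t", index=False)
            regions = gwas.call_regions(res, gcfg.get("pthresh", 1e-4),
                                        gcfg.get("window_bp", 200_000))
            io.write_bed([(r.chrom, r.start, r.end, f"p={r.best_p:.3g}") for r in regions],
                         out_dir / "gwas_regions.bed")
            manifest["stages"]["gwas"] = {
                "markers_tested": len(res.frame), "regions": len(regions),
                "lambda": gwas.genomic_inflation(res) if len(res.frame) >= 100 else None,
            }

        if "qtl" in stages:
            qcfg = config.get("qtl", {})
            cross, qy = _simulated_cross_stage(panel, qcfg, seed + 2)
            model = qtl.QtlScanModel(cross, qy, step_cM=qcfg.get("step_cM", 1.0))
            scan = model.fit(method="cim", n_cofactors=qcfg.get("n_cofactors", 5),
                             window_cM=qcfg.get("window_cM", 10.0))
            thr = model.permutation_threshold(qcfg.get("perms", 1000),
                                              qcfg.get("alpha", 0.05), seed=seed + 3)
            peaks = model.peak_summary(scan, thr)
            scan.profile.to_csv(out_dir / "qtl_profile.tsv", sep="\t", index=False)
            peaks.to_csv(out_dir / "qtl_peaks.tsv", sep="\t", index=False)
            manifest["stages"]["qtl"] = {"positions": len(scan.profile),
                                         "threshold": thr, "peaks": len(peaks)}

        if "ancestry" in stages:
            acfg = config.get("ancestry", {})
            controls = _pick_controls(panel, acfg.get("controls_per_subpop", 5))
            Gsub = ancestry.select_ancestry_snps(panel.genotypes, controls,
                                                 spacing_bp=acfg.get("spacing_bp", 20_000))
            hmm = ancestry.AncestryHMM(Gsub, controls, tau=acfg.get("tau", 0.01))
            fit = hmm.fit(max_iter=acfg.get("max_iter", 30), tol=acfg.get("tol", 1e-3))
            paths = fit.decode()
            fractions = fit.ancestry_fractions(paths)
            fractions.to_csv(out_dir / "ancestry_fractions.tsv", sep="\t", index=False)
            io.write_ancestry_bed(paths, out_dir / "ancestry_tracks")
            calls = fit.call_introgressions(
                paths, acfg.get("min_markers", 5), acfg.get("min_bp", 100_000))
            io.write_introgressions(calls, out_dir / "introgressions.tsv",
                                    out_dir / "introgressions.bed")
            manifest["stages"]["ancestry"] = {
                "markers_used": Gsub.n_markers, "introgressions": len(calls),
                "loglik": fit.loglik,
            }

        if "haplotype" in stages:
            hcfg = config.get("haplotype", {})
            chrom = panel.genotypes.chroms[0]
            width = hcfg.get("window_kb", 200) * 1000
            table = haplotypes.build_haplotypes(panel.genotypes, chrom, 0, width)
            hap_df = table.haplotypes.copy()
            hap_df["carriers"] = hap_df["carriers"].map(lambda c: ",".join(map(str, c)))
            hap_df["subpops"] = hap_df["subpops"].map(str)
            hap_df.to_csv(out_dir / "haplotypes.tsv", sep="\t", index=False)
            ld = haplotypes.pairwise_ld(panel.genotypes, chrom, 0, width)
            ld["table"].to_csv(out_dir / "ld_pairs.tsv", sep="\t", index=False)
            manifest["stages"]["haplotype"] = {
                "haplotypes": len(table.haplotypes), "ld_pairs": len(ld["table"]),
                "decay_bp": ld["decay_bp"],
            }
    except Exception as exc:  # write a partial-output manifest before failing
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        io.save_manifest(manifest, out_dir / "manifest.json")
        raise
    io.save_manifest(manifest, out_dir / "manifest.json")
    return manifest


def _pick_controls(panel, per_subpop: int) -> dict:
    controls = {}
    for sub, grp in panel.genotypes.lines.groupby("subpop", sort=False):
        for lid in grp["id"].head(per_subpop):
            controls[lid] = sub
    return controls


def _simulated_cross_stage(panel, qcfg: dict, seed: int):
    """Build a bi-parental cross between two panel-derived inbred parents."""
    G = panel.genotypes
    rng = np.random.default_rng(seed)
    # synthesize fully inbred parents from the first two subpopulations' freqs
    pa = (2 * (panel.subpop_freqs[0] > 0.5)).astype(np.int8)
    pb = (2 * (panel.subpop_freqs[-1] > 0.5)).astype(np.int8)
    gmap = G.markers.copy()
    # 1 cM per 250 kb, the usual rice scale
    gmap["cM"] = gmap.groupby("chrom")["pos"].transform(lambda p: (p - p.min()) / 250_000)
    informative = pa != pb
    gmap = gmap[informative].reset_index(drop=True)
    cross = simulate.simulate_cross(pa[informative], pb[informative], qcfg.get("design", "RIL"),
                                    qcfg.get("n_lines", 150), gmap, seed=seed)
    codes = simulate.cross_to_qtl_codes(cross)
    # plant a QTL at the middle marker of the first chromosome
    qtl_j = len(gmap) // 4
    y = codes[:, qtl_j] * qcfg.get("effect", 0.5) + rng.normal(0, 1.0, codes.shape[0])
    cg = qtl.CrossGenotypes(codes, gmap, qcfg.get("design", "RIL"))
    return cg, y
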