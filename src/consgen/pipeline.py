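"""End-to-end analysis pipeline driven by a YAML config.

Stage order mirrors the analysis flow: QC -> diversity -> ROH ->
inbreeding -> LD/Ne -> ancestry -> kinship -> families.  Each stage
writes TSV (or Newick) outputs into the run directory and records itself
in a machine-readable manifest (stage name, parameters, input hashes,
output files), so reruns with unchanged inputs are byte-stable and
completed stages can be audited.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import ancestry, families, inbreeding, kinship, ldne, qc, roh
from .plinkio import (
    GenotypeMatrix,
    PedigreeTable,
    read_pedigree,
    read_plink_binary,
    read_plink_text,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "qc": {"sample_cr": 0.90, "snp_cr": 0.90, "maf_min": 0.01, "hwe_p_min": 1e-6},
    "roh": {},
    "ld": {"bin_edges_kb": list(ldne.DEFAULT_BIN_EDGES_KB), "mapping": "halfc"},
    "ancestry": {"K": 2, "seed": 0, "n_starts": 5, "r2_max": 0.5,
                 "prune_window": 50, "prune_step": 5, "reference_ids": []},
    "kinship": {"blend_w": 0.05},
    "families": {"threshold": 0.0625, "matrix": "G", "n_families": None},
    "l_auto_kb": roh.DEFAULT_L_AUTO_KB,
}


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_config(config_path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(config_path).read_text()) or {}
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _read_inputs(cfg: dict) -> tuple[GenotypeMatrix, PedigreeTable | None]:
    inputs = cfg.get("inputs", {})
    if "bed" in inputs:
        g = read_plink_binary(inputs["bed"], inputs["bim"], inputs["fam"])
    elif "ped" in inputs:
        g = read_plink_text(inputs["ped"], inputs["map"])
    else:
        raise ValueError("config inputs must name either bed/bim/fam or ped/map files")
    ped = read_pedigree(inputs["pedigree"]) if "pedigree" in inputs else None
    return g.sort_by_position(), ped


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> dict:
    """Run every stage; returns the manifest dict (also written as JSON)."""
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "inputs": {}}
    for key, path in cfg.get("inputs", {}).items():
        manifest["inputs"][key] = {"path": str(path), "sha256": _hash_file(Path(path))}

    g_raw, ped = _read_inputs(cfg)

    def record(stage: str, params: dict, outputs: list[str], t0: float) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "params": params,
                "outputs": outputs,
                "seconds": round(time.perf_counter() - t0, 3),
            }
        )
        _write_manifest(manifest, out)

    # --- QC ---------------------------------------------------------------
    t0 = time.perf_counter()
    g, report = qc.apply_qc(g_raw, **cfg["qc"])
    (out / "qc_report.tsv").write_text(report.to_tsv())
    record("qc", cfg["qc"], ["qc_report.tsv"], t0)

    # --- diversity ---------------------------------------------------------
    t0 = time.perf_counter()
    stats = qc.diversity_stats(g)
    (out / "diversity.tsv").write_text(stats.to_tsv())
    record("diversity", {}, ["diversity.tsv"], t0)

    # --- ROH ----------------------------------------------------------------
    t0 = time.perf_counter()
    params = roh.ROHParams(**cfg["roh"])
    segments = roh.detect_roh(g, params)
    roh.segments_to_frame(segments).to_csv(out / "roh_segments.tsv", sep="\t", index=False)
    summaries = roh.roh_summary(segments, g.n_samples, cfg["l_auto_kb"])
    _summaries_tsv(summaries, out / "roh_summary.tsv")
    roh.per_chromosome_summary(segments, g.variants, g.n_samples).to_csv(
        out / "roh_per_chromosome.tsv", sep="\t", index=False
    )
    record("roh", asdict(params), ["roh_segments.tsv", "roh_summary.tsv", "roh_per_chromosome.tsv"], t0)

    # --- inbreeding ---------------------------------------------------------
    t0 = time.perf_counter()
    table = inbreeding.inbreeding_table(g, segments, ped, cfg["l_auto_kb"])
    table.to_csv(out / "inbreeding.tsv", sep="\t", index_label="id")
    corr = inbreeding.correlate_inbreeding(table)
    corr.to_csv(out / "inbreeding_correlations.tsv", sep="\t", index_label="estimator")
    if ped is None:
        logger.warning("no pedigree supplied: F_PED and A-matrix stages skipped")
    record("inbreeding", {"pedigree": ped is not None}, ["inbreeding.tsv", "inbreeding_correlations.tsv"], t0)

    # --- LD / Ne -------------------------------------------------------------
    t0 = time.perf_counter()
    bins = ldne.bin_ld(g, tuple(cfg["ld"]["bin_edges_kb"]))
    traj = ldne.ne_trajectory(bins, cfg["ld"]["mapping"])
    lines = ["min_kb\tmax_kb\tn_pairs\tmean_r2\tgenerations_ago\tne"]
    for b, t in zip(bins, traj):
        lines.append(
            f"{b.min_kb:g}\t{b.max_kb:g}\t{b.n_pairs}\t{b.mean_r2:.6f}\t{t.generations_ago:g}\t{t.ne:.3f}"
        )
    (out / "ne_trajectory.tsv").write_text("\n".join(lines) + "\n")
    record("ne", cfg["ld"], ["ne_trajectory.tsv"], t0)

    # --- ancestry -------------------------------------------------------------
    t0 = time.perf_counter()
    acfg = cfg["ancestry"]
    pruned = ancestry.ld_prune(g, acfg["r2_max"], acfg["prune_window"], acfg["prune_step"])
    model = ancestry.admixture_fit(pruned, K=acfg["K"], seed=acfg["seed"], n_starts=acfg["n_starts"])
    np.savetxt(out / "ancestry_Q.tsv", model.Q, delimiter="\t", fmt="%.6f")
    np.savetxt(out / "ancestry_F.tsv", model.F, delimiter="\t", fmt="%.6f")
    ref_ids = acfg.get("reference_ids") or []
    outputs = ["ancestry_Q.tsv", "ancestry_F.tsv"]
    nucleus_ids = list(g.sample_ids)
    if ref_ids and acfg["K"] >= 2:
        props = ancestry.target_lineage_proportion(model, pruned.sample_ids, ref_ids)
        classes = ancestry.classify_lineage(props)
        classes.to_csv(out / "lineage_classification.tsv", sep="\t", index_label="id")
        nucleus_ids = list(classes.index[classes["nucleus"]])
        outputs.append("lineage_classification.tsv")
    record("ancestry", {k: v for k, v in acfg.items()}, outputs, t0)

    # --- kinship -------------------------------------------------------------
    t0 = time.perf_counter()
    gsub = g.subset(sample_idx=[g.sample_ids.index(s) for s in nucleus_ids])
    G = kinship.g_matrix(gsub)
    (out / "kinship_G.tsv").write_text(G.to_tsv())
    outputs = ["kinship_G.tsv"]
    matrices = {"G": G}
    if ped is not None:
        A_full = kinship.a_matrix(ped)
        A = A_full.restrict([i for i in nucleus_ids if i in A_full.ids])
        H = kinship.h_matrix(A_full, G, genotyped_ids=[s for s in G.ids if s in A_full.ids],
                             blend_w=cfg["kinship"]["blend_w"])
        (out / "kinship_A.tsv").write_text(A.to_tsv())
        (out / "kinship_H.tsv").write_text(H.to_tsv())
        matrices.update({"A": A, "H": H})
        outputs += ["kinship_A.tsv", "kinship_H.tsv"]
        corr_lines = ["pair\tr\tp"]
        for pair in (("A", "G"), ("A", "H"), ("G", "H")):
            m1 = matrices[pair[0]].restrict(G.ids) if pair[0] != "G" else matrices[pair[0]]
            m2 = matrices[pair[1]].restrict(G.ids) if pair[1] != "G" else matrices[pair[1]]
            try:
                r, p = kinship.matrix_correlation(m1, m2)
                corr_lines.append(f"{pair[0]}-{pair[1]}\t{r:.4f}\t{p:.3g}")
            except (ValueError, KeyError) as exc:
                corr_lines.append(f"{pair[0]}-{pair[1]}\tNA\tNA")
        (out / "kinship_correlations.tsv").write_text("\n".join(corr_lines) + "\n")
        outputs.append("kinship_correlations.tsv")
    record("kinship", cfg["kinship"], outputs, t0)

    # --- families -------------------------------------------------------------
    t0 = time.perf_counter()
    fcfg = cfg["families"]
    mat = matrices.get(fcfg["matrix"], G)
    D = kinship.genetic_distance(mat)
    boar_ids = [s.id for s in gsub.samples if s.sex == "male" and s.id in mat.ids]
    if len(boar_ids) < 2:
        boar_ids = list(mat.ids)  # no sex information: cluster everyone
    bidx = [mat.ids.index(b) for b in boar_ids]
    labels_b = families.cluster_boars(
        D[np.ix_(bidx, bidx)], boar_ids,
        threshold_r=fcfg["threshold"], n_families=fcfg["n_families"],
    )
    labels = families.assign_population(D, list(mat.ids), labels_b)
    families.family_table(labels, boar_ids).to_csv(out / "families.tsv", sep="\t", index=False)
    (out / "tree.nwk").write_text(families.export_tree(D, list(mat.ids)) + "\n")
    record("families", fcfg, ["families.tsv", "tree.nwk"], t0)

    return manifest


def _summaries_tsv(summaries, path: Path) -> None:
    lines = ["class\tn_segments\tpct\tmean_mb\tsd_mb\tcoverage_pct"]
    for s in summaries:
        lines.append(
            f"{s.class_label}\t{s.n_segments}\t{s.pct_of_segments:.2f}"
            f"\t{s.mean_length_mb:.2f}\t{s.sd_length_mb:.2f}\t{s.genome_coverage_pct:.2f}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
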