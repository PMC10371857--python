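"""End-to-end orchestration: simulate -> PBS scan -> loci -> genes -> variants.

A run is described by a key-value (YAML) config with three sections —
``simulate``, ``scan`` and ``variants`` — plus a mandatory top-level
``seed``.  The single seed fans out to per-stage child streams through a
fixed derivation, so every stage is individually reproducible and a rerun
with the same config produces byte-identical artifacts.  Each run leaves a
``manifest.json`` recording the config snapshot, the tool version, and a
SHA-256 digest of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differentiation import pbs_scan
from .io import write_features, write_results, write_sync
from .scan import (ScanConfig, associate_genes, consensus_loci, loci_to_frame,
                   selected_gene_set, triplet_combinations)
from .simulate import (SimConfig, Sweep, simulate_annotation, simulate_effect_scores,
                       simulate_frequency_landscape, simulate_pool_counts, write_truth)
from .variants import DeleteriousnessRule, af_contrast, screen_candidates

_AA = list("ACDEFGHIKLMNPQRSTVWY")


class PipelineConfigError(ValueError):
    """Config schema violation; ``key`` names the offending entry."""

    def __init__(self, key: str, message: str):
        super().__init__(f"config key {key!r}: {message}")
        self.key = key


def _require(section: dict, key: str, where: str):
    if key not in section:
        raise PipelineConfigError(f"{where}.{key}" if where else key, "missing")
    return section[key]


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineConfigError("<root>", "config must be a mapping")
    return cfg


def _build_sim_config(cfg: dict, seed: int) -> tuple[SimConfig, dict]:
    sim = _require(cfg, "simulate", "")
    genome_spec = _require(sim, "genome", "simulate")
    if isinstance(genome_spec, dict):
        genome = [(str(c), int(l)) for c, l in genome_spec.items()]
    else:
        genome = [(str(c), int(l)) for c, l in genome_spec]
    sweeps = [
        Sweep(str(s["chrom"]), int(s["start"]), int(s["end"]), float(s["sweep_f"]))
        for s in sim.get("sweeps", [])
    ]
    sim_cfg = SimConfig(
        pop_names=_require(sim, "pop_names", "simulate"),
        focal_pop=_require(sim, "focal", "simulate"),
        genome=genome,
        n_snps=int(_require(sim, "n_snps", "simulate")),
        baseline_F=float(_require(sim, "baseline_f", "simulate")),
        sweeps=sweeps,
        pool_diploids=int(sim.get("pool_diploids", 8)),
        depth_mean=float(sim.get("depth_mean", 20.0)),
        depth_shape=float(sim.get("depth_shape", 5.0)),
        seed=seed,
    )
    return sim_cfg, sim


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_scan_pipeline(config, out_dir, verbose: bool = False) -> dict:
    """Execute the full synthetic scan pipeline described by ``config``.

    Returns the manifest dictionary; all artifacts (sync table, annotation,
    truth table, per-triplet PBS tracks, loci, selected genes, candidate
    variants, manifest) are written under ``out_dir``.
    """
    t_start = time.time()
    cfg = load_config(config)
    if "seed" not in cfg:
        raise PipelineConfigError("seed", "missing")
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def log(msg):
        if verbose:
            print(f"[poolscan] {msg}", file=sys.stderr)

    # stage seeds derived once from the master seed
    children = np.random.SeedSequence(seed).spawn(4)
    stage_seed = [int(c.generate_state(1, np.uint32)[0]) % (2 ** 31)
                  for c in children]

    # ---- simulate -----------------------------------------------------
    sim_cfg, sim_section = _build_sim_config(cfg, stage_seed[0])
    panel = simulate_frequency_landscape(sim_cfg)
    table = simulate_pool_counts(panel, sim_cfg)
    genes = simulate_annotation(
        sim_cfg,
        n_genes=int(sim_section.get("n_genes", 50)),
        gene_len=int(sim_section.get("gene_len", 2000)),
        seed=stage_seed[1],
    )
    write_sync(table, out / "sync.tsv")
    write_features(genes, out / "genes.bed", fmt="bed")
    write_truth(panel, out / "truth.tsv")
    log(f"simulated {table.n_sites} sites, {len(genes)} genes")

    # ---- scan ---------------------------------------------------------
    scan_sec = cfg.get("scan", {})
    window = int(scan_sec.get("window", 5000))
    step = int(scan_sec.get("step", 4000))
    min_cov = int(scan_sec.get("min_cov", 4))
    max_cov = int(scan_sec.get("max_cov", 16))
    min_sites = int(scan_sec.get("min_sites", 1))
    min_minor = int(scan_sec.get("min_minor_count", 2))
    top_fraction = float(scan_sec.get("top_fraction", 0.001))
    min_support = int(scan_sec.get("min_support", 2))
    flank_bp = int(scan_sec.get("flank_bp", 50_000))

    others = [p for p in sim_cfg.pop_names if p != sim_cfg.focal_pop]
    triplets = triplet_combinations(sim_cfg.focal_pop, others)
    log(f"scanning {len(triplets)} triplets, window {window}, step {step}, "
        f"coverage [{min_cov}, {max_cov}], top {top_fraction:g}")
    tracks = []
    for trip in triplets:
        track = pbs_scan(table, trip, sim_cfg.genome, window=window, step=step,
                         min_cov=min_cov, max_cov=max_cov,
                         min_minor_count=min_minor, min_sites=min_sites)
        tracks.append(track)
        write_results(track, out / ("pbs_" + "-".join(trip) + ".tsv"))

    scan_cfg = ScanConfig(triplets=triplets, top_fraction=top_fraction,
                          min_support=min_support, flank_bp=flank_bp)
    loci = consensus_loci(tracks, scan_cfg)
    loci = associate_genes(loci, genes, flank_bp=flank_bp)
    write_results(loci_to_frame(loci), out / "loci.tsv")
    gene_set = sorted(selected_gene_set(loci))
    pd.DataFrame({"gene_id": gene_set}).to_csv(out / "selected_genes.tsv",
                                               sep="\t", index=False)
    log(f"{len(loci)} loci, {len(gene_set)} associated genes")

    # ---- variants -----------------------------------------------------
    var_sec = cfg.get("variants", {})
    daf_floor = float(var_sec.get("daf_floor", 0.5))
    alpha = float(var_sec.get("alpha", 0.05))
    rule = DeleteriousnessRule(
        provean_cutoff=float(var_sec.get("provean_cutoff", -2.5)),
        sift_cutoff=float(var_sec.get("sift_cutoff", 0.05)),
    )
    variant_list = _variants_in_loci(table, loci, genes, seed=stage_seed[2])
    if len(variant_list):
        contrasts = af_contrast(table, variant_list, sim_cfg.focal_pop, others)
        effects_path = var_sec.get("effects")
        if effects_path:
            effects = pd.read_csv(effects_path, sep="\t")
        else:
            effects = simulate_effect_scores(variant_list, seed=stage_seed[3])
        candidates = screen_candidates(contrasts, loci, effects, rule=rule,
                                       daf_floor=daf_floor, alpha=alpha)
    else:
        candidates = pd.DataFrame(
            columns=["chrom", "pos", "gene_id", "position", "ref_aa", "alt_aa",
                     "af_focal", "d_af", "p_value", "p_adjusted",
                     "provean", "sift", "deleterious"])
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False, na_rep="NA")
    log(f"{len(candidates)} candidate substitutions")

    # ---- manifest -----------------------------------------------------
    artifacts = {}
    for path in sorted(out.glob("*.tsv")):
        artifacts[path.name] = {"sha256": _sha256(path),
                                "n_bytes": path.stat().st_size}
    manifest = {
        "tool": "poolscan",
        "version": __version__,
        "seed": seed,
        "stage_seeds": stage_seed,
        "config": cfg,
        "artifacts": artifacts,
        "runtime_s": round(time.time() - t_start, 2),
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _variants_in_loci(table, loci, genes, seed: int) -> pd.DataFrame:
    """Candidate non-synonymous variants: genic SNP sites inside loci.

    Substitution annotations (residue index, amino acids) are synthesised
    deterministically — real data would carry them from a variant annotator.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for locus in loci:
        in_locus = (table.chroms == locus.chrom) & \
                   (table.pos >= locus.start) & (table.pos < locus.end)
        for i in np.flatnonzero(in_locus):
            pos = int(table.pos[i])
            gene = next((g for g in genes
                         if g.chrom == locus.chrom and g.start <= pos < g.end), None)
            if gene is None:
                continue
            ref_aa, alt_aa = rng.choice(_AA, size=2, replace=False)
            rows.append({
                "chrom": locus.chrom,
                "pos": pos + 1,
                "gene_id": gene.gene_id,
                "position": (pos - gene.start) // 3 + 1,
                "ref_aa": ref_aa,
                "alt_aa": alt_aa,
            })
    return pd.DataFrame(rows)
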