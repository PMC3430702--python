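"""End-to-end orchestration: simulate (optional) -> segment -> estimate ->
call -> frequency -> recurrent regions -> gene summaries -> cross-species
projection -> similarity -> clustering, with a reproducibility manifest.

Configuration is a YAML mapping with sections mirroring each stage's
parameters; every run is fully determined by the config plus one seed, and a
rerun writes byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from ._util import child_rng
from .aberration import (ABERRANT_CLASSES, CallerConfig,
                         call_probes, frequency_track, genes_in_calls,
                         most_overlapping_section, write_calls, write_frequency)
from .cn_estimation import assign_copy_numbers, fit_tumor_model, write_cn_profile
from .cohort_stats import hierarchical_cluster
from .crossspecies import (SyntenyBlock, project_profile, read_synteny_blocks,
                           read_target_grid, similarity_matrix,
                           write_synteny_blocks, write_target_grid)
from .io import GeneModel, read_genes_bed, read_ratio_profile, write_genes_bed, \
    write_ratio_profile
from .segmentation import SegmentationConfig, segment_profile, write_segments
from .synthetic import (AberrationSpec, GenomeLayout, NoiseModel, make_genome,
                        render_ratios, simulate_truth, write_truth)

log = logging.getLogger("cnapipe")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError(f"config: {path} is not a YAML mapping")
    return cfg


def _simulate_cohort(cfg: dict, seed: int, outdir: Path):
    sim = cfg["simulate"]
    layout = make_genome(
        n_chromosomes=int(sim.get("n_chromosomes", 20)),
        chrom_length=int(sim.get("chrom_length", 50_000_000)),
        probes_per_chromosome=int(sim.get("probes_per_chromosome", 500)),
        probe_length=int(sim.get("probe_length", 60)),
        seed=seed,
    )
    archetypes = {}
    for k, (name, arch) in enumerate(sorted(sim["archetypes"].items())):
        spec = AberrationSpec(**arch.get("aberrations", {}))
        archetypes[name] = simulate_truth(
            layout, spec, purity=float(arch["purity"]),
            target_ploidy=float(arch.get("target_ploidy", 2.0)),
            seed=int(child_rng(seed, 11, k).integers(2**31)),
        )
    sd = float(sim.get("noise_sd", 0.15))
    profiles, groups = [], {}
    for si, entry in enumerate(sim["samples"]):
        sid, arch = str(entry["id"]), str(entry["archetype"])
        truth = archetypes[arch]
        noise = NoiseModel(sd=sd, seed=int(child_rng(seed, 13, si).integers(2**31)))
        prof = render_ratios(truth, layout, noise, sample_id=sid)
        write_ratio_profile(prof, outdir / f"ratios_{sid}.tsv")
        write_truth(truth, outdir / f"truth_{arch}.tsv")
        profiles.append(prof)
        groups[sid] = arch
    genes = _toy_genes(layout, seed, int(sim.get("genes_per_chromosome", 2)))
    write_genes_bed(genes, outdir / "genes.bed")
    blocks = _toy_synteny(layout)
    write_synteny_blocks(blocks, outdir / "synteny.tsv")
    grid = _toy_target_grid(layout, int(sim.get("target_positions_per_chromosome", 150)))
    write_target_grid(grid, outdir / "target_grid.tsv")
    return profiles, groups, genes, blocks, grid


def _toy_genes(layout: GenomeLayout, seed: int, per_chrom: int):
    genes = []
    for k, name in enumerate(layout.chrom_names):
        rng = child_rng(seed, 17, k)
        length = layout.length_of(name)
        for g in range(per_chrom):
            start = int(rng.integers(0, length - 500_000))
            genes.append(GeneModel(f"gene_{name}_{g}", name, start, start + 400_000,
                                   "+" if rng.integers(2) else "-"))
    return genes


def _toy_synteny(layout: GenomeLayout):
    """Map each simulated chromosome onto a same-sized 'h' chromosome, first
    half forward and second half reversed, to exercise both orientations."""
    blocks = []
    for name, length in layout.chromosomes:
        tgt = "h" + name.removeprefix("chr")
        half = length // 2
        blocks.append(SyntenyBlock(name, 0, half, tgt, 0, half, "forward"))
        blocks.append(SyntenyBlock(name, half, length, tgt, half, length, "reverse"))
    return blocks


def _toy_target_grid(layout: GenomeLayout, per_chrom: int) -> pd.DataFrame:
    rows = []
    for name, length in layout.chromosomes:
        tgt = "h" + name.removeprefix("chr")
        step = length // per_chrom
        rows.extend({"chromosome": tgt, "position": int(i * step + step // 2)}
                    for i in range(per_chrom))
    return pd.DataFrame(rows)


def _load_inputs(cfg: dict, outdir: Path):
    inp = cfg["inputs"]
    profiles = [read_ratio_profile(p) for p in inp["ratio_files"]]
    groups = {str(k): str(v) for k, v in inp.get("groups", {}).items()}
    genes = read_genes_bed(inp["genes_bed"]) if inp.get("genes_bed") else []
    blocks = read_synteny_blocks(inp["synteny"]) if inp.get("synteny") else None
    grid = read_target_grid(inp["target_grid"]) if inp.get("target_grid") else None
    return profiles, groups, genes, blocks, grid


def run_pipeline(cfg: dict, outdir, seed: Optional[int] = None) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure raises PipelineError naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    if "simulate" in cfg:
        profiles, groups, genes, blocks, grid = stage(
            "simulate", _simulate_cohort, cfg, seed, outdir)
    elif "inputs" in cfg:
        profiles, groups, genes, blocks, grid = stage(
            "inputs", _load_inputs, cfg, outdir)
    else:
        raise PipelineError("config must contain a 'simulate' or 'inputs' section")

    seg_cfg = SegmentationConfig(seed=seed, **cfg.get("segmentation", {}))
    caller = CallerConfig(**{k: v for k, v in cfg.get("calling", {}).items()})
    est = cfg.get("estimation", {})

    calls, cns = [], []
    for prof in profiles:
        seg = stage(f"segment:{prof.sample_id}", segment_profile, prof, seg_cfg)
        write_segments(seg, outdir / f"segments_{prof.sample_id}.tsv")
        model = stage(f"estimate:{prof.sample_id}", fit_tumor_model, seg,
                      c_max=int(est.get("c_max", 12)))
        cn = assign_copy_numbers(
            seg, model, prof.data[["chromosome", "start", "end", "probe_id"]])
        write_cn_profile(cn, outdir / f"cn_{prof.sample_id}.tsv")
        cns.append(cn)
        call = stage(f"call:{prof.sample_id}", call_probes, cn, caller)
        write_calls(call, outdir / f"calls_{prof.sample_id}.tsv")
        calls.append(call)

    freq = stage("frequency", frequency_track, calls)
    write_frequency(freq, outdir / "frequency.tsv")

    recurrent_rows = []
    wanted = cfg.get("recurrent", {}).get("classes", list(ABERRANT_CLASSES))
    chroms = list(dict.fromkeys(calls[0].probes["chromosome"]))
    for cls in wanted:
        for chrom in chroms:
            try:
                reg = most_overlapping_section(calls, chrom, cls)
            except ValueError:
                continue
            recurrent_rows.append({"chromosome": reg.chromosome, "start": reg.start,
                                   "end": reg.end, "support": reg.support,
                                   "class": reg.cls})
    pd.DataFrame(recurrent_rows,
                 columns=["chromosome", "start", "end", "support", "class"]
                 ).to_csv(outdir / "recurrent.tsv", sep="\t", index=False)

    if genes:
        gene_cfg = cfg.get("genes", {})
        rows = []
        for cls in ("homozygous_deletion", "amplification"):
            for gid, n in stage("genes", genes_in_calls, calls, genes, cls,
                                int(gene_cfg.get("min_samples", 2))):
                rows.append({"gene_id": gid, "class": cls, "n_samples": n})
        pd.DataFrame(rows, columns=["gene_id", "class", "n_samples"]
                     ).to_csv(outdir / "genes.tsv", sep="\t", index=False)

    if blocks is not None and grid is not None:
        min_overlap = int(cfg.get("similarity", {}).get("min_overlap", 10))
        projected = [stage(f"project:{cn.sample_id}", project_profile, cn, blocks,
                           grid, groups.get(cn.sample_id, "")) for cn in cns]
        matrix, summary = stage("similarity", similarity_matrix, projected,
                                min_overlap=min_overlap)
        matrix.to_csv(outdir / "similarity_matrix.tsv", sep="\t",
                      index_label="sample")
        summary.to_csv(outdir / "similarity_groups.tsv", sep="\t", index=False)
    elif cfg.get("similarity"):
        raise PipelineError("stage 'similarity' failed: synteny blocks or target "
                            "grid missing from config")

    dendro = stage("cluster", hierarchical_cluster, cns)
    (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n",
                                           encoding="utf-8")

    _write_manifest(cfg, seed, outdir)
    return outdir


def _write_manifest(cfg: dict, seed: int, outdir: Path) -> None:
    artifacts = {}
    for p in sorted(outdir.glob("*")):
        if p.name == "manifest.json" or p.is_dir():
            continue
        artifacts[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "package": "cnapipe",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "artifacts": artifacts,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
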