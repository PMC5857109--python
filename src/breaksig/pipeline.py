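"""End-to-end orchestration: read -> filter -> subtract -> signature ->
breakpoint association -> kataegis, with a JSON summary and run manifest.

Every stage is a pure function of (inputs, parameters, seed); re-running a
configuration reproduces its outputs byte for byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .variant_io import read_vcf, read_genome, read_breakpoints, write_vcf, SNS
from .filtering import (FilterThresholds, apply_filters, derive_case_specific,
                        sns_load, FilterTally)
from .signature import (count_contexts, genome_triplets, correct_profile,
                        cosine_rank, read_catalog, write_catalog,
                        write_similarity, SignatureCatalog)
from .breakpoint_assoc import (build_windows, enrichment, per_breakpoint_counts,
                               detect_kataegis, rainfall_table,
                               write_enrichment, write_kataegis,
                               DEFAULT_WINDOW, DEFAULT_IMD_MAX,
                               DEFAULT_MIN_CLUSTER)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    off_vcf: str
    esc_vcf: str
    genome_fasta: str
    breakpoints_bed: str
    outdir: str
    catalog_tsv: str | None = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    mean_coverage: float | None = None
    window: int = DEFAULT_WINDOW
    imd_max: int = DEFAULT_IMD_MAX
    min_cluster_size: int = DEFAULT_MIN_CLUSTER
    n_perm: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for name in ("off_vcf", "esc_vcf", "genome_fasta", "breakpoints_bed"):
            p = getattr(self, name)
            if not os.path.exists(p):
                raise FileNotFoundError(f"{name}: {p}")
        if self.catalog_tsv is not None and not os.path.exists(self.catalog_tsv):
            raise FileNotFoundError(f"catalog_tsv: {self.catalog_tsv}")


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_all(cfg: RunConfig, catalog: SignatureCatalog | None = None) -> dict:
    """Execute the full analysis and write all reports under cfg.outdir.

    Returns the summary dict (also written as summary.json).
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if catalog is None:
        if cfg.catalog_tsv is not None:
            catalog = _stage("read_catalog")(read_catalog)(cfg.catalog_tsv)
        else:
            from .simulate import default_catalog
            catalog = default_catalog()

    g = _stage("read_genome")(read_genome)(cfg.genome_fasta)
    bps, n_dup_bp = _stage("read_breakpoints")(read_breakpoints)(cfg.breakpoints_bed)
    off = _stage("read_vcf")(read_vcf)(cfg.off_vcf, "off", "OFF",
                                       mean_coverage=cfg.mean_coverage)
    esc = _stage("read_vcf")(read_vcf)(cfg.esc_vcf, "esc", "ESC",
                                       mean_coverage=cfg.mean_coverage)
    off.parse_report.to_tsv(outdir / "off.parse_report.tsv")
    esc.parse_report.to_tsv(outdir / "esc.parse_report.tsv")

    # MQ-filter both sets, subtract, then AF+depth filter the remainder
    esc_specific, stages = _stage("derive_case_specific")(derive_case_specific)(
        esc, off, cfg.thresholds)
    for stage_name, tally in stages.items():
        if isinstance(tally, FilterTally):
            tally.to_tsv(outdir / f"filter.{stage_name}.tsv")
    write_vcf(esc_specific, outdir / "esc_specific.vcf",
              contig_lengths={c: len(s) for c, s in g.sequences.items()})

    loads = {}
    if cfg.mean_coverage:
        esc_full, _ = apply_filters(esc, cfg.thresholds)
        off_full, _ = apply_filters(off, cfg.thresholds)
        for label, cs in (("esc_filtered_total", esc_full),
                          ("off_filtered_total", off_full),
                          ("esc_specific", esc_specific)):
            load, count = sns_load(cs)
            loads[label] = {"sns_load": load, "sns_count": count}

    prof = _stage("count_contexts")(count_contexts)(
        esc_specific.by_class(SNS), g)
    tri = _stage("genome_triplets")(genome_triplets)(g)
    prof = _stage("correct_profile")(correct_profile)(prof, tri)
    prof.to_tsv(outdir / "signature.tsv")
    ranks = _stage("cosine_rank")(cosine_rank)(prof, catalog)
    write_similarity(ranks, outdir / "similarity.tsv")
    write_catalog(catalog, outdir / "catalog_used.tsv")

    ws = _stage("build_windows")(build_windows)(bps, g, cfg.window)
    enr = _stage("enrichment")(enrichment)(esc_specific, ws,
                                           n_perm=cfg.n_perm, seed=cfg.seed)
    write_enrichment(enr, outdir / "enrichment.tsv")
    pbc = _stage("per_breakpoint_counts")(per_breakpoint_counts)(
        esc_specific, bps, cfg.window)
    pbc.to_csv(outdir / "per_breakpoint.tsv", sep="\t", index=False)
    clusters = _stage("detect_kataegis")(detect_kataegis)(
        esc_specific, imd_max=cfg.imd_max,
        min_cluster_size=cfg.min_cluster_size, breakpoints=bps)
    write_kataegis(clusters, outdir / "kataegis.tsv")
    rainfall_table(esc_specific).to_csv(outdir / "rainfall.tsv", sep="\t",
                                        index=False)

    summary = {
        "seed": cfg.seed,
        "inputs": {k: getattr(cfg, k) for k in
                   ("off_vcf", "esc_vcf", "genome_fasta", "breakpoints_bed",
                    "catalog_tsv")},
        "parameters": {
            "thresholds": asdict(cfg.thresholds),
            "mean_coverage": cfg.mean_coverage,
            "window": cfg.window, "imd_max": cfg.imd_max,
            "min_cluster_size": cfg.min_cluster_size, "n_perm": cfg.n_perm,
        },
        "counts": {
            "off_kept": len(off), "esc_kept": len(esc),
            "esc_specific": len(esc_specific),
            "esc_specific_sns": len(esc_specific.by_class(SNS)),
            "shared": stages["n_shared"],
            "breakpoints": len(bps), "breakpoint_duplicates": n_dup_bp,
        },
        "sns_load": loads,
        "signature": {
            "n_mutations": prof.n_mutations,
            "n_excluded": prof.n_excluded,
            "raw": [int(x) for x in prof.raw_counts],
            "corrected": ([float(x) for x in prof.corrected]
                          if prof.corrected is not None else None),
            "cosine_ranks": [[name, round(sim, 10)] for name, sim in ranks],
        },
        "enrichment": {cls: {
            "n_near": r.n_near, "n_far": r.n_far,
            "density_near": round(r.density_near, 6),
            "density_far": round(r.density_far, 6),
            "ratio": (round(r.ratio, 6) if r.ratio == r.ratio
                      and r.ratio != float("inf") else str(r.ratio)),
            "perm_p": round(r.perm_p, 8) if r.perm_p == r.perm_p else "nan",
        } for cls, r in enr.items()},
        "per_breakpoint_histogram": {
            cls: {str(k): int(v) for k, v in
                  pbc[cls].value_counts().sort_index().items()}
            for cls in ("SNS", "INS", "DEL")
        },
        "kataegis": {
            "n_clusters": len(clusters),
            "clusters": [vars(c) for c in clusters],
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2)
    manifest = {
        "tool": "breaksig", "version": __version__, "seed": cfg.seed,
        "config": {**{k: getattr(cfg, k) for k in
                      ("off_vcf", "esc_vcf", "genome_fasta", "breakpoints_bed",
                       "catalog_tsv", "outdir", "mean_coverage", "window",
                       "imd_max", "min_cluster_size", "n_perm")},
                   "thresholds": asdict(cfg.thresholds)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    return summary
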