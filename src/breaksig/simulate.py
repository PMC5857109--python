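"""Synthetic paired call sets with known ground truth.

Generates, from a single seed, a desk-scale reference genome, breakpoint
list, and paired OFF/ESC VCFs in which:

* shared (germline-like) variants appear in both call sets with one
  germline genotype but per-file MQ/DP noise;
* case-specific substitutions are drawn from an implanted 96-channel
  signature mixture, placed context-conditionally (channel sampled
  proportional to profile x genome triplet availability, then a matching
  triplet site chosen uniformly) so the triplet-corrected recovered profile
  converges to the implanted mixture;
* kataegis-like clusters of strand-coordinated C>T/C>G mutations are
  planted near a subset of breakpoints;
* MQ, DP and GT noise exercises every downstream filter.

All ground-truth labels (variant origin, generating channel, cluster
membership, implanted profile) are written to a truth JSON for recovery
scoring.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .variant_io import (Breakpoint, Callset, GenomeRef, VariantCall,
                         SNS, INS, DEL, write_breakpoints, write_genome,
                         write_vcf)
from .signature import (CHANNELS, CHANNEL_TRIPLET, SUBSTITUTIONS, TRIPLETS,
                        COMPLEMENT, SignatureCatalog, _BYTE_CODE, _COLLAPSE,
                        channel_index, genome_triplets)
from .breakpoint_assoc import WindowSet

_BASE_BYTES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_BASES = "ACGT"


class SimError(ValueError):
    pass


@dataclass(frozen=True)
class KataegisSim:
    """Planted hypermutation clusters near breakpoints."""

    n_clusters: int = 10
    cluster_size: int = 8
    cluster_span_bp: int = 2_000
    max_distance_to_breakpoint: int = 50_000


@dataclass(frozen=True)
class NoiseModel:
    """Per-record annotation noise.

    DP is negative-binomial around ``depth_mean`` with dispersion
    ``depth_overdispersion`` (larger = closer to Poisson); a
    ``fraction_below_mq`` share of records gets MQ < 30.
    """

    fraction_below_mq: float = 0.05
    fraction_het: float = 0.6
    depth_mean: float = 30.0
    depth_overdispersion: float = 10.0


@dataclass
class SimConfig:
    genome_length: int = 5_000_000
    n_chromosomes: int = 2
    gc_content: float = 0.41
    n_breakpoints: int = 20
    n_shared_mutations: int = 20_000
    n_case_specific: int = 10_000
    n_shared_indels: int = 2_000
    n_case_specific_indels: int = 1_000
    signature_mixture: dict[str, float] = field(
        default_factory=lambda: {"APOBEC": 0.55, "FLAT": 0.30, "CPG": 0.15})
    kataegis: KataegisSim = field(default_factory=KataegisSim)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise SimError("SimConfig.seed is mandatory")
        if abs(sum(self.signature_mixture.values()) - 1.0) > 1e-9:
            raise SimError("signature mixture weights must sum to 1")
        for name in ("genome_length", "n_breakpoints", "n_shared_mutations",
                     "n_case_specific", "n_shared_indels",
                     "n_case_specific_indels"):
            if getattr(self, name) < 0:
                raise SimError(f"{name} must be >= 0")


def default_catalog() -> SignatureCatalog:
    """A small deterministic reference catalog of distinct process-like
    signatures:

    * ``APOBEC`` — C>T/C>G concentrated at TpC (T[C>T/G]A and T[C>T/G]T);
    * ``CPG`` — C>T at NpCpG (spontaneous deamination of methyl-C);
    * ``FLAT`` — uniform over all 96 channels (broad, HR-deficiency-like);
    * ``TC`` — T>C biased toward ApT contexts.
    """
    def spiky(spikes: list[tuple[str, str, str]], spike_mass: float) -> np.ndarray:
        v = np.full(96, (1.0 - spike_mass) / (96 - len(spikes)))
        for sub, f, t in spikes:
            v[channel_index(sub, f, t)] = spike_mass / len(spikes)
        return v

    apobec = spiky([("C>T", "T", "A"), ("C>T", "T", "T"),
                    ("C>G", "T", "A"), ("C>G", "T", "T")], 0.80)
    cpg = spiky([("C>T", f, "G") for f in _BASES], 0.90)
    flat = np.full(96, 1.0 / 96)
    tc = spiky([("T>C", "A", t) for t in _BASES], 0.80)
    return SignatureCatalog(names=["APOBEC", "CPG", "FLAT", "TC"],
                            profiles=np.column_stack([apobec, cpg, flat, tc]))


def mixture_profile(mixture: dict[str, float],
                    cat: SignatureCatalog | None = None) -> np.ndarray:
    """The implanted post-mixture 96-profile: sum of weighted catalog
    signatures."""
    cat = cat or default_catalog()
    p = np.zeros(96)
    for name, w in mixture.items():
        p += w * cat[name]
    return p / p.sum()


# ---------------------------------------------------------------------------
# genome construction helpers (also used directly by tests)
# ---------------------------------------------------------------------------

def random_genome(length: int = 5_000_000, n_chromosomes: int = 2,
                  gc_content: float = 0.41, rng: np.random.Generator | None = None,
                  n_run_length: int = 5_000, n_runs_per_chrom: int = 2) -> GenomeRef:
    """I.i.d. genome at the given GC content with a few N runs per
    chromosome to exercise effective-size accounting."""
    rng = rng if rng is not None else np.random.default_rng(0)
    at, gc = (1.0 - gc_content) / 2, gc_content / 2
    probs = np.array([at, gc, gc, at])
    per = length // n_chromosomes
    seqs: dict[str, str] = {}
    for i in range(n_chromosomes):
        n = per if i < n_chromosomes - 1 else length - per * (n_chromosomes - 1)
        codes = rng.choice(4, size=n, p=probs).astype(np.uint8)
        for _ in range(n_runs_per_chrom):
            if n > 3 * n_run_length:
                s = int(rng.integers(n_run_length, n - 2 * n_run_length))
                codes[s:s + n_run_length] = 4
        seqs[f"chr{i + 1}"] = _BASE_BYTES[codes].tobytes().decode()
    return GenomeRef.from_sequences(seqs)


def _codes(g: GenomeRef) -> dict[str, np.ndarray]:
    return {c: _BYTE_CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
            for c, s in g.sequences.items()}


def random_breakpoints(g: GenomeRef, n: int, rng: np.random.Generator,
                       margin: int = 60_000) -> list[Breakpoint]:
    """Uniform breakpoints over non-N positions, kept ``margin`` bp from
    chromosome ends so +-50 kb windows stay informative."""
    codes = _codes(g)
    chroms = list(g.sequences)
    eligible = {}
    for c in chroms:
        m = margin if len(codes[c]) > 3 * margin else 0
        pool = np.flatnonzero(codes[c][m:len(codes[c]) - m] < 4) + m
        eligible[c] = pool
    weights = np.array([len(eligible[c]) for c in chroms], dtype=float)
    if weights.sum() == 0:
        raise SimError("no eligible breakpoint positions in genome")
    weights /= weights.sum()
    bps = set()
    while len(bps) < n:
        c = chroms[rng.choice(len(chroms), p=weights)]
        pos = int(eligible[c][rng.integers(len(eligible[c]))])
        bps.add(Breakpoint(chrom=c, pos=pos))
    return sorted(bps, key=lambda b: (b.chrom, b.pos))


def place_enriched_snvs(g: GenomeRef, ws: WindowSet, n: int, ratio: float,
                        rng: np.random.Generator, sample_id: str = "sim",
                        condition: str = "ESC") -> Callset:
    """Place ``n`` substitutions so that the expected mutation density
    inside the window set is ``ratio`` times the outside density.  Used to
    construct enrichment fixtures with a known truth ratio."""
    codes = _codes(g)
    inside: list[tuple[str, np.ndarray]] = []
    outside: list[tuple[str, np.ndarray]] = []
    for chrom, seq_codes in codes.items():
        mask = seq_codes < 4
        iv = ws.windows.get(chrom)
        win_mask = np.zeros(len(seq_codes), dtype=bool)
        if iv is not None:
            for s, e in iv:
                win_mask[s:e] = True
        inside.append((chrom, np.flatnonzero(mask & win_mask)))
        outside.append((chrom, np.flatnonzero(mask & ~win_mask)))
    w_bp = sum(len(p) for _, p in inside)
    o_bp = sum(len(p) for _, p in outside)
    p_in = ratio * w_bp / (ratio * w_bp + o_bp)
    n_in = int(rng.binomial(n, p_in))
    variants = []
    used = set()
    for pool, count in ((inside, n_in), (outside, n - n_in)):
        sizes = np.array([len(p) for _, p in pool], dtype=float)
        sizes /= sizes.sum()
        placed = 0
        while placed < count:
            ci = int(rng.choice(len(pool), p=sizes))
            chrom, positions = pool[ci]
            pos = int(positions[rng.integers(len(positions))])
            if (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            ref = _BASES[codes[chrom][pos]]
            alt = _BASES[int(rng.choice([b for b in range(4) if _BASES[b] != ref]))]
            variants.append(VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                        vclass=SNS, mq=60.0, dp=30, gt="1/1",
                                        af=1.0))
            placed += 1
    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return Callset(sample_id=sample_id, condition=condition, variants=variants,
                   mean_coverage=30.0)


# ---------------------------------------------------------------------------
# the generator proper
# ---------------------------------------------------------------------------

def _triplet_sites(codes: dict[str, np.ndarray]) -> dict[int, list[tuple[str, np.ndarray]]]:
    """Positions (per chromosome) of every pyrimidine-collapsed triplet."""
    sites: dict[int, list[tuple[str, np.ndarray]]] = {i: [] for i in range(32)}
    for chrom, c in codes.items():
        if len(c) < 3:
            continue
        a, b, d = c[:-2], c[1:-1], c[2:]
        valid = (a < 4) & (b < 4) & (d < 4)
        word = 16 * a.astype(np.intp) + 4 * b + d
        tri = np.where(valid, _COLLAPSE[np.where(valid, word, 0)], -1)
        for t in range(32):
            pos = np.flatnonzero(tri == t) + 1  # center coordinate
            if len(pos):
                sites[t].append((chrom, pos))
    return sites


def _sample_noise(rng: np.random.Generator, n: int, noise: NoiseModel
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-record (MQ, DP) draws."""
    low = rng.random(n) < noise.fraction_below_mq
    mq = np.where(low,
                  rng.uniform(10.0, 29.9, n),
                  rng.uniform(30.0, 60.0, n)).round(1)
    k = noise.depth_overdispersion
    dp = rng.negative_binomial(k, k / (k + noise.depth_mean), n)
    return mq, dp


@dataclass
class _PlannedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    gt: str
    origin: str          # shared | case | kataegis | shared_indel | case_indel
    channel: int = -1
    cluster: int = -1

    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def _pick_unused(rng, pool: np.ndarray, k: int, chrom: str, used: set):
    out = []
    attempts = 0
    while len(out) < k:
        attempts += 1
        if attempts > 50 * max(k, 1) + 1000:
            raise SimError("cannot place requested mutations: pool exhausted")
        pos = int(pool[rng.integers(len(pool))])
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        out.append(pos)
    return out


def generate(cfg: SimConfig, outdir: str | os.PathLike,
             catalog: SignatureCatalog | None = None) -> dict:
    """Write genome FASTA, breakpoints BED, OFF/ESC VCFs and a truth JSON.

    Deterministic: the same config and seed give byte-identical files.
    Returns the run manifest (paths, seed, parameters, truth path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    cat = catalog or default_catalog()
    for name in cfg.signature_mixture:
        if name not in cat.names:
            raise SimError(f"mixture component {name!r} not in catalog")

    g = random_genome(cfg.genome_length, cfg.n_chromosomes, cfg.gc_content, rng)
    codes = _codes(g)
    chrom_lengths = {c: len(s) for c, s in g.sequences.items()}
    bps = random_breakpoints(g, cfg.n_breakpoints, rng)

    used: set[tuple[str, int]] = set()
    planned: list[_PlannedVariant] = []

    # uniform eligible positions, away from contig edges so contexts exist
    eligible = {c: np.flatnonzero(codes[c][1:-1] < 4) + 1 for c in codes}
    chroms = list(codes)
    chrom_w = np.array([len(eligible[c]) for c in chroms], dtype=float)
    chrom_w /= chrom_w.sum()

    def uniform_sites(k: int) -> list[tuple[str, int]]:
        out = []
        counts = rng.multinomial(k, chrom_w)
        for c, kk in zip(chroms, counts):
            for pos in _pick_unused(rng, eligible[c], int(kk), c, used):
                out.append((c, pos))
        return out

    def draw_gt() -> str:
        return "0/1" if rng.random() < cfg.noise.fraction_het else "1/1"

    # (b) shared background substitutions
    for chrom, pos in uniform_sites(cfg.n_shared_mutations):
        ref = _BASES[codes[chrom][pos]]
        alt = _BASES[int(rng.choice([b for b in range(4) if _BASES[b] != ref]))]
        planned.append(_PlannedVariant(chrom, pos, ref, alt, SNS, draw_gt(),
                                       "shared"))

    # (c) case-specific substitutions from the implanted mixture
    implanted = mixture_profile(cfg.signature_mixture, cat)
    tri_table = genome_triplets(g)
    avail = tri_table.counts[CHANNEL_TRIPLET].astype(float)
    q = implanted * avail
    if q.sum() == 0:
        raise SimError("no genome context available for the implanted profile")
    q /= q.sum()
    sites = _triplet_sites(codes)
    per_channel = rng.multinomial(cfg.n_case_specific, q)
    for ch, k in enumerate(per_channel):
        if k == 0:
            continue
        tri = int(CHANNEL_TRIPLET[ch])
        pools = sites[tri]
        n_avail = sum(len(p) for _, p in pools)
        if n_avail < k:
            raise SimError(f"channel {CHANNELS[ch]}: {k} mutations requested "
                           f"but only {n_avail} sites available")
        pw = np.array([len(p) for _, p in pools], dtype=float)
        pw /= pw.sum()
        per_pool = rng.multinomial(k, pw)
        sub = CHANNELS[ch]
        pyr_ref, pyr_alt = sub[2], sub[4]
        for (chrom, pool), kk in zip(pools, per_pool):
            for pos in _pick_unused(rng, pool, int(kk), chrom, used):
                base = _BASES[codes[chrom][pos]]
                if base == pyr_ref:
                    ref, alt = pyr_ref, pyr_alt
                else:
                    ref, alt = COMPLEMENT[pyr_ref], COMPLEMENT[pyr_alt]
                planned.append(_PlannedVariant(chrom, pos, ref, alt, SNS,
                                               draw_gt(), "case", channel=ch))

    # (d) kataegis clusters of strand-coordinated C>T/C>G near breakpoints
    clusters_truth = []
    kc = cfg.kataegis
    if kc.n_clusters > 0:
        order = rng.permutation(len(bps))
        chosen = [bps[i] for i in order[:kc.n_clusters]]
        if len(chosen) < kc.n_clusters:
            raise SimError("more kataegis clusters requested than breakpoints")
        for cid, bp in enumerate(chosen):
            clen = chrom_lengths[bp.chrom]
            for _attempt in range(200):
                center = bp.pos + int(rng.integers(-kc.max_distance_to_breakpoint,
                                                   kc.max_distance_to_breakpoint + 1))
                lo = max(1, center - kc.cluster_span_bp // 2)
                hi = min(clen - 1, lo + kc.cluster_span_bp)
                strand = "+" if rng.random() < 0.5 else "-"
                want = 1 if strand == "+" else 2  # C or G code
                seg = codes[bp.chrom][lo:hi]
                cand = np.flatnonzero(seg == want) + lo
                cand = np.array([p for p in cand if (bp.chrom, p) not in used],
                                dtype=np.int64)
                if len(cand) >= kc.cluster_size:
                    break
            else:
                raise SimError("cannot place kataegis cluster: no site run found")
            pick = np.sort(rng.choice(cand, size=kc.cluster_size, replace=False))
            gt = draw_gt()
            pos_list = []
            for pos in pick:
                pos = int(pos)
                used.add((bp.chrom, pos))
                # strand-coordinated APOBEC-type: C>T or C>G on one strand
                to_t = rng.random() < 0.6
                if strand == "+":
                    ref, alt = "C", ("T" if to_t else "G")
                else:
                    ref, alt = "G", ("A" if to_t else "C")
                planned.append(_PlannedVariant(bp.chrom, pos, ref, alt, SNS, gt,
                                               "kataegis", cluster=cid))
                pos_list.append(pos)
            clusters_truth.append({"chrom": bp.chrom, "start": int(pick[0]),
                                   "end": int(pick[-1]) + 1,
                                   "n_mut": kc.cluster_size,
                                   "breakpoint_pos": bp.pos,
                                   "positions": pos_list})

    # indels (uniform background; exercise the INS/DEL code paths)
    def plan_indels(k: int, origin: str):
        for chrom, pos in uniform_sites(k):
            seq = g.sequences[chrom]
            if rng.random() < 0.5:
                ins = "".join(_BASES[int(b)] for b in rng.integers(0, 4,
                              int(rng.integers(1, 4))))
                planned.append(_PlannedVariant(chrom, pos, seq[pos],
                                               seq[pos] + ins, INS, draw_gt(),
                                               origin))
            else:
                dlen = int(rng.integers(1, 4))
                span = seq[pos:pos + 1 + dlen]
                if len(span) < 1 + dlen or "N" in span:
                    continue
                planned.append(_PlannedVariant(chrom, pos, span, span[0], DEL,
                                               draw_gt(), origin))

    plan_indels(cfg.n_shared_indels, "shared_indel")
    plan_indels(cfg.n_case_specific_indels, "case_indel")

    planned.sort(key=lambda p: (p.chrom, p.pos, p.ref, p.alt))
    shared = [p for p in planned if p.origin in ("shared", "shared_indel")]
    esc_only = [p for p in planned if p.origin not in ("shared", "shared_indel")]
    assert not ({p.key_str() for p in esc_only} &
                {p.key_str() for p in shared}), "ESC-specific leaked into OFF"

    # (e) per-file annotation noise; germline GT shared across conditions
    def materialize(pvars: list[_PlannedVariant], condition: str) -> Callset:
        mq, dp = _sample_noise(rng, len(pvars), cfg.noise)
        variants = [
            VariantCall(chrom=p.chrom, pos=p.pos, ref=p.ref, alt=p.alt,
                        vclass=p.vclass, mq=float(m), dp=int(d), gt=p.gt,
                        af=0.5 if p.gt == "0/1" else 1.0)
            for p, m, d in zip(pvars, mq, dp)
        ]
        return Callset(sample_id=condition.lower(), condition=condition,
                       variants=variants, mean_coverage=cfg.noise.depth_mean)

    off_cs = materialize(shared, "OFF")
    esc_cs = materialize(shared + esc_only, "ESC")
    esc_cs = esc_cs.sorted_copy()

    paths = {
        "genome_fasta": str(outdir / "genome.fa"),
        "breakpoints_bed": str(outdir / "breakpoints.bed"),
        "off_vcf": str(outdir / "off.vcf"),
        "esc_vcf": str(outdir / "esc.vcf"),
        "truth_json": str(outdir / "truth.json"),
        "manifest_json": str(outdir / "manifest.json"),
    }
    write_genome(g, paths["genome_fasta"])
    write_breakpoints(bps, paths["breakpoints_bed"])
    write_vcf(off_cs, paths["off_vcf"], contig_lengths=chrom_lengths)
    write_vcf(esc_cs, paths["esc_vcf"], contig_lengths=chrom_lengths)

    case_sns = [p for p in planned if p.origin == "case"]
    kat = [p for p in planned if p.origin == "kataegis"]
    truth = {
        "seed": cfg.seed,
        "implanted_profile": [float(x) for x in implanted],
        "mixture": cfg.signature_mixture,
        "dominant_signature": max(cfg.signature_mixture,
                                  key=cfg.signature_mixture.get),
        "catalog_names": cat.names,
        "mean_coverage": cfg.noise.depth_mean,
        "expected_enrichment_ratio": 1.0,
        "n_shared": cfg.n_shared_mutations,
        "n_case_specific_sns": len(case_sns) + len(kat),
        "case_specific_keys": [p.key_str() for p in case_sns + kat],
        "case_specific_channels": {p.key_str(): p.channel for p in case_sns},
        "clusters": clusters_truth,
    }
    with open(paths["truth_json"], "w") as fh:
        json.dump(truth, fh, sort_keys=True)
    manifest = {
        "seed": cfg.seed,
        "config": {
            **{k: v for k, v in asdict(cfg).items()
               if k not in ("kataegis", "noise")},
            "kataegis": asdict(cfg.kataegis),
            "noise": asdict(cfg.noise),
        },
        "paths": paths,
    }
    with open(paths["manifest_json"], "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    return manifest


def truth_compare(summary: dict, truth: dict) -> dict:
    """Score a pipeline run against generator truth.

    ``summary`` is the pipeline's summary dict (see pipeline.run_all);
    ``truth`` the generator's truth JSON.  Returns signature cosine,
    kataegis precision/recall, and the enrichment-ratio error relative to
    the truth's expected background ratio.
    """
    from .signature import cosine_similarity

    if summary.get("seed") is not None and truth.get("seed") is not None \
            and summary["seed"] != truth["seed"]:
        raise SimError("run/truth seed mismatch: outputs are from another run")
    report: dict = {}
    corrected = np.asarray(summary["signature"]["corrected"], dtype=float)
    implanted = np.asarray(truth["implanted_profile"], dtype=float)
    report["signature_cosine"] = cosine_similarity(corrected, implanted)
    ranks = summary["signature"]["cosine_ranks"]
    report["top_signature"] = ranks[0][0]
    report["dominant_recovered_first"] = bool(
        ranks[0][0] == truth["dominant_signature"])

    detected = summary["kataegis"]["clusters"]
    true_clusters = truth["clusters"]
    matched_true = set()
    tp = 0
    for d in detected:
        hit = None
        for i, t in enumerate(true_clusters):
            if (d["chrom"] == t["chrom"] and d["start"] < t["end"]
                    and t["start"] < d["end"]):
                hit = i
                break
        if hit is None:
            continue
        tp += 1
        matched_true.add(hit)
    n_det = len(detected)
    n_true = len(true_clusters)
    report["kataegis_precision"] = tp / n_det if n_det else float("nan")
    report["kataegis_recall"] = len(matched_true) / n_true if n_true else float("nan")

    sns_enr = summary["enrichment"]["SNS"]
    expected = truth.get("expected_enrichment_ratio")
    report["enrichment_ratio"] = sns_enr["ratio"]
    if expected is not None and np.isfinite(sns_enr["ratio"]):
        report["enrichment_ratio_error"] = abs(sns_enr["ratio"] - expected)
    return report
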