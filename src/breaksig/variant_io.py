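"""Input/output layer: VCF call sets, reference FASTA, breakpoint BED.

The in-memory model is deliberately small: a :class:`VariantCall` per
biallelic substitution/indel, a :class:`Callset` per sample/condition, and a
:class:`GenomeRef` holding uppercase chromosome sequences plus their
effective (non-N) sizes.  All internal coordinates are 0-based half-open;
conversion to/from the 1-based VCF convention happens only here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import pysam
from Bio import SeqIO

VALID_BASES = frozenset("ACGT")

SNS = "SNS"
INS = "INS"
DEL = "DEL"
UNSUPPORTED = "UNSUPPORTED"


class VcfFormatError(ValueError):
    """Malformed VCF/BED/FASTA input."""


@dataclass(frozen=True)
class VariantCall:
    """One biallelic variant call.

    ``pos`` is the 0-based coordinate of the first REF base.  ``af`` is the
    allele fraction; when absent from the record it is derived from the
    genotype (0/1 -> 0.5, 1/1 -> 1.0, 0/0 -> 0.0).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    mq: float = 0.0
    dp: int = 0
    gt: str = "./."
    af: float = 0.0

    def key(self) -> tuple[str, int, str, str]:
        """Allele-aware identity used for subtraction and deduplication."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ParseReport:
    """Tallies of kept/rejected records for one VCF parse.

    Conservation: ``records_in == records_kept + records_rejected`` where a
    multi-allelic input record counts once per ALT.
    """

    records_in: int = 0
    records_kept: int = 0
    symbolic: int = 0
    n_allele: int = 0
    mnv: int = 0
    no_genotype: int = 0
    duplicate: int = 0

    @property
    def records_rejected(self) -> int:
        return self.symbolic + self.n_allele + self.mnv + self.no_genotype + self.duplicate

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("tally\tcount\n")
            for k, v in asdict(self).items():
                fh.write(f"{k}\t{v}\n")
            fh.write(f"records_rejected\t{self.records_rejected}\n")


@dataclass
class Callset:
    """An ordered, duplicate-free collection of calls for one sample."""

    sample_id: str
    condition: str
    variants: list[VariantCall] = field(default_factory=list)
    mean_coverage: float | None = None
    parse_report: ParseReport | None = None

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def by_class(self, vclass: str) -> list[VariantCall]:
        return [v for v in self.variants if v.vclass == vclass]

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key() for v in self.variants}

    def sorted_copy(self) -> "Callset":
        return Callset(
            sample_id=self.sample_id,
            condition=self.condition,
            variants=sorted(self.variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)),
            mean_coverage=self.mean_coverage,
            parse_report=self.parse_report,
        )


@dataclass
class GenomeRef:
    """Reference genome held in memory (uppercase strings, N allowed)."""

    sequences: dict[str, str]
    effective_sizes: dict[str, int]

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "GenomeRef":
        seqs = {name: str(s).upper() for name, s in sequences.items()}
        eff = {name: sum(1 for b in s if b in VALID_BASES) for name, s in seqs.items()}
        return cls(sequences=seqs, effective_sizes=eff)

    @property
    def total_effective_size(self) -> int:
        return sum(self.effective_sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True)
class Breakpoint:
    """One side of a rearrangement junction (0-based point coordinate)."""

    chrom: str
    pos: int


def classify_variant(ref: str, alt: str) -> str:
    """Classify an allele pair as SNS / INS / DEL.

    Equal-length multi-base substitutions (MNVs) are UNSUPPORTED; callers
    exclude them with a tally.
    """
    if not ref or not alt or not set(ref) <= VALID_BASES or not set(alt) <= VALID_BASES:
        raise ValueError(f"alleles must be non-empty A/C/G/T strings: {ref!r}>{alt!r}")
    if len(ref) == len(alt):
        if len(ref) == 1 and ref != alt:
            return SNS
        return UNSUPPORTED
    return INS if len(alt) > len(ref) else DEL


def derive_af(gt: str, af_tag: float | None = None) -> float:
    """Allele fraction from an explicit AF tag, else from the genotype.

    The genotype mapping embodies the 0/1 = one allele, 1/1 = both alleles
    convention: 0/1 -> 0.5, 1/1 -> 1.0, 0/0 -> 0.0.
    """
    if af_tag is not None:
        return float(af_tag)
    for sep in ("/", "|"):
        if sep in gt:
            fields = gt.split(sep)
            if len(fields) == 2 and all(f in ("0", "1") for f in fields):
                return (int(fields[0]) + int(fields[1])) / 2.0
    raise ValueError(f"unparseable genotype {gt!r} and no AF tag")


def _gt_string(gt_tuple, alt_index: int) -> str | None:
    """Render a per-ALT genotype string from a pysam GT tuple.

    For a multi-allelic record split on ALT ``alt_index`` (1-based), alleles
    equal to that index become '1', reference stays '0'; other ALT indices
    are treated as non-carrier ('0') for this split record.
    """
    if gt_tuple is None or any(a is None for a in gt_tuple):
        return None
    mapped = sorted("1" if a == alt_index else "0" for a in gt_tuple)
    return "/".join(mapped)


def read_vcf(path: str | os.PathLike, sample_id: str, condition: str,
             mean_coverage: float | None = None) -> Callset:
    """Read a VCF into a :class:`Callset`.

    Multi-allelic records are split per ALT (each split inherits site MQ/DP).
    Records with symbolic or N-containing alleles, MNVs, and records lacking
    both a genotype and an AF tag are skipped and tallied in the parse
    report.  Exact-duplicate (chrom, pos, ref, alt) entries are dropped.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    report = ParseReport()
    variants: list[VariantCall] = []
    seen: set[tuple[str, int, str, str]] = set()
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        sample = next(iter(vf.header.samples), None)
        declared = set(vf.header.info.keys())
        has_mq, has_dp, has_af = ("MQ" in declared, "DP" in declared,
                                  "AF" in declared)
        for rec in vf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                report.records_in += 1
                ref = (rec.ref or "").upper()
                alt = (alt or "").upper()
                if alt.startswith("<") or alt in ("*", ".") or not alt:
                    report.symbolic += 1
                    continue
                if not set(ref) <= VALID_BASES or not set(alt) <= VALID_BASES:
                    report.n_allele += 1
                    continue
                vclass = classify_variant(ref, alt)
                if vclass == UNSUPPORTED:
                    report.mnv += 1
                    continue
                mq = rec.info.get("MQ", 0.0) if has_mq else 0.0
                dp = rec.info.get("DP", 0) if has_dp else 0
                af_tag = rec.info.get("AF", None) if has_af else None
                if isinstance(af_tag, tuple):
                    af_tag = af_tag[ai - 1] if len(af_tag) >= ai else af_tag[0]
                gt = None
                if sample is not None and "GT" in rec.samples[sample]:
                    gt = _gt_string(rec.samples[sample]["GT"], ai)
                if gt is None and af_tag is None:
                    report.no_genotype += 1
                    continue
                if gt is None:
                    gt = "./."
                try:
                    af = derive_af(gt, af_tag)
                except ValueError:
                    report.no_genotype += 1
                    continue
                v = VariantCall(chrom=rec.chrom, pos=rec.start, ref=ref, alt=alt,
                                vclass=vclass, mq=float(mq), dp=int(dp), gt=gt,
                                af=float(af))
                if v.key() in seen:
                    report.duplicate += 1
                    continue
                seen.add(v.key())
                variants.append(v)
                report.records_kept += 1
    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return Callset(sample_id=sample_id, condition=condition, variants=variants,
                   mean_coverage=mean_coverage, parse_report=report)


def write_vcf(cs: Callset, path: str | os.PathLike,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a Callset as an uncompressed sorted VCF v4.2 with MQ/DP/GT."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">')
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chroms: dict[str, int] = {}
    for v in cs.variants:
        need = v.pos + len(v.ref)
        chroms[v.chrom] = max(chroms.get(v.chrom, 0), need)
    if contig_lengths:
        for c, ln in contig_lengths.items():
            chroms[c] = max(chroms.get(c, 0), ln)
    for c in sorted(chroms):
        header.add_line(f"##contig=<ID={c},length={chroms[c]}>")
    header.add_sample(cs.sample_id)
    ordered = sorted(cs.variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(contig=v.chrom, start=v.pos,
                                 alleles=(v.ref, v.alt))
            rec.info["MQ"] = float(v.mq)
            rec.info["DP"] = int(v.dp)
            gt = v.gt.replace("|", "/")
            if gt in ("0/0", "0/1", "1/0", "1/1"):
                a, b = gt.split("/")
                rec.samples[cs.sample_id]["GT"] = (int(a), int(b))
            rec.samples[cs.sample_id].phased = False
            out.write(rec)


def read_genome(path: str | os.PathLike) -> GenomeRef:
    """Read a FASTA into a :class:`GenomeRef` (case-insensitive, N kept)."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise VcfFormatError(f"duplicate FASTA header {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise VcfFormatError(f"no FASTA records in {path}")
    return GenomeRef.from_sequences(sequences)


def write_genome(g: GenomeRef, path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in g.sequences:
            fh.write(f">{name}\n")
            s = g.sequences[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_breakpoints(path: str | os.PathLike) -> tuple[list[Breakpoint], int]:
    """Read a BED3+ file of junction sides.

    Each record contributes one :class:`Breakpoint` at its 0-based start.
    Returns the sorted, deduplicated list and the number of duplicates
    dropped.  An empty file yields an empty list.
    """
    bps: list[Breakpoint] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise VcfFormatError(f"{path}:{lineno}: BED3 needs 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise VcfFormatError(f"{path}:{lineno}: non-integer interval") from exc
            if end <= start:
                raise VcfFormatError(f"{path}:{lineno}: interval end <= start")
            bps.append(Breakpoint(chrom=fields[0], pos=start))
    unique = sorted(set(bps), key=lambda b: (b.chrom, b.pos))
    return unique, len(bps) - len(unique)


def write_breakpoints(bps: Iterable[Breakpoint], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for b in sorted(bps, key=lambda b: (b.chrom, b.pos)):
            fh.write(f"{b.chrom}\t{b.pos}\t{b.pos + 1}\n")
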