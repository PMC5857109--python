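"""96-channel trinucleotide-context mutational signatures.

Single-nucleotide substitutions are collapsed onto the pyrimidine strand
(purine-centered variants and their flanks are reverse-complemented), giving
6 substitution classes x 16 flanking-base combinations = 96 channels.  Raw
channel counts are corrected for the genome-wide abundance of each
pyrimidine-centered triplet and renormalized, so signatures from genomes
with different base composition are comparable; similarity to a reference
catalog is ranked by cosine.

Channel order is substitution-major (C>A, C>G, C>T, T>A, T>C, T>G) with
flanks lexicographic; labels render as ``A[C>T]G``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import GenomeRef, VariantCall, SNS

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_SUB_INDEX = {s: i for i, s in enumerate(SUBSTITUTIONS)}

#: 32 pyrimidine-centered triplets, center-major then flanks lexicographic.
TRIPLETS = tuple(f + c + t for c in "CT" for f in BASES for t in BASES)
_TRIPLET_INDEX = {t: i for i, t in enumerate(TRIPLETS)}

#: canonical labels for the 96 channels.
CHANNELS = tuple(
    f"{f}[{sub}]{t}" for sub in SUBSTITUTIONS for f in BASES for t in BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

#: channel index -> index of its pyrimidine-centered triplet in TRIPLETS.
CHANNEL_TRIPLET = np.array(
    [_TRIPLET_INDEX[c[0] + c[2] + c[6]] for c in CHANNELS], dtype=np.intp
)

# byte-level base codes for fast genome scans: A,C,G,T -> 0..3, else 4
_BYTE_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _i in _CODE.items():
    _BYTE_CODE[ord(_b)] = _i
    _BYTE_CODE[ord(_b.lower())] = _i

# collapse map: 3-mer code (16a+4b+c, b any base) -> pyrimidine triplet index
_COLLAPSE = np.full(64, -1, dtype=np.intp)
for _a in range(4):
    for _b in range(4):
        for _c in range(4):
            code = 16 * _a + 4 * _b + _c
            tri = BASES[_a] + BASES[_b] + BASES[_c]
            if tri[1] in "AG":
                tri = "".join(COMPLEMENT[x] for x in reversed(tri))
            _COLLAPSE[code] = _TRIPLET_INDEX[tri]


class ProfileError(ValueError):
    pass


def channel_index(substitution: str, five_prime: str, three_prime: str) -> int:
    """Index of a channel in the canonical 96-channel order."""
    return 16 * _SUB_INDEX[substitution] + 4 * _CODE[five_prime] + _CODE[three_prime]


def channel_label(idx: int) -> str:
    return CHANNELS[idx]


@dataclass(frozen=True)
class ContextChannel:
    substitution: str
    five_prime: str
    three_prime: str

    @property
    def index(self) -> int:
        return channel_index(self.substitution, self.five_prime, self.three_prime)

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.substitution}]{self.three_prime}"


@dataclass
class SignatureProfile:
    """Raw 96-channel counts plus the triplet-corrected distribution."""

    raw_counts: np.ndarray
    n_mutations: int = 0
    n_excluded: int = 0
    corrected: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"context": list(CHANNELS), "raw_count": self.raw_counts.astype(int)}
        if self.corrected is not None:
            data["corrected"] = self.corrected
        return pd.DataFrame(data)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class TripletTable:
    """Genome-wide occurrence counts of the 32 pyrimidine triplets."""

    counts: np.ndarray  # (32,), order of TRIPLETS

    def __getitem__(self, triplet: str) -> int:
        return int(self.counts[_TRIPLET_INDEX[triplet]])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[str, int]:
        return {t: int(c) for t, c in zip(TRIPLETS, self.counts)}


@dataclass
class SignatureCatalog:
    """Named reference signatures as columns of a (96, n) matrix."""

    names: list[str]
    profiles: np.ndarray

    def __post_init__(self):
        if self.profiles.shape != (96, len(self.names)):
            raise ProfileError("catalog must be 96 x n_signatures")
        sums = self.profiles.sum(axis=0)
        if np.any(self.profiles < 0) or np.any(sums <= 0):
            raise ProfileError("catalog profiles must be non-negative, non-zero")
        self.profiles = self.profiles / sums

    def __getitem__(self, name: str) -> np.ndarray:
        return self.profiles[:, self.names.index(name)]


def mutation_context(v: VariantCall, g: GenomeRef) -> ContextChannel | None:
    """Pyrimidine-collapsed channel of one SNS, or None if a flank is N or
    the site sits at a contig edge (callers tally the exclusion).

    Raises if the variant class is not SNS, the chromosome is unknown, or
    the genome base disagrees with the REF allele.
    """
    if v.vclass != SNS:
        raise ProfileError(f"mutation_context needs an SNS, got {v.vclass}")
    seq = g.sequences.get(v.chrom)
    if seq is None:
        raise ProfileError(f"chromosome {v.chrom!r} absent from reference")
    if v.pos < 1 or v.pos >= len(seq) - 1:
        return None
    five, center, three = seq[v.pos - 1], seq[v.pos], seq[v.pos + 1]
    if center != v.ref:
        raise ProfileError(
            f"REF mismatch at {v.chrom}:{v.pos}: genome {center!r} vs call {v.ref!r}")
    if five not in _CODE or three not in _CODE:
        return None
    ref, alt = v.ref, v.alt
    if ref in "AG":  # collapse to the pyrimidine strand
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five, three = COMPLEMENT[three], COMPLEMENT[five]
    return ContextChannel(substitution=f"{ref}>{alt}", five_prime=five,
                          three_prime=three)


def count_contexts(variants, g: GenomeRef) -> SignatureProfile:
    """Tally SNS calls into the 96 channels.

    Conservation: raw_counts.sum() + n_excluded == number of input SNSs.
    """
    raw = np.zeros(96, dtype=np.int64)
    excluded = 0
    n = 0
    for v in variants:
        n += 1
        ch = mutation_context(v, g)
        if ch is None:
            excluded += 1
        else:
            raw[ch.index] += 1
    return SignatureProfile(raw_counts=raw, n_mutations=n - excluded,
                            n_excluded=excluded)


def genome_triplets(g: GenomeRef) -> TripletTable:
    """Slide a width-3 window over every chromosome and tally the
    pyrimidine-collapsed triplet of each window; windows containing N are
    skipped."""
    counts = np.zeros(32, dtype=np.int64)
    for seq in g.sequences.values():
        if len(seq) < 3:
            continue
        codes = _BYTE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        a, b, c = codes[:-2], codes[1:-1], codes[2:]
        valid = (a < 4) & (b < 4) & (c < 4)
        if not valid.any():
            continue
        word = (16 * a[valid].astype(np.intp) + 4 * b[valid] + c[valid])
        counts += np.bincount(_COLLAPSE[word], minlength=32)
    return TripletTable(counts=counts)


def correct_profile(p: SignatureProfile, t: TripletTable) -> SignatureProfile:
    """Divide each channel count by the genome abundance of its triplet and
    renormalize to a probability vector.

    A channel observed in a context the genome does not contain is an
    inconsistency and raises.  A zero raw vector leaves ``corrected`` None.
    """
    raw = p.raw_counts.astype(float)
    tvec = t.counts[CHANNEL_TRIPLET].astype(float)
    bad = (raw > 0) & (tvec == 0)
    if bad.any():
        labels = [CHANNELS[i] for i in np.flatnonzero(bad)]
        raise ProfileError(f"mutations observed in absent contexts: {labels}")
    if raw.sum() == 0:
        p.corrected = None
        return p
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(tvec > 0, raw / np.where(tvec > 0, tvec, 1.0), 0.0)
    p.corrected = rate / rate.sum()
    return p


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ProfileError("cosine undefined for zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


def cosine_rank(p: SignatureProfile, cat: SignatureCatalog
                ) -> list[tuple[str, float]]:
    """Rank catalog signatures by cosine similarity to the corrected
    profile, descending; ties keep catalog order."""
    if p.corrected is None:
        raise ProfileError("profile has no corrected vector")
    sims = [(name, cosine_similarity(p.corrected, cat.profiles[:, j]))
            for j, name in enumerate(cat.names)]
    return sorted(sims, key=lambda x: -x[1])


def read_catalog(path: str | os.PathLike) -> SignatureCatalog:
    """Read a catalog TSV: first column ``context`` with ``A[C>A]A`` labels,
    one column per signature.  Rows may appear in any order but must cover
    the 96 channels exactly once."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "context":
        raise ProfileError("catalog TSV must start with a 'context' column")
    labels = list(df["context"])
    if sorted(labels) != sorted(CHANNELS):
        raise ProfileError("catalog must contain each of the 96 contexts once")
    order = [labels.index(c) for c in CHANNELS]
    names = list(df.columns[1:])
    if not names:
        raise ProfileError("catalog has no signature columns")
    mat = df.iloc[order, 1:].to_numpy(dtype=float)
    return SignatureCatalog(names=names, profiles=mat)


def write_catalog(cat: SignatureCatalog, path: str | os.PathLike) -> None:
    df = pd.DataFrame(cat.profiles, columns=cat.names)
    df.insert(0, "context", list(CHANNELS))
    df.to_csv(path, sep="\t", index=False)


def write_similarity(ranks: list[tuple[str, float]], path: str | os.PathLike) -> None:
    pd.DataFrame(ranks, columns=["signature", "cosine"]).to_csv(
        path, sep="\t", index=False)
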