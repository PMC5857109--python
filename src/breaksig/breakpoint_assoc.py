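"""Breakpoint-proximity enrichment and kataegis-like cluster detection.

Mutation density inside merged windows of half-width ``w`` (default 50 kb)
around rearrangement junction sides is compared with the remaining
effective (non-N) genome, per variant class.  Significance comes from a
one-sided permutation test that re-places the same number of variants
uniformly over the effective genome.  Kataegis candidates are maximal runs
of closely spaced substitutions (inter-mutation distance <= 1 kb, >= 6
mutations by default), annotated with their APOBEC-type content — C>T
transitions and C>G transversions on the pyrimidine strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import Breakpoint, Callset, GenomeRef, VariantCall, SNS, INS, DEL

DEFAULT_WINDOW = 50_000
DEFAULT_IMD_MAX = 1_000
DEFAULT_MIN_CLUSTER = 6

#: allele pairs counted as APOBEC-type (C>T / C>G after pyrimidine collapse)
_APOBEC_PAIRS = {("C", "T"), ("C", "G"), ("G", "A"), ("G", "C")}


class WindowError(ValueError):
    pass


def _effective_prefix(seq: str) -> np.ndarray:
    """Prefix sums of the non-N indicator; prefix[i] = effective bp in [0, i)."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ok = (codes != ord("N")) & (codes != ord("n"))
    out = np.zeros(len(seq) + 1, dtype=np.int64)
    np.cumsum(ok, out=out[1:])
    return out


@dataclass
class WindowSet:
    """Merged half-open windows around breakpoints with bp accounting.

    ``total_window_bp`` and ``total_outside_bp`` count effective (non-N)
    bases and always sum to the genome's total effective size.
    """

    windows: dict[str, np.ndarray]  # chrom -> (k, 2) array of [start, end)
    w: int
    total_window_bp: int
    total_outside_bp: int

    def contains(self, chrom: str, pos: int) -> bool:
        iv = self.windows.get(chrom)
        if iv is None or len(iv) == 0:
            return False
        i = int(np.searchsorted(iv[:, 0], pos, side="right")) - 1
        return i >= 0 and pos < iv[i, 1]

    def n_inside(self, positions: np.ndarray, chrom: str) -> int:
        iv = self.windows.get(chrom)
        if iv is None or len(iv) == 0 or len(positions) == 0:
            return 0
        idx = np.searchsorted(iv[:, 0], positions, side="right") - 1
        ok = (idx >= 0) & (positions < iv[np.clip(idx, 0, len(iv) - 1), 1])
        return int(ok.sum())


def build_windows(bps: list[Breakpoint], g: GenomeRef, w: int = DEFAULT_WINDOW
                  ) -> WindowSet:
    """Merge per-breakpoint intervals [pos-w, pos+w), clipped to chromosome
    bounds, and account effective bp inside/outside."""
    if w <= 0:
        raise WindowError("window half-width must be > 0")
    if not bps:
        raise WindowError("no breakpoints: enrichment undefined")
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in bps:
        if b.chrom not in g.sequences:
            raise WindowError(f"breakpoint chromosome {b.chrom!r} not in reference")
        clen = len(g.sequences[b.chrom])
        if not 0 <= b.pos < clen:
            raise WindowError(f"breakpoint {b.chrom}:{b.pos} outside chromosome")
        start, end = max(0, b.pos - w), min(clen, b.pos + w)
        per_chrom.setdefault(b.chrom, []).append((start, end))
    windows: dict[str, np.ndarray] = {}
    inside = 0
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged, dtype=np.int64)
        windows[chrom] = arr
        prefix = _effective_prefix(g.sequences[chrom])
        inside += int((prefix[arr[:, 1]] - prefix[arr[:, 0]]).sum())
    total_eff = g.total_effective_size
    return WindowSet(windows=windows, w=w, total_window_bp=inside,
                     total_outside_bp=total_eff - inside)


@dataclass
class EnrichmentResult:
    vclass: str
    n_near: int
    n_far: int
    density_near: float  # mutations per effective Mb inside windows
    density_far: float
    ratio: float
    perm_p: float

    @property
    def total(self) -> int:
        return self.n_near + self.n_far


def _class_positions(vs: Callset) -> dict[str, dict[str, np.ndarray]]:
    out: dict[str, dict[str, list[int]]] = {SNS: {}, INS: {}, DEL: {}}
    for v in vs.variants:
        out.setdefault(v.vclass, {}).setdefault(v.chrom, []).append(v.pos)
    return {
        cls: {c: np.asarray(sorted(p), dtype=np.int64) for c, p in chroms.items()}
        for cls, chroms in out.items() if cls in (SNS, INS, DEL)
    }


def enrichment(vs: Callset, ws: WindowSet, n_perm: int = 1000,
               seed: int | None = None) -> dict[str, EnrichmentResult]:
    """Near/far densities, their ratio and a one-sided permutation p-value
    per variant class.

    The null re-places the class's n variants uniformly over the effective
    genome; the in-window count under that null is Binomial(n, p_in) with
    p_in the effective fraction of the genome inside windows, which is
    sampled directly.  perm_p uses the +1/(n_perm+1) correction.
    """
    rng = np.random.default_rng(seed)
    total_bp = ws.total_window_bp + ws.total_outside_bp
    p_in = ws.total_window_bp / total_bp
    results: dict[str, EnrichmentResult] = {}
    positions = _class_positions(vs)
    for cls in (SNS, INS, DEL):
        chrom_pos = positions.get(cls, {})
        n_total = int(sum(len(p) for p in chrom_pos.values()))
        n_near = int(sum(ws.n_inside(p, c) for c, p in chrom_pos.items()))
        n_far = n_total - n_near
        d_near = n_near / (ws.total_window_bp / 1e6) if ws.total_window_bp else 0.0
        d_far = n_far / (ws.total_outside_bp / 1e6) if ws.total_outside_bp else 0.0
        if n_total == 0:
            ratio, perm_p = float("nan"), float("nan")
        else:
            ratio = d_near / d_far if d_far > 0 else float("inf")
            draws = rng.binomial(n_total, p_in, size=n_perm)
            perm_p = (1 + int((draws >= n_near).sum())) / (n_perm + 1)
        results[cls] = EnrichmentResult(vclass=cls, n_near=n_near, n_far=n_far,
                                        density_near=d_near, density_far=d_far,
                                        ratio=ratio, perm_p=perm_p)
    return results


def per_breakpoint_counts(vs: Callset, bps: list[Breakpoint],
                          w: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Per-breakpoint SNS/INS/DEL counts within [pos-w, pos+w).

    Counting is window-local: a variant inside k overlapping breakpoint
    windows contributes to each of the k rows.
    """
    positions = _class_positions(vs)
    rows = []
    for b in sorted(bps, key=lambda b: (b.chrom, b.pos)):
        row = {"chrom": b.chrom, "pos": b.pos}
        for cls in (SNS, INS, DEL):
            p = positions.get(cls, {}).get(b.chrom)
            if p is None:
                row[cls] = 0
            else:
                lo = np.searchsorted(p, b.pos - w, side="left")
                hi = np.searchsorted(p, b.pos + w, side="left")
                row[cls] = int(hi - lo)
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "pos", SNS, INS, DEL])


@dataclass
class KataegisCluster:
    chrom: str
    start: int   # 0-based inclusive position of first mutation
    end: int     # 0-based half-open (last mutation pos + 1)
    n_mut: int
    n_apobec_type: int
    mean_imd: float
    nearest_breakpoint_distance: int | None = None

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


def detect_kataegis(vs: Callset, imd_max: int = DEFAULT_IMD_MAX,
                    min_cluster_size: int = DEFAULT_MIN_CLUSTER,
                    breakpoints: list[Breakpoint] | None = None
                    ) -> list[KataegisCluster]:
    """Maximal runs of >= min_cluster_size SNSs with successive
    inter-mutation distances <= imd_max; input order is irrelevant
    (positions are sorted internally)."""
    by_chrom: dict[str, list[VariantCall]] = {}
    for v in vs.variants:
        if v.vclass == SNS:
            by_chrom.setdefault(v.chrom, []).append(v)
    clusters: list[KataegisCluster] = []
    for chrom in sorted(by_chrom):
        muts = sorted(by_chrom[chrom], key=lambda v: v.pos)
        i = 0
        while i < len(muts):
            j = i
            while j + 1 < len(muts) and muts[j + 1].pos - muts[j].pos <= imd_max:
                j += 1
            run = muts[i:j + 1]
            if len(run) >= min_cluster_size:
                diffs = [b.pos - a.pos for a, b in zip(run, run[1:])]
                n_apo = sum(1 for v in run if (v.ref, v.alt) in _APOBEC_PAIRS)
                cl = KataegisCluster(
                    chrom=chrom, start=run[0].pos, end=run[-1].pos + 1,
                    n_mut=len(run), n_apobec_type=n_apo,
                    mean_imd=float(np.mean(diffs)))
                if breakpoints:
                    dists = [
                        max(0, cl.start - b.pos, b.pos - (cl.end - 1))
                        for b in breakpoints if b.chrom == chrom
                    ]
                    cl.nearest_breakpoint_distance = min(dists) if dists else None
                clusters.append(cl)
            i = j + 1
    return clusters


def rainfall_table(vs: Callset) -> pd.DataFrame:
    """Per-SNS inter-mutation distance table for rainfall plots."""
    rows = []
    by_chrom: dict[str, list[VariantCall]] = {}
    for v in vs.variants:
        if v.vclass == SNS:
            by_chrom.setdefault(v.chrom, []).append(v)
    for chrom in sorted(by_chrom):
        muts = sorted(by_chrom[chrom], key=lambda v: v.pos)
        prev = None
        for v in muts:
            ref, alt = v.ref, v.alt
            if ref in "AG":
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                ref, alt = comp[ref], comp[alt]
            rows.append({
                "chrom": chrom, "pos": v.pos,
                "imd": (v.pos - prev) if prev is not None else np.nan,
                "substitution": f"{ref}>{alt}",
            })
            prev = v.pos
    return pd.DataFrame(rows, columns=["chrom", "pos", "imd", "substitution"])


def write_enrichment(results: dict[str, EnrichmentResult],
                     path: str | os.PathLike) -> None:
    df = pd.DataFrame([vars(r) for r in results.values()])
    df.to_csv(path, sep="\t", index=False)


def write_kataegis(clusters: list[KataegisCluster], path: str | os.PathLike) -> None:
    df = pd.DataFrame([vars(c) for c in clusters],
                      columns=["chrom", "start", "end", "n_mut", "n_apobec_type",
                               "mean_imd", "nearest_breakpoint_distance"])
    df.to_csv(path, sep="\t", index=False)
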