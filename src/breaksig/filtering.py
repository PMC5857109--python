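"""Quality filtering, case/control subtraction and SNS load.

The escaped-cell ("ESC")-specific call set is derived in three steps:
mapping-quality filter on both call sets, allele-aware subtraction of the
non-induced ("OFF") control, then allele-fraction and read-depth filtering
of the remaining case-specific calls.  Both quality thresholds are
inclusive: MQ >= 30 and AF >= 0.5 by default.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .variant_io import Callset, SNS

NONE = "NONE"
GE_MEAN = "GE_MEAN"
BAND = "BAND"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusive quality thresholds plus the read-depth policy.

    depth_policy:
      * ``NONE`` — no depth filtering.
      * ``GE_MEAN`` — keep DP >= mean coverage.
      * ``BAND`` — keep |DP - mean| <= depth_band_fraction * mean.
    """

    mq_min: float = 30.0
    af_min: float = 0.5
    depth_policy: str = NONE
    depth_band_fraction: float = 0.25

    def __post_init__(self):
        if self.mq_min < 0:
            raise ConfigError("mq_min must be >= 0")
        if not 0.0 <= self.af_min <= 1.0:
            raise ConfigError("af_min must be in [0, 1]")
        if self.depth_policy not in (NONE, GE_MEAN, BAND):
            raise ConfigError(f"unknown depth_policy {self.depth_policy!r}")
        if not 0.0 < self.depth_band_fraction < 1.0:
            raise ConfigError("depth_band_fraction must be in (0, 1)")


@dataclass
class FilterTally:
    """Per-criterion removal counts for one apply_filters call."""

    input: int = 0
    kept: int = 0
    removed_mq: int = 0
    removed_af: int = 0
    removed_depth: int = 0

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("criterion\tcount\n")
            fh.write(f"input\t{self.input}\n")
            fh.write(f"kept\t{self.kept}\n")
            fh.write(f"removed_mq\t{self.removed_mq}\n")
            fh.write(f"removed_af\t{self.removed_af}\n")
            fh.write(f"removed_depth\t{self.removed_depth}\n")


def _depth_ok(dp: int, th: FilterThresholds, mean_coverage: float) -> bool:
    if th.depth_policy == NONE:
        return True
    if th.depth_policy == GE_MEAN:
        return dp >= mean_coverage
    return abs(dp - mean_coverage) <= th.depth_band_fraction * mean_coverage


def apply_filters(cs: Callset, th: FilterThresholds) -> tuple[Callset, FilterTally]:
    """Keep variants with mq >= mq_min AND af >= af_min AND depth rule.

    A variant failing several criteria is tallied under the first failed
    one (MQ, then AF, then depth).  Input order is preserved.
    """
    if th.depth_policy != NONE and (cs.mean_coverage is None or cs.mean_coverage <= 0):
        raise ConfigError("depth filtering requires mean_coverage > 0")
    tally = FilterTally(input=len(cs.variants))
    kept = []
    for v in cs.variants:
        if v.mq < th.mq_min:
            tally.removed_mq += 1
        elif v.af < th.af_min:
            tally.removed_af += 1
        elif not _depth_ok(v.dp, th, cs.mean_coverage or 0.0):
            tally.removed_depth += 1
        else:
            kept.append(v)
    tally.kept = len(kept)
    out = Callset(sample_id=cs.sample_id, condition=cs.condition, variants=kept,
                  mean_coverage=cs.mean_coverage, parse_report=cs.parse_report)
    return out, tally


@dataclass
class SubtractionResult:
    """Case calls partitioned against the control by exact allele key."""

    case_specific: Callset
    shared: Callset
    control_only: Callset = field(repr=False, default=None)


def subtract(case: Callset, control: Callset) -> SubtractionResult:
    """Partition ``case`` by exact (chrom, pos, ref, alt) membership in
    ``control``.  A different ALT at the same site is a different mutation.
    """
    control_keys = control.keys()
    case_keys = case.keys()
    case_only = [v for v in case.variants if v.key() not in control_keys]
    shared = [v for v in case.variants if v.key() in control_keys]
    ctrl_only = [v for v in control.variants if v.key() not in case_keys]

    def _mk(variants, condition, src):
        return Callset(sample_id=src.sample_id, condition=condition,
                       variants=variants, mean_coverage=src.mean_coverage)

    return SubtractionResult(
        case_specific=_mk(case_only, case.condition, case),
        shared=_mk(shared, case.condition, case),
        control_only=_mk(ctrl_only, control.condition, control),
    )


def sns_load(cs: Callset) -> tuple[float, int]:
    """Depth-normalized SNS load: (SNS count / mean coverage, raw count)."""
    if cs.mean_coverage is None or cs.mean_coverage <= 0:
        raise ConfigError("sns_load requires mean_coverage > 0")
    n = len(cs.by_class(SNS))
    return n / cs.mean_coverage, n


def derive_case_specific(case: Callset, control: Callset, th: FilterThresholds
                         ) -> tuple[Callset, dict]:
    """The full case-specific derivation: MQ-filter both call sets,
    subtract control from case, then AF+depth filter what remains.

    Returns the final case-specific Callset and a dict of per-stage tallies.
    """
    mq_only = FilterThresholds(mq_min=th.mq_min, af_min=0.0, depth_policy=NONE,
                               depth_band_fraction=th.depth_band_fraction)
    case_mq, t_case = apply_filters(case, mq_only)
    ctrl_mq, t_ctrl = apply_filters(control, mq_only)
    sub = subtract(case_mq, ctrl_mq)
    af_depth = FilterThresholds(mq_min=0.0, af_min=th.af_min,
                                depth_policy=th.depth_policy,
                                depth_band_fraction=th.depth_band_fraction)
    final, t_final = apply_filters(sub.case_specific, af_depth)
    stages = {
        "case_mq_filter": t_case,
        "control_mq_filter": t_ctrl,
        "n_case_specific_pre_filter": len(sub.case_specific),
        "n_shared": len(sub.shared),
        "case_specific_af_depth_filter": t_final,
    }
    return final, stages
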