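"""Recruitment-kinetics double normalization for laser-ablation ROI traces.

Three regions of interest are measured per frame: the damage site (ROI1),
the whole cell (ROI2), and a background area outside the cell (ROI3).
After background correction (subtracting the mean ROI3 intensity), the
damage-site signal is normalized twice — once for expression level and once
for acquisition photobleaching — using the ``n_pre`` pre-damage frames:

    I(t) = [ mean_pre(ROI2') / ROI2'(t) ] * [ ROI1'(t) / mean_pre(ROI1') ]

With constant traces I(t) = 1; jointly rescaling ROI1' and ROI2' by any
positive factor (an expression-level change) leaves I(t) unchanged.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd


class TraceError(ValueError):
    pass


@dataclass
class RecruitmentTrace:
    """Per-frame ROI intensities with the pre-damage frame count."""

    t: np.ndarray
    roi1: np.ndarray
    roi2: np.ndarray
    roi3: np.ndarray
    n_pre: int
    background_pre_only: bool = False  # average ROI3 over pre-frames only

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.roi1 = np.asarray(self.roi1, dtype=float)
        self.roi2 = np.asarray(self.roi2, dtype=float)
        self.roi3 = np.asarray(self.roi3, dtype=float)
        n = len(self.t)
        if not (len(self.roi1) == len(self.roi2) == len(self.roi3) == n):
            raise TraceError("t, roi1, roi2, roi3 must have equal length")
        if not 1 <= self.n_pre < n:
            raise TraceError("need 1 <= n_pre < number of frames")

    @classmethod
    def from_csv(cls, path: str | os.PathLike, n_pre: int,
                 background_pre_only: bool = False) -> "RecruitmentTrace":
        df = pd.read_csv(path)
        missing = {"t", "roi1", "roi2", "roi3"} - set(df.columns)
        if missing:
            raise TraceError(f"missing columns {sorted(missing)} in {path}")
        return cls(t=df["t"].to_numpy(), roi1=df["roi1"].to_numpy(),
                   roi2=df["roi2"].to_numpy(), roi3=df["roi3"].to_numpy(),
                   n_pre=n_pre, background_pre_only=background_pre_only)


def background_correct(tr: RecruitmentTrace) -> tuple[np.ndarray, np.ndarray]:
    """ROI1'(t), ROI2'(t): subtract the mean background intensity.

    Pre-damage corrected intensities must stay positive; if not, the
    background ROI likely overlaps the cell and the trace is rejected.
    """
    bg_frames = tr.roi3[:tr.n_pre] if tr.background_pre_only else tr.roi3
    bg = float(np.mean(bg_frames))
    roi1p = tr.roi1 - bg
    roi2p = tr.roi2 - bg
    if np.any(roi1p[:tr.n_pre] <= 0) or np.any(roi2p[:tr.n_pre] <= 0):
        raise TraceError("pre-damage corrected intensity <= 0 after background "
                         "subtraction")
    return roi1p, roi2p


def double_normalize(tr: RecruitmentTrace) -> np.ndarray:
    """The double-normalized recruitment curve I(t)."""
    roi1p, roi2p = background_correct(tr)
    if np.any(roi2p == 0):
        raise TraceError("corrected whole-cell intensity is zero at some frame")
    pre1 = float(np.mean(roi1p[:tr.n_pre]))
    pre2 = float(np.mean(roi2p[:tr.n_pre]))
    return (pre2 / roi2p) * (roi1p / pre1)


def normalize_csv(in_path: str | os.PathLike, out_path: str | os.PathLike,
                  n_pre: int, background_pre_only: bool = False) -> pd.DataFrame:
    """CSV-to-CSV convenience wrapper: adds roi1p, roi2p and I_norm columns."""
    tr = RecruitmentTrace.from_csv(in_path, n_pre=n_pre,
                                   background_pre_only=background_pre_only)
    roi1p, roi2p = background_correct(tr)
    out = pd.DataFrame({"t": tr.t, "roi1": tr.roi1, "roi2": tr.roi2,
                        "roi3": tr.roi3, "roi1p": roi1p, "roi2p": roi2p,
                        "I_norm": double_normalize(tr)})
    out.to_csv(out_path, index=False)
    return out


def average_traces(curves: list[np.ndarray]) -> np.ndarray:
    """Cross-cell mean of normalized curves (frame-aligned)."""
    if not curves:
        raise TraceError("no curves to average")
    n = {len(c) for c in curves}
    if len(n) != 1:
        raise TraceError("curves must share the same number of frames")
    return np.mean(np.vstack(curves), axis=0)
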