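"""Decision layer: transform, windowed KS statistics, majority vote.

A read is compared against the positive and null indexes window by window
(non-overlapping 90-bp windows by default).  Within a window, both samples
are shifted by the mean of the null sample and floored at 1 — this
collapses random-length matches to a common value of 1 so the empirical
CDFs differ mainly where the positive matches are genuinely long.  The
two-sample Kolmogorov-Smirnov statistic of the transformed samples is then
compared against a calibrated threshold (0.25 for exact matching
statistics, 0.10 for pseudo-matching lengths); the read is called a match
— and ejected under depletion — iff a strict majority of windows exceeds
the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.stats import ks_2samp

from .errors import InsufficientDataError
from .matching import MatchProfile


@dataclass(frozen=True)
class WindowDecision:
    window_index: int
    ks_stat: float
    exceeds: bool


@dataclass(frozen=True)
class ClassifyConfig:
    """Operating point of the classifier.

    Defaults reproduce the published operating point: 90-bp windows inside
    180-base chunks, at most 4 chunks (720 bases), KS thresholds 0.25 (MS)
    and 0.10 (PML).
    """

    window_bp: int = 90
    ks_threshold_ms: float = 0.25
    ks_threshold_pml: float = 0.10
    chunk_bp: int = 180
    max_chunks: int = 4

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.chunk_bp % self.window_bp != 0:
            raise ValueError("window_bp must divide chunk_bp")
        for t in (self.ks_threshold_ms, self.ks_threshold_pml):
            if not 0.0 < t < 1.0:
                raise ValueError("KS thresholds must lie in (0,1)")

    def threshold_for(self, kind: str) -> float:
        return self.ks_threshold_ms if kind == "MS" else self.ks_threshold_pml


def transform(
    pos_vals: np.ndarray, null_vals: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Subtract the null-window mean from both samples and floor at 1."""
    pos_vals = np.asarray(pos_vals, dtype=np.float64)
    null_vals = np.asarray(null_vals, dtype=np.float64)
    if pos_vals.size == 0 or null_vals.size == 0:
        raise InsufficientDataError("empty window")
    mu = null_vals.mean()
    return np.maximum(pos_vals - mu, 1.0), np.maximum(null_vals - mu, 1.0)


def ks_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample two-sided KS statistic sup_x |ECDF_a(x) - ECDF_b(x)|."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("empty sample")
    return float(ks_2samp(a, b, alternative="two-sided", method="asymp").statistic)


def classify_read(
    pos_profile: MatchProfile,
    null_profile: MatchProfile,
    cfg: ClassifyConfig,
) -> Tuple[bool, List[WindowDecision]]:
    """Windowed KS + strict majority.

    Profiles are cut into ``len // window_bp`` full windows (a trailing
    partial window is discarded); the decision is True iff strictly more
    than half of the windows exceed the threshold for the profile kind.
    With an even window count an exact tie is *not* a majority.
    """
    if pos_profile.kind != null_profile.kind:
        raise ValueError("profiles have different kinds")
    if len(pos_profile) != len(null_profile):
        raise ValueError("profiles have different lengths")
    w = cfg.window_bp
    n_windows = len(pos_profile) // w
    if n_windows == 0:
        raise InsufficientDataError(
            f"need at least one full {w}-bp window, got {len(pos_profile)} bases"
        )
    threshold = cfg.threshold_for(pos_profile.kind)
    windows: List[WindowDecision] = []
    for wi in range(n_windows):
        sl = slice(wi * w, (wi + 1) * w)
        tp, tn = transform(pos_profile.values[sl], null_profile.values[sl])
        ks = ks_stat(tp, tn)
        windows.append(WindowDecision(wi, ks, ks > threshold))
    n_exceed = sum(wd.exceeds for wd in windows)
    return n_exceed > n_windows / 2, windows


def density_report(
    pos_profile: MatchProfile, null_profile: MatchProfile, path
) -> None:
    """Write a TSV of per-value counts for positive vs null profiles — the
    raw material for a positive-vs-null density comparison plot."""
    pv = np.asarray(pos_profile.values)
    nv = np.asarray(null_profile.values)
    if pv.size == 0 or nv.size == 0:
        raise InsufficientDataError("empty profile")
    values = np.union1d(pv, nv)
    with open(path, "wt") as fh:
        fh.write("value\tpos_count\tnull_count\n")
        for v in values:
            fh.write(f"{int(v)}\t{int((pv == v).sum())}\t{int((nv == v).sum())}\n")
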