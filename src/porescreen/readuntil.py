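"""Adaptive-sampling harness: chunked delivery, per-batch decisions,
ejection bookkeeping and evaluation metrics.

Nanopore control software delivers read data in ~0.4 s chunks (~180 bases
at ~450 bases/s).  This harness emulates that protocol on base space: a
read is delivered in ``chunk_bp`` slices up to ``max_chunks`` (720 bases
by default); after each batch the classifier is run and, if it calls a
match, the read is "ejected" at that batch and no further bases are
consumed.  The positive index holds depletion targets by default; with
``enrich=True`` the ejection action is inverted (non-matching reads are
ejected at the final batch) without changing the classifier.

Metric conventions: a correctly ejected target read is a true positive, an
ejected non-target read a false positive, a target read that is never
ejected a false negative, and a non-target read left alone a true
negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np

from .classify import ClassifyConfig, classify_read
from .errors import InsufficientDataError
from .index import MODE_MS, RLBWTIndex
from .matching import (
    MatchProfile,
    StreamState,
    matching_statistics,
    pseudo_matching_lengths,
)


@dataclass
class ReadOutcome:
    read_id: str
    truth_label: str  # "target" | "nontarget" | "."
    ejected: bool
    eject_batch: Optional[int]  # 1-based batch of ejection, None if kept
    bases_consumed: int
    n_windows: int = 0
    n_exceed: int = 0
    insufficient_data: bool = False


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float


def _ms_profile(index: RLBWTIndex, prefix: str) -> MatchProfile:
    """Two-pass MS of the read prefix, in the same backward orientation
    the PML stream uses, with values in delivery order."""
    ms = matching_statistics(index, prefix[::-1])
    return MatchProfile(values=ms.values[::-1].copy(), kind="MS")


def run_read(
    read: str,
    pos_index: RLBWTIndex,
    null_index: RLBWTIndex,
    cfg: ClassifyConfig,
    mode: str = "PML",
    read_id: str = "read",
    truth_label: str = ".",
    batch_independent: bool = False,
    enrich: bool = False,
) -> ReadOutcome:
    """Deliver ``read`` in chunks and decide per batch.

    By default the decision at each batch uses all complete windows
    accumulated since the read started.  With ``batch_independent=True``
    each 180-base batch is scored on its own (profile computed right-to-
    left within the batch, windows from that batch only).
    """
    read = read.upper()
    if mode == "MS":
        pos_index.require_mode(MODE_MS)
        null_index.require_mode(MODE_MS)
    delivered = 0
    pos_state = StreamState()
    null_state = StreamState()
    pos_vals: List[np.ndarray] = []
    null_vals: List[np.ndarray] = []
    outcome = ReadOutcome(
        read_id=read_id,
        truth_label=truth_label,
        ejected=False,
        eject_batch=None,
        bases_consumed=0,
    )
    matched = False
    any_decision = False
    for batch in range(1, cfg.max_chunks + 1):
        chunk = read[delivered : delivered + cfg.chunk_bp]
        if not chunk:
            break
        delivered += len(chunk)
        outcome.bases_consumed = delivered
        if batch_independent:
            # score this batch alone, right-to-left within the batch
            if mode == "PML":
                prof_p, _ = pseudo_matching_lengths(pos_index, chunk[::-1])
                prof_n, _ = pseudo_matching_lengths(null_index, chunk[::-1])
                pos_prof = MatchProfile(prof_p.values[::-1].copy(), "PML")
                null_prof = MatchProfile(prof_n.values[::-1].copy(), "PML")
            else:
                ms_p = matching_statistics(pos_index, chunk[::-1])
                ms_n = matching_statistics(null_index, chunk[::-1])
                pos_prof = MatchProfile(ms_p.values[::-1].copy(), "MS")
                null_prof = MatchProfile(ms_n.values[::-1].copy(), "MS")
        else:
            if mode == "PML":
                prof_p, pos_state = pseudo_matching_lengths(pos_index, chunk, pos_state)
                prof_n, null_state = pseudo_matching_lengths(null_index, chunk, null_state)
                pos_vals.append(prof_p.values)
                null_vals.append(prof_n.values)
                pos_prof = MatchProfile(np.concatenate(pos_vals), "PML")
                null_prof = MatchProfile(np.concatenate(null_vals), "PML")
            else:
                prefix = read[:delivered]
                pos_prof = _ms_profile(pos_index, prefix)
                null_prof = _ms_profile(null_index, prefix)
        try:
            decision, windows = classify_read(pos_prof, null_prof, cfg)
        except InsufficientDataError:
            continue
        any_decision = True
        outcome.n_windows = len(windows)
        outcome.n_exceed = sum(w.exceeds for w in windows)
        if decision:
            matched = True
            if not enrich:
                outcome.ejected = True
                outcome.eject_batch = batch
            break
    if not any_decision:
        outcome.insufficient_data = True
    if enrich and any_decision and not matched:
        # enrichment: eject reads the classifier never called a match
        outcome.ejected = True
        outcome.eject_batch = min(cfg.max_chunks, -(-len(read) // cfg.chunk_bp))
    return outcome


def evaluate(outcomes: Iterable[ReadOutcome]) -> Metrics:
    """Tally TP/FP/FN/TN and the derived rates.

    Degenerate denominators follow the usual conservative conventions:
    precision and recall default to 1.0 when their denominator is 0.
    """
    tp = fp = fn = tn = 0
    for o in outcomes:
        if o.truth_label not in ("target", "nontarget"):
            raise ValueError(f"read {o.read_id}: missing truth label")
        if o.truth_label == "target":
            if o.ejected:
                tp += 1
            else:
                fn += 1
        else:
            if o.ejected:
                fp += 1
            else:
                tn += 1
    total = tp + fp + fn + tn
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    specificity = tn / (tn + fp) if tn + fp else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / total if total else 0.0
    return Metrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
    )
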