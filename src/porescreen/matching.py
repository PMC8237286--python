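"""Query engine: LF steps, threshold-guided jumps, matching statistics and
streaming pseudo-matching lengths.

Both statistics are computed by a backward walk over the pattern.  At each
step the engine tries to extend the current match with the next pattern
character c: if the BWT character at the current row is already c, one LF
step extends the match; otherwise the engine *jumps* to the nearest run of
c above or below, choosing the side whose suffix shares the longer prefix
with the query — which is exactly what the precomputed threshold row
encodes.

* ``matching_statistics`` (MS): the exact two-pass algorithm.  Pass one
  records, for every pattern position, a text position whose suffix
  achieves the matching statistic (from SA samples at run boundaries);
  pass two turns positions into lengths by direct comparison against the
  retained text, reusing the previous length whenever positions chain.
* ``pseudo_matching_lengths`` (PML): the one-pass streaming surrogate — a
  running length incremented on BWT-character agreement and reset to zero
  on a jump.  PMLs never exceed the true MS, but long MSs yield long PMLs,
  which is what classification needs.  The computation suspends and
  resumes via an explicit :class:`StreamState`, matching chunked delivery.

Orientation: the recurrences are right-to-left over a pattern, but chunked
delivery is left-to-right over a read.  Arriving bases are consumed in
delivery order, each as one backward-extension step — equivalent to
computing PMLs of the reversed read.  Because the positive index carries
both strands and the null index is the reversed text, the classification
statistics are distribution-equivalent under this convention.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .errors import CapabilityError
from .index import MODE_MS, RLBWTIndex


@dataclass(frozen=True)
class MatchProfile:
    """Per-base MS or PML values, aligned to base order as delivered."""

    values: np.ndarray  # int64, one per queried base
    kind: str  # "MS" | "PML"

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class StreamState:
    """Resumable cursor for streaming PML computation."""

    row: int = 0  # start at the terminator row: deterministic, and the
    length: int = 0  # first base nearly always jumps anyway
    pos: int = -1  # text position candidate (MS engine only)
    bases_consumed: int = 0


class _CharAbsent(Exception):
    """Raised internally when the query character does not occur in the BWT."""


def lf_step(index: RLBWTIndex, row: int) -> int:
    """One LF step: the row of the suffix one character longer."""
    return index.lf(row)


def _jump(index: RLBWTIndex, row: int, c: int) -> Tuple[int, str, int]:
    """Threshold-guided jump to the nearest c-run boundary.

    Returns ``(new_row, side, ordinal)`` where side is ``"pred"`` (last row
    of the nearest c-run above) or ``"succ"`` (first row of the nearest
    c-run below) and ordinal is the c-run's index among c's runs.
    BWT[new_row] = c always.
    """
    starts = index._c_starts[c]
    if not starts:
        raise _CharAbsent
    index.probes += 1
    j = bisect_right(starts, row) - 1
    have_pred = j >= 0
    have_succ = j + 1 < len(starts)
    if have_pred and not have_succ:
        return starts[j] + index._c_lens[c][j] - 1, "pred", j
    if have_succ and not have_pred:
        return starts[j + 1], "succ", j + 1
    t = index._c_thr[c][j]  # threshold stored for the later run of the pair
    if row < t:
        return starts[j] + index._c_lens[c][j] - 1, "pred", j
    return starts[j + 1], "succ", j + 1


def jump(index: RLBWTIndex, row: int, c: str) -> Tuple[int, str]:
    """Public jump; requires BWT[row] != c and c present in the BWT."""
    code = index.encode(c)
    if code < 0:
        raise ValueError(f"character {c!r} absent from index alphabet")
    try:
        new_row, side, _ = _jump(index, row, code)
    except _CharAbsent:
        raise ValueError(f"character {c!r} does not occur in the BWT")
    return new_row, side


# ---------------------------------------------------------------------------
# exact matching statistics (two-pass)
# ---------------------------------------------------------------------------

def matching_statistics(index: RLBWTIndex, pattern: str) -> MatchProfile:
    """Exact matching statistics MS[0..m-1] of ``pattern`` against the
    indexed text: MS[i] is the length of the longest prefix of
    ``pattern[i:]`` occurring in any indexed document.

    Requires an MS-mode index (SA samples + retained text).
    """
    index.require_mode(MODE_MS)
    m = len(pattern)
    if m == 0:
        return MatchProfile(values=np.zeros(0, dtype=np.int64), kind="MS")
    text = index.text.text
    n = index.n

    # Pass 1 (right to left): maintain (row, pos) with pos = SA[row]; record
    # for every i a text position pos_i whose suffix attains MS[i].
    pos_list = np.empty(m, dtype=np.int64)
    row, pos = 0, n - 1
    for i in range(m - 1, -1, -1):
        c = index.encode(pattern[i])
        if c < 0 or c == index._sep_code:
            # character absent: MS[i] = 0; restart from the terminator row
            # to keep pos = SA[row] valid for subsequent steps
            pos_list[i] = -1
            row, pos = 0, n - 1
            continue
        k = index.run_at(row)
        if index._run_codes_l[k] == c:
            row = index.C[c] + index._run_occ_l[k] + (row - index._run_starts_l[k])
            pos -= 1
            pos_list[i] = pos
        else:
            try:
                new_row, side, j = _jump(index, row, c)
            except _CharAbsent:
                pos_list[i] = -1
                row, pos = 0, n - 1
                continue
            sample = (
                index._c_sa_last[c][j] if side == "pred" else index._c_sa_first[c][j]
            )
            row = index.lf_from_run(new_row, c, j)
            pos = sample - 1
            pos_list[i] = pos

    # Pass 2 (right to left): lengths from positions, chaining when
    # consecutive positions are consecutive in the text.
    ms = np.zeros(m, dtype=np.int64)
    for i in range(m - 1, -1, -1):
        p = pos_list[i]
        if p < 0:
            continue
        if i + 1 < m and pos_list[i + 1] >= 0 and p == pos_list[i + 1] - 1:
            ms[i] = ms[i + 1] + 1
            continue
        length = 0
        j = int(p)
        while i + length < m and j < n and pattern[i + length] == text[j]:
            length += 1
            j += 1
        ms[i] = length
    return MatchProfile(values=ms, kind="MS")


# ---------------------------------------------------------------------------
# pseudo-matching lengths (one pass, streaming)
# ---------------------------------------------------------------------------

def pml_step(
    index: RLBWTIndex, state: StreamState, c: str
) -> Tuple[StreamState, int]:
    """Consume one base: extend on BWT agreement, else reset and jump.

    Returns the updated state and the post-update length (the PML for this
    base).  A character absent from the index alphabet is a universal
    mismatch: length resets to 0 and the row is unchanged.
    """
    code = index.encode(c)
    row, length = state.row, state.length
    if code >= 0 and code != index._sep_code:
        k = index.run_at(row)
        if index._run_codes_l[k] == code:
            length += 1
            row = index.C[code] + index._run_occ_l[k] + (row - index._run_starts_l[k])
        else:
            length = 0
            try:
                new_row, _, j = _jump(index, row, code)
            except _CharAbsent:
                return (
                    replace(state, length=0, bases_consumed=state.bases_consumed + 1),
                    0,
                )
            row = index.lf_from_run(new_row, code, j)
    else:
        length = 0
    new_state = StreamState(
        row=row, length=length, pos=-1, bases_consumed=state.bases_consumed + 1
    )
    return new_state, length


def pseudo_matching_lengths(
    index: RLBWTIndex, pattern: str, state: Optional[StreamState] = None
) -> Tuple[MatchProfile, StreamState]:
    """Fold :func:`pml_step` over the bases of ``pattern`` in delivery
    order, resuming from ``state`` if given.  Splitting a read into chunks
    and passing the state between calls yields the same profile as a
    single call.
    """
    if state is None:
        state = StreamState()
    values = np.empty(len(pattern), dtype=np.int64)
    # hot loop: inline pml_step, keep state in locals
    row, length, consumed = state.row, state.length, state.bases_consumed
    encode = index.encode
    run_starts = index._run_starts_l
    run_codes = index._run_codes_l
    run_occ = index._run_occ_l
    C = index.C
    sep = index._sep_code
    for i, ch in enumerate(pattern):
        code = encode(ch)
        if code >= 0 and code != sep:
            k = index.run_at(row)
            if run_codes[k] == code:
                length += 1
                row = C[code] + run_occ[k] + (row - run_starts[k])
            else:
                length = 0
                try:
                    new_row, _, j = _jump(index, row, code)
                except _CharAbsent:
                    values[i] = 0
                    consumed += 1
                    continue
                row = index.lf_from_run(new_row, code, j)
        else:
            length = 0
        values[i] = length
        consumed += 1
    final = StreamState(row=row, length=length, pos=-1, bases_consumed=consumed)
    return MatchProfile(values=values, kind="PML"), final
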