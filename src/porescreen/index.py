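"""The r-index: run-length BWT, thresholds, and (MS mode) SA samples + text.

The index is the space-efficient substrate for backward search.  Its size
driver is ``r``, the number of maximal equal-letter runs of the BWT, which
grows far more slowly than the text length on repetitive collections such
as pan-genomes.  Components:

* run-length encoded BWT (one ``(char, length, start_row)`` triple per run)
  with per-character occurrence tables supporting O(log r) LF steps;
* **thresholds** — for every pair of consecutive same-character runs, a row
  attaining the minimum of the LCP array strictly between them; a threshold
  decides whether a mismatching query row should jump up to the preceding
  run or down to the following one;
* in MS mode only: SA samples at the first and last row of every run, and
  the text itself for the second-pass length computation.  A PML-mode index
  stores neither.

Construction is direct and in-memory (prefix-doubling suffix array, Kasai
LCP), sized for desk-scale references up to a few megabases.  Multiple
occurrences of the separator symbol are disambiguated by position, i.e. the
standard distinct-terminator emulation: ties among separator-led suffixes
break by suffix position, which makes the suffix array well defined.
"""

from __future__ import annotations

import struct
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import CapabilityError, IndexFormatError
from .reference import SEPARATOR, ConcatenatedText

MODE_MS = "MS"
MODE_PML = "PML"

_MAGIC = b"PSIX"
_VERSION = 2


# ---------------------------------------------------------------------------
# suffix array / BWT / LCP construction
# ---------------------------------------------------------------------------

def _as_text(text: Union[str, ConcatenatedText]) -> str:
    return text.text if isinstance(text, ConcatenatedText) else text


def _encode_distinct(s: str) -> np.ndarray:
    """Integer codes in which every separator occurrence is distinct.

    Separators receive codes 0..d-1 in position order (so separator-led
    suffixes sort by position); all other symbols receive codes >= d in
    byte order.  Comparisons on this encoding never equate two separators,
    which keeps matches from crossing document boundaries.
    """
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8).astype(np.int64)
    is_sep = arr == ord(SEPARATOR)
    d = int(is_sep.sum())
    out = np.empty(arr.shape, dtype=np.int64)
    out[is_sep] = np.arange(d, dtype=np.int64)
    other = arr[~is_sep]
    uniq = np.unique(other)
    out[~is_sep] = d + np.searchsorted(uniq, other)
    return out


def suffix_array(text: Union[str, ConcatenatedText]) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy lexsort).

    The text must end with the terminator; the terminator convention makes
    all suffixes distinct, so the result is a permutation of ``0..n-1``.
    """
    s = _as_text(text)
    if not s.endswith(SEPARATOR):
        raise ValueError("text must end with the terminator")
    rank = _encode_distinct(s)
    n = len(rank)
    if n == 1:
        return np.array([0], dtype=np.int64)
    order = np.argsort(rank, kind="stable")
    k = 1
    while True:
        rank2 = np.full(n, -1, dtype=np.int64)
        rank2[: n - k] = rank[k:]
        order = np.lexsort((rank2, rank))
        r1, r2 = rank[order], rank2[order]
        changed = np.ones(n, dtype=bool)
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:  # all ranks distinct
            return order.astype(np.int64)
        k *= 2


def bwt_from_sa(text: Union[str, ConcatenatedText], sa: Sequence[int]) -> str:
    """BWT[i] = text[sa[i]-1], wrapping to the terminator when sa[i] = 0."""
    s = _as_text(text)
    sa = np.asarray(sa, dtype=np.int64)
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    return arr[(sa - 1) % len(s)].tobytes().decode("ascii")


def run_length_encode(bwt: str) -> Tuple[List[Tuple[str, int, int]], int]:
    """Maximal equal-letter runs as ``(char, length, start_row)``; returns
    the run list and ``r``."""
    if not bwt:
        return [], 0
    arr = np.frombuffer(bwt.encode("ascii"), dtype=np.uint8)
    boundaries = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(arr)]])
    runs = [
        (chr(arr[s]), int(e - s), int(s)) for s, e in zip(starts, ends)
    ]
    return runs, len(runs)


def compute_lcp(text: Union[str, ConcatenatedText], sa: Sequence[int]) -> np.ndarray:
    """LCP array via Kasai's algorithm; LCP[0] = 0.

    Computed on the distinct-separator encoding, so two separator
    occurrences never contribute to a common prefix.
    """
    s = _as_text(text)
    enc = _encode_distinct(s).tolist()
    sa = np.asarray(sa, dtype=np.int64)
    n = len(s)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    rank_l = rank.tolist()
    sa_l = sa.tolist()
    lcp = [0] * n
    h = 0
    for i in range(n):
        ri = rank_l[i]
        if ri > 0:
            j = sa_l[ri - 1]
            while i + h < n and j + h < n and enc[i + h] == enc[j + h]:
                h += 1
            lcp[ri] = h
            if h:
                h -= 1
        else:
            h = 0
    return np.asarray(lcp, dtype=np.int64)


def compute_thresholds(
    runs: Sequence[Tuple[str, int, int]], lcp: Sequence[int]
) -> Dict[int, int]:
    """One threshold row per consecutive same-character run pair.

    For runs of character c ending at row e and next starting at row s, the
    threshold is the argmin of LCP over rows in ``(e, s]``; ties break to
    the smallest row so outputs are deterministic.  Keyed by the index of
    the later run.
    """
    lcp = np.asarray(lcp, dtype=np.int64)
    last_run_of: Dict[str, int] = {}
    thresholds: Dict[int, int] = {}
    for k, (ch, length, start) in enumerate(runs):
        if ch in last_run_of:
            pk = last_run_of[ch]
            pch, plen, pstart = runs[pk]
            e = pstart + plen - 1
            s = start
            t = int(e + 1 + np.argmin(lcp[e + 1 : s + 1]))
            thresholds[k] = t
        last_run_of[ch] = k
    return thresholds


# ---------------------------------------------------------------------------
# the index object
# ---------------------------------------------------------------------------

@dataclass
class RLBWTIndex:
    """Run-length BWT index with thresholds (and SA samples / text in MS
    mode).  Query navigation never materializes the BWT string: LF and rank
    are answered from run-level cumulative tables plus an in-run offset.
    """

    mode: str
    n: int
    alphabet: str  # sorted, separator first
    run_starts: np.ndarray  # int64[r]
    run_codes: np.ndarray  # uint8[r], codes into alphabet
    thr_by_run: np.ndarray  # int64[r]; threshold keyed by later run, -1 if none
    sep_rows: np.ndarray  # rows whose BWT char is the separator
    sep_targets: np.ndarray  # their LF images (position-order disambiguation)
    sa_first: Optional[np.ndarray] = None  # MS only: SA at first row of run
    sa_last: Optional[np.ndarray] = None  # MS only: SA at last row of run
    text: Optional[ConcatenatedText] = None  # MS only
    probes: int = field(default=0, compare=False)  # run-table probe counter

    # ---- derived tables -------------------------------------------------

    def __post_init__(self) -> None:
        self._finalize()

    def _finalize(self) -> None:
        sigma = len(self.alphabet)
        starts = np.asarray(self.run_starts, dtype=np.int64)
        codes = np.asarray(self.run_codes, dtype=np.int64)
        lens = np.diff(np.append(starts, self.n))
        counts = np.zeros(sigma, dtype=np.int64)
        np.add.at(counts, codes, lens)
        self.C = np.concatenate([[0], np.cumsum(counts)[:-1]]).tolist()
        run_occ = np.empty(len(starts), dtype=np.int64)
        self._c_starts: List[List[int]] = []
        self._c_lens: List[List[int]] = []
        self._c_cum: List[List[int]] = []
        self._c_runidx: List[List[int]] = []
        self._c_thr: List[List[int]] = []
        thr = np.asarray(self.thr_by_run, dtype=np.int64)
        for c in range(sigma):
            idxs = np.flatnonzero(codes == c)
            clens = lens[idxs]
            cum = np.concatenate([[0], np.cumsum(clens)[:-1]]).astype(np.int64)
            run_occ[idxs] = cum
            self._c_starts.append(starts[idxs].tolist())
            self._c_lens.append(clens.tolist())
            self._c_cum.append(cum.tolist())
            self._c_runidx.append(idxs.tolist())
            self._c_thr.append(thr[idxs[1:]].tolist() if len(idxs) > 1 else [])
        self._run_starts_l = starts.tolist()
        self._run_codes_l = codes.tolist()
        self._run_occ_l = run_occ.tolist()
        self._sep_rows_l = np.asarray(self.sep_rows, dtype=np.int64).tolist()
        self._sep_targets_l = np.asarray(self.sep_targets, dtype=np.int64).tolist()
        self._code_of = {ch: i for i, ch in enumerate(self.alphabet)}
        self._sep_code = self._code_of.get(SEPARATOR)
        if self.sa_first is not None:
            saf = np.asarray(self.sa_first, dtype=np.int64)
            sal = np.asarray(self.sa_last, dtype=np.int64)
            self._c_sa_first = [saf[np.asarray(ix, dtype=np.int64)].tolist() for ix in self._c_runidx]
            self._c_sa_last = [sal[np.asarray(ix, dtype=np.int64)].tolist() for ix in self._c_runidx]

    # ---- basic accessors -------------------------------------------------

    @property
    def r(self) -> int:
        return len(self._run_starts_l)

    def encode(self, ch: str) -> int:
        """Alphabet code of ``ch``, or -1 if absent from the index."""
        return self._code_of.get(ch, -1)

    def run_at(self, row: int) -> int:
        """Index of the run containing ``row`` (one table probe)."""
        self.probes += 1
        return bisect_right(self._run_starts_l, row) - 1

    def bwt_code(self, row: int) -> int:
        return self._run_codes_l[self.run_at(row)]

    def bwt_char(self, row: int) -> str:
        return self.alphabet[self.bwt_code(row)]

    def lf(self, row: int) -> int:
        """LF mapping: C[c] + rank_c(row) for c = BWT[row].

        Separator rows use a small explicit table because their F-column
        order follows separator *position*, not BWT row order.
        """
        k = self.run_at(row)
        c = self._run_codes_l[k]
        if c == self._sep_code:
            self.probes += 1
            j = bisect_right(self._sep_rows_l, row) - 1
            return self._sep_targets_l[j]
        return self.C[c] + self._run_occ_l[k] + (row - self._run_starts_l[k])

    def lf_from_run(self, row: int, c: int, j: int) -> int:
        """LF for a row known to lie in the j-th run of character ``c``
        (no probe needed)."""
        return self.C[c] + self._c_cum[c][j] + (row - self._c_starts[c][j])

    def decode_bwt(self) -> str:
        """Materialize the BWT string (testing / diagnostics only)."""
        lens = np.diff(np.append(self.run_starts, self.n))
        return "".join(
            self.alphabet[c] * int(l) for c, l in zip(self._run_codes_l, lens)
        )

    def require_mode(self, mode: str) -> None:
        if self.mode != mode:
            raise CapabilityError(
                f"index mode is {self.mode}; operation requires {mode}"
            )

    def __eq__(self, other) -> bool:  # field-for-field (derived tables excluded)
        if not isinstance(other, RLBWTIndex):
            return NotImplemented
        same = (
            self.mode == other.mode
            and self.n == other.n
            and self.alphabet == other.alphabet
            and np.array_equal(self.run_starts, other.run_starts)
            and np.array_equal(self.run_codes, other.run_codes)
            and np.array_equal(self.thr_by_run, other.thr_by_run)
            and np.array_equal(self.sep_rows, other.sep_rows)
            and np.array_equal(self.sep_targets, other.sep_targets)
        )
        if not same or self.mode == MODE_PML:
            return same
        return (
            np.array_equal(self.sa_first, other.sa_first)
            and np.array_equal(self.sa_last, other.sa_last)
            and self.text.text == other.text.text
            and self.text.doc_offsets == other.text.doc_offsets
            and self.text.role == other.text.role
        )


def build_index(text: ConcatenatedText, mode: str = MODE_PML) -> RLBWTIndex:
    """Assemble the index from a concatenated text.

    PML mode keeps only the run-length BWT and thresholds; MS mode
    additionally stores SA samples at run boundaries and the text itself.
    """
    if mode not in (MODE_MS, MODE_PML):
        raise ValueError(f"unknown mode {mode!r}")
    sa = suffix_array(text)
    bwt = bwt_from_sa(text, sa)
    lcp = compute_lcp(text, sa)
    runs, r = run_length_encode(bwt)
    thr_map = compute_thresholds(runs, lcp)
    alphabet = "".join(sorted(set(text.text)))
    code_of = {ch: i for i, ch in enumerate(alphabet)}
    run_starts = np.array([s for _, _, s in runs], dtype=np.int64)
    run_codes = np.array([code_of[ch] for ch, _, _ in runs], dtype=np.uint8)
    thr_by_run = np.full(r, -1, dtype=np.int64)
    for k, t in thr_map.items():
        thr_by_run[k] = t

    # separator LF table: BWT row i holding '$' corresponds to the separator
    # at position sa[i]-1; its F-column row is that separator's position rank.
    s = text.text
    sep_positions = np.flatnonzero(
        np.frombuffer(s.encode("ascii"), dtype=np.uint8) == ord(SEPARATOR)
    )
    bwt_arr = np.frombuffer(bwt.encode("ascii"), dtype=np.uint8)
    sep_rows = np.flatnonzero(bwt_arr == ord(SEPARATOR)).astype(np.int64)
    sep_pos_at_row = (sa[sep_rows] - 1) % len(s)
    sep_targets = np.searchsorted(sep_positions, sep_pos_at_row).astype(np.int64)

    kwargs = {}
    if mode == MODE_MS:
        lens = np.diff(np.append(run_starts, len(s)))
        kwargs["sa_first"] = sa[run_starts]
        kwargs["sa_last"] = sa[run_starts + lens - 1]
        kwargs["text"] = text
    return RLBWTIndex(
        mode=mode,
        n=len(s),
        alphabet=alphabet,
        run_starts=run_starts,
        run_codes=run_codes,
        thr_by_run=thr_by_run,
        sep_rows=sep_rows,
        sep_targets=sep_targets,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# serialization: magic, version, mode flag, length-prefixed tagged sections
# ---------------------------------------------------------------------------

def _write_section(fh, tag: bytes, payload: bytes) -> None:
    fh.write(tag + struct.pack("<Q", len(payload)) + payload)


def _arr_bytes(a: np.ndarray, dtype) -> bytes:
    return np.ascontiguousarray(np.asarray(a, dtype=dtype)).tobytes()


def save_index(index: RLBWTIndex, path) -> None:
    """Write the index as a single binary container (see module docstring
    of the format: magic, version, mode flag, tagged length-prefixed
    sections)."""
    with open(path, "wb") as fh:
        fh.write(_MAGIC + struct.pack("<HB", _VERSION, 1 if index.mode == MODE_MS else 0))
        _write_section(fh, b"ALPH", index.alphabet.encode("ascii"))
        _write_section(fh, b"NLEN", struct.pack("<q", index.n))
        _write_section(fh, b"RST_", _arr_bytes(index.run_starts, np.int64))
        _write_section(fh, b"RCD_", _arr_bytes(index.run_codes, np.uint8))
        _write_section(fh, b"THR_", _arr_bytes(index.thr_by_run, np.int64))
        _write_section(fh, b"SEPR", _arr_bytes(index.sep_rows, np.int64))
        _write_section(fh, b"SEPT", _arr_bytes(index.sep_targets, np.int64))
        if index.mode == MODE_MS:
            _write_section(fh, b"SAF_", _arr_bytes(index.sa_first, np.int64))
            _write_section(fh, b"SAL_", _arr_bytes(index.sa_last, np.int64))
            _write_section(fh, b"TXT_", index.text.text.encode("ascii"))
            _write_section(fh, b"DOF_", _arr_bytes(index.text.doc_offsets, np.int64))
            _write_section(fh, b"ROLE", index.text.role.encode("ascii"))
        _write_section(fh, b"END_", b"")


def _read_exact(fh, k: int) -> bytes:
    data = fh.read(k)
    if len(data) != k:
        raise IndexFormatError("truncated index file")
    return data


def load_index(path) -> RLBWTIndex:
    """Read an index written by :func:`save_index`; round-trips
    field-for-field."""
    with open(path, "rb") as fh:
        head = fh.read(7)
        if len(head) != 7 or head[:4] != _MAGIC:
            raise IndexFormatError(f"{path}: not a porescreen index (bad magic)")
        version, mode_flag = struct.unpack("<HB", head[4:])
        if version != _VERSION:
            raise IndexFormatError(f"{path}: unsupported index version {version}")
        sections = {}
        while True:
            tag = _read_exact(fh, 4)
            (size,) = struct.unpack("<Q", _read_exact(fh, 8))
            payload = _read_exact(fh, size)
            if tag == b"END_":
                break
            sections[tag] = payload
    required = [b"ALPH", b"NLEN", b"RST_", b"RCD_", b"THR_", b"SEPR", b"SEPT"]
    mode = MODE_MS if mode_flag else MODE_PML
    if mode == MODE_MS:
        required += [b"SAF_", b"SAL_", b"TXT_", b"DOF_", b"ROLE"]
    missing = [t for t in required if t not in sections]
    if missing:
        raise IndexFormatError(f"{path}: missing sections {missing}")
    kwargs = {}
    if mode == MODE_MS:
        kwargs["sa_first"] = np.frombuffer(sections[b"SAF_"], dtype=np.int64)
        kwargs["sa_last"] = np.frombuffer(sections[b"SAL_"], dtype=np.int64)
        kwargs["text"] = ConcatenatedText(
            text=sections[b"TXT_"].decode("ascii"),
            doc_offsets=np.frombuffer(sections[b"DOF_"], dtype=np.int64).tolist(),
            role=sections[b"ROLE"].decode("ascii"),
        )
    return RLBWTIndex(
        mode=mode,
        n=struct.unpack("<q", sections[b"NLEN"])[0],
        alphabet=sections[b"ALPH"].decode("ascii"),
        run_starts=np.frombuffer(sections[b"RST_"], dtype=np.int64),
        run_codes=np.frombuffer(sections[b"RCD_"], dtype=np.uint8),
        thr_by_run=np.frombuffer(sections[b"THR_"], dtype=np.int64),
        sep_rows=np.frombuffer(sections[b"SEPR"], dtype=np.int64),
        sep_targets=np.frombuffer(sections[b"SEPT"], dtype=np.int64),
        **kwargs,
    )
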