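"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — plain sorts, substring scans and
per-row string comparisons — and shares no code with the package's
run-length structures, so agreement is meaningful.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

SEP = "$"


def encode_distinct(s: str) -> List[Tuple[int, int]]:
    """Comparison keys making each separator occurrence distinct and
    smaller than every other symbol (ties by position)."""
    keys = []
    sep_rank = 0
    for ch in s:
        if ch == SEP:
            keys.append((0, sep_rank))
            sep_rank += 1
        else:
            keys.append((1, ord(ch)))
    return keys


def naive_suffix_array(s: str) -> List[int]:
    keys = encode_distinct(s)
    return sorted(range(len(s)), key=lambda i: keys[i:])


def naive_bwt_rotations(s: str) -> str:
    """BWT by sorting all rotations (single-terminator texts)."""
    keys = encode_distinct(s)
    n = len(s)
    rots = sorted(range(n), key=lambda i: keys[i:] + keys[:i])
    return "".join(s[(i - 1) % n] for i in rots)


def naive_lcp(s: str, sa: Sequence[int]) -> List[int]:
    keys = encode_distinct(s)
    out = [0] * len(sa)
    for r in range(1, len(sa)):
        a, b = keys[sa[r - 1] :], keys[sa[r] :]
        l = 0
        while l < len(a) and l < len(b) and a[l] == b[l]:
            l += 1
        out[r] = l
    return out


def naive_ms(documents: Sequence[str], pattern: str) -> List[int]:
    """MS[i] = length of the longest prefix of pattern[i:] occurring in
    any document (matches never cross documents)."""
    m = len(pattern)
    out = []
    for i in range(m):
        best = 0
        for l in range(m - i, 0, -1):
            sub = pattern[i : i + l]
            if any(sub in doc for doc in documents):
                best = l
                break
        out.append(best)
    return out


class NaiveFM:
    """Flat (non-run-length) FM structures over a text, driving the same
    extension/jump rules as the package's streaming engine."""

    def __init__(self, text: str):
        self.text = text
        self.sa = naive_suffix_array(text)
        n = len(text)
        self.bwt = "".join(text[(i - 1) % n] for i in self.sa)
        self.lcp = naive_lcp(text, self.sa)
        counts: Dict[str, int] = {}
        for ch in text:
            counts[ch] = counts.get(ch, 0) + 1
        self.C = {}
        acc = 0
        for ch in sorted(counts):
            self.C[ch] = acc
            acc += counts[ch]
        # thresholds between consecutive same-character runs, smallest-row
        # tie-break — recomputed here from the flat BWT and LCP
        self.thresholds: Dict[Tuple[str, int], int] = {}
        prev_run_end: Dict[str, int] = {}
        i = 0
        while i < n:
            j = i
            while j < n and self.bwt[j] == self.bwt[i]:
                j += 1
            ch = self.bwt[i]
            if ch in prev_run_end:
                e, s = prev_run_end[ch], i
                rows = range(e + 1, s + 1)
                t = min(rows, key=lambda r: (self.lcp[r], r))
                self.thresholds[(ch, i)] = t  # keyed by later run's start row
            prev_run_end[ch] = j - 1
            i = j

    def rank(self, ch: str, row: int) -> int:
        return self.bwt[:row].count(ch)

    def lf(self, row: int) -> int:
        ch = self.bwt[row]
        if ch == SEP:
            # separator F-rows follow separator position order
            sep_positions = [i for i, c in enumerate(self.text) if c == SEP]
            pos = (self.sa[row] - 1) % len(self.text)
            return sep_positions.index(pos)
        return self.C[ch] + self.rank(ch, row)

    def jump(self, row: int, ch: str):
        """Nearest-run boundary chosen by the threshold rule; returns
        (new_row, side) or None if ch is absent."""
        if ch not in self.bwt:
            return None
        above = [i for i in range(row) if self.bwt[i] == ch]
        below = [i for i in range(row + 1, len(self.bwt)) if self.bwt[i] == ch]
        if not above:
            return below[0], "succ"
        if not below:
            return above[-1], "pred"
        e, s = above[-1], below[0]
        # s is the first ch-row below `row`, hence the start of its run,
        # which is how thresholds are keyed
        t = self.thresholds[(ch, s)]
        return (e, "pred") if row < t else (s, "succ")

    def pml(self, consumed: str) -> List[int]:
        """Streaming rules (arrival order, backward extension) on the flat
        structures."""
        row, length = 0, 0
        out = []
        for ch in consumed:
            if ch in self.C and ch != SEP and ch in self.bwt:
                if self.bwt[row] == ch:
                    length += 1
                    row = self.lf(row)
                else:
                    length = 0
                    new_row, _ = self.jump(row, ch)
                    row = self.lf(new_row)
            else:
                length = 0
            out.append(length)
        return out


def lcp_strings(a: str, b: str) -> int:
    l = 0
    while l < len(a) and l < len(b) and a[l] == b[l] and a[l] != SEP:
        l += 1
    return l
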