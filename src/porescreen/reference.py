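"""Reference handling: FASTA input and positive / null text construction.

The classifier compares a read against two indexes built from the same
reference collection:

* the **positive text** — every reference record followed by its reverse
  complement, so matches on either strand are found by a single backward
  search;
* the **null text** — the character-wise *reversal* (not reverse complement)
  of each positive document.  Reversal preserves length, nucleotide
  frequencies and simple repeats such as homopolymers, so match lengths
  against the null text estimate what a read would score against random
  sequence of the same composition.

Documents are concatenated with a single separator symbol ``$`` between
consecutive documents and one final terminator.  ``$`` sorts before every
other symbol and never matches a read base, so matches cannot cross
document boundaries.  All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Sequence

from Bio import SeqIO

from .errors import AlphabetError, FastaFormatError

#: Document separator / terminator; must sort before A,C,G,N,T.
SEPARATOR = "$"

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (uppercase after normalization)."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise FastaFormatError(f"record {self.name!r} has an empty sequence")


@dataclass
class ConcatenatedText:
    """Separator-joined document collection; the substrate of the BWT.

    ``text`` is ``doc_0 $ doc_1 $ ... doc_{k-1} $`` with the trailing ``$``
    acting as the terminator.  ``doc_offsets`` holds the start position of
    each document.
    """

    text: str
    doc_offsets: List[int]
    role: str  # "positive" | "null"
    alphabet: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.text.endswith(SEPARATOR):
            raise ValueError("concatenated text must end with the terminator")
        self.alphabet = "".join(sorted(set(self.text)))

    @property
    def n(self) -> int:
        return len(self.text)

    @property
    def documents(self) -> List[str]:
        out = []
        for i, start in enumerate(self.doc_offsets):
            end = (
                self.doc_offsets[i + 1] - 1
                if i + 1 < len(self.doc_offsets)
                else len(self.text) - 1
            )
            out.append(self.text[start:end])
        return out


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> List[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into a list of records.

    Sequences are uppercased; record order follows file order.  A file with
    no ``>`` header, or an empty file, raises :class:`FastaFormatError`.
    """
    records: List[SequenceRecord] = []
    seen = set()
    with _open_maybe_gzip(path) as handle:
        first = handle.read(1)
        if first != ">":
            raise FastaFormatError(f"{path}: not FASTA (expected '>' as first byte)")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FastaFormatError(f"{path}: duplicate record name {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def read_reads(path) -> Iterator[SequenceRecord]:
    """Iterate reads from a FASTA or FASTQ file (format sniffed from the
    first byte)."""
    with _open_maybe_gzip(path) as handle:
        first = handle.read(1)
        if first not in (">", "@"):
            raise FastaFormatError(f"{path}: neither FASTA nor FASTQ")
        handle.seek(0)
        fmt = "fasta" if first == ">" else "fastq"
        for rec in SeqIO.parse(handle, fmt):
            yield SequenceRecord(rec.id, str(rec.seq).upper())


def revcomp(s: str) -> str:
    """Reverse complement with IUPAC-aware complementation (N stays N)."""
    s = s.upper()
    bad = set(s) - set("ACGTNRYSWKMBDHV")
    if bad:
        raise AlphabetError(f"cannot complement symbol(s) {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def _concatenate(documents: Sequence[str], role: str) -> ConcatenatedText:
    offsets = []
    pos = 0
    for doc in documents:
        offsets.append(pos)
        pos += len(doc) + 1
    text = SEPARATOR.join(documents) + SEPARATOR
    return ConcatenatedText(text=text, doc_offsets=offsets, role=role)


def concatenate_documents(
    documents: Sequence[str], role: str = "positive"
) -> ConcatenatedText:
    """Join raw documents with the separator convention (no strand
    doubling); useful for indexing arbitrary document collections."""
    if not documents:
        raise ValueError("no documents given")
    return _concatenate(documents, role)


def build_positive_text(records: Sequence[SequenceRecord]) -> ConcatenatedText:
    """Forward documents followed by their reverse complements, one block
    each, joined per the separator convention."""
    if not records:
        raise ValueError("no records given")
    docs = [r.seq for r in records] + [revcomp(r.seq) for r in records]
    return _concatenate(docs, role="positive")


def build_null_text(pos: ConcatenatedText) -> ConcatenatedText:
    """Character-reverse every positive document (no complementation).

    The null text is length-matched and composition-matched to the positive
    text; reversing it again recovers the positive documents exactly.
    """
    if pos.role != "positive":
        raise ValueError("build_null_text expects a positive text")
    docs = [doc[::-1] for doc in pos.documents]
    return _concatenate(docs, role="null")
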