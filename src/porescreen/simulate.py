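"""Synthetic fixtures: pan-genome-like references and nanopore-like reads.

The generator emulates the study conditions used throughout the package:
references are random DNA (optionally a strain collection derived from a
common ancestor by point mutations, giving the repetitive structure that
makes the r-index shine), and reads are reference substrings — either
strand — corrupted by substitutions, insertions and deletions at a
configurable mean accuracy (the 85–98% range typical of nanopore base
calls).  Non-target reads are i.i.d. uniform DNA of the same length, or
optionally substrings of a second, unrelated genome.

The error budget 1 - accuracy is split 55% substitutions / 25% insertions
/ 20% deletions, a fixed approximation of nanopore error composition.
All randomness flows through an explicit seed; the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .errors import ParameterError
from .reference import SequenceRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DEFAULT_ERROR_SPLIT = (0.55, 0.25, 0.20)  # sub, ins, del


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    seq: str
    origin_doc: str  # reference record name, or "random"
    origin_pos: int  # 0-based start on the forward strand (-1 for random)
    strand: str  # "+" | "-" ("." for random)
    truth_label: str  # "target" | "nontarget"
    mean_accuracy: float


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def make_pangenome(
    seed: int, base_len: int, n_strains: int, mut_rate: float
) -> List[SequenceRecord]:
    """One random ancestor plus ``n_strains - 1`` mutated copies.

    Each copy carries i.i.d. substitutions at ``mut_rate`` (always to a
    different base), emulating a strain collection at a given divergence.
    """
    if base_len < 1000:
        raise ParameterError("base_len must be >= 1000")
    if not 0 <= mut_rate < 0.1:
        raise ParameterError("mut_rate must be in [0, 0.1)")
    if n_strains < 1:
        raise ParameterError("n_strains must be >= 1")
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(_BASES, size=base_len)
    records = [SequenceRecord("strain0", ancestor.tobytes().decode("ascii"))]
    for k in range(1, n_strains):
        strain = ancestor.copy()
        mut = rng.random(base_len) < mut_rate
        idx = np.flatnonzero(mut)
        # substitute with one of the three other bases
        shifts = rng.integers(1, 4, size=len(idx))
        base_idx = np.searchsorted(_BASES, strain[idx])
        strain[idx] = _BASES[(base_idx + shifts) % 4]
        records.append(SequenceRecord(f"strain{k}", strain.tobytes().decode("ascii")))
    return records


def _corrupt(
    rng: np.random.Generator,
    source: str,
    start: int,
    read_len: int,
    error_rate: float,
    split: Sequence[float],
) -> str:
    """Emit ``read_len`` bases from ``source[start:]`` with errors.

    Per emitted position: substitution with probability e*split[0]
    (different base), insertion e*split[1] (random base, source not
    advanced), deletion e*split[2] (source base skipped, nothing emitted).
    """
    p_sub, p_ins, p_del = (error_rate * s for s in split)
    out = []
    j = start
    n = len(source)
    while len(out) < read_len and j < n:
        u = rng.random()
        if u < p_del:
            j += 1
        elif u < p_del + p_ins:
            out.append(chr(_BASES[rng.integers(4)]))
        elif u < p_del + p_ins + p_sub:
            orig = source[j]
            choices = [b for b in "ACGT" if b != orig]
            out.append(choices[rng.integers(3)])
            j += 1
        else:
            out.append(source[j])
            j += 1
    while len(out) < read_len:  # ran off the end: pad with random bases
        out.append(chr(_BASES[rng.integers(4)]))
    return "".join(out)


def simulate_reads(
    refs: Sequence[SequenceRecord],
    n_reads: int,
    read_len: int,
    accuracy: float,
    frac_nontarget: float,
    seed: int,
    error_split: Sequence[float] = _DEFAULT_ERROR_SPLIT,
    nontarget_refs: Optional[Sequence[SequenceRecord]] = None,
) -> List[SimulatedRead]:
    """Target reads from ``refs`` (uniform record, position and strand) at
    the given mean accuracy; non-target reads are uniform random DNA (or
    substrings of ``nontarget_refs`` when given, emulating an unrelated
    organism)."""
    if not 0.5 < accuracy <= 1.0:
        raise ParameterError("accuracy must be in (0.5, 1]")
    if not 0.0 <= frac_nontarget <= 1.0:
        raise ParameterError("frac_nontarget must be in [0, 1]")
    if abs(sum(error_split) - 1.0) > 1e-9:
        raise ParameterError("error_split must sum to 1")
    if read_len > min(len(r.seq) for r in refs):
        raise ParameterError("read_len exceeds the shortest reference")
    rng = np.random.default_rng(seed)
    error_rate = 1.0 - accuracy
    n_nontarget = int(round(n_reads * frac_nontarget))
    n_target = n_reads - n_nontarget
    reads: List[SimulatedRead] = []
    # source slack: deletions consume extra source bases
    slack = int(np.ceil(read_len * (1 + 2 * error_rate))) + 10
    for i in range(n_target):
        rec = refs[rng.integers(len(refs))]
        strand = "+" if rng.random() < 0.5 else "-"
        template = rec.seq if strand == "+" else revcomp(rec.seq)
        max_start = max(len(template) - slack, 0)
        start = int(rng.integers(max_start + 1))
        seq = _corrupt(rng, template, start, read_len, error_rate, error_split)
        # origin_pos reported on the forward strand
        origin_pos = start if strand == "+" else len(rec.seq) - start - read_len
        reads.append(
            SimulatedRead(
                read_id=f"r{i}_target",
                seq=seq,
                origin_doc=rec.name,
                origin_pos=max(origin_pos, 0),
                strand=strand,
                truth_label="target",
                mean_accuracy=accuracy,
            )
        )
    if nontarget_refs is not None:
        decoys = simulate_reads(
            nontarget_refs, n_nontarget, read_len, accuracy, 0.0, int(rng.integers(2**31)),
            error_split=error_split,
        )
        for i, d in enumerate(decoys):
            reads.append(
                SimulatedRead(
                    read_id=f"r{n_target + i}_nontarget",
                    seq=d.seq,
                    origin_doc=d.origin_doc,
                    origin_pos=d.origin_pos,
                    strand=d.strand,
                    truth_label="nontarget",
                    mean_accuracy=accuracy,
                )
            )
    else:
        for i in range(n_nontarget):
            reads.append(
                SimulatedRead(
                    read_id=f"r{n_target + i}_nontarget",
                    seq=_random_dna(rng, read_len),
                    origin_doc="random",
                    origin_pos=-1,
                    strand=".",
                    truth_label="nontarget",
                    mean_accuracy=accuracy,
                )
            )
    return reads


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n{rec.seq}\n")


def write_reads_fastq(reads: Sequence[SimulatedRead], path) -> None:
    """FASTQ with a constant placeholder quality line."""
    with open(path, "wt") as fh:
        for rd in reads:
            fh.write(f"@{rd.read_id}\n{rd.seq}\n+\n{'?' * len(rd.seq)}\n")
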