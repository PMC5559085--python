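"""Raw-read quality control and pair merging.

Read pairs are dropped when either mate's mean phred score falls below 15
or more than 5% of its bases are N; surviving pairs are merged into one
full-length sequence by an exhaustive overlap search, resolving overlap
disagreements toward the higher-quality base.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .simulate import revcomp

DEFAULT_MIN_MEAN_Q = 15.0
DEFAULT_MAX_N_FRAC = 0.05
DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_RATE = 0.1


class FastqFormatError(ValueError):
    pass


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    qual1: tuple[int, ...]
    qual2: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise FastqFormatError(
                f"{self.read_id}: sequence/quality length mismatch"
            )


@dataclass
class MergedSequence:
    read_id: str
    sequence: str
    overlap_len: int
    n_mismatches_in_overlap: int


def quality_filter(
    pair: ReadPair,
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
    max_n_frac: float = DEFAULT_MAX_N_FRAC,
) -> tuple[bool, str]:
    """Keep/drop decision with reason code.

    Reasons: ``low_quality`` (either mate's arithmetic mean phred score
    below ``min_mean_q``), ``n_excess`` (N fraction above ``max_n_frac``),
    ``ok``.
    """
    for seq, qual in ((pair.seq1, pair.qual1), (pair.seq2, pair.qual2)):
        if np.mean(qual) < min_mean_q:
            return False, "low_quality"
    for seq, qual in ((pair.seq1, pair.qual1), (pair.seq2, pair.qual2)):
        if seq.count("N") / len(seq) > max_n_frac:
            return False, "n_excess"
    return True, "ok"


def merge_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> MergedSequence | None:
    """Merge a pair into one sequence, or return None if no valid overlap.

    Mate 2 is reverse-complemented; every overlap length from the maximum
    down to ``min_overlap`` is scored, the one with the most matching bases
    wins (ties toward the longer overlap), subject to the mismatch-rate
    ceiling.  Disagreeing overlap positions take the higher-quality base
    (mate 1 on quality ties).
    """
    s1 = np.frombuffer(pair.seq1.encode(), dtype=np.uint8)
    rc2 = revcomp(pair.seq2)
    s2 = np.frombuffer(rc2.encode(), dtype=np.uint8)
    q1 = np.asarray(pair.qual1)
    q2 = np.asarray(pair.qual2)[::-1]

    best: tuple[int, int] | None = None  # (matches, overlap_len)
    max_l = min(len(s1), len(s2))
    for L in range(max_l, min_overlap - 1, -1):
        matches = int((s1[len(s1) - L :] == s2[:L]).sum())
        if (L - matches) / L > max_mismatch_rate:
            continue
        if best is None or matches > best[0]:
            best = (matches, L)
    if best is None:
        return None
    matches, L = best
    head = pair.seq1[: len(s1) - L]
    tail = rc2[L:]
    ov1 = s1[len(s1) - L :]
    ov2 = s2[:L]
    take2 = q2[:L] > q1[len(s1) - L :]
    consensus = np.where(take2, ov2, ov1).tobytes().decode()
    return MergedSequence(
        read_id=pair.read_id,
        sequence=head + consensus + tail,
        overlap_len=L,
        n_mismatches_in_overlap=L - matches,
    )


def read_pairs(fastq1: str | Path, fastq2: str | Path) -> Iterator[ReadPair]:
    """Iterate paired phred+33 FASTQ files in lockstep."""
    it1 = SeqIO.parse(str(fastq1), "fastq")
    it2 = SeqIO.parse(str(fastq2), "fastq")
    for rec1, rec2 in itertools.zip_longest(it1, it2):
        if rec1 is None or rec2 is None:
            raise FastqFormatError("paired FASTQ files differ in record count")
        yield ReadPair(
            read_id=rec1.id.rsplit("/", 1)[0],
            seq1=str(rec1.seq).upper(),
            seq2=str(rec2.seq).upper(),
            qual1=tuple(rec1.letter_annotations["phred_quality"]),
            qual2=tuple(rec2.letter_annotations["phred_quality"]),
        )


def process_pairs(
    pairs: Iterable[ReadPair],
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
    max_n_frac: float = DEFAULT_MAX_N_FRAC,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> tuple[list[MergedSequence], dict[str, int]]:
    """QC-filter and merge an iterable of pairs; returns merged + counts.

    The report accounts for every input pair exactly once:
    ``reads_in = dropped_low_quality + dropped_n_excess + merged + unmerged``.
    """
    report = {
        "reads_in": 0,
        "dropped_low_quality": 0,
        "dropped_n_excess": 0,
        "merged": 0,
        "unmerged": 0,
    }
    merged: list[MergedSequence] = []
    for pair in pairs:
        report["reads_in"] += 1
        keep, reason = quality_filter(pair, min_mean_q, max_n_frac)
        if not keep:
            report[f"dropped_{reason}"] += 1
            continue
        m = merge_pair(pair, min_overlap, max_mismatch_rate)
        if m is None:
            report["unmerged"] += 1
        else:
            report["merged"] += 1
            merged.append(m)
    return merged, report


def write_merged_fasta(merged: Iterable[MergedSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in merged:
            fh.write(f">{m.read_id}\n{m.sequence}\n")


def write_qc_report(report: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tcount\n")
        for key, value in report.items():
            fh.write(f"{key}\t{value}\n")
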