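"""V/(D)/J assignment, CDR3 extraction and junction decomposition.

Merged sequences are locally aligned (Smith-Waterman, match +1 / mismatch
-1 / gap open -3 / gap extend -1) against every functional V and J gene;
the best-scoring gene wins per segment.  A shared-k-mer prescreen bounds
the number of full alignments per read; it can be disabled for exhaustive
search.  The CDR3 spans the conserved V cysteine codon through the J
[FW]GXG phenylalanine/tryptophan codon, both inclusive.  The junction is
decomposed into the canonical seven sections (3'V / 5'D / 3'D / 5'J
deletions, V-D / D-J or V-J insertions) under the maximal-germline-match
parse convention of :mod:`vdjprof._junction`.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from . import germline as gl
from ._junction import place_d

logger = logging.getLogger(__name__)

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -3, -1


@dataclass
class AnnotationConfig:
    min_v_length: int = 40
    min_v_identity: float = 0.80
    min_j_length: int = 15
    min_j_identity: float = 0.80
    min_d_match: int = 5
    prescreen_top: int | None = 8   # None = exhaustive scoring of all genes
    boundary_min_run: int = 10      # trailing exact-match run anchoring a boundary
    collapse_max_dist: int = 1
    collapse_ratio: float = 0.01


@dataclass
class Alignment:
    """Local alignment of one germline gene against a read.

    Coordinates are 1-based inclusive; ``blocks`` holds the gapless aligned
    segments as ``(query_start, ref_start, length)`` (0-based starts).
    ``mismatch_positions`` lists ``(ref_pos, ref_base, query_base)``.
    """

    gene_name: str
    score: float
    identity: float
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    mismatch_positions: list[tuple[int, str, str]] = field(default_factory=list)
    blocks: list[tuple[int, int, int]] = field(default_factory=list)
    tie: bool = False

    def map_ref_to_query(self, ref_pos: int) -> int | None:
        """Query position (1-based) aligned to a 1-based reference position."""
        for q0, r0, length in self.blocks:
            if r0 < ref_pos <= r0 + length:
                return q0 + (ref_pos - r0)
        return None


@dataclass
class Annotation:
    read_id: str
    locus: str
    v: Alignment | None = None
    j: Alignment | None = None
    d: Alignment | None = None
    cdr3_nt: str | None = None
    cdr3_aa: str | None = None
    productive: bool = False
    productive_reason: str = ""
    status: str = "ok"  # ok | unassigned_v | unassigned_j | no_cdr3 | junction_conflict
    del_3v: int | None = None
    del_5d: int | None = None
    del_3d: int | None = None
    del_5j: int | None = None
    ins_vd: str | None = None
    ins_dj: str | None = None
    ins_vj: str | None = None
    read_count: int = 1


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


class SegmentAligner:
    """Best-gene local alignment for one segment with k-mer prescreen."""

    def __init__(self, genes: Sequence[gl.GermlineGene], k: int,
                 prescreen_top: int | None):
        if not genes:
            raise ValueError("empty gene collection")
        self.genes = sorted(genes, key=lambda g: g.gene_name)
        self.k = k
        self.top = prescreen_top
        self._aligner = _make_aligner()
        self._kmer_sets = [
            frozenset(g.sequence[i : i + k] for i in range(len(g.sequence) - k + 1))
            for g in self.genes
        ]

    def _candidates(self, read: str) -> list[int]:
        if self.top is None or self.top >= len(self.genes):
            return list(range(len(self.genes)))
        kmers = {read[i : i + self.k] for i in range(len(read) - self.k + 1)}
        shared = [len(kmers & s) for s in self._kmer_sets]
        order = sorted(range(len(self.genes)), key=lambda i: (-shared[i], i))
        return order[: self.top]

    def best(self, read: str) -> Alignment | None:
        """Highest-scoring gene; score ties go to the smaller gene name."""
        scored = [
            (self._aligner.score(read, self.genes[i].sequence), i)
            for i in self._candidates(read)
        ]
        if not scored:
            return None
        best_score = max(s for s, _ in scored)
        winners = sorted(i for s, i in scored if s == best_score)
        aln = self._full_alignment(read, winners[0])  # genes are name-sorted
        aln.tie = len(winners) > 1
        return aln

    def _full_alignment(self, read: str, gene_idx: int) -> Alignment:
        gene = self.genes[gene_idx]
        result = self._aligner.align(read, gene.sequence)[0]
        q_blocks, r_blocks = result.aligned
        blocks, mismatches, matched = [], [], 0
        for (q0, q1), (r0, r1) in zip(q_blocks, r_blocks):
            blocks.append((int(q0), int(r0), int(q1 - q0)))
            for off in range(q1 - q0):
                qb, rb = read[q0 + off], gene.sequence[r0 + off]
                if qb == rb:
                    matched += 1
                else:
                    mismatches.append((int(r0 + off + 1), rb, qb))
        ncols = sum(b[2] for b in blocks)
        return Alignment(
            gene_name=gene.gene_name,
            score=float(result.score),
            identity=matched / ncols if ncols else 0.0,
            query_start=int(q_blocks[0][0]) + 1,
            query_end=int(q_blocks[-1][1]),
            ref_start=int(r_blocks[0][0]) + 1,
            ref_end=int(r_blocks[-1][1]),
            mismatch_positions=mismatches,
            blocks=blocks,
        )


def _refined_v_end(aln: Alignment, min_run: int) -> tuple[int, int]:
    """(query_end, ref_end) after trimming unanchored alignment tails.

    Walking from the 3' end, any terminal exact-match run shorter than
    ``min_run`` — together with the mismatch or gap that precedes it — is
    discarded, so the boundary rests on solid germline evidence rather than
    on chance matches of N-nucleotides.
    """
    cols = _columns(aln)
    while cols:
        run = 0
        while run < len(cols) and cols[-1 - run][2]:
            run += 1
        if run == len(cols) or run >= min_run:
            break
        del cols[len(cols) - run - 1 :]
    if not cols:
        cols = _columns(aln)  # degenerate: keep the raw SW boundary
    return cols[-1][0], cols[-1][1]


def _refined_j_start(aln: Alignment, min_run: int) -> tuple[int, int]:
    cols = _columns(aln)
    while cols:
        run = 0
        while run < len(cols) and cols[run][2]:
            run += 1
        if run == len(cols) or run >= min_run:
            break
        del cols[: run + 1]
    if not cols:
        cols = _columns(aln)
    return cols[0][0], cols[0][1]


def _columns(aln: Alignment) -> list[tuple[int | None, int | None, bool]]:
    """Aligned columns as (query_pos, ref_pos, is_match), 1-based.

    A sentinel non-match column marks every gap between blocks so that
    indel columns break exact-match runs during boundary refinement.
    """
    mm = {pos for pos, _r, _q in aln.mismatch_positions}
    cols: list[tuple[int | None, int | None, bool]] = []
    for bi, (q0, r0, length) in enumerate(aln.blocks):
        if bi:
            cols.append((None, None, False))
        for off in range(length):
            rpos = r0 + off + 1
            cols.append((q0 + off + 1, rpos, rpos not in mm))
    return cols


class Annotator:
    """Caches per-segment aligners for one functional germline database."""

    def __init__(self, db: gl.GermlineDatabase, config: AnnotationConfig | None = None):
        self.config = config or AnnotationConfig()
        if not db.v_genes or not db.j_genes:
            raise ValueError("annotation requires a functional-filtered V+J database")
        self.db = db
        self._v = SegmentAligner(db.v_genes, k=11, prescreen_top=self.config.prescreen_top)
        self._j = SegmentAligner(db.j_genes, k=7, prescreen_top=self.config.prescreen_top)

    # -- spec operations -------------------------------------------------
    def assign_vj(self, sequence: str) -> tuple[Alignment | None, Alignment | None]:
        cfg = self.config
        v = self._v.best(sequence)
        if v is not None and (
            v.ref_end - v.ref_start + 1 < cfg.min_v_length
            or v.identity < cfg.min_v_identity
        ):
            v = None
        j = self._j.best(sequence)
        if j is not None and (
            j.ref_end - j.ref_start + 1 < cfg.min_j_length
            or j.identity < cfg.min_j_identity
        ):
            j = None
        return v, j

    def extract_cdr3(
        self, sequence: str, v: Alignment, j: Alignment
    ) -> tuple[str, str | None] | None:
        """CDR3 from the V anchor-Cys codon through the J anchor-F/W codon."""
        v_anchor = self.db.get(v.gene_name).anchor_pos
        j_anchor = self.db.get(j.gene_name).anchor_pos
        q_c = v.map_ref_to_query(v_anchor)
        q_f = j.map_ref_to_query(j_anchor)
        q_f_end = j.map_ref_to_query(j_anchor + 2)
        if None in (q_c, q_f, q_f_end) or q_f_end != q_f + 2 or q_f <= q_c:
            return None
        cdr3_nt = sequence[q_c - 1 : q_f + 2]
        cdr3_aa = (
            str(Seq(cdr3_nt).translate()) if len(cdr3_nt) % 3 == 0 else None
        )
        return cdr3_nt, cdr3_aa

    def classify_productive(
        self, sequence: str, ann: Annotation
    ) -> tuple[bool, str]:
        """In-frame, stop-free, functional-gene test in the C-anchored frame."""
        v_gene = self.db.get(ann.v.gene_name)
        j_gene = self.db.get(ann.j.gene_name)
        if not (v_gene.functional and j_gene.functional):
            return False, "nonfunctional_gene"
        if len(ann.cdr3_nt) % 3 != 0:
            return False, "out_of_frame"
        q_c = ann.v.map_ref_to_query(v_gene.anchor_pos)
        end = ann.j.query_end
        span = sequence[q_c - 1 : q_c - 1 + 3 * ((end - q_c + 1) // 3)]
        if "*" in str(Seq(span).translate()):
            return False, "stop_codon"
        return True, "ok"

    def assign_d_and_decompose(self, sequence: str, ann: Annotation) -> None:
        """Fill the seven junction sections on ``ann`` in place."""
        cfg = self.config
        v, j = ann.v, ann.j
        vq, vr = _refined_v_end(v, cfg.boundary_min_run)
        jq, jr = _refined_j_start(j, cfg.boundary_min_run)
        if vq >= jq:  # V/J alignments overlap on the read: trim the weaker
            overlap = vq - jq + 1
            if v.score >= j.score:
                jq, jr = jq + overlap, jr + overlap
                if jr > len(self.db.get(j.gene_name).sequence):
                    ann.status = "junction_conflict"
                    return
            else:
                vq, vr = vq - overlap, vr - overlap
                if vr < 1:
                    ann.status = "junction_conflict"
                    return
        v_len = len(self.db.get(v.gene_name).sequence)
        ann.del_3v = v_len - vr
        ann.del_5j = jr - 1
        gap = sequence[vq : jq - 1]
        if self.db.locus in gl.D_LOCI:
            hit = place_d(gap, self.db.d_genes, cfg.min_d_match)
            if hit is None:
                ann.d = None
                ann.ins_vd, ann.ins_dj = gap, ""
                ann.del_5d = ann.del_3d = 0
            else:
                d_ref = self.db.get(hit.gene_name)
                ann.del_5d = hit.d_start
                ann.del_3d = len(d_ref) - (hit.d_start + hit.length)
                ann.ins_vd = gap[: hit.gap_start]
                ann.ins_dj = gap[hit.gap_start + hit.length :]
                ann.d = Alignment(
                    gene_name=hit.gene_name, score=float(hit.length), identity=1.0,
                    query_start=vq + hit.gap_start + 1,
                    query_end=vq + hit.gap_start + hit.length,
                    ref_start=hit.d_start + 1, ref_end=hit.d_start + hit.length,
                    blocks=[(vq + hit.gap_start, hit.d_start, hit.length)],
                )
            ann.ins_vj = None
        else:
            ann.ins_vj = gap
            ann.ins_vd = ann.ins_dj = None
            ann.del_5d = ann.del_3d = None

    # -- orchestration ---------------------------------------------------
    def annotate(self, read_id: str, sequence: str, read_count: int = 1) -> Annotation:
        ann = Annotation(read_id=read_id, locus=self.db.locus, read_count=read_count)
        v, j = self.assign_vj(sequence)
        ann.v, ann.j = v, j
        if v is None or j is None:
            ann.status = "unassigned_v" if v is None else "unassigned_j"
            return ann
        cdr3 = self.extract_cdr3(sequence, v, j)
        if cdr3 is None:
            ann.status = "no_cdr3"
            return ann
        ann.cdr3_nt, ann.cdr3_aa = cdr3
        ann.productive, ann.productive_reason = self.classify_productive(sequence, ann)
        self.assign_d_and_decompose(sequence, ann)
        return ann


# ---------------------------------------------------------------------------
# module-level convenience wrappers (single calls; Annotator caches indexes)

def assign_vj(sequence: str, db: gl.GermlineDatabase,
              config: AnnotationConfig | None = None):
    return Annotator(db, config).assign_vj(sequence)


def extract_cdr3(sequence: str, v: Alignment, j: Alignment, db: gl.GermlineDatabase,
                 config: AnnotationConfig | None = None):
    return Annotator(db, config).extract_cdr3(sequence, v, j)


def split_igkl(
    sequence: str,
    igk: "Annotator | gl.GermlineDatabase",
    igl: "Annotator | gl.GermlineDatabase",
) -> str:
    """Assign a light-chain read to IGK or IGL by best V-alignment score.

    Returns ``"IGK"``, ``"IGL"`` or ``"unresolved"`` (equal best scores).
    """
    if isinstance(igk, gl.GermlineDatabase):
        igk = Annotator(igk)
    if isinstance(igl, gl.GermlineDatabase):
        igl = Annotator(igl)
    vk = igk._v.best(sequence)
    vl = igl._v.best(sequence)
    sk = vk.score if vk else float("-inf")
    sl = vl.score if vl else float("-inf")
    if sk == sl:
        return "unresolved"
    return "IGK" if sk > sl else "IGL"


def collapse_errors(
    counts: pd.DataFrame,
    max_dist: int = 1,
    ratio: float = 0.01,
) -> pd.DataFrame:
    """Absorb likely PCR/sequencing-error clonotypes into their parents.

    ``counts`` has columns cdr3_nt, v_gene, j_gene, read_count (one row per
    clonotype).  A clonotype is merged into a larger one when both share V
    and J, their CDR3s differ by at most ``max_dist`` substitutions, and
    its abundance is at most ``ratio`` times the larger one's.  Applied in
    one pass, largest absorbers first.
    """
    df = counts.sort_values(
        ["read_count", "cdr3_nt"], ascending=[False, True]
    ).reset_index(drop=True)
    original = df["read_count"].to_numpy().copy()
    groups: dict[tuple, list[int]] = defaultdict(list)
    for i, row in df.iterrows():
        groups[(row.v_gene, row.j_gene, len(row.cdr3_nt))].append(i)
    absorbed: set[int] = set()
    gained = Counter()
    for key, members in groups.items():
        for ai in members:  # descending original abundance within group
            if ai in absorbed:
                continue
            for bi in members:
                if bi <= ai or bi in absorbed:
                    continue
                if original[bi] > ratio * original[ai]:
                    continue
                a, b = df.at[ai, "cdr3_nt"], df.at[bi, "cdr3_nt"]
                if sum(x != y for x, y in zip(a, b)) <= max_dist:
                    absorbed.add(bi)
                    gained[ai] += original[bi]
    df["read_count"] = original
    for ai, extra in gained.items():
        df.at[ai, "read_count"] += extra
    return df.drop(index=list(absorbed)).reset_index(drop=True)


# ---------------------------------------------------------------------------
# repertoire-scale driver

def annotate_repertoire(
    merged: Iterable,
    db: gl.GermlineDatabase,
    config: AnnotationConfig | None = None,
) -> tuple[list[Annotation], dict[str, int]]:
    """Annotate merged sequences, deduplicating identical ones.

    ``merged`` yields objects with ``read_id`` and ``sequence`` attributes
    (e.g. :class:`~vdjprof.preprocess.MergedSequence`).  Identical sequences
    are annotated once and carry their summed read count.
    """
    annotator = Annotator(db, config)
    buckets: dict[str, list[str]] = defaultdict(list)
    for m in merged:
        buckets[m.sequence].append(m.read_id)
    annotations = []
    summary = Counter(
        reads_in=0, unassigned=0, no_cdr3=0, junction_conflict=0,
        nonproductive_out_of_frame=0, nonproductive_stop_codon=0,
        nonproductive_nonfunctional_gene=0, productive=0,
    )
    for seq, ids in buckets.items():
        ann = annotator.annotate(ids[0], seq, read_count=len(ids))
        annotations.append(ann)
        n = len(ids)
        summary["reads_in"] += n
        if ann.status in ("unassigned_v", "unassigned_j"):
            summary["unassigned"] += n
        elif ann.status == "no_cdr3":
            summary["no_cdr3"] += n
        elif ann.status == "junction_conflict":
            summary["junction_conflict"] += n
        elif ann.productive:
            summary["productive"] += n
        if ann.status == "ok" and not ann.productive:
            summary[f"nonproductive_{ann.productive_reason}"] += n
    return annotations, dict(summary)


def annotations_to_frame(annotations: Iterable[Annotation]) -> pd.DataFrame:
    """Flatten annotations to an AIRR-style table (one row per unique read)."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "sequence_id": a.read_id,
                "locus": a.locus,
                "status": a.status,
                "v_call": a.v.gene_name if a.v else None,
                "j_call": a.j.gene_name if a.j else None,
                "d_call": a.d.gene_name if a.d else None,
                "v_score": a.v.score if a.v else None,
                "j_score": a.j.score if a.j else None,
                "v_identity": a.v.identity if a.v else None,
                "junction": a.cdr3_nt,
                "junction_aa": a.cdr3_aa,
                "productive": a.productive,
                "productive_reason": a.productive_reason,
                "del_3v": a.del_3v, "del_5d": a.del_5d,
                "del_3d": a.del_3d, "del_5j": a.del_5j,
                "ins_vd": a.ins_vd, "ins_dj": a.ins_dj, "ins_vj": a.ins_vj,
                "read_count": a.read_count,
            }
        )
    return pd.DataFrame(rows)
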