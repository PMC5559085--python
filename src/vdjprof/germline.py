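"""Germline V/(D)/J gene databases.

Reads per-locus germline FASTA files, applies the conserved-motif
functionality filter (V: in-frame cysteine codon within the last 30 nt;
J: [FW]GXG in some reading frame), and exposes IMGT-anchored coordinates:
the CDR3-starting cysteine codon on V, the [FW] codon on J, and the FR3
span (nucleotides 196-310 of the V reference under IMGT unique numbering).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

LOCI = ("TRA", "TRB", "IGH", "IGK", "IGL")
#: loci whose rearrangements use a D segment
D_LOCI = ("TRB", "IGH")
SEGMENTS = ("V", "D", "J")

#: FR3 on the V reference, 1-based inclusive, IMGT unique numbering
FR3_START = 196
FR3_END = 310

#: window (nt) at the V 3' end searched for the conserved cysteine codon
V_ANCHOR_WINDOW = 30

_CYS_CODONS = ("TGT", "TGC")
_J_MOTIF_AA = re.compile(r"[FW]G.G")
_VALID_BASES = frozenset("ACGT")


class GermlineError(ValueError):
    """Malformed or invalid germline input."""


@dataclass(frozen=True)
class GermlineGene:
    """One germline V, D or J reference sequence.

    ``anchor_pos`` is the 1-based position (on the ungapped sequence) of the
    first nucleotide of the conserved motif: for V the CDR3-starting cysteine
    codon, for J the [FW] codon of [FW]GXG.  ``numbering``, when present,
    maps each ungapped base to its original (IMGT-gapped) 1-based position.
    """

    gene_name: str
    locus: str
    segment: str
    sequence: str
    functional: bool = False
    anchor_pos: int | None = None
    numbering: tuple[int, ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise GermlineError(f"unknown locus {self.locus!r}")
        if self.segment not in SEGMENTS:
            raise GermlineError(f"unknown segment {self.segment!r}")
        if not self.sequence:
            raise GermlineError(f"gene {self.gene_name}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise GermlineError(
                f"gene {self.gene_name}: invalid symbol(s) {sorted(bad)} "
                "(alphabet is A/C/G/T)"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def anchor_codon(self) -> str | None:
        if self.anchor_pos is None:
            return None
        return self.sequence[self.anchor_pos - 1 : self.anchor_pos + 2]


@dataclass
class GermlineDatabase:
    """Per-locus collections of V, D and J genes."""

    locus: str
    v_genes: list[GermlineGene] = field(default_factory=list)
    d_genes: list[GermlineGene] = field(default_factory=list)
    j_genes: list[GermlineGene] = field(default_factory=list)
    version_tag: str = ""

    def __post_init__(self) -> None:
        names = [g.gene_name for g in self.v_genes + self.d_genes + self.j_genes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise GermlineError(f"duplicate gene names in database: {sorted(dupes)}")
        if self.locus not in D_LOCI and self.d_genes:
            raise GermlineError(f"locus {self.locus} must not carry D genes")

    def genes(self, segment: str) -> list[GermlineGene]:
        return {"V": self.v_genes, "D": self.d_genes, "J": self.j_genes}[segment]

    def get(self, gene_name: str) -> GermlineGene:
        for g in self.v_genes + self.d_genes + self.j_genes:
            if g.gene_name == gene_name:
                return g
        raise KeyError(gene_name)

    def functional_only(self) -> "GermlineDatabase":
        """Database restricted to motif-bearing V/J genes (D kept as-is)."""
        return GermlineDatabase(
            locus=self.locus,
            v_genes=filter_functional(self.v_genes, "V"),
            d_genes=list(self.d_genes),
            j_genes=filter_functional(self.j_genes, "J"),
            version_tag=self.version_tag,
        )


def _degap(raw: str, name: str) -> tuple[str, tuple[int, ...] | None]:
    """Uppercase and remove IMGT '.' gaps, retaining gapped positions."""
    raw = raw.upper()
    if "." not in raw:
        return raw, None
    seq = []
    numbering = []
    for i, base in enumerate(raw, start=1):
        if base == ".":
            continue
        seq.append(base)
        numbering.append(i)
    return "".join(seq), tuple(numbering)


def read_germline_fasta(path: str | Path, locus: str, segment: str) -> list[GermlineGene]:
    """Read one germline FASTA file into :class:`GermlineGene` records.

    The header token before the first whitespace becomes the gene name;
    lowercase bases are uppercased, IMGT '.' gaps removed (original numbering
    retained).  The functional flag is left unset; run
    :func:`filter_functional` afterwards.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes: list[GermlineGene] = []
    for idx, record in enumerate(SeqIO.parse(str(path), "fasta")):
        seq, numbering = _degap(str(record.seq), record.id)
        if not seq:
            raise GermlineError(f"record {idx} ({record.id}): empty sequence")
        try:
            genes.append(
                GermlineGene(
                    gene_name=record.id,
                    locus=locus,
                    segment=segment,
                    sequence=seq,
                    numbering=numbering,
                )
            )
        except GermlineError as err:
            raise GermlineError(f"record {idx}: {err}") from err
    if not genes:
        logger.warning("no records in %s (%s %s)", path, locus, segment)
    return genes


def _v_anchor(seq: str) -> int | None:
    """Rightmost in-frame Cys codon starting within the last 30 nt, 1-based.

    The reading frame is frame 1 of the (ungapped) reference.
    """
    window_start = max(1, len(seq) - V_ANCHOR_WINDOW + 1)
    best = None
    for pos in range(1, len(seq) - 2 + 1, 3):  # codon starts, frame 1
        if pos >= window_start and seq[pos - 1 : pos + 2] in _CYS_CODONS:
            best = pos
    return best


def _j_anchor(seq: str) -> int | None:
    """1-based nt position of the 5'-most [FW]GXG across all three frames."""
    hits = []
    for frame in range(3):
        sub = seq[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        aa = str(Seq(sub).translate(to_stop=False))
        m = _J_MOTIF_AA.search(aa)
        if m:
            hits.append(frame + 3 * m.start() + 1)
    return min(hits) if hits else None


def filter_functional(genes: Iterable[GermlineGene], segment: str) -> list[GermlineGene]:
    """Keep genes carrying the conserved CDR3-boundary motif.

    V genes must have an in-frame TGT/TGC codon whose start lies within the
    final 30 nt; J genes must contain [FW]GXG in some reading frame.  Kept
    genes are returned with ``functional=True`` and ``anchor_pos`` set.
    """
    if segment == "D":
        raise GermlineError("D genes are not motif-filtered")
    if segment not in ("V", "J"):
        raise GermlineError(f"unknown segment {segment!r}")
    out = []
    finder = _v_anchor if segment == "V" else _j_anchor
    for gene in genes:
        anchor = finder(gene.sequence)
        if anchor is None:
            continue
        out.append(replace(gene, functional=True, anchor_pos=anchor))
    return out


def fr3_span(gene: GermlineGene) -> tuple[int, int]:
    """FR3 coordinates (1-based inclusive) on the ungapped V reference.

    FR3 occupies nucleotides 196-310 of the V gene under IMGT unique
    numbering; for gapped inputs the span is mapped through the retained
    numbering, otherwise it is (196, 310) clipped to the sequence length.
    """
    if gene.segment != "V":
        raise GermlineError("FR3 is defined on V genes only")
    if not gene.functional:
        raise GermlineError("FR3 requested for a non-functional V gene")
    if gene.numbering is not None:
        inside = [i + 1 for i, p in enumerate(gene.numbering) if FR3_START <= p <= FR3_END]
        if not inside:
            raise GermlineError(f"gene {gene.gene_name}: no FR3 (gapped numbering)")
        return inside[0], inside[-1]
    if len(gene.sequence) < FR3_START:
        raise GermlineError(
            f"gene {gene.gene_name}: sequence shorter than {FR3_START} nt, no FR3"
        )
    return FR3_START, min(FR3_END, len(gene.sequence))


def count_possible_pairings(n_v: int, n_j: int) -> int:
    """Size of the V-J combination space: ``n_v * n_j``."""
    if n_v < 0 or n_j < 0:
        raise ValueError("gene counts must be non-negative")
    return n_v * n_j


def write_gene_table(db: GermlineDatabase, path: str | Path) -> None:
    """Write the gene inventory as TSV."""
    import pandas as pd

    rows = [
        {
            "gene_name": g.gene_name,
            "locus": g.locus,
            "segment": g.segment,
            "length": len(g),
            "functional": g.functional,
            "anchor_pos": g.anchor_pos if g.anchor_pos is not None else "",
        }
        for seg in SEGMENTS
        for g in db.genes(seg)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_database(
    locus: str,
    v_fasta: str | Path,
    j_fasta: str | Path,
    d_fasta: str | Path | None = None,
    version_tag: str = "",
    functional_filter: bool = True,
) -> GermlineDatabase:
    """Read per-segment FASTA files into a (optionally filtered) database."""
    v = read_germline_fasta(v_fasta, locus, "V")
    j = read_germline_fasta(j_fasta, locus, "J")
    d = read_germline_fasta(d_fasta, locus, "D") if d_fasta else []
    db = GermlineDatabase(locus=locus, v_genes=v, d_genes=d, j_genes=j, version_tag=version_tag)
    return db.functional_only() if functional_filter else db


def write_fasta(genes: Sequence[GermlineGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_name}\n{g.sequence}\n")
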