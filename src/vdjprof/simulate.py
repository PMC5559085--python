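"""Ground-truthed V(D)J read simulation.

Builds rearranged receptor transcripts from a germline database —
exonucleolytic trimming of the 3'V / 5'D / 3'D / 5'J ends, non-template
insertions with a configurable base bias, optional heterozygous germline
polymorphism, per-position somatic hypermutation (B-cell loci only) and a
heavy-tailed clone-size model — then emits overlapping paired-end reads
(phred+33) with sequencing errors and N bases, together with a ground-truth
table of every junction section.

The simulated library mimics a 5'-RACE protocol read from the
constant-region side: templates are anchored at the junction-containing 3'
end, so CDR3 and the 3' part of FR3 are well covered while coverage decays
toward the V 5' end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import germline as gl
from ._junction import place_d

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: study-like insertion base biases (A, C, G, T) per locus; the beta-chain
#: and heavy-chain pools are C/G-biased, light chains closer to uniform
DEFAULT_INSERTION_BASE_PROBS = {
    "TRB": (0.21, 0.31, 0.28, 0.20),
    "IGH": (0.17, 0.27, 0.39, 0.17),
    "TRA": (0.25, 0.25, 0.25, 0.25),
    "IGK": (0.25, 0.25, 0.25, 0.25),
    "IGL": (0.25, 0.25, 0.25, 0.25),
}

#: baseline FR3-scale SHM rate for B-cell loci (per nt)
DEFAULT_SHM_RATE = {"IGH": 0.06, "IGK": 0.04, "IGL": 0.04, "TRA": 0.0, "TRB": 0.0}

#: functional gene counts used for the default synthetic databases
SYNTHETIC_GENE_COUNTS = {
    "TRB": (59, 2, 13),
    "TRA": (31, 0, 55),
    "IGH": (19, 10, 6),
    "IGK": (83, 0, 4),
    "IGL": (83, 0, 5),
}


class SimulationError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """All tunables of the simulator; defaults are the study conditions.

    Length models for trims and insertions are geometric with the given
    means; clone sizes follow a truncated discrete power law (Zipf) with
    exponent ``reads_per_clonotype_dispersion``.
    """

    locus: str
    n_clonotypes: int = 5000
    reads_per_clonotype_dispersion: float = 2.0
    max_clone_size: int = 10_000
    v_usage_weights: dict[str, float] | None = None
    d_usage_weights: dict[str, float] | None = None
    j_usage_weights: dict[str, float] | None = None
    deletion_mean: float = 2.0
    insertion_mean: float = 4.0
    insertion_base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    shm_rate_per_nt: float = 0.0
    shm_hotspots: tuple[tuple[str, int, float], ...] = ()
    shm_transition_weight: float = 1.0
    polymorphic_alleles: tuple[tuple[str, int, str, float], ...] = ()
    frame_mode: str = "random"  # or "in_frame"
    min_d_retained: int = 6
    min_d_match: int = 5
    read_length: int = 100
    fragment_min: int = 150
    fragment_max: int = 190
    per_base_error_rate: float = 0.001
    n_rate: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.locus not in gl.LOCI:
            raise SimulationError(f"unknown locus {self.locus!r}")
        if abs(sum(self.insertion_base_probs) - 1.0) > 1e-9:
            raise SimulationError("insertion_base_probs must sum to 1")
        if self.locus not in gl.D_LOCI and self.d_usage_weights:
            raise SimulationError(f"{self.locus} rearrangements carry no D gene")
        if not 0 <= self.shm_rate_per_nt < 1:
            raise SimulationError("shm_rate_per_nt must be in [0, 1)")
        if self.frame_mode not in ("random", "in_frame"):
            raise SimulationError(f"unknown frame_mode {self.frame_mode!r}")

    @classmethod
    def for_locus(cls, locus: str, **overrides) -> "SimulationConfig":
        """Config with locus-specific study-condition defaults filled in."""
        defaults = dict(
            insertion_base_probs=DEFAULT_INSERTION_BASE_PROBS[locus],
            shm_rate_per_nt=DEFAULT_SHM_RATE[locus],
        )
        defaults.update(overrides)
        return cls(locus=locus, **defaults)


@dataclass
class Rearrangement:
    """One simulated clonotype with full junction ground truth.

    Junction fields follow the canonical maximal-germline-match parse (see
    :mod:`vdjprof._junction`); ``shm_events`` and ``allele_events`` record
    substitutions applied after junction assembly, as
    ``(position, ref_base, alt_base)`` — 1-based on ``full_sequence`` for
    SHM, 1-based on the V reference for allele events.
    """

    clonotype_id: int
    v_gene: str
    d_gene: str | None
    j_gene: str
    del_3v: int
    del_5d: int
    del_3d: int
    del_5j: int
    ins_vd: str
    ins_dj: str
    ins_vj: str
    full_sequence: str
    cdr3_nt: str
    shm_events: list[tuple[int, str, str]] = field(default_factory=list)
    allele_events: list[tuple[int, str, str]] = field(default_factory=list)
    abundance: int = 1
    #: as-drawn junction values before canonical reparsing (diagnostics)
    raw: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# synthetic germline references

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _make_v(rng: np.random.Generator, length: int, anchor: int, functional: bool = True) -> str:
    """Random V reference with a frame-1 Cys codon planted at ``anchor``.

    Later in-frame Cys codons inside the 30-nt window are resampled away so
    the planted codon is the rightmost one; non-functional genes get no Cys
    codon in the window at all.
    """
    window_start = length - gl.V_ANCHOR_WINDOW + 1
    while True:
        seq = list(_random_seq(rng, length))
        if functional:
            seq[anchor - 1 : anchor + 2] = list("TGT" if rng.random() < 0.7 else "TGC")
        ok = True
        for pos in range(1, length - 2 + 1, 3):
            if pos < window_start or pos == (anchor if functional else -1):
                continue
            if "".join(seq[pos - 1 : pos + 2]) in ("TGT", "TGC"):
                ok = False
                break
        if ok:
            return "".join(seq)


_STOPS = ("TAA", "TAG", "TGA")


def _make_j(rng: np.random.Generator, length: int, anchor: int, functional: bool = True) -> str:
    """Random J reference whose 5'-most [FW]GXG motif starts at ``anchor``.

    Downstream of the anchor the reference is kept stop-free in the anchor
    frame, as real J genes read through into the constant region.
    """
    while True:
        seq = list(_random_seq(rng, length))
        if functional:
            fw = ["TTT", "TTC", "TGG"][rng.integers(0, 3)]
            x = _random_seq(rng, 3)
            motif = fw + "GG" + _BASES[rng.integers(0, 4)] + x + "GG" + _BASES[rng.integers(0, 4)]
            seq[anchor - 1 : anchor + 11] = list(motif)
            for p in range(anchor - 1, length - 2, 3):
                while "".join(seq[p : p + 3]) in _STOPS:
                    seq[p : p + 3] = list(_random_seq(rng, 3))
        found = gl._j_anchor("".join(seq))
        if functional and found == anchor:
            return "".join(seq)
        if not functional and found is None:
            return "".join(seq)


def synthetic_database(
    locus: str,
    n_v: int | None = None,
    n_d: int | None = None,
    n_j: int | None = None,
    seed: int = 0,
    v_length: int = 318,
    d_length: int = 16,
    j_length: int = 48,
    n_pseudo_v: int = 0,
    n_pseudo_j: int = 0,
) -> gl.GermlineDatabase:
    """Generate a synthetic germline database for ``locus``.

    Gene counts default to the functional inventory sizes of the rhesus
    loci (59/2/13 TRB, 31/-/55 TRA, 19/10/6 IGH, 83/-/4 IGK, 83/-/5 IGL).
    V genes are 318 nt with the conserved Cys codon at 307-309 (within the
    final 30 nt, frame 1) so FR3 (196-310) lies inside the reference; J
    genes carry [FW]GXG starting at nt 16.  ``n_pseudo_*`` adds
    motif-lacking (non-functional) genes for filter testing.
    """
    counts = SYNTHETIC_GENE_COUNTS[locus]
    n_v = counts[0] if n_v is None else n_v
    n_d = counts[1] if n_d is None else n_d
    n_j = counts[2] if n_j is None else n_j
    if locus not in gl.D_LOCI:
        n_d = 0
    locus_key = int.from_bytes(locus.encode(), "little") % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([seed, locus_key]))
    v_anchor = 3 * ((v_length - 12) // 3) + 1  # frame-1 codon start, 12 nt from 3' end
    j_anchor = 16

    v_genes = [
        gl.GermlineGene(f"{locus}V{i + 1}", locus, "V", _make_v(rng, v_length, v_anchor))
        for i in range(n_v)
    ] + [
        gl.GermlineGene(f"{locus}VP{i + 1}", locus, "V", _make_v(rng, v_length, v_anchor, False))
        for i in range(n_pseudo_v)
    ]
    d_genes = [
        gl.GermlineGene(f"{locus}D{i + 1}", locus, "D", _random_seq(rng, d_length))
        for i in range(n_d)
    ]
    j_genes = [
        gl.GermlineGene(f"{locus}J{i + 1}", locus, "J", _make_j(rng, j_length, j_anchor))
        for i in range(n_j)
    ] + [
        gl.GermlineGene(f"{locus}JP{i + 1}", locus, "J", _make_j(rng, j_length, j_anchor, False))
        for i in range(n_pseudo_j)
    ]
    db = gl.GermlineDatabase(
        locus=locus, v_genes=v_genes, d_genes=d_genes, j_genes=j_genes,
        version_tag=f"synthetic-{seed}",
    )
    return db.functional_only() if n_pseudo_v == n_pseudo_j == 0 else db


# ---------------------------------------------------------------------------
# rearrangement construction

def _geometric(rng: np.random.Generator, mean: float) -> int:
    """Geometric draw on {0,1,2,...} with the given mean."""
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (1.0 + mean)) - 1)


def _weights(weights: dict[str, float] | None, genes: Sequence[gl.GermlineGene]) -> np.ndarray:
    if weights is None:
        return np.full(len(genes), 1.0 / len(genes))
    w = np.array([float(weights.get(g.gene_name, 0.0)) for g in genes])
    if w.sum() <= 0:
        raise SimulationError("usage weights sum to zero over the database")
    return w / w.sum()


def _draw_insertion(rng: np.random.Generator, mean: float, probs: np.ndarray) -> str:
    n = _geometric(rng, mean)
    if n == 0:
        return ""
    return "".join(_BASES[i] for i in rng.choice(4, size=n, p=probs))


def _canonicalize(
    v_seq: str, j_seq: str, d_genes: Sequence[gl.GermlineGene],
    del_3v: int, del_5j: int, junction: str, min_d_match: int,
) -> tuple[int, int, str, str | None, int, int, str, str]:
    """Reparse the junction under the maximal-germline-match convention.

    Returns ``(del_3v, del_5j, gap, d_gene, del_5d, del_3d, ins_left,
    ins_right)`` where ``gap`` is the junction string left between the
    extended V and J ends.
    """
    # V absorbs junction bases matching its trimmed continuation
    extra = 0
    while (
        extra < del_3v
        and extra < len(junction)
        and junction[extra] == v_seq[len(v_seq) - del_3v + extra]
    ):
        extra += 1
    junction = junction[extra:]
    del_3v -= extra
    # J absorbs junction bases leftward
    extra = 0
    while (
        extra < del_5j
        and extra < len(junction)
        and junction[-1 - extra] == j_seq[del_5j - 1 - extra]
    ):
        extra += 1
    if extra:
        junction = junction[:-extra]
    del_5j -= extra
    # D placed as longest exact match inside the remaining gap
    d_gene = None
    del_5d = del_3d = 0
    ins_left, ins_right = junction, ""
    if d_genes:
        hit = place_d(junction, d_genes, min_d_match)
        if hit is not None:
            d_ref = next(g for g in d_genes if g.gene_name == hit.gene_name)
            d_gene = hit.gene_name
            del_5d = hit.d_start
            del_3d = len(d_ref) - (hit.d_start + hit.length)
            ins_left = junction[: hit.gap_start]
            ins_right = junction[hit.gap_start + hit.length :]
    return del_3v, del_5j, junction, d_gene, del_5d, del_3d, ins_left, ins_right


def simulate_repertoire(
    config: SimulationConfig, db: gl.GermlineDatabase
) -> list[Rearrangement]:
    """Draw ``n_clonotypes`` ground-truthed rearrangements.

    Per clonotype the RNG is consumed in a fixed order (genes, trims,
    insertions, frame fix, allele, SHM, abundance) so a fixed seed gives
    byte-identical output.
    """
    if db.locus != config.locus:
        raise SimulationError("database locus does not match config locus")
    for seg in ("V", "J") + (("D",) if config.locus in gl.D_LOCI else ()):
        if not db.genes(seg):
            raise SimulationError(f"no {seg} genes in database")
    for gene, pos, _rate in config.shm_hotspots:
        if pos > len(db.get(gene)):
            raise SimulationError(f"hotspot position {pos} beyond gene {gene}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    has_d = config.locus in gl.D_LOCI
    vw = _weights(config.v_usage_weights, db.v_genes)
    jw = _weights(config.j_usage_weights, db.j_genes)
    dw = _weights(config.d_usage_weights, db.d_genes) if has_d else None
    ins_p = np.asarray(config.insertion_base_probs, dtype=float)

    out: list[Rearrangement] = []
    for cid in range(config.n_clonotypes):
        v = db.v_genes[rng.choice(len(db.v_genes), p=vw)]
        j = db.j_genes[rng.choice(len(db.j_genes), p=jw)]
        d = db.d_genes[rng.choice(len(db.d_genes), p=dw)] if has_d else None

        # trims, capped so the conserved anchor codons survive
        cap_v = len(v) - (v.anchor_pos + 2)
        cap_j = j.anchor_pos - 1
        del_3v = min(_geometric(rng, config.deletion_mean), cap_v)
        del_5j = min(_geometric(rng, config.deletion_mean), cap_j)
        if d is not None:
            del_5d = _geometric(rng, config.deletion_mean)
            del_3d = _geometric(rng, config.deletion_mean)
            excess = del_5d + del_3d - (len(d) - config.min_d_retained)
            if excess > 0:  # keep a detectable D core
                take = min(del_3d, excess)
                del_3d -= take
                del_5d -= excess - take
            d_part = d.sequence[del_5d : len(d) - del_3d]
            ins_a = _draw_insertion(rng, config.insertion_mean, ins_p)
            ins_b = _draw_insertion(rng, config.insertion_mean, ins_p)
            junction = ins_a + d_part + ins_b
            raw_ins = (ins_a, ins_b)
        else:
            del_5d = del_3d = 0
            junction = _draw_insertion(rng, config.insertion_mean, ins_p)
            raw_ins = (junction,)

        v_part = v.sequence[: len(v) - del_3v]
        j_part = j.sequence[del_5j:]
        if config.frame_mode == "in_frame":
            cdr3_len = (
                (len(v) - del_3v - v.anchor_pos + 1)
                + len(junction)
                + (j.anchor_pos + 2 - del_5j)
            )
            pad = (3 - cdr3_len % 3) % 3
            junction += "".join(_BASES[i] for i in rng.choice(4, size=pad, p=ins_p))

        raw = {
            "del_3v": del_3v, "del_5d": del_5d, "del_3d": del_3d, "del_5j": del_5j,
            "insertions": raw_ins,
        }
        del_3v, del_5j, _gap, d_name, del_5d, del_3d, ins_left, ins_right = _canonicalize(
            v.sequence, j.sequence, db.d_genes if has_d else (),
            del_3v, del_5j, junction, config.min_d_match,
        )
        v_part = v.sequence[: len(v) - del_3v]
        j_part = j.sequence[del_5j:]
        if d_name is not None:
            d_ref = db.get(d_name)
            d_part = d_ref.sequence[del_5d : len(d_ref) - del_3d]
            seq = v_part + ins_left + d_part + ins_right + j_part
            ins_vd, ins_dj, ins_vj = ins_left, ins_right, ""
        elif has_d:
            seq = v_part + _gap + j_part
            ins_vd, ins_dj, ins_vj = _gap, "", ""
        else:
            seq = v_part + _gap + j_part
            ins_vd, ins_dj, ins_vj = "", "", _gap

        r = Rearrangement(
            clonotype_id=cid, v_gene=v.gene_name, d_gene=d_name, j_gene=j.gene_name,
            del_3v=del_3v, del_5d=del_5d, del_3d=del_3d, del_5j=del_5j,
            ins_vd=ins_vd, ins_dj=ins_dj, ins_vj=ins_vj,
            full_sequence=seq, cdr3_nt="", raw=raw,
        )
        r = apply_shm(r, config, rng, v_ref=v)
        j_anchor_full = len(r.full_sequence) - len(j_part) + (j.anchor_pos - del_5j)
        r.cdr3_nt = r.full_sequence[v.anchor_pos - 1 : j_anchor_full + 2]
        r.abundance = int(min(rng.zipf(config.reads_per_clonotype_dispersion),
                              config.max_clone_size))
        out.append(r)
    return out


def apply_shm(
    r: Rearrangement,
    config: SimulationConfig,
    rng: np.random.Generator,
    v_ref: gl.GermlineGene | None = None,
) -> Rearrangement:
    """Apply heterozygous-allele substitution, then per-position SHM.

    A no-op for TCR loci.  Allele substitutions (positions on the V
    reference) are drawn per clonotype at the configured allele fraction and
    recorded separately from true SHM events.
    """
    if config.locus.startswith("TR"):
        return r
    if v_ref is None and (config.polymorphic_alleles or config.shm_hotspots):
        raise SimulationError(
            "apply_shm needs the V reference to resolve per-gene positions"
        )
    seq = list(r.full_sequence)
    v_len_kept = (len(v_ref) - r.del_3v) if v_ref is not None else 0
    # germline polymorphism first: the clonotype's template carries the allele
    for gene, pos, alt, fraction in config.polymorphic_alleles:
        if gene != r.v_gene or pos > v_len_kept:
            continue
        if rng.random() < fraction:
            ref = seq[pos - 1]
            if alt != ref:
                seq[pos - 1] = alt
                r.allele_events.append((pos, ref, alt))
    # per-position SHM over the whole transcript
    rate = np.full(len(seq), config.shm_rate_per_nt)
    for gene, pos, hot in config.shm_hotspots:
        if gene == r.v_gene and pos <= v_len_kept:
            rate[pos - 1] = hot
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    tw = config.shm_transition_weight
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for i in hits:
        ref = seq[i]
        alts = [b for b in _BASES if b != ref]
        w = np.array([tw if b == transition[ref] else 1.0 for b in alts])
        alt = alts[rng.choice(3, p=w / w.sum())]
        seq[i] = alt
        r.shm_events.append((int(i) + 1, ref, alt))
    r.full_sequence = "".join(seq)
    return r


def reconstruct(r: Rearrangement, db: gl.GermlineDatabase) -> str:
    """Rebuild ``full_sequence`` from the ground-truth parts and events."""
    v = db.get(r.v_gene)
    j = db.get(r.j_gene)
    v_part = v.sequence[: len(v) - r.del_3v]
    j_part = j.sequence[r.del_5j:]
    if r.d_gene is not None:
        d = db.get(r.d_gene)
        d_part = d.sequence[r.del_5d : len(d) - r.del_3d]
        seq = list(v_part + r.ins_vd + d_part + r.ins_dj + j_part)
    else:
        mid = r.ins_vd if r.ins_vd else r.ins_vj
        seq = list(v_part + mid + j_part)
    for pos, _ref, alt in r.allele_events:  # V-reference positions
        seq[pos - 1] = alt
    for pos, _ref, alt in r.shm_events:  # full-sequence positions
        seq[pos - 1] = alt
    return "".join(seq)


# ---------------------------------------------------------------------------
# read emission

_Q_BASE = chr(33 + 30)   # baseline quality Q30
_Q_ERR = chr(33 + 15)    # errored / N bases Q15


def _sequencing_noise(
    seq: str, rng: np.random.Generator, error_rate: float, n_rate: float
) -> tuple[str, str]:
    bases = list(seq)
    qual = [_Q_BASE] * len(bases)
    if error_rate > 0:
        for i in np.nonzero(rng.random(len(bases)) < error_rate)[0]:
            alts = [b for b in _BASES if b != bases[i]]
            bases[i] = alts[rng.integers(0, 3)]
            qual[i] = _Q_ERR
    if n_rate > 0:
        for i in np.nonzero(rng.random(len(bases)) < n_rate)[0]:
            bases[i] = "N"
            qual[i] = _Q_ERR
    return "".join(bases), "".join(qual)


def emit_reads(
    rearrangements: Sequence[Rearrangement],
    config: SimulationConfig,
    fastq1: str | Path,
    fastq2: str | Path,
    truth_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write paired FASTQ files and return the ground-truth table.

    Each read copy draws a fragment length uniformly in
    ``[fragment_min, fragment_max]``; the template is the fragment-length 3'
    tail of the transcript (constant-region-side sequencing), read 1 runs
    5'→3' from the template start and read 2 is the reverse complement of
    the template 3' end.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    with open(fastq1, "w") as f1, open(fastq2, "w") as f2:
        for r in rearrangements:
            for copy in range(r.abundance):
                frag = int(rng.integers(config.fragment_min, config.fragment_max + 1))
                template = r.full_sequence[-frag:]
                rid = f"clono{r.clonotype_id}_copy{copy}"
                s1, q1 = _sequencing_noise(
                    template[: config.read_length], rng,
                    config.per_base_error_rate, config.n_rate,
                )
                s2, q2 = _sequencing_noise(
                    revcomp(template)[: config.read_length], rng,
                    config.per_base_error_rate, config.n_rate,
                )
                f1.write(f"@{rid}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{rid}/2\n{s2}\n+\n{q2}\n")
    truth = ground_truth_table(rearrangements)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


def ground_truth_table(rearrangements: Sequence[Rearrangement]) -> pd.DataFrame:
    rows = []
    for r in rearrangements:
        row = dataclasses.asdict(r)
        row.pop("raw", None)
        row["shm_events"] = ";".join(f"{p}:{a}>{b}" for p, a, b in r.shm_events)
        row["allele_events"] = ";".join(f"{p}:{a}>{b}" for p, a, b in r.allele_events)
        rows.append(row)
    return pd.DataFrame(rows)


def write_config_echo(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(config):
            fh.write(f"{f.name}\t{getattr(config, f.name)!r}\n")
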