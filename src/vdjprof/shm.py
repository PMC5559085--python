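"""Per-position FR3 somatic-hypermutation profiling for BCR repertoires.

For each functional V gene, reads that aligned best to it contribute
read-weighted coverage and observed-base counts at every FR3 position
(nt 196-310 on the V reference).  On top of the profiles: overall and
per-gene mutation rates (nucleotide and codon/amino-acid level), hotspot
calling (mutation frequency strictly above 10% at coverage >= 31),
polymorphic-site inference (a single dominant non-reference base carried
by 40-60% of deep coverage, pointing at an unreported heterozygous
germline allele rather than SHM), and substitution spectra.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import germline as gl
from .annotate import Annotation

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

DEFAULT_HOTSPOT_MIN_COVERAGE = 31   # excludes positions with <= 30 bases
DEFAULT_HOTSPOT_THRESHOLD = 0.10
DEFAULT_POLY_BAND = (0.40, 0.60)
DEFAULT_POLY_CANDIDATE_BAND = (0.30, 0.70)
DEFAULT_POLY_MIN_COVERAGE = 1000
DEFAULT_POLY_DOMINANCE = 0.80

_CODON_CACHE: dict[str, str] = {}


def _translate(codon: str) -> str:
    aa = _CODON_CACHE.get(codon)
    if aa is None:
        aa = str(Seq(codon).translate())
        _CODON_CACHE[codon] = aa
    return aa


class UnsupportedLocusError(ValueError):
    pass


@dataclass
class MutationProfile:
    """Read-weighted FR3 mutation evidence for one V gene.

    Arrays are indexed by FR3 offset (position ``fr3_start + i`` on the V
    reference).  ``base_counts`` rows follow A, C, G, T.  Codon arrays
    cover the in-frame codons fully contained in FR3.
    """

    gene_name: str
    fr3_start: int
    fr3_end: int
    ref_bases: str
    coverage: np.ndarray = field(repr=False, default=None)
    mismatches: np.ndarray = field(repr=False, default=None)
    base_counts: np.ndarray = field(repr=False, default=None)
    codon_coverage: np.ndarray = field(repr=False, default=None)
    codon_mismatches: np.ndarray = field(repr=False, default=None)
    aa_substitutions: Counter = field(default_factory=Counter, repr=False)

    @property
    def n_positions(self) -> int:
        return self.fr3_end - self.fr3_start + 1

    def positions(self) -> np.ndarray:
        """1-based V-reference positions of the profile columns."""
        return np.arange(self.fr3_start, self.fr3_end + 1)

    def validate(self) -> None:
        assert (self.mismatches <= self.coverage + 1e-9).all()
        assert np.allclose(self.base_counts.sum(axis=0), self.coverage)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position": self.positions(),
                "ref_base": list(self.ref_bases),
                "coverage": self.coverage,
                "mismatches": self.mismatches,
            }
        )
        for i, b in enumerate(_BASES):
            df[b] = self.base_counts[i]
        return df


@dataclass
class PolymorphicCall:
    gene_name: str
    position: int
    ref_base: str
    alt_base: str
    alt_fraction: float
    coverage: float
    verdict: str       # polymorphic | candidate | not_polymorphic
    reason: str        # ok | near_band | below_band | above_band | dominance_unmet

    def __post_init__(self) -> None:
        if self.alt_base == self.ref_base:
            raise ValueError("alt base must differ from reference")


def _codon_starts(fr3_start: int, fr3_end: int) -> list[int]:
    """Frame-1 codon start positions fully contained in the FR3 span."""
    first = fr3_start + (-(fr3_start - 1)) % 3
    return [p for p in range(first, fr3_end - 1, 3) if p + 2 <= fr3_end]


def build_profiles(
    annotations: Iterable[Annotation],
    db: gl.GermlineDatabase,
    productive_only: bool = True,
    head_guard: int = 5,
    tail_guard: int = 10,
) -> dict[str, MutationProfile]:
    """Accumulate per-gene FR3 profiles from BCR annotations.

    Uses each annotation's V alignment blocks and mismatch positions;
    contributions are weighted by ``read_count`` and restricted by default
    to the productive repertoire.  Positions outside the FR3 span are
    ignored; codon-level tallies require the whole codon to be covered by
    gapless alignment.

    Alignment-edge columns are excluded by guard bands: a local alignment
    must start and end on exact matches, so mutated bases at the read's 5'
    edge and at the refined V 3' boundary are preferentially dropped from
    the alignment — counting the surviving edge columns would bias
    per-position mutation rates downward.  ``head_guard`` columns after
    the alignment start and ``tail_guard`` positions before the inferred V
    end are therefore ignored for every read, mutated or not.
    """
    if db.locus.startswith("TR"):
        raise UnsupportedLocusError("SHM profiling applies to BCR loci only")
    profiles: dict[str, MutationProfile] = {}
    codon_starts_cache: dict[str, list[int]] = {}
    for ann in annotations:
        if ann.v is None or ann.status != "ok":
            continue
        if productive_only and not ann.productive:
            continue
        gene = db.get(ann.v.gene_name)
        prof = profiles.get(gene.gene_name)
        if prof is None:
            start, end = gl.fr3_span(gene)
            n = end - start + 1
            prof = MutationProfile(
                gene_name=gene.gene_name,
                fr3_start=start,
                fr3_end=end,
                ref_bases=gene.sequence[start - 1 : end],
                coverage=np.zeros(n),
                mismatches=np.zeros(n),
                base_counts=np.zeros((4, n)),
                codon_coverage=np.zeros(len(_codon_starts(start, end))),
                codon_mismatches=np.zeros(len(_codon_starts(start, end))),
            )
            profiles[gene.gene_name] = prof
            codon_starts_cache[gene.gene_name] = _codon_starts(start, end)
        w = float(ann.read_count)
        start, end = prof.fr3_start, prof.fr3_end
        # columns past the refined V end are junction-derived (chance
        # extension of the local alignment), not V evidence
        v_end = (
            len(gene.sequence) - ann.del_3v - tail_guard
            if ann.del_3v is not None
            else end
        )
        head = ann.v.ref_start + head_guard
        covered = np.zeros(prof.n_positions, dtype=bool)
        for _q0, r0, length in ann.v.blocks:
            lo = max(r0 + 1, start, head)
            hi = min(r0 + length, end, v_end)
            if lo <= hi:
                covered[lo - start : hi - start + 1] = True
        prof.coverage[covered] += w
        mm_in = {
            pos: qb
            for pos, _rb, qb in ann.v.mismatch_positions
            if max(start, head) <= pos <= min(end, v_end) and qb in _BASE_IDX
        }
        for pos, qb in mm_in.items():
            prof.mismatches[pos - start] += w
            prof.base_counts[_BASE_IDX[qb], pos - start] += w
        # codon-level: whole codon covered; any mismatch marks the codon
        for ci, cstart in enumerate(codon_starts_cache[gene.gene_name]):
            o = cstart - start
            if not covered[o : o + 3].all():
                continue
            prof.codon_coverage[ci] += w
            ref_codon = prof.ref_bases[o : o + 3]
            obs = list(ref_codon)
            hit = False
            for k in range(3):
                qb = mm_in.get(cstart + k)
                if qb is not None:
                    obs[k] = qb
                    hit = True
            if hit:
                prof.codon_mismatches[ci] += w
                ref_aa, obs_aa = _translate(ref_codon), _translate("".join(obs))
                if ref_aa != obs_aa:
                    prof.aa_substitutions[(ref_aa, obs_aa)] += w
    # matched bases observed as the reference base
    for prof in profiles.values():
        ref_idx = np.array([_BASE_IDX[b] for b in prof.ref_bases])
        matched = prof.coverage - prof.base_counts.sum(axis=0)
        prof.base_counts[ref_idx, np.arange(prof.n_positions)] += matched
    return profiles


def overall_rate(
    profiles: dict[str, MutationProfile] | Sequence[MutationProfile],
    level: str = "nt",
) -> float | None:
    """Pooled mutation rate: mutated bases (codons) / sequenced bases (codons)."""
    profs = list(profiles.values()) if isinstance(profiles, dict) else list(profiles)
    if level == "nt":
        cov = sum(p.coverage.sum() for p in profs)
        mut = sum(p.mismatches.sum() for p in profs)
    elif level == "aa":
        cov = sum(p.codon_coverage.sum() for p in profs)
        mut = sum(p.codon_mismatches.sum() for p in profs)
    else:
        raise ValueError("level must be 'nt' or 'aa'")
    if cov == 0:
        logger.warning("zero coverage: mutation rate undefined")
        return None
    return float(mut / cov)


def per_gene_rate(
    profiles: dict[str, MutationProfile], level: str = "nt"
) -> dict[str, float]:
    out = {}
    for name, prof in profiles.items():
        rate = overall_rate([prof], level)
        if rate is None:
            logger.warning("gene %s has no aligned coverage; excluded", name)
            continue
        out[name] = rate
    return out


def call_hotspots(
    profile: MutationProfile,
    min_coverage: int = DEFAULT_HOTSPOT_MIN_COVERAGE,
    threshold: float = DEFAULT_HOTSPOT_THRESHOLD,
) -> tuple[list[int], list[int]]:
    """Hotspot positions (mutation frequency strictly > threshold).

    Returns ``(hotspots, excluded)`` where ``excluded`` lists positions
    failing the coverage floor (the grey cells of a mutation heatmap);
    both in 1-based V-reference coordinates.
    """
    positions = profile.positions()
    deep = profile.coverage >= min_coverage
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(profile.coverage > 0, profile.mismatches / profile.coverage, 0.0)
    hot = [int(p) for p, d, f in zip(positions, deep, freq) if d and f > threshold]
    excluded = [int(p) for p, d in zip(positions, deep) if not d]
    return hot, excluded


def detect_polymorphic_sites(
    profile: MutationProfile,
    band: tuple[float, float] = DEFAULT_POLY_BAND,
    min_coverage: int = DEFAULT_POLY_MIN_COVERAGE,
    dominance: float = DEFAULT_POLY_DOMINANCE,
    candidate_band: tuple[float, float] = DEFAULT_POLY_CANDIDATE_BAND,
    min_alt_fraction: float = 0.05,
) -> list[PolymorphicCall]:
    """Infer unreported-allele positions from deep-coverage profiles.

    A position is polymorphic when coverage passes ``min_coverage``, one
    single non-reference base accounts for a fraction of coverage inside
    ``band`` (endpoints inclusive), and that base makes up at least
    ``dominance`` of all mismatches there.  Dominant sites just outside
    the band (within ``candidate_band``) are reported as candidates.
    Positions whose top alternative base stays below ``min_alt_fraction``
    are ordinary SHM background and are not reported.
    """
    calls: list[PolymorphicCall] = []
    for i, pos in enumerate(profile.positions()):
        cov = profile.coverage[i]
        if cov < min_coverage:
            continue
        ref = profile.ref_bases[i]
        alt_counts = {
            b: profile.base_counts[_BASE_IDX[b], i] for b in _BASES if b != ref
        }
        total_mm = sum(alt_counts.values())
        if total_mm == 0:
            continue
        alt_base = max(sorted(alt_counts), key=lambda b: alt_counts[b])
        alt_frac = alt_counts[alt_base] / cov
        if alt_frac < min_alt_fraction:
            continue
        dominant = alt_counts[alt_base] / total_mm >= dominance
        in_band = band[0] <= alt_frac <= band[1]
        near_band = candidate_band[0] <= alt_frac <= candidate_band[1]
        if not dominant:
            verdict, reason = "not_polymorphic", "dominance_unmet"
        elif in_band:
            verdict, reason = "polymorphic", "ok"
        elif near_band:
            verdict, reason = "candidate", "near_band"
        else:
            verdict, reason = (
                ("not_polymorphic", "below_band")
                if alt_frac < band[0]
                else ("not_polymorphic", "above_band")
            )
        calls.append(
            PolymorphicCall(
                gene_name=profile.gene_name, position=int(pos), ref_base=ref,
                alt_base=alt_base, alt_fraction=float(alt_frac),
                coverage=float(cov), verdict=verdict, reason=reason,
            )
        )
    return calls


def substitution_spectrum(
    profiles: dict[str, MutationProfile] | Sequence[MutationProfile],
    level: str = "nt",
    top: int | None = None,
) -> pd.Series | None:
    """Relative frequency of substitution types, summing to 1.

    nt level: the 12 ref>alt base types pooled over all positions; aa
    level: ref>alt amino-acid types from codon comparison (``top`` keeps
    the most frequent types, e.g. a top-15 view).  Returns None when no
    mutation events exist.
    """
    profs = list(profiles.values()) if isinstance(profiles, dict) else list(profiles)
    counts: Counter = Counter()
    if level == "nt":
        for p in profs:
            for i, ref in enumerate(p.ref_bases):
                for b in _BASES:
                    if b != ref and p.base_counts[_BASE_IDX[b], i] > 0:
                        counts[f"{ref}>{b}"] += p.base_counts[_BASE_IDX[b], i]
    elif level == "aa":
        for p in profs:
            for (ref_aa, alt_aa), w in p.aa_substitutions.items():
                counts[f"{ref_aa}>{alt_aa}"] += w
    else:
        raise ValueError("level must be 'nt' or 'aa'")
    total = sum(counts.values())
    if total == 0:
        logger.warning("no mutation events: spectrum undefined")
        return None
    spectrum = pd.Series(counts, dtype=float).sort_values(ascending=False) / total
    if top is not None:
        spectrum = spectrum.head(top)
    return spectrum


def plot_mutation_heatmap(
    profiles: dict[str, MutationProfile],
    path,
    min_coverage: int = DEFAULT_HOTSPOT_MIN_COVERAGE,
) -> None:
    """Gene x FR3-position mutation-frequency heatmap.

    Cells with coverage below the floor are greyed out, mirroring the
    usual presentation of low-confidence positions.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = sorted(profiles)
    if not genes:
        raise ValueError("no profiles to plot")
    n_pos = max(p.n_positions for p in profiles.values())
    mat = np.full((len(genes), n_pos), np.nan)
    for gi, g in enumerate(genes):
        p = profiles[g]
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(p.coverage >= min_coverage, p.mismatches / np.maximum(p.coverage, 1), np.nan)
        mat[gi, : p.n_positions] = freq
    fig, ax = plt.subplots(figsize=(12, 0.3 * len(genes) + 2))
    masked = np.ma.masked_invalid(mat)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("lightgrey")
    im = ax.imshow(masked, aspect="auto", cmap=cmap, vmin=0)
    ax.set_yticks(range(len(genes)), genes, fontsize=6)
    first = profiles[genes[0]]
    ax.set_xlabel(f"FR3 position ({first.fr3_start}-{first.fr3_end})")
    fig.colorbar(im, ax=ax, label="mutation frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
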