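"""Repertoire summary statistics.

Usage frequencies (V, J, V-J), CDR3 length distributions, clonotype
rank-abundance, amino-acid composition, junction indel length
distributions and inserted-nucleotide composition.  All statistics are
read-weighted by default (each sequenced read contributes once); a
clonotype-weighted mode is available via ``weight="clonotypes"``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .germline import D_LOCI, count_possible_pairings

logger = logging.getLogger(__name__)

_AA20 = tuple("ACDEFGHIKLMNPQRSTVWY")

#: junction sections applicable per locus class
SECTIONS_D = ("del_3v", "del_5d", "del_3d", "del_5j", "ins_vd", "ins_dj")
SECTIONS_VJ = ("del_3v", "del_5j", "ins_vj")


class EmptyTableError(ValueError):
    pass


@dataclass
class RepertoireTable:
    """Clonotype abundance table: (cdr3_nt, v_gene, j_gene) -> read_count."""

    locus: str
    data: pd.DataFrame = field(repr=False, default=None)

    REQUIRED = ("cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "read_count")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.data["read_count"] < 1).any():
            raise ValueError("read_count must be >= 1")
        keys = self.data[["cdr3_nt", "v_gene", "j_gene"]]
        if keys.duplicated().any():
            raise ValueError("clonotype keys must be unique")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def total_reads(self) -> int:
        return int(self.data["read_count"].sum())

    @classmethod
    def from_annotations(
        cls,
        annotations: pd.DataFrame | Iterable,
        locus: str,
        productive_only: bool = True,
    ) -> "RepertoireTable":
        """Aggregate per-read annotations into a clonotype table.

        Accepts the frame from :func:`vdjprof.annotate.annotations_to_frame`
        or an iterable of Annotation objects; only reads with an extracted
        CDR3 (and, by default, productive ones) are counted.
        """
        if not isinstance(annotations, pd.DataFrame):
            from .annotate import annotations_to_frame

            annotations = annotations_to_frame(annotations)
        df = annotations[annotations["junction"].notna()]
        if productive_only:
            df = df[df["productive"]]
        if df.empty:
            raise EmptyTableError("no usable annotations")
        grouped = (
            df.groupby(["junction", "junction_aa", "v_call", "j_call"], dropna=False)[
                "read_count"
            ]
            .sum()
            .reset_index()
            .rename(
                columns={
                    "junction": "cdr3_nt",
                    "junction_aa": "cdr3_aa",
                    "v_call": "v_gene",
                    "j_call": "j_gene",
                }
            )
        )
        return cls(locus=locus, data=grouped)


def _weights(table: RepertoireTable, weight: str) -> np.ndarray:
    if weight == "reads":
        return table.data["read_count"].to_numpy(dtype=float)
    if weight == "clonotypes":
        return np.ones(len(table.data))
    raise ValueError(f"unknown weighting {weight!r}")


def usage_frequencies(
    table: RepertoireTable, axis: str = "V", weight: str = "reads"
) -> pd.Series:
    """Relative usage of V genes, J genes, or V-J pairs; sums to 1."""
    if len(table) == 0:
        raise EmptyTableError("empty repertoire table")
    w = pd.Series(_weights(table, weight))
    if axis == "V":
        keys = table.data["v_gene"].reset_index(drop=True)
    elif axis == "J":
        keys = table.data["j_gene"].reset_index(drop=True)
    elif axis == "VJ":
        keys = pd.Series(
            list(zip(table.data["v_gene"], table.data["j_gene"]))
        )
    else:
        raise ValueError(f"axis must be V, J or VJ, got {axis!r}")
    out = w.groupby(keys).sum()
    return (out / out.sum()).sort_index()


def cdr3_length_distribution(
    table: RepertoireTable, unit: str = "aa", weight: str = "reads"
) -> pd.Series:
    """Weighted histogram over CDR3 lengths; masses sum to 1."""
    if unit == "aa":
        lengths = table.data["cdr3_aa"].str.len()
    elif unit == "nt":
        lengths = table.data["cdr3_nt"].str.len()
    else:
        raise ValueError("unit must be 'aa' or 'nt'")
    w = pd.Series(_weights(table, weight))
    mask = lengths.notna()
    hist = w[mask.to_numpy()].groupby(lengths[mask].astype(int).to_numpy()).sum()
    return (hist / hist.sum()).sort_index()


def rank_abundance(table: RepertoireTable) -> pd.DataFrame:
    """Clonotype frequencies sorted descending, ties by cdr3_nt."""
    if len(table) == 0:
        raise EmptyTableError("empty repertoire table")
    df = table.data.sort_values(
        ["read_count", "cdr3_nt"], ascending=[False, True]
    ).reset_index(drop=True)
    df["frequency"] = df["read_count"] / df["read_count"].sum()
    df["rank"] = np.arange(1, len(df) + 1)
    return df[["rank", "cdr3_nt", "v_gene", "j_gene", "read_count", "frequency"]]


def aa_composition(table: RepertoireTable, weight: str = "reads") -> pd.Series:
    """Frequency of the 20 amino acids over all CDR3 positions; sums to 1."""
    counts = Counter()
    w = _weights(table, weight)
    for aa_seq, wt in zip(table.data["cdr3_aa"], w):
        if not isinstance(aa_seq, str):
            continue
        for aa in aa_seq:
            if aa in _AA20:
                counts[aa] += wt
    total = sum(counts.values())
    if total == 0:
        raise EmptyTableError("no amino-acid CDR3 sequences in table")
    return pd.Series({aa: counts.get(aa, 0.0) / total for aa in _AA20})


def junction_indel_distributions(
    annotations: pd.DataFrame, locus: str, weight_col: str = "read_count"
) -> dict[str, pd.Series]:
    """Per-section length histograms of junction trims and insertions.

    Six sections for D-loci (TRB/IGH), three for V-J loci; masses sum to 1
    per section.  Rows lacking junction fields (unassigned reads) are
    ignored; D-gene sections pool only reads where a D was placed.
    """
    sections = SECTIONS_D if locus in D_LOCI else SECTIONS_VJ
    out: dict[str, pd.Series] = {}
    for section in sections:
        col = annotations[section]
        if section.startswith("ins"):
            lengths = col.map(lambda x: len(x) if isinstance(x, str) else np.nan)
        else:
            lengths = pd.to_numeric(col, errors="coerce")
        mask = lengths.notna()
        if not mask.any():
            out[section] = pd.Series(dtype=float)
            continue
        w = annotations.loc[mask, weight_col].astype(float)
        hist = w.groupby(lengths[mask].astype(int).to_numpy()).sum()
        out[section] = (hist / hist.sum()).sort_index()
    return out


def inserted_nt_composition(
    annotations: pd.DataFrame, weight_col: str = "read_count"
) -> pd.Series | None:
    """Pooled A/C/G/T frequencies over all inserted nucleotides.

    Returns None (undefined composition) when no insertions exist.
    """
    counts = Counter()
    for _, row in annotations.iterrows():
        w = float(row[weight_col])
        for section in ("ins_vd", "ins_dj", "ins_vj"):
            s = row.get(section)
            if isinstance(s, str):
                for base in s:
                    counts[base] += w
    total = sum(counts.values())
    if total == 0:
        logger.warning("no inserted nucleotides: composition undefined")
        return None
    return pd.Series({b: counts.get(b, 0.0) / total for b in "ACGT"})


def captured_pairing_fraction(table: RepertoireTable, n_v: int, n_j: int) -> float:
    """Observed distinct V-J pairs over the possible pairing space."""
    possible = count_possible_pairings(n_v, n_j)
    if possible == 0:
        raise ValueError("empty pairing space")
    observed = table.data[["v_gene", "j_gene"]].drop_duplicates().shape[0]
    return observed / possible


def write_stat_tsv(stat: pd.Series | pd.DataFrame, path, name: str = "value") -> None:
    if isinstance(stat, pd.Series):
        stat.rename(name).to_csv(path, sep="\t", header=True)
    else:
        stat.to_csv(path, sep="\t", index=False)
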