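"""Repertoire diversity: Chao1 estimation and rarefaction.

The Chao1 estimator extrapolates true clonotype richness from singleton
and doubleton counts, S1 = S_obs + F1^2 / (2 F2); rarefaction resamples
reads without replacement at ten increasing depths (10%, 20%, ..., 100%),
ten replicates per depth.  Because repertoire richness can be counted on
distinct CDR3 nucleotide or amino-acid sequences, the unit is an explicit
required parameter throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .repstats import RepertoireTable

logger = logging.getLogger(__name__)


class Chao1Estimate(float):
    """Chao1 richness estimate; ``bias_corrected`` flags the F2=0 fallback."""

    bias_corrected: bool = False

    def __new__(cls, value: float, bias_corrected: bool = False):
        obj = super().__new__(cls, value)
        obj.bias_corrected = bias_corrected
        return obj


def chao1(s_obs: int, f1: int, f2: int) -> Chao1Estimate:
    """Chao1 estimator S1 = S_obs + F1^2 / (2 F2).

    ``f1``/``f2`` are the numbers of clonotypes seen exactly once / twice.
    When F2 = 0 the printed form is undefined and the standard
    bias-corrected fallback S_obs + F1 (F1 - 1) / (2 (F2 + 1)) is returned
    with ``bias_corrected=True``.
    """
    if min(s_obs, f1, f2) < 0:
        raise ValueError("counts must be non-negative")
    if f1 > s_obs or f2 > s_obs:
        raise ValueError("singleton/doubleton counts cannot exceed richness")
    if f2 == 0:
        return Chao1Estimate(s_obs + f1 * (f1 - 1) / 2.0, bias_corrected=True)
    return Chao1Estimate(s_obs + f1 * f1 / (2.0 * f2))


def chao1_from_counts(counts: np.ndarray) -> Chao1Estimate:
    """Chao1 from a vector of per-clonotype abundances."""
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    return chao1(
        int(counts.size), int((counts == 1).sum()), int((counts == 2).sum())
    )


def fraction_captured(s_obs: int, chao1_estimate: float) -> int:
    """Observed share of the estimated richness, as a whole percentage."""
    if s_obs <= 0:
        raise ValueError("s_obs must be positive")
    if chao1_estimate < s_obs:
        raise ValueError("Chao1 estimate cannot be below observed richness")
    return int(round(100.0 * s_obs / chao1_estimate))


@dataclass
class RarefactionCurve:
    unit: str
    seed: int
    fractions: np.ndarray          # shape (n_points,)
    s_obs: np.ndarray              # shape (n_points, n_replicates)
    chao1: np.ndarray              # shape (n_points, n_replicates)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.fractions):
            for r in range(self.s_obs.shape[1]):
                rows.append(
                    {
                        "fraction": float(f),
                        "replicate": r + 1,
                        "s_obs": float(self.s_obs[i, r]),
                        "chao1": float(self.chao1[i, r]),
                    }
                )
        return pd.DataFrame(rows)


def rarefaction(
    table: RepertoireTable,
    unit: str,
    seed: int,
    n_points: int = 10,
    n_replicates: int = 10,
) -> RarefactionCurve:
    """Subsample reads without replacement at increasing depths.

    At each fraction i/n_points the stated share of total reads is drawn
    (without replacement, reads expanded from clonotype counts) and S_obs
    and Chao1 computed on the subsample, ``n_replicates`` times.
    """
    if unit not in ("aa", "nt"):
        raise ValueError("unit must be 'aa' or 'nt'")
    if len(table) == 0:
        raise ValueError("empty repertoire table")
    col = "cdr3_aa" if unit == "aa" else "cdr3_nt"
    labels, _ = pd.factorize(table.data[col])
    counts = table.data["read_count"].to_numpy()
    n_species = labels.max() + 1
    reads = np.repeat(labels, counts)
    total = reads.size
    rng = np.random.default_rng(seed)
    fractions = np.arange(1, n_points + 1) / n_points
    s_obs = np.zeros((n_points, n_replicates))
    est = np.zeros((n_points, n_replicates))
    for i, f in enumerate(fractions):
        size = int(round(f * total))
        if size < 1:
            logger.warning("fraction %.2f yields no reads; point skipped", f)
            continue
        for r in range(n_replicates):
            sample = rng.choice(reads, size=size, replace=False)
            tally = np.bincount(sample, minlength=n_species)
            s_obs[i, r] = (tally > 0).sum()
            est[i, r] = float(chao1_from_counts(tally))
    return RarefactionCurve(unit=unit, seed=seed, fractions=fractions,
                            s_obs=s_obs, chao1=est)


def diversity_summary(table: RepertoireTable, unit: str) -> dict:
    """S_obs, F1, F2, Chao1 and captured fraction for one repertoire."""
    col = "cdr3_aa" if unit == "aa" else "cdr3_nt"
    counts = table.data.groupby(col)["read_count"].sum().to_numpy()
    est = chao1_from_counts(counts)
    s_obs = int((counts > 0).sum())
    return {
        "unit": unit,
        "s_obs": s_obs,
        "f1": int((counts == 1).sum()),
        "f2": int((counts == 2).sum()),
        "chao1": float(est),
        "chao1_bias_corrected": est.bias_corrected,
        "fraction_captured_pct": fraction_captured(s_obs, float(est)),
    }
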