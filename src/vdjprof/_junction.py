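"""Shared junction parse convention.

A rearranged junction admits many equivalent parses: an N-nucleotide that
happens to equal the adjacent germline base cannot be distinguished from an
untrimmed germline base.  Both the simulator's ground truth and the
annotator's decomposition therefore use one canonical convention — germline
segments absorb boundary bases maximally (V rightward, J leftward), and the
D segment is placed as the longest contiguous exact match inside the
remaining gap, with deterministic tie-breaking.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple


class DPlacement(NamedTuple):
    gene_name: str
    gap_start: int  # 0-based offset of the D match within the gap
    d_start: int    # 0-based offset of the match within the D reference
    length: int


def longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """Longest contiguous exact match between ``a`` and ``b``.

    Returns ``(length, start_in_a, start_in_b)``; ties resolved toward the
    smallest ``start_in_a``, then the smallest ``start_in_b``.
    """
    if not a or not b:
        return 0, 0, 0
    best = (0, 0, 0)
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                length = prev[j - 1] + 1
                cur[j] = length
                if length > best[0]:
                    best = (length, i - length, j - length)
        prev = cur
    return best


def place_d(gap: str, d_genes: Iterable, min_match: int) -> DPlacement | None:
    """Place a D gene inside the inter-anchor gap.

    The winning placement is the longest contiguous exact match of any D
    reference within the gap, requiring at least ``min_match`` nt; ties go
    to the lexicographically smaller gene name, then the leftmost gap
    offset, then the leftmost D offset.
    """
    best: DPlacement | None = None
    for gene in sorted(d_genes, key=lambda g: g.gene_name):
        length, i, p = longest_common_substring(gap, gene.sequence)
        if length >= min_match and (best is None or length > best.length):
            best = DPlacement(gene.gene_name, i, p, length)
    return best
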