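"""Kimura 2-parameter divergence between TE copies and their consensus.

The age of a TE insertion is proxied by its substitution distance from the
subfamily consensus.  The two-parameter model separates transitions
(A<->G, C<->T, proportion P of aligned sites) from transversions (all other
mismatches, proportion Q) and corrects for multiple hits:

    K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Columns containing a gap or an ambiguous base on either sequence are
excluded from the site count.  An optional CpG mode drops all columns that
fall inside a CpG dinucleotide of the consensus, mirroring the
CpG-adjusted divergence some annotation pipelines report (hypermutable
CpG transitions otherwise inflate the apparent age of young copies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = frozenset("ACGT")


class DivergenceUndefinedError(ValueError):
    """The observed P, Q lie outside the K2P domain (sequences too divergent)."""


@dataclass(frozen=True)
class SubstitutionCounts:
    n_sites: int
    n_transitions: int
    n_transversions: int
    n_cpg_sites: int

    def __post_init__(self) -> None:
        if self.n_transitions + self.n_transversions > self.n_sites:
            raise ValueError("more substitutions than sites")

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_sites

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_sites


def _cpg_columns(aligned_consensus: str) -> set[int]:
    """Columns of the gapped consensus that belong to a CpG dinucleotide."""
    cols: set[int] = set()
    prev_base_col = None
    for i, base in enumerate(aligned_consensus):
        if base == "-":
            continue
        if prev_base_col is not None and aligned_consensus[prev_base_col] == "C" and base == "G":
            cols.add(prev_base_col)
            cols.add(i)
        prev_base_col = i
    return cols


def count_substitutions(aligned_query: str, aligned_consensus: str,
                        cpg_mode: str = "include") -> SubstitutionCounts:
    """Count transitions and transversions over usable alignment columns.

    cpg_mode="exclude" removes every column inside a consensus CpG
    dinucleotide from both the substitution counts and the denominator.
    """
    if len(aligned_query) != len(aligned_consensus):
        raise ValueError("aligned sequences differ in length")
    if cpg_mode not in ("include", "exclude"):
        raise ValueError(f"cpg_mode must be include|exclude, got {cpg_mode!r}")
    cpg = _cpg_columns(aligned_consensus.upper()) if cpg_mode == "exclude" else frozenset()
    n_sites = n_ts = n_tv = n_cpg = 0
    for i, (q, c) in enumerate(zip(aligned_query.upper(), aligned_consensus.upper())):
        if q not in _BASES or c not in _BASES:  # gap / N / other ambiguity
            continue
        if i in cpg:
            n_cpg += 1
            continue
        n_sites += 1
        if q == c:
            continue
        if (q, c) in _TRANSITIONS:
            n_ts += 1
        else:
            n_tv += 1
    if n_sites == 0:
        raise ValueError("no usable alignment columns")
    return SubstitutionCounts(n_sites, n_ts, n_tv, n_cpg)


def kimura2p(P: float, Q: float) -> float:
    """Kimura 2-parameter distance from transition/transversion proportions.

    Raises DivergenceUndefinedError when the log arguments are non-positive,
    i.e. the sequences are saturated beyond what the model can correct.
    """
    if P < 0 or Q < 0:
        raise ValueError("P and Q must be non-negative")
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        raise DivergenceUndefinedError(
            f"distance undefined (too divergent): P={P}, Q={Q}"
        )
    return -0.5 * math.log(a * math.sqrt(b))


def block_divergence(aligned_query: str, aligned_consensus: str,
                     cpg_mode: str = "include") -> float:
    """K2P distance of one alignment block (convenience wrapper)."""
    c = count_substitutions(aligned_query, aligned_consensus, cpg_mode)
    return kimura2p(c.P, c.Q)


def insertion_divergence(fragments: Sequence[tuple[float, int]]) -> float:
    """Merge per-fragment divergences into one insertion-level value.

    Fragments of an interrupted insertion each contribute their K2P distance
    weighted by aligned length, so the merged value estimates the distance
    of the full copy.
    """
    fragments = list(fragments)
    if not fragments:
        raise ValueError("no fragments to merge")
    total = 0.0
    weight = 0
    for k, length in fragments:
        if length <= 0:
            raise ValueError(f"non-positive fragment length {length}")
        total += k * length
        weight += length
    return total / weight
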