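"""Fragment merging, divergence landscapes and TE-content summaries.

A repeat annotator reports interrupted insertions as several fragments that
share one integer identifier; merging by that identifier recovers a count
of insertion *events* rather than alignment fragments.  The landscape is
the classic stacked histogram: genome percent occupied by each TE class,
binned by divergence from consensus — recent activity sits at the left
(low divergence), ancient accumulation at the right.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .divergence import insertion_divergence
from .rmsk_io import TE_CLASSES, AnnotationRecord, classify_family

logger = logging.getLogger(__name__)

LANDSCAPE_MAX_DIV = 50  # percent; anything above accumulates in an overflow bin


@dataclass
class TEInsertion:
    """Fragments sharing one identifier, merged into a single insertion."""

    query_name: str
    span: tuple[int, int]
    total_bp: int
    te_class: str
    family: str
    divergence: float  # proportion, length-weighted over fragments
    insertion_id: int
    n_fragments: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.total_bp < 1:
            raise ValueError("total_bp must be >= 1")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


@dataclass
class Landscape:
    """Genome percent per (divergence bin x TE class) for one assembly.

    ``bp`` holds exact integer base-pair totals; ``values`` (percent of the
    denominator) is derived from it, so cell sums reconcile with total TE bp
    without float drift.
    """

    bp: pd.DataFrame  # index: bin labels, columns: TE classes, integer bp
    denominator_bp: int
    assembly_name: str = ""

    @property
    def values(self) -> pd.DataFrame:
        return 100.0 * self.bp / self.denominator_bp

    @property
    def total_te_bp(self) -> int:
        return int(self.bp.to_numpy().sum())


def merge_fragments(records: Sequence[AnnotationRecord],
                    divergences: Sequence[float],
                    include_suppressed: bool = True) -> list[TEInsertion]:
    """Group annotation fragments by (query, identifier) into insertions.

    ``divergences`` gives one per-record divergence proportion, positionally
    matched to ``records`` (typically K2P from alignment blocks, or
    pct_div/100 as fallback).  Class and family are taken from the longest
    fragment; divergence is the length-weighted mean.
    """
    if len(records) != len(divergences):
        raise ValueError("records and divergences differ in length")
    groups: dict[tuple[str, int], list[tuple[AnnotationRecord, float]]] = {}
    for rec, div in zip(records, divergences):
        if rec.overlap_suppressed and not include_suppressed:
            continue
        groups.setdefault((rec.query_name, rec.insertion_id), []).append((rec, div))
    insertions = []
    for (query_name, ins_id), members in sorted(groups.items()):
        longest, _ = max(members, key=lambda m: m[0].query_length)
        classes = {classify_family(r.class_family) for r, _ in members}
        if len(classes) > 1:
            logger.debug("id %d on %s mixes classes %s; using longest fragment",
                         ins_id, query_name, sorted(classes))
        insertions.append(TEInsertion(
            query_name=query_name,
            span=(min(r.query_begin for r, _ in members),
                  max(r.query_end for r, _ in members)),
            total_bp=sum(r.query_length for r, _ in members),
            te_class=classify_family(longest.class_family),
            family=longest.repeat_name,
            divergence=insertion_divergence(
                [(d, r.query_length) for r, d in members]),
            insertion_id=ins_id,
            n_fragments=len(members),
            strand=longest.strand,
        ))
    return insertions


def record_divergences(records: Sequence[AnnotationRecord],
                       blocks=None, cpg_mode: str = "include") -> list[float]:
    """Per-record divergence proportions, preferring K2P from ``.align`` blocks.

    Blocks are matched to records by (query, interval).  Records without a
    matching block fall back to the ``.out`` mismatch percent (which is a
    raw proportion, not a K2P distance) with a warning.
    """
    from .divergence import block_divergence

    by_key: dict[tuple[str, int, int], object] = {}
    if blocks is not None:
        by_key = {(b.query_name, b.query_begin, b.query_end): b for b in blocks}
    out = []
    n_fallback = 0
    for rec in records:
        block = by_key.get((rec.query_name, rec.query_begin, rec.query_end))
        if block is not None:
            out.append(block_divergence(block.aligned_query,
                                        block.aligned_consensus, cpg_mode))
        else:
            n_fallback += 1
            out.append(rec.pct_div / 100.0)
    if n_fallback and blocks is not None:
        logger.warning("%d/%d records had no alignment block; using raw "
                       "mismatch percent (not K2P)", n_fallback, len(records))
    elif blocks is None and records:
        logger.warning("no alignment data: divergences are raw mismatch "
                       "percents from .out, not K2P distances")
    return out


def _bin_labels(bin_width: int) -> list[str]:
    labels = [f"{lo}-{lo + bin_width}" for lo in range(0, LANDSCAPE_MAX_DIV, bin_width)]
    labels.append(f">{LANDSCAPE_MAX_DIV}")
    return labels


def build_landscape(insertions: Sequence[TEInsertion], denominator_bp: int,
                    bin_width: int = 1, assembly_name: str = "") -> Landscape:
    """Accumulate insertion bp into (divergence bin, class) cells.

    Bins are half-open percent intervals [k, k+width) over [0, 50], with an
    overflow bin for anything more divergent.
    """
    if denominator_bp <= 0:
        raise ValueError("denominator_bp must be positive")
    labels = _bin_labels(bin_width)
    bp = pd.DataFrame(0, index=labels, columns=list(TE_CLASSES), dtype=np.int64)
    n_over = 0
    for ins in insertions:
        pct = 100.0 * ins.divergence
        if pct >= LANDSCAPE_MAX_DIV:
            label = labels[-1]
            n_over += 1
        else:
            label = labels[int(pct // bin_width)]
        bp.loc[label, ins.te_class] += ins.total_bp
    if n_over:
        logger.info("%d insertions above %d%% divergence in overflow bin",
                    n_over, LANDSCAPE_MAX_DIV)
    return Landscape(bp=bp, denominator_bp=denominator_bp,
                     assembly_name=assembly_name)


def summarize_content(insertions: Sequence[TEInsertion],
                      denominator_bp: int) -> pd.Series:
    """Per-class genome percent plus a TE total that excludes class Other.

    Mirrors the content tables repeat annotation reports ship with: each TE
    class (and Unknown) as percent of the assembly, with satellites/simple
    repeats (Other) listed but not counted as TEs.
    """
    if denominator_bp <= 0:
        raise ValueError("denominator_bp must be positive")
    bp = {cls: 0 for cls in TE_CLASSES}
    for ins in insertions:
        bp[ins.te_class] += ins.total_bp
    out = {cls: 100.0 * v / denominator_bp for cls, v in bp.items()}
    out["Total_TE"] = sum(v for cls, v in out.items() if cls != "Other")
    return pd.Series(out)


def export_landscape(ls: Landscape, tsv_path: str | os.PathLike,
                     plot_path: str | os.PathLike | None = None) -> None:
    """Write the landscape as TSV (one row per bin) and a stacked bar chart."""
    values = ls.values
    values.index.name = "divergence_bin"
    values.to_csv(tsv_path, sep="\t", float_format="%.10g")
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 4))
        bottom = np.zeros(len(values))
        x = np.arange(len(values))
        for cls in values.columns:
            ax.bar(x, values[cls].to_numpy(), bottom=bottom, width=0.9, label=cls)
            bottom += values[cls].to_numpy()
        ax.set_xticks(x[::5])
        ax.set_xticklabels(values.index[::5], rotation=45, ha="right")
        ax.set_xlabel("Kimura 2-p divergence from consensus (%)")
        ax.set_ylabel("genome (%)")
        if ls.assembly_name:
            ax.set_title(ls.assembly_name)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)


def read_landscape_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
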