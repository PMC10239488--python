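"""Readers and writers for the external formats of the repeat-annotation world.

RepeatMasker ``.out`` tables and ``.align`` alignment dumps, genome FASTA,
gene annotation (GFF3/BED) and BED6 exports all pass through this module.
All coordinates are converted to 0-based half-open intervals at the format
boundary and stay that way everywhere inside the package; the original
1-based inclusive convention is restored only on write.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: canonical TE classes, in the order content tables report them.
TE_CLASSES = ("DNA", "Helitron", "SINE", "LINE", "LTR", "Unknown", "Other")

OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)     ID\n"
    "\n"
)


@dataclass
class AnnotationRecord:
    """One aligned repeat fragment: a single data row of a ``.out`` table."""

    score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    query_name: str
    query_begin: int  # 0-based
    query_end: int  # half-open
    query_left: int
    strand: str  # "+" or "C"
    repeat_name: str
    class_family: str
    repeat_begin: int
    repeat_end: int
    repeat_left: int
    insertion_id: int
    overlap_suppressed: bool = False

    def __post_init__(self) -> None:
        if self.query_begin >= self.query_end:
            raise ValueError(
                f"empty query interval [{self.query_begin}, {self.query_end})"
            )
        for name in ("pct_div", "pct_del", "pct_ins"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.insertion_id < 1:
            raise ValueError(f"insertion_id must be >= 1, got {self.insertion_id}")
        if self.strand not in ("+", "C"):
            raise ValueError(f"strand must be '+' or 'C', got {self.strand!r}")

    @property
    def query_length(self) -> int:
        return self.query_end - self.query_begin


@dataclass
class AlignmentBlock:
    """One gapped query/consensus alignment from a ``.align`` file."""

    query_name: str
    query_begin: int  # 0-based
    query_end: int  # half-open
    consensus_name: str
    aligned_query: str
    aligned_consensus: str
    strand: str = "+"
    kimura_div_reported: float | None = None
    insertion_id: int | None = None

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_consensus):
            raise ValueError("aligned strings differ in length")
        span = self.query_end - self.query_begin
        ungapped = sum(1 for c in self.aligned_query if c != "-")
        if ungapped != span:
            raise ValueError(
                f"query interval length {span} != non-gap count {ungapped}"
            )


@dataclass
class GenomeSequences:
    """Residues and length bookkeeping for one FASTA assembly."""

    sequences: dict[str, str]
    lengths: dict[str, int] = field(init=False)
    total_length: int = field(init=False)
    non_n_length: int = field(init=False)

    def __post_init__(self) -> None:
        self.lengths = {name: len(s) for name, s in self.sequences.items()}
        self.total_length = sum(self.lengths.values())
        self.non_n_length = sum(
            len(s) - s.upper().count("N") - s.upper().count("X")
            for s in self.sequences.values()
        )


Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of half-open intervals, returned sorted and non-overlapping."""
    merged: list[Interval] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return [(s, e) for s, e in merged if e > s]


def subtract_intervals(base: Iterable[Interval], holes: Iterable[Interval]) -> list[Interval]:
    """Set difference base \\ holes on half-open intervals (both need not be sorted)."""
    holes = merge_intervals(holes)
    out: list[Interval] = []
    for start, end in merge_intervals(base):
        cur = start
        for hs, he in holes:
            if he <= cur or hs >= end:
                continue
            if hs > cur:
                out.append((cur, hs))
            cur = max(cur, he)
            if cur >= end:
                break
        if cur < end:
            out.append((cur, end))
    return out


@dataclass
class GeneFeatureSet:
    """Per-chromosome gene/exon intervals plus derived introns and intergenic.

    Introns are genes minus exons; intergenic is chromosome minus genes.
    All interval lists are sorted, half-open and non-overlapping.
    """

    genes: dict[str, list[Interval]]
    exons: dict[str, list[Interval]]
    chrom_lengths: dict[str, int]
    introns: dict[str, list[Interval]] = field(init=False)
    intergenic: dict[str, list[Interval]] = field(init=False)

    def __post_init__(self) -> None:
        self.genes = {c: merge_intervals(iv) for c, iv in self.genes.items()}
        self.exons = {c: merge_intervals(iv) for c, iv in self.exons.items()}
        self.introns = {}
        self.intergenic = {}
        for chrom, length in self.chrom_lengths.items():
            genes = self.genes.get(chrom, [])
            exons = self.exons.get(chrom, [])
            clipped = []
            for s, e in exons:
                inside = False
                for gs, ge in genes:
                    if s >= gs and e <= ge:
                        inside = True
                        break
                if not inside:
                    logger.warning(
                        "exon [%d,%d) on %s extends outside genes; clipping", s, e, chrom
                    )
            # clip exons to gene space regardless; well-formed input is a no-op
            for gs, ge in genes:
                for s, e in exons:
                    cs, ce = max(s, gs), min(e, ge)
                    if cs < ce:
                        clipped.append((cs, ce))
            self.exons[chrom] = merge_intervals(clipped)
            self.introns[chrom] = subtract_intervals(genes, self.exons[chrom])
            self.intergenic[chrom] = subtract_intervals([(0, length)], genes)

    def feature_intervals(self, feature: str) -> dict[str, list[Interval]]:
        return {
            "gene": self.genes,
            "exon": self.exons,
            "intron": self.introns,
            "intergenic": self.intergenic,
        }[feature]


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def _strip_parens(tok: str) -> int:
    return int(tok[1:-1]) if tok.startswith("(") else int(tok)


def read_out(path: str | os.PathLike) -> list[AnnotationRecord]:
    """Parse a RepeatMasker ``.out`` table into annotation records.

    Accepts the standard 3-line header or a headerless table.  Rows flagged
    with a trailing ``*`` (lower-scoring overlap with a higher-scoring match)
    are kept with ``overlap_suppressed=True``.
    """
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if not tokens[0].lstrip("-").isdigit():  # header line
                continue
            try:
                records.append(_parse_out_row(tokens))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"malformed .out row at line {lineno}: {exc}") from exc
    return records


def _parse_out_row(tokens: list[str]) -> AnnotationRecord:
    suppressed = tokens[-1] == "*"
    if suppressed:
        tokens = tokens[:-1]
    if len(tokens) != 15:
        raise ValueError(f"expected 15 fields, got {len(tokens)}")
    strand = tokens[8]
    if strand == "-":
        strand = "C"
    # consensus coordinates: + strand prints begin end (left); C strand
    # prints (left) end begin
    if strand == "C":
        r_left = _strip_parens(tokens[11])
        r_end = int(tokens[12])
        r_begin = int(tokens[13])
    else:
        r_begin = int(tokens[11])
        r_end = int(tokens[12])
        r_left = _strip_parens(tokens[13])
    return AnnotationRecord(
        score=int(tokens[0]),
        pct_div=float(tokens[1]),
        pct_del=float(tokens[2]),
        pct_ins=float(tokens[3]),
        query_name=tokens[4],
        query_begin=int(tokens[5]) - 1,
        query_end=int(tokens[6]),
        query_left=_strip_parens(tokens[7]),
        strand=strand,
        repeat_name=tokens[9],
        class_family=tokens[10],
        repeat_begin=r_begin,
        repeat_end=r_end,
        repeat_left=r_left,
        insertion_id=int(tokens[14]),
        overlap_suppressed=suppressed,
    )


def write_out(records: Sequence[AnnotationRecord], path: str | os.PathLike) -> None:
    """Write records back to ``.out`` format (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write(OUT_HEADER)
        for r in records:
            if r.strand == "C":
                rcoords = f"({r.repeat_left}) {r.repeat_end} {r.repeat_begin}"
            else:
                rcoords = f"{r.repeat_begin} {r.repeat_end} ({r.repeat_left})"
            row = (
                f"{r.score} {r.pct_div:.1f} {r.pct_del:.1f} {r.pct_ins:.1f} "
                f"{r.query_name} {r.query_begin + 1} {r.query_end} ({r.query_left}) "
                f"{r.strand} {r.repeat_name} {r.class_family} {rcoords} "
                f"{r.insertion_id}"
            )
            if r.overlap_suppressed:
                row += " *"
            fh.write(row + "\n")


def classify_family(class_family: str) -> str:
    """Map a RepeatMasker class/family label onto the canonical TE class set.

    The prefix before "/" decides: ``RC/Helitron`` is its own class, DNA
    transposons and the three retrotransposon classes keep their name,
    unclassified repeats go to Unknown, and non-TE annotation (satellites,
    simple repeats, low complexity, RNA genes) lands in Other — excluded
    from TE totals downstream.  Total: every string maps to exactly one class.
    """
    prefix = class_family.split("/", 1)[0].strip()
    low = prefix.lower()
    if low == "rc" or "helitron" in class_family.lower():
        return "Helitron"
    if low in ("dna", "dna?"):
        return "DNA"
    if low in ("sine", "sine?"):
        return "SINE"
    if low in ("line", "line?"):
        return "LINE"
    if low in ("ltr", "ltr?"):
        return "LTR"
    if low in ("unknown", "unclassified", "unknown?"):
        return "Unknown"
    if low in ("retroposon",):  # SVA-like; keep with the non-LTR retro side
        return "Other"
    if low in ("satellite", "simple_repeat", "low_complexity", "trna", "rrna",
               "snrna", "scrna", "srprna", "rna", "segmental", "artefact"):
        return "Other"
    logger.debug("unrecognized class/family %r -> Other", class_family)
    return "Other"


# ---------------------------------------------------------------------------
# RepeatMasker .align
# ---------------------------------------------------------------------------

def read_align(path: str | os.PathLike) -> list[AlignmentBlock]:
    """Parse a RepeatMasker ``.align`` file into gapped alignment blocks.

    A block is a score line, interleaved pairs of query/consensus sequence
    lines with 1-based position prefixes, and optional trailing
    ``Kimura (with divCpGMod) = x`` metadata.  The consensus line of a
    complement match is prefixed with ``C``.
    """
    blocks: list[AlignmentBlock] = []
    cur: dict | None = None
    block_index = 0

    def finish(c: dict) -> None:
        nonlocal block_index
        block_index += 1
        try:
            blocks.append(
                AlignmentBlock(
                    query_name=c["query_name"],
                    query_begin=c["query_begin"] - 1,
                    query_end=c["query_end"],
                    consensus_name=c["consensus_name"],
                    aligned_query="".join(c["q"]),
                    aligned_consensus="".join(c["c"]),
                    strand=c.get("strand", "+"),
                    kimura_div_reported=c.get("kimura"),
                    insertion_id=c.get("insertion_id"),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed .align block {block_index}: {exc}") from exc

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            tokens = line.split()
            if not tokens:
                continue
            if tokens[0][0].isdigit() and len(tokens) >= 9:  # score/header line
                if cur is not None:
                    finish(cur)
                cur = {"q": [], "c": [], "expect_query": True}
                cur["query_name"] = tokens[4]
                cur["query_begin"] = int(tokens[5])
                cur["query_end"] = int(tokens[6])
                if tokens[8] == "C":
                    cur["strand"] = "C"
                if tokens[-1].isdigit():
                    cur["insertion_id"] = int(tokens[-1])
                continue
            if cur is None:
                continue
            if line.startswith("Kimura"):
                cur["kimura"] = float(tokens[-1])
                continue
            if line.startswith(("Matrix", "Gap_init", "Transitions")):
                continue
            # sequence line: [C] name begin SEQ end
            seq_tokens = tokens[1:] if tokens[0] == "C" else tokens
            if len(seq_tokens) != 4:
                continue
            name, _begin, seq, _end = seq_tokens
            if cur["expect_query"]:
                cur["q"].append(seq.upper())
            else:
                cur["c"].append(seq.upper())
                cur.setdefault("consensus_name", name)
            cur["expect_query"] = not cur["expect_query"]
    if cur is not None:
        if not cur["expect_query"] or len(cur["q"]) != len(cur["c"]):
            raise ValueError(f"truncated final .align block {block_index + 1}")
        finish(cur)
    return blocks


def write_align(blocks: Sequence[AlignmentBlock], path: str | os.PathLike,
                width: int = 50) -> None:
    """Write alignment blocks in the ``.align`` dialect read_align consumes."""
    with open(path, "w") as fh:
        for b in blocks:
            sid = b.insertion_id if b.insertion_id is not None else 0
            strand_tok = "C" if b.strand == "C" else "+"
            fh.write(
                f"100 0.00 0.00 0.00 {b.query_name} {b.query_begin + 1} "
                f"{b.query_end} (0) {strand_tok} {b.consensus_name} {sid}\n\n"
            )
            qpos = b.query_begin + 1
            cpos = 1
            for off in range(0, len(b.aligned_query), width):
                qchunk = b.aligned_query[off:off + width]
                cchunk = b.aligned_consensus[off:off + width]
                qlen = sum(1 for ch in qchunk if ch != "-")
                clen = sum(1 for ch in cchunk if ch != "-")
                fh.write(f"  {b.query_name} {qpos} {qchunk} {qpos + qlen - 1}\n")
                prefix = "C " if b.strand == "C" else "  "
                fh.write(f"{prefix}{b.consensus_name} {cpos} {cchunk} {cpos + clen - 1}\n\n")
                qpos += qlen
                cpos += clen
            if b.kimura_div_reported is not None:
                fh.write(f"Kimura (with divCpGMod) = {b.kimura_div_reported:.2f}\n\n")


# ---------------------------------------------------------------------------
# FASTA / gene annotation / BED
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | os.PathLike) -> GenomeSequences:
    """Load a genome FASTA; reports per-sequence lengths and non-N length."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ValueError(f"no sequences found in {path}")
    return GenomeSequences(sequences)


def read_gene_annotation(path: str | os.PathLike, fmt: str,
                         chrom_lengths: dict[str, int]) -> GeneFeatureSet:
    """Read gene/exon features from GFF3 or BED and derive introns/intergenic.

    BED input carries gene intervals only (each gene is one exon).  GFF3 input
    uses ``gene`` and ``exon`` feature types.
    """
    genes: dict[str, list[Interval]] = {c: [] for c in chrom_lengths}
    exons: dict[str, list[Interval]] = {c: [] for c in chrom_lengths}
    fmt = fmt.upper()
    if fmt == "BED":
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                chrom, start, end = f[0], int(f[1]), int(f[2])
                genes.setdefault(chrom, []).append((start, end))
                exons.setdefault(chrom, []).append((start, end))
    elif fmt == "GFF3":
        import gffutils
        from gffutils.exceptions import EmptyInputError

        try:
            db = gffutils.create_db(
                str(path), ":memory:", merge_strategy="create_unique",
                force=True, keep_order=True,
            )
        except EmptyInputError:
            db = None
        for feat in (db.all_features() if db is not None else ()):
            if feat.featuretype == "gene":
                genes.setdefault(feat.seqid, []).append((feat.start - 1, feat.end))
            elif feat.featuretype == "exon":
                exons.setdefault(feat.seqid, []).append((feat.start - 1, feat.end))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return GeneFeatureSet(genes=genes, exons=exons, chrom_lengths=dict(chrom_lengths))


def write_bed(insertions, path: str | os.PathLike) -> None:
    """Write insertions as BED6; RepeatMasker strand "C" becomes "-"."""
    with open(path, "w") as fh:
        for ins in insertions:
            strand = "-" if getattr(ins, "strand", "+") == "C" else "+"
            name = getattr(ins, "family", None) or getattr(ins, "repeat_name", ".")
            start, end = (ins.span if hasattr(ins, "span")
                          else (ins.query_begin, ins.query_end))
            fh.write(f"{ins.query_name}\t{start}\t{end}\t{name}\t.\t{strand}\n")


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str, str]]:
    """Read BED6 back as (chrom, start, end, name, strand) tuples."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.split()
            strand = f[5] if len(f) > 5 else "+"
            rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ".", strand))
    return rows
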