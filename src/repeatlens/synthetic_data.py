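"""Ground-truthed synthetic inputs for every stage of the pipeline.

The generator emulates what a repeat annotator sees when it scans a mammal
genome: a background sequence carrying TE copies descended from known
consensus sequences, mutated to target divergences drawn from an age
mixture (an ancient accumulation peak around 25% divergence and an
optional recent component below 3%), optionally split into fragments that
share one insertion identifier, and written out as RepeatMasker-style
``.out``/``.align`` files together with the exact truth.  Gene annotations,
LINE loci with intact or disrupted ORFs, and multi-species cohorts with
configurable lifespan/recent-activity relationships complete the set.

The mutation model is substitution-only (no indels) so the true alignment
of every emitted copy is the identity mapping and its Kimura 2-parameter
divergence is exact by construction.  Everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.optimize import brentq

from . import rmsk_io
from .divergence import block_divergence, insertion_divergence, kimura2p
from .landscape import TEInsertion
from .orf_screen import load_domain_profiles

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# default age mixture, divergence percent: ancient accumulation peak at
# 20-30% with an optional recent (<3%) component for the non-LTR classes
ANCIENT_MEAN, ANCIENT_SD = 25.0, 3.0
RECENT_MEAN, RECENT_SD = 1.0, 0.7


@dataclass(frozen=True)
class ConsensusSpec:
    count: int
    length: int


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome.

    Class composition and copy counts are scaled-down analogues of a
    mammalian assembly (TE fraction ~40-50%, LINE-dominated); ``w_recent``
    is the weight of the recent age component and applies to the non-LTR
    classes only — the other classes are ancient relics, as in the real
    landscapes.
    """

    seed: int = 0
    genome_length: int = 300_000
    gc_content: float = 0.41
    kappa: float = 2.0  # transition:transversion odds
    consensus_library: dict[str, ConsensusSpec] = field(default_factory=lambda: {
        "LINE": ConsensusSpec(2, 3000),
        "SINE": ConsensusSpec(2, 300),
        "LTR": ConsensusSpec(1, 500),
        "DNA": ConsensusSpec(1, 800),
        "Helitron": ConsensusSpec(1, 1000),
    })
    insertion_counts: dict[str, int] = field(default_factory=lambda: {
        "LINE": 30, "SINE": 60, "LTR": 15, "DNA": 15, "Helitron": 10,
    })
    w_recent: float = 0.3
    recent_classes: frozenset[str] = frozenset({"LINE", "SINE"})
    fragmentation_prob: float = 0.2
    fragment_count_range: tuple[int, int] = (2, 3)
    spacer_range: tuple[int, int] = (50, 200)

    def __post_init__(self) -> None:
        if not 0 <= self.w_recent <= 1:
            raise ValueError("w_recent must lie in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @classmethod
    def scaled(cls, genome_length: int, **kwargs) -> "SimulationConfig":
        """Default composition rescaled to another genome length.

        Copy counts shrink or grow proportionally so the TE fraction stays
        at the default ~45% regardless of genome size.
        """
        cfg = cls(genome_length=genome_length, **kwargs)
        factor = genome_length / 300_000
        cfg.insertion_counts = {
            cls_: max(1, round(n * factor))
            for cls_, n in cfg.insertion_counts.items()}
        return cfg


_CLASS_FAMILY = {"LINE": "LINE/L1", "SINE": "SINE/B1", "LTR": "LTR/ERVL",
                 "DNA": "DNA/hAT", "Helitron": "RC/Helitron"}


@dataclass
class TruthFragment:
    genome_start: int
    genome_end: int
    cons_start: int
    cons_end: int
    aligned_copy: str  # consensus orientation
    aligned_consensus: str
    mismatch_pct: float  # raw percent, rounded as printed in .out


@dataclass
class TruthInsertion:
    insertion_id: int
    chrom: str
    te_class: str
    family: str
    consensus_length: int
    strand: str  # "+" or "C"
    target_divergence: float  # K2P proportion the copy was mutated toward
    realized_divergence: float  # K2P of the emitted alignment (length-weighted)
    fragments: list[TruthFragment]

    @property
    def span(self) -> tuple[int, int]:
        return (min(f.genome_start for f in self.fragments),
                max(f.genome_end for f in self.fragments))

    @property
    def total_bp(self) -> int:
        return sum(f.genome_end - f.genome_start for f in self.fragments)


@dataclass
class TruthTable:
    genome: dict[str, str]
    insertions: list[TruthInsertion]

    def recent_count(self, max_div: float = 0.03,
                     classes: frozenset[str] = frozenset({"LINE", "SINE"})) -> int:
        return sum(1 for i in self.insertions
                   if i.te_class in classes and i.realized_divergence < max_div)

    def total_te_bp(self) -> int:
        return sum(i.total_bp for i in self.insertions)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"insertion_id": i.insertion_id, "chrom": i.chrom,
             "te_class": i.te_class, "family": i.family, "strand": i.strand,
             "start": i.span[0], "end": i.span[1], "total_bp": i.total_bp,
             "n_fragments": len(i.fragments),
             "target_divergence": i.target_divergence,
             "realized_divergence": i.realized_divergence}
            for i in self.insertions
        ])

    def as_te_insertions(self) -> list[TEInsertion]:
        """Truth rendered in the analysis container (for direct pipeline input)."""
        return [TEInsertion(
            query_name=i.chrom, span=i.span, total_bp=i.total_bp,
            te_class=i.te_class, family=i.family,
            divergence=i.realized_divergence, insertion_id=i.insertion_id,
            n_fragments=len(i.fragments), strand=i.strand,
        ) for i in self.insertions]


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def make_consensus(length: int, gc: float, rng: np.random.Generator | int) -> str:
    """Random consensus sequence with the requested GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def solve_site_rates(target_K: float, kappa: float) -> tuple[float, float]:
    """Per-site (transition, transversion) probabilities whose expected
    substitution proportions invert the K2P formula to ``target_K``."""
    if target_K == 0:
        return 0.0, 0.0
    # stay 5% inside the K2P domain boundary: beyond it the expected
    # substitution proportions saturate and the estimator is undefined
    t_max = 0.95 * min(1.0 / (2 * kappa + 1), 0.5)
    k_max = kimura2p(kappa * t_max, t_max)
    if not 0 < target_K < k_max:
        raise ValueError(
            f"target divergence {target_K} unreachable (max {k_max:.3f} at kappa={kappa})")
    t = brentq(lambda q: kimura2p(kappa * q, q) - target_K, 1e-12, t_max)
    return kappa * t, t


def mutate_copy(consensus: str, target_K: float, kappa: float,
                rng: np.random.Generator | int) -> tuple[str, tuple[str, str]]:
    """Mutate a consensus copy to an expected K2P divergence of ``target_K``.

    Substitutions are placed independently per site with transition odds
    ``kappa``:1 over transversions; the realized alignment (copy, consensus)
    is returned alongside (substitution-only, so it is gap-free).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    p_ts, p_tv = solve_site_rates(target_K, kappa)
    u = rng.random(len(consensus))
    pick = rng.random(len(consensus))
    out = []
    for i, base in enumerate(consensus):
        if u[i] < p_ts:
            out.append(_TRANSITION[base])
        elif u[i] < p_ts + p_tv:
            tv = _TRANSVERSIONS[base]
            out.append(tv[0] if pick[i] < 0.5 else tv[1])
        else:
            out.append(base)
    copy = "".join(out)
    return copy, (copy, consensus)


# ---------------------------------------------------------------------------
# genome assembly with planted insertions
# ---------------------------------------------------------------------------

def _draw_divergence(cls: str, cfg: SimulationConfig,
                     rng: np.random.Generator) -> float:
    recent = (cls in cfg.recent_classes) and (rng.random() < cfg.w_recent)
    if recent:
        d = rng.normal(RECENT_MEAN, RECENT_SD)
    else:
        d = rng.normal(ANCIENT_MEAN, ANCIENT_SD)
    return float(np.clip(d, 0.0, 42.0)) / 100.0


def place_insertions(cfg: SimulationConfig, chrom: str = "chr1") -> TruthTable:
    """Build a genome with non-overlapping planted TE insertions plus truth.

    Copies are placed uniformly at random without overlap; a fragmented
    insertion occupies one footprint whose fragments are separated by
    unannotated background spacers but share a single insertion identifier.
    """
    rng = np.random.default_rng(cfg.seed)
    background = make_consensus(cfg.genome_length, cfg.gc_content, rng)
    library = {
        cls: [make_consensus(spec.length, cfg.gc_content, rng)
              for _ in range(spec.count)]
        for cls, spec in cfg.consensus_library.items()
    }

    plans = []  # (class, consensus index, target divergence)
    for cls, n in cfg.insertion_counts.items():
        if cls not in library:
            raise ValueError(f"no consensus for class {cls!r}")
        for _ in range(n):
            idx = int(rng.integers(len(library[cls])))
            plans.append((cls, idx, _draw_divergence(cls, cfg, rng)))
    # place the longest copies first: packing stays feasible at high density
    plans.sort(key=lambda p: -len(library[p[0]][p[1]]))

    genome = list(background)
    occupied: list[tuple[int, int]] = []
    insertions: list[TruthInsertion] = []
    next_id = 1
    for cls, idx, target in plans:
        consensus = library[cls][idx]
        copy, (a_copy, a_cons) = mutate_copy(consensus, target, cfg.kappa, rng)
        # cut into fragments (in consensus coordinates); fragments are kept
        # >= 200 bp so per-fragment divergence stays well inside the K2P domain
        if rng.random() < cfg.fragmentation_prob and len(copy) >= 600:
            lo, hi = cfg.fragment_count_range
            n_frag = int(rng.integers(lo, hi + 1))
        else:
            n_frag = 1
        cuts = [0, len(copy)]
        if n_frag > 1:
            for _ in range(50):
                interior = sorted(rng.choice(
                    np.arange(200, len(copy) - 200), size=n_frag - 1,
                    replace=False))
                candidate = [0, *map(int, interior), len(copy)]
                if min(b - a for a, b in zip(candidate, candidate[1:])) >= 200:
                    cuts = candidate
                    break
        spacers = [int(rng.integers(*cfg.spacer_range))
                   for _ in range(len(cuts) - 2)]
        footprint = len(copy) + sum(spacers)
        start = _find_slot(rng, cfg.genome_length, footprint, occupied)
        occupied.append((start, start + footprint))

        strand = "+" if rng.random() < 0.5 else "C"
        fragments = []
        gpos = start
        frag_segments = list(zip(cuts[:-1], cuts[1:]))
        if strand == "C":
            # genome order is the reverse of consensus order for a complement hit
            frag_segments = frag_segments[::-1]
        for j, (cs, ce) in enumerate(frag_segments):
            frag_copy = copy[cs:ce]
            frag_cons = consensus[cs:ce]
            frag_seq = frag_copy if strand == "+" else str(
                Seq(frag_copy).reverse_complement())
            genome[gpos:gpos + len(frag_seq)] = list(frag_seq)
            mism = sum(1 for a, b in zip(frag_copy, frag_cons) if a != b)
            fragments.append(TruthFragment(
                genome_start=gpos, genome_end=gpos + len(frag_seq),
                cons_start=cs, cons_end=ce,
                aligned_copy=frag_copy, aligned_consensus=frag_cons,
                mismatch_pct=round(100.0 * mism / len(frag_copy), 1),
            ))
            gpos += len(frag_seq)
            if j < len(frag_segments) - 1:
                gpos += spacers[j]
        realized = insertion_divergence([
            (block_divergence(f.aligned_copy, f.aligned_consensus),
             f.genome_end - f.genome_start) for f in fragments])
        insertions.append(TruthInsertion(
            insertion_id=next_id, chrom=chrom, te_class=cls,
            family=f"{cls}_cons{idx}", consensus_length=len(consensus),
            strand=strand, target_divergence=target,
            realized_divergence=realized, fragments=fragments))
        next_id += 1
    return TruthTable(genome={chrom: "".join(genome)}, insertions=insertions)


def _find_slot(rng: np.random.Generator, genome_length: int, footprint: int,
               occupied: list[tuple[int, int]], max_tries: int = 2000) -> int:
    if footprint > genome_length:
        raise ValueError("insertion footprint exceeds genome length")
    for _ in range(max_tries):
        start = int(rng.integers(0, genome_length - footprint + 1))
        end = start + footprint
        if all(end <= s or start >= e for s, e in occupied):
            return start
    raise ValueError("could not place insertion without overlap (packing infeasible)")


# ---------------------------------------------------------------------------
# emission in RepeatMasker dialects
# ---------------------------------------------------------------------------

def truth_to_records(truth: TruthTable) -> list[rmsk_io.AnnotationRecord]:
    records = []
    for ins in truth.insertions:
        for f in ins.fragments:
            records.append(rmsk_io.AnnotationRecord(
                score=max(1, (f.genome_end - f.genome_start) * 10),
                pct_div=f.mismatch_pct, pct_del=0.0, pct_ins=0.0,
                query_name=ins.chrom,
                query_begin=f.genome_start, query_end=f.genome_end,
                query_left=len(truth.genome[ins.chrom]) - f.genome_end,
                strand=ins.strand, repeat_name=ins.family,
                class_family=_CLASS_FAMILY.get(ins.te_class, ins.te_class),
                repeat_begin=f.cons_start + 1, repeat_end=f.cons_end,
                repeat_left=ins.consensus_length - f.cons_end,
                insertion_id=ins.insertion_id,
            ))
    records.sort(key=lambda r: (r.query_name, r.query_begin))
    return records


def truth_to_align_blocks(truth: TruthTable) -> list[rmsk_io.AlignmentBlock]:
    blocks = []
    for ins in truth.insertions:
        for f in ins.fragments:
            blocks.append(rmsk_io.AlignmentBlock(
                query_name=ins.chrom, query_begin=f.genome_start,
                query_end=f.genome_end, consensus_name=ins.family,
                aligned_query=f.aligned_copy, aligned_consensus=f.aligned_consensus,
                strand=ins.strand,
                kimura_div_reported=round(
                    100 * block_divergence(f.aligned_copy, f.aligned_consensus), 4),
                insertion_id=ins.insertion_id,
            ))
    blocks.sort(key=lambda b: (b.query_name, b.query_begin))
    return blocks


def emit_annotation(truth: TruthTable, prefix: str | os.PathLike,
                    style: str = "both") -> dict[str, str]:
    """Write ``.out`` / ``.align`` / FASTA files that parse under rmsk_io."""
    if style not in ("out", "align", "both"):
        raise ValueError(f"unknown style {style!r}")
    prefix = str(prefix)
    paths = {}
    if style in ("out", "both"):
        paths["out"] = prefix + ".out"
        rmsk_io.write_out(truth_to_records(truth), paths["out"])
    if style in ("align", "both"):
        paths["align"] = prefix + ".align"
        rmsk_io.write_align(truth_to_align_blocks(truth), paths["align"])
    paths["fasta"] = prefix + ".fa"
    with open(paths["fasta"], "w") as fh:
        for name, seq in truth.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    return paths


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def make_genes(genome_length: int, n_genes: int, clustering: float,
               seed: int, path: str | os.PathLike, chrom: str = "chr1",
               cluster_spans: tuple[tuple[float, float], ...] = ((0.1, 0.2), (0.6, 0.7)),
               ) -> list[tuple[int, int]]:
    """Write a GFF3 gene/exon annotation; returns the true gene intervals.

    ``clustering`` is the probability that a gene start is drawn from one of
    two cluster regions (fractions of the genome given by ``cluster_spans``)
    instead of uniformly; 0 gives a homogeneous gene distribution.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if not 0 <= clustering <= 1:
        raise ValueError("clustering must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes: list[tuple[int, int]] = []
    occupied: list[tuple[int, int]] = []
    lines = ["##gff-version 3", f"##sequence-region {chrom} 1 {genome_length}"]
    for g in range(n_genes):
        length = int(rng.integers(2000, 8001))
        for _ in range(2000):
            if rng.random() < clustering:
                lo, hi = cluster_spans[int(rng.integers(len(cluster_spans)))]
                start = int(rng.integers(int(lo * genome_length),
                                         max(int(hi * genome_length) - length, int(lo * genome_length) + 1)))
            else:
                start = int(rng.integers(0, genome_length - length + 1))
            end = start + length
            if all(end <= s or start >= e for s, e in occupied):
                break
        else:
            raise ValueError("could not place gene without overlap")
        occupied.append((start, end))
        genes.append((start, end))
        gid = f"gene{g}"
        lines.append(f"{chrom}\t.\tgene\t{start + 1}\t{end}\t.\t+\t.\tID={gid}")
        n_exons = int(rng.integers(1, 5))
        bounds = sorted(rng.choice(np.arange(1, length), size=2 * n_exons - 2,
                                   replace=False)) if n_exons > 1 else []
        edges = [0, *bounds, length]
        for e in range(n_exons):
            es, ee = edges[2 * e], edges[2 * e + 1]
            if ee <= es:
                ee = es + 1
            lines.append(
                f"{chrom}\t.\texon\t{start + es + 1}\t{start + ee}\t.\t+\t."
                f"\tID={gid}.e{e};Parent={gid}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return sorted(genes)


# ---------------------------------------------------------------------------
# LINE loci with intact / disrupted ORFs
# ---------------------------------------------------------------------------

_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"), "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"), "E": ("GAA", "GAG"), "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"), "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"), "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"), "M": ("ATG",),
    "N": ("AAT", "AAC"), "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"), "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"), "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",), "Y": ("TAT", "TAC"),
}


def back_translate(peptide: str, rng: np.random.Generator) -> str:
    """Nucleotide sequence coding for ``peptide``; uniform synonymous codons."""
    return "".join(
        _CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in peptide)


def make_line_locus(intact: bool, disruption: str = "stop",
                    rng: np.random.Generator | int = 0,
                    profiles: dict[str, str] | None = None,
                    flank: int = 150) -> tuple[str, bool]:
    """One LINE locus sequence with a known ORF-intactness truth flag.

    The intact form back-translates EN + linker + RT into a single
    ATG-initiated ORF with flanking background.  Disruptions break it:
    ``stop`` puts a premature in-frame stop in the linker, ``frameshift``
    deletes one nucleotide there, ``deletion`` removes the second half of
    the RT domain in frame.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if profiles is None:
        profiles = load_domain_profiles()
    linker = "GSTAGSTAGS"
    peptide = "M" + profiles["EN"] + linker + profiles["RT"]
    cds = back_translate(peptide, rng) + "TAA"
    linker_codon = 1 + len(profiles["EN"]) + len(linker) // 2  # aa index in linker
    if not intact:
        if disruption == "stop":
            cds = cds[:3 * linker_codon] + "TAA" + cds[3 * (linker_codon + 1):]
        elif disruption == "frameshift":
            cds = cds[:3 * linker_codon] + cds[3 * linker_codon + 1:]
        elif disruption == "deletion":
            rt_start_aa = 1 + len(profiles["EN"]) + len(linker)
            cut_aa = rt_start_aa + len(profiles["RT"]) // 2
            cds = cds[:3 * cut_aa] + cds[3 * len(peptide):]  # keep the stop codon
        else:
            raise ValueError(f"unknown disruption {disruption!r}")
    left = make_consensus(flank, 0.41, rng)
    right = make_consensus(flank, 0.41, rng)
    return left + cds + right, intact


def make_orf_panel(n_loci: int, seed: int,
                   profiles: dict[str, str] | None = None,
                   ) -> tuple[dict[str, str], list[TEInsertion], list[bool]]:
    """A genome of planted LINE loci, half intact and half disrupted.

    Disruption types cycle through stop / frameshift / deletion.  Returns
    (genome, LINE insertion calls, truth flags) ready for ``screen_lines``.
    """
    rng = np.random.default_rng(seed)
    if profiles is None:
        profiles = load_domain_profiles()
    disruptions = ("stop", "frameshift", "deletion")
    pieces = []
    insertions = []
    flags = []
    pos = 0
    spacer = 200
    for i in range(n_loci):
        intact = i % 2 == 0
        seq, flag = make_line_locus(
            intact, disruptions[(i // 2) % 3], rng, profiles)
        strand = "+" if rng.random() < 0.5 else "C"
        if strand == "C":
            seq = str(Seq(seq).reverse_complement())
        gap = make_consensus(spacer, 0.41, rng)
        pieces.extend([seq, gap])
        insertions.append(TEInsertion(
            query_name="chr1", span=(pos, pos + len(seq)), total_bp=len(seq),
            te_class="LINE", family="L1_panel", divergence=0.0,
            insertion_id=i + 1, n_fragments=1, strand=strand))
        flags.append(flag)
        pos += len(seq) + spacer
    return {"chr1": "".join(pieces)}, insertions, flags


# ---------------------------------------------------------------------------
# multi-species cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpeciesSpec:
    name: str
    lifespan_years: float
    w_recent: float
    mass_g: float = 100.0
    phenotype: str = ""


@dataclass
class CohortResult:
    species: list  # SpeciesProfile per species
    truths: dict[str, TruthTable]
    paths: dict[str, dict[str, str]]
    table_path: str | None = None


def default_cohort_spec() -> list[CohortSpeciesSpec]:
    """A 10-species cohort shaped like the rodent/bat study design.

    Lifespans are the packaged fixture values; long-lived species get a
    recent-age mixture weight half that of short-lived species, emulating
    the roughly two-fold DI contrast the comparison is built to detect.
    """
    from .density_stats import bundled_species_table

    spec = []
    for p in bundled_species_table():
        long_lived = p.phenotype.startswith("long_lived")
        spec.append(CohortSpeciesSpec(
            name=p.species_name, lifespan_years=p.max_lifespan_years,
            w_recent=0.15 if long_lived else 0.30,
            mass_g=p.body_mass_g, phenotype=p.phenotype))
    return spec


def make_cohort(cohort_spec: Sequence[CohortSpeciesSpec],
                out_dir: str | os.PathLike | None = None,
                seed: int = 0,
                base_config: SimulationConfig | None = None) -> CohortResult:
    """Simulate one annotated genome per species plus the species TSV.

    Each species genome uses the base configuration with its own seed and
    recent-age weight; assembly size in the species table is the simulated
    genome length in Gb, so downstream DI values are internally consistent.
    """
    from .density_stats import SpeciesProfile

    if len(cohort_spec) < 2:
        raise ValueError("a cohort needs at least 2 species")
    base = base_config or SimulationConfig.scaled(200_000)
    child_seeds = np.random.SeedSequence(seed).spawn(len(cohort_spec))
    species = []
    truths = {}
    paths: dict[str, dict[str, str]] = {}
    for sp, ss in zip(cohort_spec, child_seeds):
        cfg = replace(base, seed=int(ss.generate_state(1)[0] % (2 ** 31)),
                      w_recent=sp.w_recent)
        truth = place_insertions(cfg)
        truths[sp.name] = truth
        species.append(SpeciesProfile(
            species_name=sp.name, max_lifespan_years=sp.lifespan_years,
            body_mass_g=sp.mass_g,
            assembly_size_gb=cfg.genome_length / 1e9,
            phenotype=sp.phenotype))
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            paths[sp.name] = emit_annotation(
                truth, os.path.join(str(out_dir), sp.name))
    table_path = None
    if out_dir is not None:
        table_path = os.path.join(str(out_dir), "species.tsv")
        pd.DataFrame([{
            "species": p.species_name, "lifespan_years": p.max_lifespan_years,
            "mass_g": p.body_mass_g, "assembly_gb": p.assembly_size_gb,
            "phenotype": p.phenotype} for p in species
        ]).to_csv(table_path, sep="\t", index=False)
    return CohortResult(species=species, truths=truths, paths=paths,
                        table_path=table_path)
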