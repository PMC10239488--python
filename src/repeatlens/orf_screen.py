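"""Screen annotated LINE loci for intact protein-coding potential.

Autonomous LINE retrotransposons encode the reverse transcriptase (RT) and
endonuclease (EN) activities that both they and the non-autonomous SINEs
depend on.  A genome without a single LINE copy whose ORF still carries
complete RT and EN domains has, in effect, no currently mobilisable non-LTR
machinery.  The screen extracts annotated LINE sequences, scans all six
reading frames for ORFs, and aligns each translated ORF against bundled
reference domain peptides; an ORF is called intact when one reading frame
covers both domains essentially in full.

The bundled reference peptides (``synthetic_rt_domain.faa``,
``synthetic_en_domain.faa``) are deterministic synthetic stand-ins, not
curated biological domain models: they exercise and validate the screening
logic and pair with the simulator, which plants the same peptides.  Point
real curated RT/EN consensus peptides at ``load_domain_profiles`` for use
on biological data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .landscape import TEInsertion
from .rmsk_io import GenomeSequences

logger = logging.getLogger(__name__)

DEFAULT_MIN_AA = 300
DEFAULT_COVERAGE = 0.9
DEFAULT_SIMILARITY = 0.5  # identity fraction over aligned columns

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class DomainHit:
    coverage: float  # fraction of the profile covered by the local alignment
    similarity: float  # identity fraction over aligned columns
    passed: bool


@dataclass
class ORFCall:
    locus_name: str
    frame: int  # 0-2 forward, 3-5 reverse complement
    start: int  # nt offset on the scanned strand, ATG position
    end: int  # past the stop codon
    aa_sequence: str
    rt_hit: DomainHit | None = None
    en_hit: DomainHit | None = None

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)

    @property
    def intact(self) -> bool:
        return bool(self.rt_hit and self.rt_hit.passed
                    and self.en_hit and self.en_hit.passed)


def load_domain_profiles(rt_path=None, en_path=None) -> dict[str, str]:
    """Load RT/EN reference peptides; defaults to the bundled synthetic pair."""
    profiles = {}
    for key, path, default in (("RT", rt_path, "synthetic_rt_domain.faa"),
                               ("EN", en_path, "synthetic_en_domain.faa")):
        if path is None:
            with resources.as_file(resources.files("repeatlens.data") / default) as p:
                rec = next(SeqIO.parse(str(p), "fasta"))
        else:
            rec = next(SeqIO.parse(str(path), "fasta"))
        profiles[key] = str(rec.seq)
    return profiles


def extract_sequences(genome: GenomeSequences | Mapping[str, str],
                      line_insertions: Sequence[TEInsertion]) -> list[tuple[str, str]]:
    """Pull annotated LINE locus sequences; minus-strand loci reverse-complemented.

    Returns (name, sequence) pairs with names encoding chrom:start-end(strand).
    """
    seqs = genome.sequences if isinstance(genome, GenomeSequences) else genome
    out = []
    for ins in line_insertions:
        chrom = ins.query_name
        if chrom not in seqs:
            raise ValueError(f"locus {chrom}:{ins.start}-{ins.end}: unknown sequence")
        if ins.start < 0 or ins.end > len(seqs[chrom]):
            raise ValueError(
                f"locus {chrom}:{ins.start}-{ins.end} outside sequence bounds")
        s = seqs[chrom][ins.start:ins.end]
        strand = "-" if ins.strand == "C" else "+"
        if strand == "-":
            s = str(Seq(s).reverse_complement())
        out.append((f"{chrom}:{ins.start}-{ins.end}({strand})", s))
    return out


def find_orfs(nt_sequence: str, min_aa: int = DEFAULT_MIN_AA) -> list[ORFCall]:
    """Six-frame ORF scan: ATG through an in-frame stop, stop required.

    Within each stop-delimited segment the first ATG opens the (maximal)
    ORF.  ORFs shorter than ``min_aa`` amino acids (stop excluded) are
    discarded.  Frames 3-5 scan the reverse complement; coordinates are on
    the scanned strand.
    """
    nt = nt_sequence.upper()
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon")
    calls: list[ORFCall] = []
    for strand_idx, seq in enumerate((nt, str(Seq(nt).reverse_complement()))):
        for offset in range(3):
            frame = 3 * strand_idx + offset
            start_codon = None
            for pos in range(offset, len(seq) - 2, 3):
                codon = seq[pos:pos + 3]
                if codon in _STOPS:
                    if start_codon is not None:
                        aa_len = (pos - start_codon) // 3
                        if aa_len >= min_aa:
                            aa = str(Seq(seq[start_codon:pos]).translate())
                            calls.append(ORFCall(
                                locus_name="", frame=frame,
                                start=start_codon, end=pos + 3, aa_sequence=aa))
                        start_codon = None
                elif codon == "ATG" and start_codon is None:
                    start_codon = pos
    return calls


_aligner = PairwiseAligner()
_aligner.mode = "local"
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_aligner.open_gap_score = -11
_aligner.extend_gap_score = -1


def match_domain(aa_sequence: str, profile: str,
                 coverage_threshold: float = DEFAULT_COVERAGE,
                 similarity_threshold: float = DEFAULT_SIMILARITY) -> DomainHit:
    """Local-align an ORF peptide against a reference domain peptide.

    Coverage is the fraction of profile residues inside the local alignment;
    similarity is the identity fraction over aligned (ungapped) columns.
    "Complete domain" is operationalised as coverage >= 0.9 at >= 50%
    identity by default.
    """
    if not aa_sequence:
        raise ValueError("empty peptide")
    aln = _aligner.align(aa_sequence, profile)
    if len(aln) == 0:
        return DomainHit(0.0, 0.0, False)
    best = aln[0]
    q_blocks, p_blocks = best.aligned
    covered = sum(e - s for s, e in p_blocks)
    matched = 0
    aligned_cols = 0
    for (qs, qe), (ps, pe) in zip(q_blocks, p_blocks):
        aligned_cols += qe - qs
        matched += sum(1 for a, b in zip(aa_sequence[qs:qe], profile[ps:pe]) if a == b)
    coverage = covered / len(profile)
    similarity = matched / aligned_cols if aligned_cols else 0.0
    return DomainHit(
        coverage=coverage,
        similarity=similarity,
        passed=(coverage >= coverage_threshold
                and similarity >= similarity_threshold),
    )


def screen_lines(genome: GenomeSequences | Mapping[str, str],
                 line_insertions: Sequence[TEInsertion],
                 profiles: dict[str, str] | None = None,
                 min_aa: int = DEFAULT_MIN_AA,
                 coverage_threshold: float = DEFAULT_COVERAGE,
                 similarity_threshold: float = DEFAULT_SIMILARITY,
                 ) -> tuple[pd.DataFrame, bool]:
    """Screen every LINE locus; returns the per-ORF table and the species flag.

    The species-level ``has_intact_line`` is True when any locus carries an
    ORF whose single reading frame passes both the RT and the EN domain
    checks.
    """
    if profiles is None:
        profiles = load_domain_profiles()
    rows = []
    has_intact = False
    for name, seq in extract_sequences(genome, line_insertions):
        if len(seq) < 3:
            continue
        for orf in find_orfs(seq, min_aa=min_aa):
            orf.locus_name = name
            orf.rt_hit = match_domain(orf.aa_sequence, profiles["RT"],
                                      coverage_threshold, similarity_threshold)
            orf.en_hit = match_domain(orf.aa_sequence, profiles["EN"],
                                      coverage_threshold, similarity_threshold)
            has_intact = has_intact or orf.intact
            rows.append({
                "locus": name, "frame": orf.frame, "start": orf.start,
                "end": orf.end, "aa_length": orf.aa_length,
                "rt_coverage": orf.rt_hit.coverage,
                "rt_similarity": orf.rt_hit.similarity,
                "en_coverage": orf.en_hit.coverage,
                "en_similarity": orf.en_hit.similarity,
                "intact": orf.intact,
            })
    columns = ["locus", "frame", "start", "end", "aa_length", "rt_coverage",
               "rt_similarity", "en_coverage", "en_similarity", "intact"]
    return pd.DataFrame(rows, columns=columns), has_intact
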