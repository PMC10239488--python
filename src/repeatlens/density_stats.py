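"""Recent non-LTR insertion density and the comparative statistics on it.

The density of insertion (DI) of a species is the number of recently
inserted non-LTR retrotransposons (LINEs and SINEs with divergence from
consensus below 3%) divided by assembly size in Gb.  Species are compared
in ordered (long-lived, short-lived) pairs whose maximum lifespans differ
at least two-fold, and the paired DI differences are tested with an exact
Wilcoxon signed-rank test.  Window-level densities, genomic-feature
correlations (Spearman) and gene-rich vs gene-poor contrasts
(Wilcoxon rank-sum) round out the analysis.

A caveat inherited from the study design: one species contributes to many
lifespan pairs, so the paired differences are not independent and the
signed-rank null is anti-conservative at the cohort level (see the methods
note).  The procedure is reproduced as designed; interpret cohort p-values
accordingly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import TEInsertion
from .rmsk_io import GeneFeatureSet

RECENT_MAX_DIVERGENCE = 0.03  # proportion; strict "< 3%" cutoff
NONLTR_CLASSES = frozenset({"LINE", "SINE"})


@dataclass(frozen=True)
class SpeciesProfile:
    species_name: str
    max_lifespan_years: float
    body_mass_g: float
    assembly_size_gb: float
    phenotype: str = ""

    def __post_init__(self) -> None:
        if self.max_lifespan_years <= 0:
            raise ValueError("lifespan must be positive")
        if self.assembly_size_gb <= 0:
            raise ValueError("assembly size must be positive")


@dataclass(frozen=True)
class SpeciesPair:
    long_species: SpeciesProfile
    short_species: SpeciesProfile

    @property
    def lifespan_ratio(self) -> float:
        return (self.long_species.max_lifespan_years
                / self.short_species.max_lifespan_years)

    def __post_init__(self) -> None:
        if self.lifespan_ratio < 2:
            raise ValueError(
                f"lifespan ratio {self.lifespan_ratio:.3g} below two-fold")


@dataclass
class WindowTrack:
    """Non-overlapping fixed-size windows with per-window counts/densities."""

    window_size: int  # bp
    windows: list[tuple[str, int, int]]
    counts: np.ndarray
    density: np.ndarray = field(init=False)  # counts per Mb

    def __post_init__(self) -> None:
        lengths_mb = np.array([(e - s) / 1e6 for _, s, e in self.windows])
        self.counts = np.asarray(self.counts)
        self.density = self.counts / lengths_mb

    @property
    def mean_density(self) -> float:
        return float(np.mean(self.density))

    @property
    def sd_density(self) -> float:
        return float(np.std(self.density, ddof=1)) if len(self.density) > 1 else 0.0


def read_species_table(path) -> list[SpeciesProfile]:
    """Species metadata TSV: species, lifespan_years, mass_g, assembly_gb, phenotype."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        SpeciesProfile(row.species, float(row.lifespan_years), float(row.mass_g),
                       float(row.assembly_gb), str(row.phenotype))
        for row in df.itertuples()
    ]


def bundled_species_table() -> list[SpeciesProfile]:
    """The packaged 10-species rodent/bat cohort (lifespans, masses, assembly sizes)."""
    with resources.as_file(
        resources.files("repeatlens.data") / "species_lifespans.tsv"
    ) as p:
        return read_species_table(p)


# ---------------------------------------------------------------------------
# DI
# ---------------------------------------------------------------------------

def select_recent(insertions: Iterable[TEInsertion],
                  max_div: float = RECENT_MAX_DIVERGENCE,
                  classes: frozenset[str] = NONLTR_CLASSES) -> list[TEInsertion]:
    """Recently inserted non-LTR elements: divergence strictly below the cutoff."""
    return [i for i in insertions
            if i.te_class in classes and i.divergence < max_div]


def density_of_insertion(n_insertions: int, assembly_size_gb: float) -> float:
    """DI = number of recent insertions / assembly size in Gb."""
    if assembly_size_gb <= 0:
        raise ValueError("assembly size must be positive")
    return n_insertions / assembly_size_gb


def make_pairs(profiles: Sequence[SpeciesProfile],
               fold: float = 2.0) -> list[SpeciesPair]:
    """All ordered pairs whose long-lived member lives >= fold times longer.

    The boundary ratio (exactly ``fold``) is included.  Output is sorted by
    (long, short) species name; one species may appear in many pairs.
    """
    pairs = [
        SpeciesPair(a, b)
        for a in profiles for b in profiles
        if a.species_name != b.species_name
        and a.max_lifespan_years >= fold * b.max_lifespan_years
    ]
    return sorted(pairs, key=lambda p: (p.long_species.species_name,
                                        p.short_species.species_name))


# ---------------------------------------------------------------------------
# Exact Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def signed_rank_null_counts(n: int) -> np.ndarray:
    """Number of sign assignments of ranks 1..n summing to each W+ value.

    counts[w] = #subsets of {1..n} with sum w; the null distribution of the
    positive-rank sum is counts / 2^n.  Built by the standard subset-sum
    dynamic programme (polynomial product of (1 + x^k)).
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=np.float64)
    counts[0] = 1.0
    for k in range(1, n + 1):
        counts[k:] += counts[:-k].copy()
    return counts


def wilcoxon_signed_rank(differences: Sequence[float], alternative: str = "two_sided",
                         method: str = "auto") -> tuple[float, float]:
    """Paired signed-rank test on a vector of differences.

    Zero differences are dropped before ranking; ties in |difference| get
    average ranks.  ``method="exact"`` enumerates the null distribution of
    the positive-rank sum (valid when there are no ties); ``"normal"`` uses
    the large-sample normal approximation with tie correction and
    continuity correction; ``"auto"`` picks exact when n <= 30 and the
    ranks are untied.

    Returns (W, p) where W is the positive-rank sum.
    """
    if alternative not in ("less", "greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    has_ties = len(np.unique(np.abs(d))) != n
    w_pos = float(ranks[d > 0].sum())

    if method == "auto":
        method = "exact" if (not has_ties and n <= 30) else "normal"
    if method == "exact" and has_ties:
        raise ValueError("exact method requires untied |differences|")

    if method == "exact":
        counts = signed_rank_null_counts(n)
        total = 2.0 ** n
        w = int(round(w_pos))
        p_less = counts[: w + 1].sum() / total
        p_greater = counts[w:].sum() / total
    elif method == "normal":
        mu = n * (n + 1) / 4.0
        # tie correction on the variance of the rank sum
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = (n * (n + 1) * (2 * n + 1)
               - 0.5 * np.sum(tie_counts ** 3 - tie_counts)) / 24.0
        sd = math.sqrt(var)
        p_less = stats.norm.cdf((w_pos - mu + 0.5) / sd)
        p_greater = stats.norm.sf((w_pos - mu - 0.5) / sd)
    else:
        raise ValueError(f"unknown method {method!r}")

    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return w_pos, float(p)


def paired_di_test(di: Mapping[str, float], profiles: Sequence[SpeciesProfile],
                   fold: float = 2.0, alternative: str = "less",
                   method: str = "auto") -> dict:
    """Build lifespan pairs and test DI(long) - DI(short) differences.

    ``alternative="less"`` encodes the hypothesis that long-lived species
    carry fewer recent insertions per Gb.
    """
    pairs = make_pairs(profiles, fold=fold)
    if not pairs:
        raise ValueError("no species pairs satisfy the lifespan fold rule")
    diffs = [di[p.long_species.species_name] - di[p.short_species.species_name]
             for p in pairs]
    w, p = wilcoxon_signed_rank(diffs, alternative=alternative, method=method)
    return {"pairs": pairs, "differences": diffs, "n_pairs": len(pairs),
            "W": w, "p_value": p, "alternative": alternative}


# ---------------------------------------------------------------------------
# Windowed densities and genomic-feature correlations
# ---------------------------------------------------------------------------

def tile_windows(chrom_lengths: Mapping[str, int],
                 window_size: int) -> list[tuple[str, int, int]]:
    """Non-overlapping windows tiling each chromosome; last one may be short."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    windows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        for start in range(0, length, window_size):
            windows.append((chrom, start, min(start + window_size, length)))
    return windows


def _counts_by_start(starts_by_chrom: Mapping[str, Sequence[int]],
                     windows: Sequence[tuple[str, int, int]],
                     window_size: int) -> np.ndarray:
    index = {(c, s // window_size): i for i, (c, s, _) in enumerate(windows)}
    counts = np.zeros(len(windows), dtype=np.int64)
    for chrom, starts in starts_by_chrom.items():
        for pos in starts:
            i = index.get((chrom, pos // window_size))
            if i is not None:
                counts[i] += 1
    return counts


def window_density(insertions: Sequence[TEInsertion],
                   chrom_lengths: Mapping[str, int],
                   window_size: int) -> WindowTrack:
    """Insertion counts per non-overlapping window; assignment by start position."""
    windows = tile_windows(chrom_lengths, window_size)
    starts: dict[str, list[int]] = {}
    for ins in insertions:
        starts.setdefault(ins.query_name, []).append(ins.start)
    counts = _counts_by_start(starts, windows, window_size)
    return WindowTrack(window_size=window_size, windows=windows, counts=counts)


def feature_density(features: GeneFeatureSet,
                    track: WindowTrack) -> pd.DataFrame:
    """Per-window densities (per Mb) of genes, exons, introns and intergenic.

    A feature interval counts in the window containing its start, matching
    the insertion convention.
    """
    out = {}
    lengths_mb = np.array([(e - s) / 1e6 for _, s, e in track.windows])
    for feat in ("gene", "exon", "intron", "intergenic"):
        per_chrom = features.feature_intervals(feat)
        starts = {c: [s for s, _ in iv] for c, iv in per_chrom.items()}
        counts = _counts_by_start(starts, track.windows, track.window_size)
        out[f"{feat}_density"] = counts / lengths_mb
    out["te_density"] = track.density
    df = pd.DataFrame(out)
    df.insert(0, "chrom", [w[0] for w in track.windows])
    df.insert(1, "start", [w[1] for w in track.windows])
    df.insert(2, "end", [w[2] for w in track.windows])
    return df


def spearman_corr(x: Sequence[float], y: Sequence[float],
                  exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p, or exact permutation p.

    The exact variant enumerates all n! orderings (n <= 8) and reports the
    two-sided tail probability of |rho|.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rho undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    if not exact:
        return float(rho), float(p)
    if len(x) > 8:
        raise ValueError("exact permutation p limited to n <= 8")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(_rank_corr(rx, ry))
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_rank_corr(rx, np.array(perm))) >= obs - 1e-12:
            hits += 1
    return float(rho), hits / total


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def classify_windows(gene_densities: Sequence[float],
                     q_low: float = 0.25, q_high: float = 0.75) -> np.ndarray:
    """Label windows gene_poor (<= low quantile) / gene_rich (>= high quantile).

    Quantiles use the linear-interpolation definition.  If the two
    thresholds coincide (degenerate, e.g. all densities equal) every window
    would satisfy both rules; all are labelled neither instead.
    """
    d = np.asarray(gene_densities, float)
    if len(d) < 4:
        raise ValueError("need at least 4 windows to classify")
    lo = np.quantile(d, q_low)
    hi = np.quantile(d, q_high)
    labels = np.full(len(d), "neither", dtype=object)
    if lo >= hi:
        return labels
    labels[d <= lo] = "gene_poor"
    labels[d >= hi] = "gene_rich"
    return labels


def compare_rich_poor(te_density_rich: Sequence[float],
                      te_density_poor: Sequence[float],
                      alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) contrast of TE density between groups.

    Exact for small untied samples, normal approximation otherwise.
    Returns (U statistic of the rich group, p).
    """
    rich = np.asarray(te_density_rich, float)
    poor = np.asarray(te_density_poor, float)
    if len(rich) == 0 or len(poor) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(rich, poor, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)
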