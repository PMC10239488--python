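"""Determinism and statistical fidelity of the synthetic-data generator."""

import logging
import math

import numpy as np
import pytest
from scipy import stats

from repeatlens import synthetic_data as sim
from repeatlens.divergence import block_divergence
from repeatlens.landscape import merge_fragments, record_divergences
from repeatlens.rmsk_io import read_align, read_out


def test_make_consensus_determinism_and_gc():
    a = sim.make_consensus(1000, 0.5, 1)
    b = sim.make_consensus(1000, 0.5, 1)
    assert a == b
    with pytest.raises(ValueError):
        sim.make_consensus(1000, 1.0, 1)
    s = sim.make_consensus(100_000, 0.4, 2)
    gc = (s.count("G") + s.count("C")) / len(s)
    sd = math.sqrt(0.4 * 0.6 / len(s))
    assert abs(gc - 0.4) < 3 * sd


def test_mutate_copy_identity_and_kappa_limit():
    cons = sim.make_consensus(2000, 0.41, 3)
    copy, (aq, ac) = sim.mutate_copy(cons, 0.0, 2.0, 4)
    assert copy == cons and aq == copy and ac == cons

    # kappa -> infinity: substitutions become pure transitions
    _, (aq2, ac2) = sim.mutate_copy(cons, 0.05, 1e6, 4)
    from repeatlens.divergence import count_substitutions

    c = count_substitutions(aq2, ac2)
    assert c.n_transversions == 0
    assert c.n_transitions > 0

    with pytest.raises(ValueError, match="unreachable"):
        sim.mutate_copy(cons, 5.0, 2.0, 4)


def test_mutate_copy_estimator_consistency():
    cons = sim.make_consensus(5000, 0.41, 5)
    rng = np.random.default_rng(6)
    ests = [block_divergence(*sim.mutate_copy(cons, 0.10, 2.0, rng)[1])
            for _ in range(200)]
    ests = np.array(ests)
    se = ests.std(ddof=1) / math.sqrt(len(ests))
    assert abs(ests.mean() - 0.10) < 2 * se


def test_place_insertions_counts_and_fragmentation():
    cfg = sim.SimulationConfig(
        seed=1, genome_length=1_000_000,
        consensus_library={"LINE": sim.ConsensusSpec(1, 1000)},
        insertion_counts={"LINE": 10}, fragmentation_prob=0.0)
    truth = sim.place_insertions(cfg)
    assert len(truth.insertions) == 10
    assert len(truth.genome["chr1"]) == 1_000_000

    cfg2 = sim.SimulationConfig(
        seed=2, genome_length=1_000_000,
        consensus_library={"LINE": sim.ConsensusSpec(1, 1000)},
        insertion_counts={"LINE": 10}, fragmentation_prob=1.0,
        fragment_count_range=(2, 2))
    truth2 = sim.place_insertions(cfg2)
    records = sim.truth_to_records(truth2)
    assert len(records) == 20
    assert len({r.insertion_id for r in records}) == 10


def test_place_insertions_infeasible_packing():
    cfg = sim.SimulationConfig(
        seed=1, genome_length=5_000,
        consensus_library={"LINE": sim.ConsensusSpec(1, 1000)},
        insertion_counts={"LINE": 10}, fragmentation_prob=0.0)
    with pytest.raises(ValueError, match="[Ii]nfeasible|exceeds"):
        sim.place_insertions(cfg)


def test_placement_uniformity_chi_square():
    pvals = []
    for seed in range(5):
        cfg = sim.SimulationConfig(
            seed=seed, genome_length=2_000_000,
            consensus_library={"SINE": sim.ConsensusSpec(1, 300)},
            insertion_counts={"SINE": 400}, fragmentation_prob=0.0)
        truth = sim.place_insertions(cfg)
        starts = np.array([i.span[0] for i in truth.insertions])
        counts, _ = np.histogram(starts, bins=10, range=(0, 2_000_000))
        pvals.append(stats.chisquare(counts).pvalue)
    assert max(pvals) > 0.01  # not systematically non-uniform
    assert np.mean(pvals) > 0.1


def test_emit_roundtrip_matches_truth(truth, emitted, caplog):
    with caplog.at_level(logging.WARNING):
        records = read_out(emitted["out"])
        blocks = read_align(emitted["align"])
        divs = record_divergences(records, blocks)
    assert not caplog.records  # emitted files parse with zero warnings
    assert records == sim.truth_to_records(truth)
    merged = merge_fragments(records, divs)
    by_id = {t.insertion_id: t for t in truth.insertions}
    for ins in merged:
        t = by_id[ins.insertion_id]
        assert ins.total_bp == t.total_bp
        assert ins.divergence == pytest.approx(t.realized_divergence, abs=1e-12)
        assert ins.te_class == t.te_class


def test_emit_empty_truth_header_only(tmp_path):
    empty = sim.TruthTable(genome={"chr1": "ACGT" * 10}, insertions=[])
    paths = sim.emit_annotation(empty, tmp_path / "e")
    assert read_out(paths["out"]) == []
    assert read_align(paths["align"]) == []


def test_full_determinism_byte_identical(tmp_path):
    cfg = sim.SimulationConfig(seed=77, genome_length=100_000,
                               insertion_counts={"LINE": 5, "SINE": 10})
    p1 = sim.emit_annotation(sim.place_insertions(cfg), tmp_path / "a")
    p2 = sim.emit_annotation(sim.place_insertions(cfg), tmp_path / "b")
    for key in ("out", "align", "fasta"):
        assert open(p1[key], "rb").read() == open(p2[key], "rb").read()


def test_make_genes_empty_and_uniform(tmp_path):
    genes = sim.make_genes(500_000, 0, 0.0, 1, tmp_path / "e.gff3")
    assert genes == []
    from repeatlens.rmsk_io import read_gene_annotation

    fs = read_gene_annotation(tmp_path / "e.gff3", "GFF3", {"chr1": 500_000})
    assert fs.intergenic["chr1"] == [(0, 500_000)]

    genes2 = sim.make_genes(5_000_000, 200, 0.0, 2, tmp_path / "u.gff3")
    starts = np.array([s for s, _ in genes2])
    counts, _ = np.histogram(starts, bins=10, range=(0, 5_000_000))
    assert stats.chisquare(counts).pvalue > 0.01


def test_make_genes_clustering_recovered(tmp_path):
    """Quantile split of window gene density finds the planted clusters."""
    from repeatlens.density_stats import classify_windows, window_density
    from repeatlens.rmsk_io import read_gene_annotation

    L = 2_000_000
    sim.make_genes(L, 60, 0.9, 3, tmp_path / "c.gff3")
    fs = read_gene_annotation(tmp_path / "c.gff3", "GFF3", {"chr1": L})
    track = window_density([], {"chr1": L}, 100_000)
    from repeatlens.density_stats import feature_density

    table = feature_density(fs, track)
    labels = classify_windows(table["gene_density"])
    # planted clusters live at fractions [0.1,0.2] and [0.6,0.7]
    cluster_windows = {i for i, (_, s, _e) in enumerate(track.windows)
                       if 0.1 * L <= s < 0.2 * L or 0.6 * L <= s < 0.7 * L}
    rich = {i for i, lab in enumerate(labels) if lab == "gene_rich"}
    # every cluster window is recovered as gene-rich, and the cluster
    # windows are exactly the densest ones
    assert cluster_windows <= rich
    dens = np.asarray(table["gene_density"])
    top4 = set(np.argsort(dens)[-len(cluster_windows):])
    assert top4 == cluster_windows


def test_make_line_locus_truth_flags(domain_profiles):
    for intact, disruption in [(True, "stop"), (False, "stop"),
                               (False, "frameshift"), (False, "deletion")]:
        seq, flag = sim.make_line_locus(intact, disruption, rng=6,
                                        profiles=domain_profiles)
        assert flag is intact
        assert set(seq) <= set("ACGT")
    with pytest.raises(ValueError):
        sim.make_line_locus(False, "nonsense", rng=6, profiles=domain_profiles)


def test_make_cohort_di_ordering_and_errors():
    spec = sim.default_cohort_spec()
    cohort = sim.make_cohort(spec, seed=4)
    from repeatlens import density_stats as ds

    di = {}
    for p in cohort.species:
        recent = ds.select_recent(cohort.truths[p.species_name].as_te_insertions())
        di[p.species_name] = ds.density_of_insertion(len(recent),
                                                     p.assembly_size_gb)
    long_mean = np.mean([di[s.name] for s in spec if s.w_recent == 0.15])
    short_mean = np.mean([di[s.name] for s in spec if s.w_recent == 0.30])
    assert long_mean < short_mean  # DI ordering follows the planted rates

    with pytest.raises(ValueError):
        sim.make_cohort(spec[:1], seed=1)
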