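from pathlib import Path

import numpy as np
import pytest

from lnctarget import (
    GenomicInterval,
    extract_promoter_window,
    intersect_consensus,
    metaprofile,
    scan_windows,
)
from lnctarget.config import substream
from lnctarget.intervals import BedGraphCoverage
from lnctarget.synthetic import (
    SimConfig,
    SimCountModel,
    SynthTruth,
    assign_regulatory_truth,
    generate_genome,
    generate_study,
    make_pwms,
    plant_motifs,
    simulate_chirp_peaks,
    simulate_counts,
    simulate_coverage,
)

SMALL = dict(
    n_chromosomes=2,
    chrom_length_bp=400_000,
    n_genes=60,
    n_tfs=8,
    n_cofactors=4,
    n_direct=16,
    n_direct_tfs=3,
    n_direct_cofactors=1,
    n_bound_only=5,
    n_low_expression=3,
    downstream_range=(3, 6),
    n_pwms=5,
    n_chip_direct=6,
    n_chip_other=4,
)


@pytest.fixture
def small_cfg():
    return SimConfig(**SMALL)


def test_same_seed_gives_identical_files(tmp_path, small_cfg):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1, _ = generate_study(small_cfg, 5, d1)
    p2, _ = generate_study(small_cfg, 5, d2)
    for key in ("genome_fasta", "annotation_gtf", "chirp_even_bed", "counts_model_a"):
        assert Path(p1[key]).read_bytes() == Path(p2[key]).read_bytes()


def test_gene_count_and_exon_containment():
    cfg = SimConfig(**{**SMALL, "n_genes": 80})
    genome, genes = generate_genome(cfg, substream(3, "genome"))
    assert len(genes) == 80
    for g in genes:
        assert len(g.exons) >= 1
        for s, e in g.exons:  # exhaustive containment scan
            assert g.tx_start <= s < e <= g.tx_end
    # genes non-overlapping per strand (stronger here: per chromosome)
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))
    for ivs in by_chrom.values():
        ivs.sort()
        assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))


def test_infeasible_packing_reports_required_length():
    cfg = SimConfig(**{**SMALL, "chrom_length_bp": 60_000})
    with pytest.raises(ValueError, match="need chromosome length"):
        generate_genome(cfg, substream(1, "genome"))


def test_planted_motifs_present_verbatim(tmp_path, small_cfg):
    paths, truth = generate_study(small_cfg, 9, tmp_path / "s")
    from lnctarget import read_fasta, read_gtf, read_meme

    genome = read_fasta(paths["genome_fasta"])
    genes = {g.gene_id: g for g in read_gtf(paths["annotation_gtf"])}
    pwms = {p.tf_id: p for p in read_meme(paths["pwm_file"])}
    assert truth.planted_motif_positions
    for (tf, gid), (off, strand) in truth.planted_motif_positions.items():
        w = extract_promoter_window(genes[gid], genome, upstream_bp=1500, downstream_bp=500)
        L = len(pwms[tf])
        sub = w.sequence[off + 1500 : off + 1500 + L]
        expect = pwms[tf].consensus
        if strand == "-":
            from lnctarget.intervals import reverse_complement

            expect = reverse_complement(expect)
        assert sub == expect


def test_zero_planted_motifs_leaves_genome_unchanged(small_cfg):
    genome, genes = generate_genome(small_cfg, substream(2, "genome"))
    before = dict(genome)
    truth = SynthTruth()  # no TF layer -> nothing to plant
    plant_motifs(genome, genes, truth, [], small_cfg, substream(2, "plant"))
    assert genome == before


def test_scan_recovers_planted_motifs(tmp_path, small_cfg):
    """Scanning the planted promoter windows with the planting PWMs at
    q < 0.05 recovers at least the planted positions."""
    paths, truth = generate_study(small_cfg, 13, tmp_path / "s")
    from lnctarget import read_fasta, read_gtf, read_meme

    genome = read_fasta(paths["genome_fasta"])
    genes = {g.gene_id: g for g in read_gtf(paths["annotation_gtf"])}
    pwms = {p.tf_id: p for p in read_meme(paths["pwm_file"])}
    planted_genes = sorted({g for (_, g) in truth.planted_motif_positions})
    windows = [
        extract_promoter_window(genes[g], genome, upstream_bp=1500, downstream_bp=500)
        for g in planted_genes
    ]
    tf_ids = sorted({tf for (tf, _) in truth.planted_motif_positions})
    hits, _ = scan_windows([pwms[t] for t in tf_ids], windows, motif_q=0.05)
    found = set(zip(hits["tf_id"], hits["gene_id"], hits["offset"], hits["strand"]))
    for (tf, g), (off, strand) in truth.planted_motif_positions.items():
        assert (tf, g, off, strand) in found


# ---------------------------------------------------------------------------
# count model
# ---------------------------------------------------------------------------


def test_null_counts_centered(rng):
    n = 10_000
    model = SimCountModel(
        baseline_mean=np.full(n, 300.0),
        dispersion=np.full(n, 0.05),
        replicates_per_group=3,
        library_size_factors=np.ones(6),
    )
    cm = simulate_counts([f"g{i}" for i in range(n)], model, {}, rng)
    vals = cm.counts.to_numpy(dtype=float)
    ratio = np.log(vals[:, 3:].mean(axis=1) / vals[:, :3].mean(axis=1))
    assert abs(np.median(ratio)) < 0.02


def test_zero_dispersion_is_poisson(rng):
    n = 2000
    model = SimCountModel(
        baseline_mean=np.full(n, 1000.0),
        dispersion=np.zeros(n),
        replicates_per_group=50,
        library_size_factors=np.ones(100),
    )
    cm = simulate_counts([f"g{i}" for i in range(n)], model, {}, rng)
    vals = cm.counts.to_numpy(dtype=float)
    vmr = vals.var(axis=1, ddof=1) / vals.mean(axis=1)
    assert 0.95 < vmr.mean() < 1.05


def test_planted_halving_effect(rng):
    n = 200
    model = SimCountModel(
        baseline_mean=np.full(n, 1000.0),
        dispersion=np.full(n, 0.05),
        replicates_per_group=50,
        library_size_factors=np.ones(100),
    )
    genes = [f"g{i}" for i in range(n)]
    cm = simulate_counts(genes, model, {g: -1.0 for g in genes}, rng)
    vals = cm.counts.to_numpy(dtype=float)
    ratios = vals[:, 50:].mean(axis=1) / vals[:, :50].mean(axis=1)
    assert ((ratios > 0.45) & (ratios < 0.55)).mean() > 0.95
    assert 0.45 < ratios.mean() < 0.55


# ---------------------------------------------------------------------------
# peak simulation
# ---------------------------------------------------------------------------


def _truth_with_sites(sites):
    t = SynthTruth()
    t.true_binding_sites = sites
    return t


def test_noiseless_peaks_equal_truth(small_cfg):
    sites = [GenomicInterval("chr1", 1000 * i + 500, 1000 * i + 800) for i in range(20)]
    cfg = SimConfig(**{**SMALL, "detect_prob": 1.0, "jitter_bp": 0, "noise_rate_per_mb": 0.0})
    even, odd = simulate_chirp_peaks(
        _truth_with_sites(sites), {"chr1": 100_000}, cfg, substream(1, "x")
    )
    assert [(p.chrom, p.start, p.end) for p in even] == [
        (s.chrom, s.start, s.end) for s in sites
    ]
    assert [(p.start, p.end) for p in even] == [(p.start, p.end) for p in odd]


def test_zero_detection_gives_empty_files(small_cfg):
    sites = [GenomicInterval("chr1", 5000, 5300)]
    cfg = SimConfig(**{**SMALL, "detect_prob": 0.0, "noise_rate_per_mb": 0.0})
    even, odd = simulate_chirp_peaks(
        _truth_with_sites(sites), {"chr1": 100_000}, cfg, substream(1, "x")
    )
    assert even == [] and odd == []


def test_consensus_recovery_matches_binomial_expectation():
    """Over repeated simulations the dual-probe consensus recovers
    detect_prob^2 of true sites (independence of the probe sets)."""
    p = 0.9
    n_sites, n_sims = 100, 200
    sites = [
        GenomicInterval("chr1", 2000 * i + 500, 2000 * i + 800) for i in range(n_sites)
    ]
    cfg = SimConfig(**{**SMALL, "detect_prob": p, "noise_rate_per_mb": 0.0})
    truth = _truth_with_sites(sites)
    rng = substream(17, "binomial")
    recovered = []
    for _ in range(n_sims):
        even, odd = simulate_chirp_peaks(truth, {"chr1": 300_000}, cfg, rng)
        cons = intersect_consensus(even, odd)
        hit = sum(
            any(c.interval.start < s.end and s.start < c.interval.end for c in cons)
            for s in sites
        )
        recovered.append(hit)
    expect = n_sites * p * p
    se = np.sqrt(n_sites * p * p * (1 - p * p) / n_sims)
    assert abs(np.mean(recovered) - expect) <= 3 * se


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def test_coverage_no_peaks_is_flat_background():
    recs = simulate_coverage([], {"chr1": 1000}, bin_bp=25, background=1.5)
    assert all(v == 1.5 for _, _, _, v in recs)


def test_coverage_single_peak_max_at_midpoint():
    peak = GenomicInterval("chr1", 4000, 4410)  # midpoint 4205
    recs = simulate_coverage([peak], {"chr1": 10_000}, bin_bp=25)
    best = max(recs, key=lambda r: r[3])
    assert best[1] <= 4205 < best[2]


def test_metaprofile_of_peak_midpoints_peaks_at_center():
    peaks = [GenomicInterval("chr1", 10_000 * i + 4000, 10_000 * i + 4400) for i in range(5)]
    recs = simulate_coverage(peaks, {"chr1": 60_000}, bin_bp=25)
    cov = BedGraphCoverage(recs, chrom_sizes={"chr1": 60_000})
    anchors = [(p.chrom, p.midpoint, "+") for p in peaks]
    prof = metaprofile(cov, anchors, half_window_bp=3000, n_bins=60)
    assert np.nanargmax(prof) in (29, 30)


# ---------------------------------------------------------------------------
# truth invariants
# ---------------------------------------------------------------------------


def test_truth_structure_invariants(small_cfg):
    genome, genes = generate_genome(small_cfg, substream(21, "genome"))
    truth, catalog = assign_regulatory_truth(small_cfg, genes, substream(21, "truth"))
    assert not truth.direct_target_ids & truth.indirect_target_ids
    down = set()
    for tf, layer in truth.tf_layer.items():
        assert tf in truth.direct_target_ids and tf in truth.tf_ids
        down |= set(layer["downstream"])
    assert truth.indirect_target_ids <= down
    assert len(truth.tf_layer) == small_cfg.n_direct_tfs
    assert len(truth.direct_target_ids) == small_cfg.n_direct
    assert set(catalog["gene_id"]) == truth.tf_ids | truth.cofactor_ids


def test_noiseless_truth_sites_survive_consensus(small_cfg):
    cfg = SimConfig(**{**SMALL, "detect_prob": 1.0, "noise_rate_per_mb": 0.0})
    genome, genes = generate_genome(cfg, substream(23, "genome"))
    truth, _ = assign_regulatory_truth(cfg, genes, substream(23, "truth"))
    sizes = {c: len(s) for c, s in genome.items()}
    even, odd = simulate_chirp_peaks(truth, sizes, cfg, substream(23, "chirp"))
    cons = intersect_consensus(even, odd)
    for s in truth.true_binding_sites:
        assert any(
            c.interval.chrom == s.chrom
            and c.interval.start < s.end
            and s.start < c.interval.end
            for c in cons
        )
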