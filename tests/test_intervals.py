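import numpy as np
import pandas as pd
import pytest

from lnctarget import (
    BedGraphCoverage,
    GeneAnnotation,
    GenomicInterval,
    annotate_peak,
    annotate_peaks,
    feature_distribution,
    intersect_consensus,
    metaprofile,
    read_bed,
    read_gtf,
    write_bed,
    write_gtf,
)
from lnctarget.intervals import GeneIndex


def random_intervals(rng, n, span=100_000, chroms=("chr1", "chr2")):
    out = []
    for i in range(n):
        start = int(rng.integers(0, span - 500))
        out.append(
            GenomicInterval(
                str(rng.choice(chroms)),
                start,
                start + int(rng.integers(1, 500)),
                name=f"iv{i}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# BED / GTF / bedGraph I/O
# ---------------------------------------------------------------------------


def test_bed_round_trip_identity(tmp_path, rng):
    ivs = random_intervals(rng, 1000)
    path = tmp_path / "a.bed"
    write_bed(ivs, path)
    back = read_bed(path)
    assert back == ivs


def test_bed_line_parsing_and_errors(tmp_path):
    p = tmp_path / "x.bed"
    p.write_text("chr1\t99\t200\n")
    (iv,) = read_bed(p)
    assert (iv.start, iv.end) == (99, 200)
    p.write_text("chr1\t99\t200\nchr1\tfoo\t300\n")
    with pytest.raises(ValueError, match=r"x\.bed:2"):
        read_bed(p)


def test_gtf_one_based_conversion_and_round_trip(tmp_path):
    p = tmp_path / "g.gtf"
    p.write_text(
        'chr1\tsrc\tgene\t100\t200\t.\t+\t.\tgene_id "gA"; gene_name "A";\n'
        'chr1\tsrc\texon\t100\t150\t.\t+\t.\tgene_id "gA";\n'
    )
    (g,) = read_gtf(p)
    assert (g.tx_start, g.tx_end) == (99, 200)
    assert g.exons == [(99, 150)]
    out = tmp_path / "h.gtf"
    write_gtf([g], out)
    assert read_gtf(out) == [g]


def test_bedgraph_accessor_background_and_bounds(tmp_path):
    p = tmp_path / "c.bedgraph"
    p.write_text("chr1\t10\t20\t3.5\nchr1\t20\t30\t1.0\n")
    cov = BedGraphCoverage.from_file(p, chrom_sizes={"chr1": 40})
    vals = cov.values("chr1", 5, 35)
    assert (vals[:5] == 0).all()  # uncovered -> 0
    assert (vals[5:15] == 3.5).all()
    assert (vals[15:25] == 1.0).all()
    off_end = cov.values("chr1", 35, 45)
    assert np.isnan(off_end[5:]).all()
    neg = cov.values("chr1", -3, 2)
    assert np.isnan(neg[:3]).all()


# ---------------------------------------------------------------------------
# dual-probe consensus
# ---------------------------------------------------------------------------


def brute_force_consensus(even, odd):
    segs = []
    for e in even:
        for o in odd:
            if e.chrom == o.chrom:
                s, t = max(e.start, o.start), min(e.end, o.end)
                if s < t:
                    segs.append((e.chrom, s, t))
    segs.sort()
    merged = []
    for c, s, t in segs:
        if merged and merged[-1][0] == c and s < merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], t)
        else:
            merged.append([c, s, t])
    return [(c, s, t) for c, s, t in merged]


def as_tuples(peaks):
    return [(p.interval.chrom, p.interval.start, p.interval.end) for p in peaks]


def test_consensus_single_overlap_and_disjoint():
    even = [GenomicInterval("chr1", 100, 200)]
    odd = [GenomicInterval("chr1", 150, 250)]
    assert as_tuples(intersect_consensus(even, odd)) == [("chr1", 150, 200)]
    assert intersect_consensus(even, [GenomicInterval("chr1", 300, 400)]) == []
    assert intersect_consensus([], odd) == []


def test_consensus_matches_bruteforce_oracle(rng):
    even = random_intervals(rng, 500)
    odd = random_intervals(rng, 500)
    got = as_tuples(intersect_consensus(even, odd))
    assert got == brute_force_consensus(even, odd)


def test_consensus_commutative_and_idempotent(rng):
    even = random_intervals(rng, 120)
    odd = random_intervals(rng, 120)
    assert as_tuples(intersect_consensus(even, odd)) == as_tuples(
        intersect_consensus(odd, even)
    )
    same = as_tuples(intersect_consensus(even, even))
    # idempotence: EVEN = ODD returns the merged EVEN intervals themselves
    merged = brute_force_consensus(even, even)
    assert same == merged


def test_consensus_total_bp_bounded_by_inputs(rng):
    even = random_intervals(rng, 200)
    odd = random_intervals(rng, 200)
    cons = intersect_consensus(even, odd)
    bp = sum(len(p.interval) for p in cons)
    assert bp <= min(sum(len(i) for i in even), sum(len(i) for i in odd))


def test_consensus_provenance_sources_cover_output(rng):
    even = random_intervals(rng, 50)
    odd = random_intervals(rng, 50)
    for iv in even:
        iv.name = "e_" + iv.name
    for iv in odd:
        iv.name = "o_" + iv.name
    by_name = {iv.name: iv for iv in even + odd}
    for p in intersect_consensus(even, odd):
        for src in p.even_sources + p.odd_sources:
            assert by_name[src].overlaps(p.interval)


# ---------------------------------------------------------------------------
# peak-to-gene annotation
# ---------------------------------------------------------------------------


def test_annotate_exact_tss_is_promoter(ten_genes):
    idx = GeneIndex(ten_genes)
    g = ten_genes[0]  # + strand, tss = 5000
    ann = annotate_peak(GenomicInterval("chr1", 4950, 5050), idx, 3000)
    assert ann.feature_class == "promoter"
    assert ann.signed_distance_to_tss == 0
    assert ann.target_gene_id == g.gene_id


def test_annotate_matches_bruteforce_nearest_gene(ten_genes, rng):
    idx = GeneIndex(ten_genes)
    for _ in range(300):
        start = int(rng.integers(0, 115_000))
        peak = GenomicInterval("chr1", start, start + int(rng.integers(50, 400)))
        ann = annotate_peak(peak, idx, 3000)
        mid = peak.midpoint
        best = min(
            ten_genes, key=lambda g: (abs(mid - g.tss), g.gene_id)
        )
        assert ann.target_gene_id == best.gene_id
        d = mid - best.tss if best.strand == "+" else best.tss - mid
        assert ann.signed_distance_to_tss == d
        assert (abs(d) <= 3000) == (ann.feature_class == "promoter")


def test_annotate_intron_past_promoter_window(ten_genes):
    # gene g00: tx 5000-7000 (+), exons end at 5300/5900-6200/6700-7000;
    # a peak centered 3001 bp past every TSS window would be distal here, so
    # shrink the window instead: midpoint 6500 is in the intron 6200..6700
    idx = GeneIndex(ten_genes)
    ann = annotate_peak(GenomicInterval("chr1", 6450, 6550), idx, tss_window_bp=1000)
    assert ann.feature_class == "intron"
    assert ann.target_gene_id == "g00"
    assert ann.signed_distance_to_tss == 1500


def test_annotate_feature_precedence_exon_downstream_distal(ten_genes):
    idx = GeneIndex(ten_genes)
    # midpoint inside the first exon of g00, outside a 100 bp promoter window
    ann = annotate_peak(GenomicInterval("chr1", 5150, 5250), idx, tss_window_bp=100)
    assert ann.feature_class == "exon"
    # just past the gene end of + gene g00 (tx_end 7000)
    ann = annotate_peak(GenomicInterval("chr1", 7020, 7120), idx, tss_window_bp=100)
    assert ann.feature_class == "downstream"
    # far from everything (but window small so not promoter)
    ann = annotate_peak(GenomicInterval("chr1", 11950, 12050), idx, tss_window_bp=100)
    assert ann.feature_class == "distal_intergenic"


def test_annotate_equidistant_tie_breaks_lexicographically():
    genes = [
        GeneAnnotation("gB", "B", "chr1", "+", 1000, 2000, [(1000, 2000)]),
        GeneAnnotation("gA", "A", "chr1", "+", 3000, 4000, [(3000, 4000)]),
    ]
    idx = GeneIndex(genes)
    ann = annotate_peak(GenomicInterval("chr1", 1995, 2005), idx, 3000)  # mid 2000
    assert abs(2000 - 1000) == abs(2000 - 3000)
    assert ann.target_gene_id == "gA"


def test_annotate_chromosome_without_genes(ten_genes):
    idx = GeneIndex(ten_genes)
    ann = annotate_peak(GenomicInterval("chrUn", 100, 200), idx, 3000)
    assert ann.feature_class == "distal_intergenic"
    assert ann.target_gene_id is None


# ---------------------------------------------------------------------------
# feature distribution
# ---------------------------------------------------------------------------


def test_feature_distribution_hand_count_and_invariance(rng):
    classes = ["intron"] * 4 + ["promoter"] * 3 + ["exon"] * 2 + ["downstream"]
    df = pd.DataFrame({"feature_class": classes})
    dist = feature_distribution(df)
    assert dist == {"promoter": 0.3, "exon": 0.2, "intron": 0.4, "downstream": 0.1}
    assert abs(sum(dist.values()) - 1.0) < 1e-12
    perm = df.sample(frac=1.0, random_state=1)
    assert feature_distribution(perm) == dist


def test_feature_distribution_all_intronic_and_empty():
    df = pd.DataFrame({"feature_class": ["intron", "intron"]})
    assert feature_distribution(df) == {"intron": 1.0}
    with pytest.raises(ValueError):
        feature_distribution(pd.DataFrame({"feature_class": []}))


# ---------------------------------------------------------------------------
# metaprofile
# ---------------------------------------------------------------------------


def test_metaprofile_constant_coverage():
    cov = BedGraphCoverage([("chr1", 0, 10_000, 2.5)], chrom_sizes={"chr1": 10_000})
    prof = metaprofile(cov, [("chr1", 5000, "+")], half_window_bp=1000, n_bins=20)
    assert np.allclose(prof, 2.5)


def test_metaprofile_single_anchor_equals_binned_window():
    recs = [("chr1", i * 10, (i + 1) * 10, float(i)) for i in range(100)]
    cov = BedGraphCoverage(recs, chrom_sizes={"chr1": 1000})
    prof = metaprofile(cov, [("chr1", 500, "+")], half_window_bp=100, n_bins=10)
    window = cov.values("chr1", 400, 600).reshape(10, 20).mean(axis=1)
    assert np.allclose(prof, window)
    # minus-strand anchor reverses the window
    prof_m = metaprofile(cov, [("chr1", 500, "-")], half_window_bp=100, n_bins=10)
    assert np.allclose(prof_m, window[::-1])


def test_metaprofile_two_pulses_hand_average():
    cov = BedGraphCoverage(
        [("chr1", 510, 511, 1.0), ("chr1", 489, 490, 1.0)],
        chrom_sizes={"chr1": 1000},
    )
    anchors = [("chr1", 500, "+"), ("chr1", 500, "+")]
    prof = metaprofile(cov, anchors, half_window_bp=20, n_bins=8)
    direct = cov.values("chr1", 480, 520).reshape(8, 5).mean(axis=1)
    assert np.allclose(prof, direct)
    # symmetric pulses at +10/-10 of the center -> symmetric profile
    assert np.allclose(prof, prof[::-1])


def test_metaprofile_truncated_window_excluded_binwise():
    cov = BedGraphCoverage([("chr1", 0, 1000, 1.0)], chrom_sizes={"chr1": 1000})
    prof = metaprofile(
        cov, [("chr1", 50, "+"), ("chr1", 500, "+")], half_window_bp=100, n_bins=10
    )
    # first anchor's leading bins fall off the chromosome; the second anchor
    # still provides signal for every bin
    assert np.allclose(prof, 1.0)
    # solo truncated anchor: window [-50, 150) at binsize 20 -> the first
    # 2 bins are fully off-chromosome (NaN); bin 2 is half-observed
    prof_solo = metaprofile(cov, [("chr1", 50, "+")], half_window_bp=100, n_bins=10)
    assert np.isnan(prof_solo[:2]).all() and np.allclose(prof_solo[2:], 1.0)


def test_metaprofile_requires_divisible_bins():
    cov = BedGraphCoverage([("chr1", 0, 100, 1.0)])
    with pytest.raises(ValueError):
        metaprofile(cov, [("chr1", 50, "+")], half_window_bp=100, n_bins=7)
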