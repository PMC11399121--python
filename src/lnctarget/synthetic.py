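"""Synthetic multi-omics study with a planted two-layer regulatory truth.

Generates everything the cascade consumes — a toy genome (FASTA), gene
annotation (GTF), dual-probe ChIRP and TF ChIP peak files (BED), knockdown
vs control NB count matrices for two cell models plus a TF-knockdown matrix
(TSV), promoter sequences with planted TF motifs, PWMs (MEME text), a
gene-set collection (GMT), a TF/co-factor catalog (TSV) and a coverage
track (bedGraph) — together with the ground truth needed to score recovery.

The planted causal structure is a hierarchical cascade: the lncRNA binds
and perturbs a set of *direct* targets, some of which are transcription
factors; each planted TF in turn propagates the perturbation to a set of
downstream genes (mostly *indirect* targets, perturbed without lncRNA
binding) whose promoters carry the TF's motif.  A designated partner TF
additionally has its own ChIP binding profile and knockdown transcriptome,
providing the inputs for the common-direct-target derivation.

Background sequence is i.i.d. uniform over A/C/G/T, which makes the exact
PWM p-values of the scanning null correct by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import substream
from .diffexpr import CountMatrix
from .intervals import (
    GeneAnnotation,
    GenomicInterval,
    write_bed,
    write_fasta,
    write_gtf,
)
from .motifs import PWM, PromoterWindow, extract_promoter_window, write_meme, write_window_sequence

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    The defaults define a 2 x 1 Mb genome with 300 genes, 20 TFs (8 of them
    planted as direct lncRNA targets), 60 direct targets in all, 5-30
    downstream genes per planted TF, and 3 vs 3 replicates per cell model —
    large enough for stable recovery statistics, small enough for
    seconds-scale runs.
    """

    # genome / annotation
    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    n_genes: int = 300
    gene_length_range: tuple = (1000, 2500)
    intergenic_gap_range: tuple = (3600, 4200)
    max_exons_per_gene: int = 3
    edge_margin_bp: int = 2500

    # regulatory truth
    n_tfs: int = 20
    n_cofactors: int = 12
    n_direct: int = 60
    n_direct_tfs: int = 8
    n_direct_cofactors: int = 4
    n_bound_only: int = 15
    n_low_expression: int = 10
    downstream_range: tuple = (5, 30)
    downstream_direct_frac: float = 0.3
    effect_range: tuple = (0.8, 2.0)
    tf_effect_range: tuple = (1.8, 2.2)
    model_b_effect_jitter: tuple = (0.9, 1.1)

    # count model
    replicates_per_group: int = 3
    baseline_range: tuple = (100.0, 2000.0)
    tf_baseline_range: tuple = (800.0, 2000.0)
    low_baseline_range: tuple = (0.05, 0.3)
    dispersion_range: tuple = (0.01, 0.05)
    dispersion_cap: float = 2.0
    library_factor_range: tuple = (0.8, 1.25)

    # binding-site geometry (offsets are TSS-relative, transcription-oriented)
    tf_site_offsets: tuple = (-1400, -880, -360, 160, 680, 1200)
    sites_per_direct: int = 2
    site_width_range: tuple = (200, 380)

    # peak simulation
    detect_prob: float = 0.9
    jitter_bp: int = 50
    noise_rate_per_mb: float = 2.0

    # TF ChIP / partner layer
    n_chip_direct: int = 25
    n_chip_other: int = 20

    # motifs
    motif_length: int = 12
    consensus_prob: float = 0.85
    n_pwms: int = 18
    motif_upstream_bp: int = 1500
    motif_downstream_bp: int = 500

    # coverage track
    coverage_bin_bp: int = 25
    coverage_shape_sd_bp: float = 300.0
    coverage_background: float = 1.0
    coverage_amplitude: float = 8.0

    # gene sets
    n_random_terms: int = 20
    n_target_terms: int = 5

    def validate(self) -> None:
        if self.n_chromosomes < 2:
            raise ValueError("need >= 2 chromosomes")
        if self.n_genes < 50:
            raise ValueError("need >= 50 genes")
        if not (0.0 <= self.detect_prob <= 1.0):
            raise ValueError("detect_prob must lie in [0, 1]")
        if self.jitter_bp < 0:
            raise ValueError("jitter_bp must be >= 0")
        if self.jitter_bp * 2 >= self.site_width_range[0]:
            raise ValueError("jitter must be < half the minimum site width")
        if self.dispersion_range[1] > self.dispersion_cap:
            raise ValueError("dispersion exceeds cap")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown SimConfig key {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


@dataclass
class SimCountModel:
    """NB noise model: per-gene mean/dispersion, variance = mu + alpha mu^2."""

    baseline_mean: np.ndarray
    dispersion: np.ndarray
    replicates_per_group: int
    library_size_factors: np.ndarray

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.baseline_mean)) or np.any(self.baseline_mean <= 0):
            raise ValueError("baseline means must be finite and > 0")
        if np.any(self.dispersion < 0):
            raise ValueError("dispersion must be >= 0")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")
        if np.any(self.library_size_factors <= 0):
            raise ValueError("library size factors must be > 0")


@dataclass
class SynthTruth:
    """Planted ground truth of the synthetic study."""

    direct_target_ids: set = field(default_factory=set)
    indirect_target_ids: set = field(default_factory=set)
    bound_only_ids: set = field(default_factory=set)
    low_expression_ids: set = field(default_factory=set)
    tf_ids: set = field(default_factory=set)
    cofactor_ids: set = field(default_factory=set)
    tf_layer: dict = field(default_factory=dict)  # tf -> {"sign", "downstream"}
    planted_effects: dict = field(default_factory=dict)  # gene -> {"A","B"}
    tfkd_effects: dict = field(default_factory=dict)  # gene -> lfc (model B)
    planted_motif_positions: dict = field(default_factory=dict)  # (tf,g)->(off,strand)
    true_binding_sites: list = field(default_factory=list)
    chip_sites: list = field(default_factory=list)
    chip_target_ids: set = field(default_factory=set)
    partner_tf: Optional[str] = None
    noise_peak_rate: float = 0.0

    def validate(self, motif_upstream_bp: int = 1500, motif_downstream_bp: int = 500) -> None:
        if self.direct_target_ids & self.indirect_target_ids:
            raise ValueError("direct and indirect target sets must be disjoint")
        downstream_union = set()
        for tf, layer in self.tf_layer.items():
            if tf not in self.direct_target_ids:
                raise ValueError(f"tf_layer TF {tf} is not a direct target")
            downstream_union |= set(layer["downstream"])
        if not self.indirect_target_ids <= downstream_union:
            raise ValueError("every indirect target must be downstream of >= 1 TF")
        for (tf, g), (off, strand) in self.planted_motif_positions.items():
            if not (-motif_upstream_bp <= off < motif_downstream_bp):
                raise ValueError(f"planted offset {off} outside promoter window")
        if self.noise_peak_rate < 0:
            raise ValueError("noise_peak_rate must be >= 0")


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


def generate_genome(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneAnnotation]]:
    """Random genome plus non-overlapping gene annotation.

    Genes are packed sequentially with generous intergenic gaps so that
    every gene's TSS neighborhood (binding sites, promoter window) is
    unambiguously closest to its own TSS.  Raises when the requested genes
    cannot fit, reporting the required minimum chromosome length.
    """
    cfg.validate()
    genome = {
        f"chr{i + 1}": random_sequence(cfg.chrom_length_bp, rng)
        for i in range(cfg.n_chromosomes)
    }
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1

    genes: list[GeneAnnotation] = []
    gi = 0
    for ci, chrom in enumerate(sorted(genome)):
        cursor = 0
        for _ in range(per_chrom[ci]):
            gap = int(rng.integers(*cfg.intergenic_gap_range))
            length = int(rng.integers(*cfg.gene_length_range))
            start = cursor + gap
            end = start + length
            if end > cfg.chrom_length_bp - cfg.edge_margin_bp:
                need = end + cfg.edge_margin_bp
                raise ValueError(
                    f"infeasible packing on {chrom}: need chromosome length "
                    f">= {need} bp for the requested gene count"
                )
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, cfg.max_exons_per_gene + 1))
            exons = _draw_exons(start, end, n_ex, rng)
            genes.append(
                GeneAnnotation(
                    gene_id=f"g{gi:04d}",
                    gene_name=f"GENE{gi}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=exons,
                )
            )
            cursor = end
    return genome, genes


def _draw_exons(start: int, end: int, n_exons: int, rng: np.random.Generator) -> list:
    """First exon starts at tx_start, last ends at tx_end; exons alternate
    with introns inside the body."""
    if n_exons == 1:
        return [(start, end)]
    n_cuts = 2 * (n_exons - 1)
    inner = rng.choice(
        np.arange(start + 50, end - 50), size=n_cuts, replace=False
    )
    cuts = np.sort(inner)
    bounds = [start, *cuts.tolist(), end]
    return [(bounds[2 * k], bounds[2 * k + 1]) for k in range(n_exons)]


# ---------------------------------------------------------------------------
# regulatory truth
# ---------------------------------------------------------------------------


def assign_regulatory_truth(
    cfg: SimConfig, genes: Sequence[GeneAnnotation], rng: np.random.Generator
) -> tuple[SynthTruth, pd.DataFrame]:
    """Draw roles, planted effects, binding sites and the TF layer."""
    ids = [g.gene_id for g in genes]
    by_id = {g.gene_id: g for g in genes}
    pool = list(ids)
    rng.shuffle(pool)

    def take(n: int) -> list[str]:
        nonlocal pool
        picked, pool = pool[:n], pool[n:]
        return picked

    low = take(cfg.n_low_expression)
    tfs = take(cfg.n_tfs)
    cofactors = take(cfg.n_cofactors)
    direct_tfs = sorted(rng.choice(tfs, cfg.n_direct_tfs, replace=False))
    direct_cof = sorted(rng.choice(cofactors, cfg.n_direct_cofactors, replace=False))
    n_plain = cfg.n_direct - cfg.n_direct_tfs - cfg.n_direct_cofactors
    direct_plain = take(n_plain)
    bound_only = take(cfg.n_bound_only)
    free = sorted(pool)  # neither TF/cofactor nor direct/bound/low

    truth = SynthTruth(
        direct_target_ids=set(direct_tfs) | set(direct_cof) | set(direct_plain),
        bound_only_ids=set(bound_only),
        low_expression_ids=set(low),
        tf_ids=set(tfs),
        cofactor_ids=set(cofactors),
        noise_peak_rate=cfg.noise_rate_per_mb,
    )

    # planted knockdown effects of the lncRNA on its direct targets
    for g in sorted(truth.direct_target_ids):
        sign = -1 if rng.random() < 0.5 else 1
        lo, hi = cfg.tf_effect_range if g in set(direct_tfs) else cfg.effect_range
        mag = rng.uniform(lo, hi)
        jit = rng.uniform(*cfg.model_b_effect_jitter)
        truth.planted_effects[g] = {"A": sign * mag, "B": sign * mag * jit}

    # TF layer: each planted TF propagates to downstream genes
    direct_nontf = sorted(set(direct_cof) | set(direct_plain))
    for tf in direct_tfs:
        sign = int(np.sign(truth.planted_effects[tf]["A"]))
        n_down = int(rng.integers(cfg.downstream_range[0], cfg.downstream_range[1] + 1))
        n_rdg = int(round(cfg.downstream_direct_frac * n_down))
        n_rdg = min(n_rdg, len(direct_nontf))
        picks_rdg = sorted(rng.choice(direct_nontf, n_rdg, replace=False))
        picks_free = sorted(rng.choice(free, n_down - n_rdg, replace=False))
        downstream = picks_rdg + picks_free
        truth.tf_layer[tf] = {"sign": sign, "downstream": downstream}
        for g in picks_free:
            if g in truth.planted_effects:
                continue  # already perturbed via another TF; keep first draw
            mag = rng.uniform(*cfg.effect_range)
            jit = rng.uniform(*cfg.model_b_effect_jitter)
            truth.planted_effects[g] = {"A": sign * mag, "B": sign * mag * jit}
            truth.indirect_target_ids.add(g)

    # true lncRNA binding sites (TF loci are dense binding hubs)
    def add_sites(gene_id: str, offsets: Sequence[int]) -> None:
        g = by_id[gene_id]
        for k, off in enumerate(offsets):
            width = int(rng.integers(*cfg.site_width_range)) // 2 * 2
            center = g.tss + off if g.strand == "+" else g.tss - off
            truth.true_binding_sites.append(
                GenomicInterval(
                    g.chrom,
                    center - width // 2,
                    center + width // 2,
                    name=f"{gene_id}:{k}",
                )
            )

    grid = np.array(cfg.tf_site_offsets)
    for g in direct_tfs:
        add_sites(g, grid.tolist())
    for g in direct_nontf:
        offs = sorted(rng.choice(grid, cfg.sites_per_direct, replace=False))
        add_sites(g, offs)
    for g in sorted(truth.bound_only_ids):
        add_sites(g, [int(rng.choice(grid))])

    # partner TF: ChIP binding and its own knockdown transcriptome (model B)
    partner = direct_tfs[0]
    truth.partner_tf = partner
    chip_direct = sorted(
        rng.choice(
            sorted(truth.direct_target_ids - {partner}),
            cfg.n_chip_direct,
            replace=False,
        )
    )
    chip_other = sorted(rng.choice(free, cfg.n_chip_other, replace=False))
    truth.chip_target_ids = set(chip_direct) | set(chip_other)
    for gene_id in sorted(truth.chip_target_ids):
        g = by_id[gene_id]
        off = int(rng.choice(grid))
        width = int(rng.integers(*cfg.site_width_range)) // 2 * 2
        center = g.tss + off if g.strand == "+" else g.tss - off
        truth.chip_sites.append(
            GenomicInterval(
                g.chrom, center - width // 2, center + width // 2,
                name=f"chip|{gene_id}",
            )
        )
    psign = truth.tf_layer[partner]["sign"]
    for g in sorted(truth.chip_target_ids | set(truth.tf_layer[partner]["downstream"])):
        truth.tfkd_effects[g] = psign * rng.uniform(*cfg.effect_range)
    truth.tfkd_effects[partner] = -2.5  # the knocked-down TF itself

    catalog = pd.DataFrame(
        [{"gene_id": g, "role": "tf"} for g in sorted(tfs)]
        + [{"gene_id": g, "role": "cofactor"} for g in sorted(cofactors)]
    )
    for g in genes:
        g.is_tf = g.gene_id in truth.tf_ids
        g.is_cofactor = g.gene_id in truth.cofactor_ids
    truth.validate(cfg.motif_upstream_bp, cfg.motif_downstream_bp)
    return truth, catalog


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------


def make_pwms(
    tf_ids: Sequence[str], cfg: SimConfig, rng: np.random.Generator
) -> list[PWM]:
    """High-information PWMs with a random consensus per TF."""
    pwms = []
    for tf in tf_ids:
        consensus = rng.integers(0, 4, cfg.motif_length)
        probs = np.full((cfg.motif_length, 4), (1 - cfg.consensus_prob) / 3)
        probs[np.arange(cfg.motif_length), consensus] = cfg.consensus_prob
        pwms.append(PWM.from_probs(tf, probs))
    return pwms


def plant_motifs(
    genome: dict[str, str],
    genes: Sequence[GeneAnnotation],
    truth: SynthTruth,
    pwms: Sequence[PWM],
    cfg: SimConfig,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> None:
    """Write each TF's consensus into the promoters of its downstream genes.

    The genome is mutated in place; (offset, strand) of every planted
    occurrence is recorded in the truth.  Offsets are TSS-relative in
    transcription orientation; two motifs never overlap within a window.
    """
    by_id = {g.gene_id: g for g in genes}
    pwm_by_tf = {p.tf_id: p for p in pwms}
    up, down = cfg.motif_upstream_bp, cfg.motif_downstream_bp
    occupied: dict[str, list[tuple[int, int]]] = {}
    for tf in sorted(truth.tf_layer):
        pwm = pwm_by_tf[tf]
        L = len(pwm)
        consensus = pwm.consensus
        for gene_id in truth.tf_layer[tf]["downstream"]:
            win = extract_promoter_window(
                by_id[gene_id], genome, upstream_bp=up, downstream_bp=down
            )
            taken = occupied.setdefault(gene_id, [])
            for attempt in range(max_retries):
                off = int(rng.integers(-up, down - L + 1))
                if all(off + L <= a or off >= b for a, b in taken):
                    break
            else:
                raise RuntimeError(
                    f"could not place motif of {tf} in promoter of {gene_id} "
                    f"after {max_retries} retries"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            ins = consensus if strand == "+" else _revcomp(consensus)
            i = off + up
            seq = win.sequence[:i] + ins + win.sequence[i + L :]
            write_window_sequence(genome, win, seq)
            taken.append((off, off + L))
            truth.planted_motif_positions[(tf, gene_id)] = (off, strand)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


def simulate_counts(
    gene_ids: Sequence[str],
    model: SimCountModel,
    effects: dict[str, float],
    rng: np.random.Generator,
    control_label: str = "control",
    knockdown_label: str = "knockdown",
) -> CountMatrix:
    """NB count matrix for a knockdown vs control design.

    Knockdown-group means are the baselines scaled by 2^(planted log2 fold
    change) before noise; per-sample library factors scale both groups.
    """
    n = model.replicates_per_group
    mu0 = model.baseline_mean
    lfc = np.array([effects.get(g, 0.0) for g in gene_ids])
    mu_kd = mu0 * 2.0**lfc
    lib = model.library_size_factors
    if len(lib) != 2 * n:
        raise ValueError("need one library factor per sample (2 * replicates)")

    cols = {}
    names = []
    for j in range(n):
        names.append(f"{control_label}_{j + 1}")
    for j in range(n):
        names.append(f"{knockdown_label}_{j + 1}")
    for sj, name in enumerate(names):
        mu = (mu0 if sj < n else mu_kd) * lib[sj]
        counts = np.empty(len(gene_ids), dtype=np.int64)
        alpha = model.dispersion
        poisson = alpha <= 0
        if poisson.any():
            counts[poisson] = rng.poisson(mu[poisson])
        if (~poisson).any():
            a = alpha[~poisson]
            m = mu[~poisson]
            counts[~poisson] = rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * m))
        cols[name] = counts
    df = pd.DataFrame(cols, index=list(gene_ids))
    df.index.name = "gene_id"
    cond = pd.Series(
        {nm: (control_label if i < n else knockdown_label) for i, nm in enumerate(names)}
    )
    return CountMatrix(df, cond)


def make_count_model(
    cfg: SimConfig,
    genes: Sequence[GeneAnnotation],
    truth: SynthTruth,
    rng: np.random.Generator,
) -> SimCountModel:
    """Draw per-gene baselines and dispersions for one cell model."""
    mu = np.exp(
        rng.uniform(np.log(cfg.baseline_range[0]), np.log(cfg.baseline_range[1]), len(genes))
    )
    for i, g in enumerate(genes):
        if g.gene_id in truth.low_expression_ids:
            mu[i] = rng.uniform(*cfg.low_baseline_range)
        elif g.gene_id in truth.tf_ids:
            mu[i] = np.exp(
                rng.uniform(
                    np.log(cfg.tf_baseline_range[0]), np.log(cfg.tf_baseline_range[1])
                )
            )
    disp = rng.uniform(*cfg.dispersion_range, len(genes))
    lib = rng.uniform(*cfg.library_factor_range, 2 * cfg.replicates_per_group)
    return SimCountModel(mu, disp, cfg.replicates_per_group, lib)


# ---------------------------------------------------------------------------
# peak simulation
# ---------------------------------------------------------------------------


def _jittered(iv: GenomicInterval, jitter: int, rng, tag: str) -> GenomicInterval:
    s = iv.start + int(rng.integers(-jitter, jitter + 1)) if jitter else iv.start
    e = iv.end + int(rng.integers(-jitter, jitter + 1)) if jitter else iv.end
    q = rng.uniform(1e-6, 0.049)
    return GenomicInterval(iv.chrom, s, e, score=q, name=f"{iv.name}|{tag}")


def _noise_peaks(
    chrom_sizes: dict[str, int],
    rate_per_mb: float,
    width_range: tuple,
    rng: np.random.Generator,
    tag: str,
) -> list[GenomicInterval]:
    genome_mb = sum(chrom_sizes.values()) / 1e6
    n = int(rng.poisson(rate_per_mb * genome_mb))
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out = []
    for k in range(n):
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        width = int(rng.integers(*width_range))
        start = int(rng.integers(0, chrom_sizes[c] - width))
        q = rng.uniform(1e-6, 0.049)
        out.append(
            GenomicInterval(c, start, start + width, score=q, name=f"noise{k}|{tag}")
        )
    return out


def simulate_chirp_peaks(
    truth: SynthTruth,
    chrom_sizes: dict[str, int],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """EVEN and ODD probe-set peak files.

    Each true site appears in each file independently with probability
    detect_prob, endpoints jittered uniformly within +/- jitter_bp; noise
    peaks are placed uniformly with count ~ Poisson(noise_rate x Mb).
    """
    out = []
    for tag in ("EVEN", "ODD"):
        peaks = []
        for iv in truth.true_binding_sites:
            if rng.random() < cfg.detect_prob:
                peaks.append(_jittered(iv, cfg.jitter_bp, rng, tag))
        peaks.extend(
            _noise_peaks(chrom_sizes, cfg.noise_rate_per_mb, cfg.site_width_range, rng, tag)
        )
        peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
        out.append(peaks)
    return out[0], out[1]


def simulate_chip_peaks(
    truth: SynthTruth,
    chrom_sizes: dict[str, int],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Single-file ChIP peak calls for the partner TF (same noise model)."""
    peaks = []
    for iv in truth.chip_sites:
        if rng.random() < cfg.detect_prob:
            peaks.append(_jittered(iv, cfg.jitter_bp, rng, "CHIP"))
    peaks.extend(
        _noise_peaks(chrom_sizes, cfg.noise_rate_per_mb, cfg.site_width_range, rng, "CHIP")
    )
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


# ---------------------------------------------------------------------------
# coverage track
# ---------------------------------------------------------------------------


def simulate_coverage(
    peaks: Sequence[GenomicInterval],
    chrom_sizes: dict[str, int],
    shape_sd_bp: float = 300.0,
    bin_bp: int = 25,
    background: float = 1.0,
    amplitude: float = 8.0,
) -> list[tuple[str, int, int, float]]:
    """Bell-shaped coverage bumps centered on peak midpoints over a flat
    background, binned for a bedGraph track."""
    if shape_sd_bp <= 0:
        raise ValueError("shape_sd_bp must be > 0")
    records = []
    reach = int(4 * shape_sd_bp)
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_bins = (size + bin_bp - 1) // bin_bp
        centers = np.arange(n_bins) * bin_bp + bin_bp / 2.0
        cov = np.full(n_bins, float(background))
        for p in peaks:
            if p.chrom != chrom:
                continue
            mid = p.midpoint
            lo = max(0, (mid - reach) // bin_bp)
            hi = min(n_bins, (mid + reach) // bin_bp + 1)
            x = centers[lo:hi]
            cov[lo:hi] += amplitude * np.exp(-((x - mid) ** 2) / (2 * shape_sd_bp**2))
        for i in range(n_bins):
            records.append(
                (chrom, i * bin_bp, min((i + 1) * bin_bp, size), float(cov[i]))
            )
    return records


# ---------------------------------------------------------------------------
# gene sets and qPCR plate
# ---------------------------------------------------------------------------


def make_gene_sets(
    cfg: SimConfig,
    gene_ids: Sequence[str],
    truth: SynthTruth,
    rng: np.random.Generator,
) -> dict[str, tuple[str, set[str]]]:
    """Synthetic GMT collection; a few terms are enriched in direct targets."""
    out = {}
    direct = sorted(truth.direct_target_ids)
    others = sorted(set(gene_ids) - truth.direct_target_ids)
    for i in range(cfg.n_target_terms):
        members = set(rng.choice(direct, 10, replace=False)) | set(
            rng.choice(others, 5, replace=False)
        )
        out[f"TERM_TGT{i + 1:02d}"] = (f"target-flavored process {i + 1}", members)
    for i in range(cfg.n_random_terms):
        size = int(rng.integers(10, 41))
        members = set(rng.choice(sorted(gene_ids), size, replace=False))
        out[f"TERM_RND{i + 1:02d}"] = (f"background process {i + 1}", members)
    return out


def make_qpcr_table(
    truth: SynthTruth, rng: np.random.Generator, n_replicates: int = 3
) -> pd.DataFrame:
    """Ct values consistent with the planted effects, for the quant stage."""
    genes = [truth.partner_tf] + sorted(
        truth.chip_target_ids & truth.direct_target_ids
    )[:2]
    rows = []
    for g in genes:
        base = rng.uniform(20, 26)
        lfc = truth.planted_effects.get(g, {"A": 0.0})["A"]
        for cond, shift in (("control", 0.0), ("knockdown", -lfc)):
            for r in range(n_replicates):
                rows.append(
                    {
                        "gene_id": g,
                        "condition": cond,
                        "replicate": f"{cond}_{r + 1}",
                        "ct_target": base + shift + rng.normal(0, 0.05),
                        "ct_ref1": 18.0 + rng.normal(0, 0.05),
                        "ct_ref2": 20.0 + rng.normal(0, 0.05),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence of truth + the master generator
# ---------------------------------------------------------------------------


def write_truth(truth: SynthTruth, genes: Sequence[GeneAnnotation], outdir: Path) -> None:
    outdir = Path(outdir)
    rows = []
    for g in genes:
        gid = g.gene_id
        if gid in truth.direct_target_ids:
            cat = "direct"
        elif gid in truth.indirect_target_ids:
            cat = "indirect"
        elif gid in truth.bound_only_ids:
            cat = "bound_only"
        elif gid in truth.low_expression_ids:
            cat = "low_expression"
        else:
            cat = "none"
        eff = truth.planted_effects.get(gid, {})
        rows.append(
            {
                "gene_id": gid,
                "category": cat,
                "lfc_a": eff.get("A", 0.0),
                "lfc_b": eff.get("B", 0.0),
                "tfkd_lfc_b": truth.tfkd_effects.get(gid, 0.0),
                "is_tf": gid in truth.tf_ids,
                "is_cofactor": gid in truth.cofactor_ids,
                "is_chip_target": gid in truth.chip_target_ids,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "truth_targets.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "tf_id": tf,
                "sign": layer["sign"],
                "downstream": ",".join(layer["downstream"]),
            }
            for tf, layer in sorted(truth.tf_layer.items())
        ]
    ).to_csv(outdir / "truth_tf_layer.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"tf_id": tf, "gene_id": g, "offset": off, "strand": strand}
            for (tf, g), (off, strand) in sorted(truth.planted_motif_positions.items())
        ]
    ).to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)
    write_bed(truth.true_binding_sites, outdir / "truth_sites.bed")
    write_bed(truth.chip_sites, outdir / "truth_chip_sites.bed")
    with open(outdir / "truth_meta.json", "w") as fh:
        json.dump(
            {
                "partner_tf": truth.partner_tf,
                "noise_peak_rate": truth.noise_peak_rate,
            },
            fh,
            sort_keys=True,
        )


def load_truth(sim_dir: str | Path) -> SynthTruth:
    sim_dir = Path(sim_dir)
    t = pd.read_csv(sim_dir / "truth_targets.tsv", sep="\t")
    truth = SynthTruth()
    for _, r in t.iterrows():
        gid = r["gene_id"]
        if r["category"] == "direct":
            truth.direct_target_ids.add(gid)
        elif r["category"] == "indirect":
            truth.indirect_target_ids.add(gid)
        elif r["category"] == "bound_only":
            truth.bound_only_ids.add(gid)
        elif r["category"] == "low_expression":
            truth.low_expression_ids.add(gid)
        if r["is_tf"]:
            truth.tf_ids.add(gid)
        if r["is_cofactor"]:
            truth.cofactor_ids.add(gid)
        if r["is_chip_target"]:
            truth.chip_target_ids.add(gid)
        if r["lfc_a"] != 0.0 or r["lfc_b"] != 0.0:
            truth.planted_effects[gid] = {"A": r["lfc_a"], "B": r["lfc_b"]}
        if r["tfkd_lfc_b"] != 0.0:
            truth.tfkd_effects[gid] = r["tfkd_lfc_b"]
    layer = pd.read_csv(sim_dir / "truth_tf_layer.tsv", sep="\t")
    for _, r in layer.iterrows():
        truth.tf_layer[r["tf_id"]] = {
            "sign": int(r["sign"]),
            "downstream": r["downstream"].split(","),
        }
    motifs = pd.read_csv(sim_dir / "truth_motifs.tsv", sep="\t")
    for _, r in motifs.iterrows():
        truth.planted_motif_positions[(r["tf_id"], r["gene_id"])] = (
            int(r["offset"]),
            r["strand"],
        )
    from .intervals import read_bed

    truth.true_binding_sites = read_bed(sim_dir / "truth_sites.bed")
    truth.chip_sites = read_bed(sim_dir / "truth_chip_sites.bed")
    with open(sim_dir / "truth_meta.json") as fh:
        meta = json.load(fh)
    truth.partner_tf = meta["partner_tf"]
    truth.noise_peak_rate = meta["noise_peak_rate"]
    return truth


def generate_study(
    cfg: SimConfig, seed: int, outdir: str | Path
) -> tuple[dict[str, str], SynthTruth]:
    """Generate the full synthetic study into ``outdir``.

    Returns the mapping of written input-file paths (keys match
    :class:`lnctarget.config.InputPaths` fields) and the planted truth.
    Every random choice flows from ``seed`` via named substreams.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome, genes = generate_genome(cfg, substream(seed, "genome"))
    truth, catalog = assign_regulatory_truth(cfg, genes, substream(seed, "truth"))

    # PWMs for n_pwms TFs; every planted TF has one, the remainder are
    # filled with other catalog TFs (a couple of TFs stay PWM-less, which
    # exercises the "TF without a PWM" reporting path downstream)
    planted = sorted(truth.tf_layer)
    others = [t for t in sorted(truth.tf_ids) if t not in planted]
    pwm_tfs = planted + others[: max(0, cfg.n_pwms - len(planted))]
    pwms = make_pwms(pwm_tfs, cfg, substream(seed, "pwms"))
    plant_motifs(genome, genes, truth, pwms, cfg, substream(seed, "plant"))

    chrom_sizes = {c: len(s) for c, s in genome.items()}
    even, odd = simulate_chirp_peaks(truth, chrom_sizes, cfg, substream(seed, "chirp"))
    chip = simulate_chip_peaks(truth, chrom_sizes, cfg, substream(seed, "chip"))

    gene_ids = [g.gene_id for g in genes]
    effects_a = {g: e["A"] for g, e in truth.planted_effects.items()}
    effects_b = {g: e["B"] for g, e in truth.planted_effects.items()}
    model_a = make_count_model(cfg, genes, truth, substream(seed, "model_a"))
    model_b = make_count_model(cfg, genes, truth, substream(seed, "model_b"))
    counts_a = simulate_counts(gene_ids, model_a, effects_a, substream(seed, "counts_a"))
    counts_b = simulate_counts(gene_ids, model_b, effects_b, substream(seed, "counts_b"))
    counts_tf_b = simulate_counts(
        gene_ids, model_b, truth.tfkd_effects, substream(seed, "counts_tf_b")
    )

    coverage = simulate_coverage(
        truth.true_binding_sites,
        chrom_sizes,
        cfg.coverage_shape_sd_bp,
        cfg.coverage_bin_bp,
        cfg.coverage_background,
        cfg.coverage_amplitude,
    )
    gene_sets = make_gene_sets(cfg, gene_ids, truth, substream(seed, "gene_sets"))
    qpcr = make_qpcr_table(truth, substream(seed, "qpcr"))

    # ---- write everything ------------------------------------------------
    from .enrichment import write_gmt

    paths = {
        "genome_fasta": outdir / "genome.fa",
        "annotation_gtf": outdir / "genes.gtf",
        "chirp_even_bed": outdir / "chirp_even.bed",
        "chirp_odd_bed": outdir / "chirp_odd.bed",
        "chip_bed": outdir / "chip_tf.bed",
        "counts_model_a": outdir / "counts_model_a.tsv",
        "counts_model_b": outdir / "counts_model_b.tsv",
        "counts_tf_model_b": outdir / "counts_tf_model_b.tsv",
        "pwm_file": outdir / "pwms.meme",
        "gene_sets_gmt": outdir / "gene_sets.gmt",
        "tf_catalog": outdir / "tf_catalog.tsv",
        "coverage_bedgraph": outdir / "coverage.bedgraph",
        "qpcr_table": outdir / "qpcr_ct.tsv",
    }
    write_fasta(genome, paths["genome_fasta"])
    write_gtf(genes, paths["annotation_gtf"])
    write_bed(even, paths["chirp_even_bed"])
    write_bed(odd, paths["chirp_odd_bed"])
    write_bed(chip, paths["chip_bed"])
    counts_a.to_tsv(paths["counts_model_a"])
    counts_b.to_tsv(paths["counts_model_b"])
    counts_tf_b.to_tsv(paths["counts_tf_model_b"])
    write_meme(pwms, paths["pwm_file"])
    write_gmt(gene_sets, paths["gene_sets_gmt"])
    catalog.to_csv(paths["tf_catalog"], sep="\t", index=False)
    with open(paths["coverage_bedgraph"], "w") as fh:
        for chrom, s, e, v in coverage:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.4f}\n")
    qpcr.to_csv(paths["qpcr_table"], sep="\t", index=False, float_format="%.4f")
    write_truth(truth, genes, outdir)

    return {k: str(v) for k, v in paths.items()}, truth
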