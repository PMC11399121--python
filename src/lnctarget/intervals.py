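"""Interval algebra, standard-format I/O, dual-probe consensus and metaprofiles.

Internal coordinates are 0-based half-open everywhere; the only conversion
happens at the GTF boundary (GTF is 1-based inclusive).  The consensus
operation implements the dual-probe rule of ChIRP-seq analysis: peaks called
independently with the EVEN and ODD probe sets are intersected and only the
overlapping regions are retained as true RNA-bound genomic elements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

FEATURE_CLASSES = (
    "promoter",
    "five_prime_utr",
    "three_prime_utr",
    "exon",
    "intron",
    "downstream",
    "distal_intergenic",
)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomicInterval:
    """Half-open genomic interval (0-based start, exclusive end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneAnnotation:
    """One gene: transcript bounds, exon structure and regulatory-role flags."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list = field(default_factory=list)  # sorted (start, end) tuples
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)
    is_tf: bool = False
    is_cofactor: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.gene_id}: invalid transcript bounds")
        self.exons = sorted(tuple(e) for e in self.exons)
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside gene bounds"
                )

    @property
    def tss(self) -> int:
        """Strand-dependent transcription start: tx_start for +, tx_end-1 for -."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass
class ConsensusPeak:
    """EVEN/ODD-supported genomic element with provenance of its sources."""

    interval: GenomicInterval
    even_sources: list
    odd_sources: list


@dataclass
class PeakAnnotation:
    peak: GenomicInterval
    feature_class: str
    target_gene_id: Optional[str]
    signed_distance_to_tss: Optional[int]


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals. Column 5 is kept as ``score`` when numeric."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    score = float(parts[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            try:
                out.append(
                    GenomicInterval(parts[0], start, end, strand, score, name)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
                fields.append("%g" % iv.score if iv.score is not None else ".")
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path) -> list[GeneAnnotation]:
    """Read a GENCODE-dialect GTF (gene/exon features; gene_id, gene_name).

    GTF coordinates are 1-based inclusive and converted to 0-based
    half-open on read.
    """
    genes: dict[str, GeneAnnotation] = {}
    children: dict[str, dict[str, list]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts
            try:
                s0, e0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr = dict(_GTF_ATTR.findall(attrs))
            gid = attr.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene":
                genes[gid] = GeneAnnotation(
                    gene_id=gid,
                    gene_name=attr.get("gene_name", gid),
                    chrom=chrom,
                    strand=strand,
                    tx_start=s0,
                    tx_end=e0,
                )
            elif feature in ("exon", "five_prime_utr", "three_prime_utr"):
                children.setdefault(gid, {}).setdefault(feature, []).append((s0, e0))
    for gid, feats in children.items():
        if gid not in genes:
            raise ValueError(f"{path}: feature for unknown gene_id {gid!r}")
        g = genes[gid]
        g.exons = sorted(feats.get("exon", []))
        g.utr5 = sorted(feats.get("five_prime_utr", []))
        g.utr3 = sorted(feats.get("three_prime_utr", []))
        g.__post_init__()  # re-validate exon containment
    return sorted(genes.values(), key=lambda g: (g.chrom, g.tx_start, g.gene_id))


def write_gtf(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write genes and exons in the GENCODE GTF dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "lnctarget",
                        "gene",
                        str(g.tx_start + 1),
                        str(g.tx_end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for s, e in g.exons:
                fh.write(
                    "\t".join(
                        [
                            g.chrom,
                            "lnctarget",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            g.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


class BedGraphCoverage:
    """Per-base coverage accessor backed by a bedGraph file.

    Positions not covered by any record have coverage 0 (the bedGraph
    convention); positions outside the chromosome (negative, or past the
    declared size when ``chrom_sizes`` is given) are NaN so that truncated
    metaprofile windows can be excluded bin-wise.
    """

    def __init__(self, records: Iterable[tuple[str, int, int, float]],
                 chrom_sizes: Optional[dict[str, int]] = None):
        by_chrom: dict[str, list] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        self._data = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            vals = np.array([r[2] for r in recs], dtype=float)
            self._data[chrom] = (starts, ends, vals)
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else None

    @classmethod
    def from_file(cls, path: str | Path,
                  chrom_sizes: Optional[dict[str, int]] = None) -> "BedGraphCoverage":
        recs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
                try:
                    recs.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed bedGraph line") from exc
        return cls(recs, chrom_sizes=chrom_sizes)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base coverage over [start, end); NaN off-chromosome."""
        if end <= start:
            raise ValueError("end must exceed start")
        n = end - start
        out = np.zeros(n, dtype=float)
        if start < 0:
            out[: min(n, -start)] = np.nan
        size = None
        if self.chrom_sizes is not None:
            size = self.chrom_sizes.get(chrom)
            if size is not None and end > size:
                out[max(0, size - start):] = np.nan
        if chrom in self._data:
            starts, ends, vals = self._data[chrom]
            lo = np.searchsorted(ends, start, side="right")
            hi = np.searchsorted(starts, end, side="left")
            for i in range(lo, hi):
                a = max(starts[i], max(start, 0)) - start
                b = min(ends[i], end if size is None else min(end, size)) - start
                if b > a:
                    out[a:b] = vals[i]
        return out


# ---------------------------------------------------------------------------
# dual-probe consensus
# ---------------------------------------------------------------------------


def _source_name(iv: GenomicInterval, prefix: str, idx: int) -> str:
    return iv.name if iv.name else f"{prefix}:{idx}"


def intersect_consensus(
    even: Sequence[GenomicInterval], odd: Sequence[GenomicInterval]
) -> list[ConsensusPeak]:
    """Retain only regions covered by both probe sets.

    The output is the union of all pairwise EVEN x ODD intersections, with
    overlapping retained segments merged (minimum overlap 1 bp), sorted by
    position.  Provenance records every contributing source peak.
    """
    even_named = [(iv, _source_name(iv, "EVEN", i)) for i, iv in enumerate(even)]
    odd_named = [(iv, _source_name(iv, "ODD", i)) for i, iv in enumerate(odd)]
    by_chrom: dict[str, tuple[list, list]] = {}
    for iv, nm in even_named:
        by_chrom.setdefault(iv.chrom, ([], []))[0].append((iv.start, iv.end, nm))
    for iv, nm in odd_named:
        by_chrom.setdefault(iv.chrom, ([], []))[1].append((iv.start, iv.end, nm))

    out: list[ConsensusPeak] = []
    for chrom in sorted(by_chrom):
        ev, od = by_chrom[chrom]
        ev.sort()
        od.sort()
        # all pairwise intersections; ODD scan restarts from the first peak
        # that can still overlap, so nested intervals are handled correctly
        segs = []  # (start, end, even_name, odd_name)
        j0 = 0
        for es, ee, en in ev:
            while j0 < len(od) and od[j0][1] <= es:
                j0 += 1
            j = j0
            while j < len(od) and od[j][0] < ee:
                os_, oe, on = od[j]
                s, e = max(es, os_), min(ee, oe)
                if s < e:
                    segs.append((s, e, en, on))
                j += 1
        segs.sort()
        # merge strictly overlapping retained segments
        cur = None
        for s, e, en, on in segs:
            if cur is None or s >= cur[1]:
                if cur is not None:
                    out.append(_make_consensus(chrom, cur))
                cur = [s, e, {en}, {on}]
            else:
                cur[1] = max(cur[1], e)
                cur[2].add(en)
                cur[3].add(on)
        if cur is not None:
            out.append(_make_consensus(chrom, cur))
    return out


def _make_consensus(chrom: str, cur: list) -> ConsensusPeak:
    s, e, evs, ods = cur
    return ConsensusPeak(
        interval=GenomicInterval(chrom, s, e, name=None),
        even_sources=sorted(evs),
        odd_sources=sorted(ods),
    )


# ---------------------------------------------------------------------------
# peak-to-gene annotation
# ---------------------------------------------------------------------------


class GeneIndex:
    """Per-chromosome TSS index supporting nearest-gene queries."""

    def __init__(self, genes: Sequence[GeneAnnotation]):
        self.genes = list(genes)
        self._by_chrom: dict[str, tuple[np.ndarray, list[GeneAnnotation]]] = {}
        by_chrom: dict[str, list[GeneAnnotation]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gl in by_chrom.items():
            gl.sort(key=lambda g: (g.tss, g.gene_id))
            self._by_chrom[chrom] = (np.array([g.tss for g in gl]), gl)

    def nearest(self, chrom: str, pos: int) -> Optional[GeneAnnotation]:
        """Gene minimizing |pos - TSS|; equidistant ties break to the
        lexicographically smaller gene_id."""
        if chrom not in self._by_chrom:
            return None
        tss, gl = self._by_chrom[chrom]
        i = int(np.searchsorted(tss, pos))
        cand_idx = {max(0, i - 1), min(len(gl) - 1, i)}
        best = min(abs(int(tss[k]) - pos) for k in cand_idx)
        # collect every gene at the minimal distance (ties possible on
        # duplicated TSS coordinates too)
        winners = []
        for k in range(len(gl)):
            d = abs(int(tss[k]) - pos)
            if d == best:
                winners.append(gl[k])
            # tss sorted: once past pos+best we can stop
            if tss[k] > pos + best:
                break
        return min(winners, key=lambda g: g.gene_id)


def _midpoint_in(intervals: Iterable[tuple[int, int]], pos: int) -> bool:
    return any(s <= pos < e for s, e in intervals)


def annotate_peak(
    peak: GenomicInterval, index: GeneIndex, tss_window_bp: int = 3000
) -> PeakAnnotation:
    """Assign a peak to the nearest gene and classify its genomic feature.

    Classification uses the peak midpoint with precedence
    promoter > 5'UTR > 3'UTR > exon > intron > downstream > distal
    intergenic; ``downstream`` means within ``tss_window_bp`` past the
    annotated gene end on the gene's strand.
    """
    mid = peak.midpoint
    gene = index.nearest(peak.chrom, mid)
    if gene is None:
        return PeakAnnotation(peak, "distal_intergenic", None, None)
    d = mid - gene.tss if gene.strand == "+" else gene.tss - mid
    if abs(d) <= tss_window_bp:
        fc = "promoter"
    elif gene.tx_start <= mid < gene.tx_end:
        if _midpoint_in(gene.utr5, mid):
            fc = "five_prime_utr"
        elif _midpoint_in(gene.utr3, mid):
            fc = "three_prime_utr"
        elif _midpoint_in(gene.exons, mid):
            fc = "exon"
        else:
            fc = "intron"
    else:
        if gene.strand == "+":
            downstream = gene.tx_end <= mid < gene.tx_end + tss_window_bp
        else:
            downstream = gene.tx_start - tss_window_bp <= mid < gene.tx_start
        fc = "downstream" if downstream else "distal_intergenic"
    return PeakAnnotation(peak, fc, gene.gene_id, int(d))


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneAnnotation],
    tss_window_bp: int = 3000,
) -> pd.DataFrame:
    """Vector wrapper over :func:`annotate_peak` returning a tidy table."""
    index = GeneIndex(genes)
    rows = []
    for k, pk in enumerate(peaks):
        ann = annotate_peak(pk, index, tss_window_bp)
        rows.append(
            {
                "peak_id": pk.name if pk.name else f"peak{k}",
                "chrom": pk.chrom,
                "start": pk.start,
                "end": pk.end,
                "feature_class": ann.feature_class,
                "gene_id": ann.target_gene_id,
                "signed_distance_to_tss": ann.signed_distance_to_tss,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peak_id",
            "chrom",
            "start",
            "end",
            "feature_class",
            "gene_id",
            "signed_distance_to_tss",
        ],
    )


def feature_distribution(annotations) -> dict[str, float]:
    """Fraction of peaks per feature class (sums to 1)."""
    if isinstance(annotations, pd.DataFrame):
        classes = list(annotations["feature_class"])
    else:
        classes = [a.feature_class for a in annotations]
    if not classes:
        raise ValueError("feature_distribution requires a non-empty annotation list")
    n = len(classes)
    return {fc: classes.count(fc) / n for fc in FEATURE_CLASSES if fc in set(classes)}


# ---------------------------------------------------------------------------
# metaprofiles
# ---------------------------------------------------------------------------


def metaprofile(
    coverage: BedGraphCoverage,
    anchors: Sequence[tuple[str, int, str]],
    half_window_bp: int,
    n_bins: int,
) -> np.ndarray:
    """Mean signal in ``n_bins`` bins of a +/- ``half_window_bp`` window
    around each anchor.

    Anchors on the minus strand contribute their window reversed, so bin 0
    is always the most upstream position in transcription orientation.
    Windows truncated at a chromosome end contribute only their observed
    bins; fully unobserved bins come out as NaN.
    """
    if (2 * half_window_bp) % n_bins != 0:
        raise ValueError("n_bins must divide 2 * half_window_bp")
    binsize = 2 * half_window_bp // n_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for chrom, pos, strand in anchors:
        vals = coverage.values(chrom, pos - half_window_bp, pos + half_window_bp)
        if strand == "-":
            vals = vals[::-1]
        binned = vals.reshape(n_bins, binsize)
        ok = ~np.all(np.isnan(binned), axis=1)
        means = np.full(n_bins, np.nan)
        if ok.any():
            means[ok] = np.nanmean(binned[ok], axis=1)
        sums[ok] += means[ok]
        counts[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
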