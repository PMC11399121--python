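"""Pipeline configuration: every threshold and convention used by the cascade.

All tunables live in :class:`PipelineConfig`, which round-trips losslessly
through YAML.  Randomness anywhere in the package flows from the single
``random_seed`` via named substreams (see :func:`substream`), so a run is
reproducible end to end and any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

__all__ = ["InputPaths", "PipelineConfig", "substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Named random substream derived from the master seed.

    Two substreams with different labels are statistically independent;
    the same (seed, label) pair always yields the same generator state.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode("utf-8"))])
    )


@dataclass
class InputPaths:
    """Locations of the files the cascade consumes.

    ``chirp_even_bed``/``chirp_odd_bed`` are the peak calls of the two
    independent ChIRP probe sets; ``chip_bed`` is the cooperating TF's ChIP
    peak file.  ``counts_model_a``/``counts_model_b`` are lncRNA-knockdown
    vs control count matrices in the two cell models, and
    ``counts_tf_model_b`` is the TF-knockdown matrix in the second model
    used for the common-direct-target derivation.
    """

    genome_fasta: Optional[str] = None
    annotation_gtf: Optional[str] = None
    chirp_even_bed: Optional[str] = None
    chirp_odd_bed: Optional[str] = None
    chip_bed: Optional[str] = None
    counts_model_a: Optional[str] = None
    counts_model_b: Optional[str] = None
    counts_tf_model_b: Optional[str] = None
    pwm_file: Optional[str] = None
    gene_sets_gmt: Optional[str] = None
    tf_catalog: Optional[str] = None
    coverage_bedgraph: Optional[str] = None
    qpcr_table: Optional[str] = None


@dataclass
class PipelineConfig:
    """Thresholds, window conventions and I/O locations for a run.

    Parameters
    ----------
    tss_window_bp:
        Promoter half-width for peak-to-gene annotation; a peak midpoint
        within +/- this distance of a TSS is classified as promoter.
    motif_upstream_bp, motif_downstream_bp:
        Promoter window scanned for TF motifs, measured from the TSS in
        transcription orientation.
    de_fdr:
        BH-adjusted significance threshold for the differential test.
    motif_q:
        BH q-value cutoff for retained motif hits.
    peak_q:
        Applied to incoming peak records when a q column is present.
    enrich_alpha:
        BH-adjusted threshold for over-representation results.
    low_count_min_total:
        Genes with total raw count below this are excluded before testing.
    jaccard_edge_min:
        Minimum Jaccard similarity for an edge in term clustering.
    """

    tss_window_bp: int = 3000
    motif_upstream_bp: int = 1500
    motif_downstream_bp: int = 500
    de_fdr: float = 0.1
    motif_q: float = 0.05
    peak_q: float = 0.05
    enrich_alpha: float = 0.05
    low_count_min_total: int = 10
    jaccard_edge_min: float = 0.2
    random_seed: int = 0
    inputs: InputPaths = field(default_factory=InputPaths)
    output_dir: Optional[str] = None
    # Optional synthetic-data section; when set, `run-all` generates its own
    # inputs before executing the cascade (see lnctarget.synthetic).
    simulate: Optional[dict] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.tss_window_bp <= 0:
            raise ValueError("tss_window_bp must be > 0")
        if self.motif_upstream_bp <= 0 or self.motif_downstream_bp <= 0:
            raise ValueError("motif window widths must be > 0")
        for name in ("de_fdr", "motif_q", "peak_q", "enrich_alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.low_count_min_total < 0:
            raise ValueError("low_count_min_total must be >= 0")
        if not (0.0 <= self.jaccard_edge_min <= 1.0):
            raise ValueError("jaccard_edge_min must lie in [0, 1]")

    # -- on-disk representation ------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        inputs = d.pop("inputs", {}) or {}
        known = {f.name for f in dataclasses.fields(InputPaths)}
        unknown = set(inputs) - known
        if unknown:
            raise ValueError(f"unknown input path keys: {sorted(unknown)}")
        return cls(inputs=InputPaths(**inputs), **d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config file must hold a mapping")
        return cls.from_dict(d)
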