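"""Quantification formulas for the bench validation assays.

Covers relative expression by the 2^-ddCt method (multi-reference qRT-PCR),
pulldown signal as % of dilution-adjusted input (ChIRP/ChIP), and simple
fold-over-control ratios (RIP over IgG, knockdown over control ChIP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QPCRMeasurement",
    "ddct_relative_expression",
    "percent_input",
    "fold_over_control",
]


@dataclass
class QPCRMeasurement:
    """One well: target Ct, reference-gene Cts, condition and replicate."""

    target_ct: float
    reference_cts: Sequence[float]
    condition: str
    replicate: str

    def __post_init__(self) -> None:
        cts = [self.target_ct, *self.reference_cts]
        if not self.reference_cts:
            raise ValueError("at least one reference Ct is required")
        if not all(np.isfinite(c) and c > 0 for c in cts):
            raise ValueError("Ct values must be finite and > 0")

    @property
    def delta_ct(self) -> float:
        """Ct_target - mean(reference Cts).

        The arithmetic mean of reference Cts equals the geometric mean of
        the corresponding linear quantities, the standard multi-reference
        normalization.
        """
        return self.target_ct - float(np.mean(self.reference_cts))


def ddct_relative_expression(
    samples: Sequence[QPCRMeasurement], control_condition: str
) -> pd.DataFrame:
    """Per-sample relative expression by the 2^-ddCt method.

    ddCt = dCt - mean(dCt over control replicates); the control-condition
    mean maps to 1 by construction.
    """
    controls = [s for s in samples if s.condition == control_condition]
    if not controls:
        raise ValueError(f"no replicate with control condition {control_condition!r}")
    control_mean_dct = float(np.mean([s.delta_ct for s in controls]))
    rows = []
    for s in samples:
        ddct = s.delta_ct - control_mean_dct
        rows.append(
            {
                "condition": s.condition,
                "replicate": s.replicate,
                "delta_ct": s.delta_ct,
                "delta_delta_ct": ddct,
                "relative_expression": 2.0 ** (-ddct),
            }
        )
    return pd.DataFrame(rows)


def percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """Pulldown signal as a percentage of the dilution-adjusted input.

    The input Ct is first adjusted for the fraction of material it
    represents (ct_input - log2(1/fraction)); equal adjusted Cts mean the
    IP recovered 100% of the input material.
    """
    if not (0.0 < input_fraction <= 1.0):
        raise ValueError("input_fraction must lie in (0, 1]")
    adjusted_input = ct_input - np.log2(1.0 / input_fraction)
    return float(100.0 * 2.0 ** (adjusted_input - ct_ip))


def fold_over_control(ip_value: float, control_value: float) -> float:
    """Simple enrichment ratio; undefined (raises) for a zero control."""
    if control_value <= 0:
        raise ValueError("control value must be > 0 for a defined fold")
    return float(ip_value / control_value)
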