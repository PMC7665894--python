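"""Closed-form assay computations: Miller units and ChIP-qPCR occupancy."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class BetaGalReading:
    a420: float
    a600: float
    time_min: float
    volume_ml: float

    def __post_init__(self):
        if self.a600 <= 0 or self.time_min <= 0 or self.volume_ml <= 0:
            raise ValueError("A600, time and volume must be positive")


def miller_units(reading: BetaGalReading) -> float:
    """Beta-galactosidase activity, 1000 * A420 / (A600 * time * volume)."""
    return 1000.0 * reading.a420 / (reading.a600 * reading.time_min * reading.volume_ml)


def miller_units_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized Miller units over a TSV-style frame.

    Expects columns sample, A420, A600, time_min, volume_ml.
    """
    out = df.copy()
    out["miller_units"] = [
        miller_units(BetaGalReading(r.A420, r.A600, r.time_min, r.volume_ml))
        for r in df.itertuples(index=False)
    ]
    return out


@dataclass
class QpcrMeasurement:
    """Fold enrichments over a control region, for target and mock samples."""
    target_enrichment: float
    background_enrichment: float

    def __post_init__(self):
        if self.target_enrichment <= 0 or self.background_enrichment <= 0:
            raise ValueError("enrichments must be positive")


def relative_occupancy(m: QpcrMeasurement) -> float:
    """Background-subtracted enrichment relative to the control region.

    Both enrichments are target-region signal divided by control-region
    signal; occupancy is their difference, so a mock-level signal reads 0.
    """
    return m.target_enrichment - m.background_enrichment


def qpcr_enrichment(cq_target_chip: float, cq_control_chip: float,
                    cq_target_input: float, cq_control_input: float,
                    efficiency: float = 2.0) -> float:
    """Input-corrected fold enrichment of a target region over a control
    region from quantification cycles (delta-delta-Cq with configurable
    amplification efficiency)."""
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    ddcq = (cq_target_chip - cq_control_chip) - (cq_target_input - cq_control_input)
    return float(efficiency ** (-ddcq))
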