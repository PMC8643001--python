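"""Plate-count arithmetic and spore-to-viable bioburden accounting.

The regulatory proxy for spacecraft bioburden is the NASA standard
assay: heat-shocked sample aliquots pour-plated in replicate, CFU
counted, and scaled to spores per square meter of sampled surface. The
Space Studies Board conversion then extrapolates total viable bioburden
as 50,000 viable cells per NSA spore; comparing that prediction with a
directly measured viable density gives the observed viable:spore ratio
and its fraction of the specification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

SSB_RATIO = 50_000.0


@dataclass
class PlateCountRecord:
    """Replicate pour-plate counts from a concentrated wipe sample."""

    colonies: Sequence[int]           # CFU per replicate plate
    volume_per_plate_ml: float | Sequence[float]
    concentrate_volume_ml: float      # total concentrate the aliquots came from
    area_m2: float                    # surface area wiped

    def __post_init__(self) -> None:
        if not self.colonies:
            raise ValueError("need at least one replicate plate")
        if any(c < 0 or int(c) != c for c in self.colonies):
            raise ValueError("colony counts must be non-negative integers")
        if isinstance(self.volume_per_plate_ml, (int, float)):
            self.volume_per_plate_ml = [float(self.volume_per_plate_ml)] * len(
                self.colonies
            )
        else:
            self.volume_per_plate_ml = [float(v) for v in self.volume_per_plate_ml]
        if len(self.volume_per_plate_ml) != len(self.colonies):
            raise ValueError("one plated volume per plate required")
        if any(v <= 0 for v in self.volume_per_plate_ml):
            raise ValueError("plated volumes must be positive")
        if self.concentrate_volume_ml <= 0 or self.area_m2 <= 0:
            raise ValueError("concentrate volume and area must be positive")


@dataclass
class BioburdenEstimate:
    spores_per_m2: float
    viable_measured_per_m2: float | None
    ssb_predicted_viable_per_m2: float
    observed_ratio: float | None          # viable measured / spores
    fraction_of_ssb: float | None         # observed ratio / SSB constant
    ssb_ratio: float = SSB_RATIO


def cfu_per_area(record: PlateCountRecord) -> float:
    """Spores per m² from replicate plate counts.

    Replicates are pooled — total colonies over total plated volume gives
    the concentrate titre (CFU/mL), which is scaled to the whole
    concentrate and normalized by the sampled area.
    """
    total_colonies = sum(record.colonies)
    total_volume = sum(record.volume_per_plate_ml)
    titre = total_colonies / total_volume
    return titre * record.concentrate_volume_ml / record.area_m2


def ssb_viable_estimate(spores_per_m2: float, ssb_ratio: float = SSB_RATIO) -> float:
    """Predicted total viable cells per m² under the SSB conversion."""
    if ssb_ratio <= 0:
        raise ValueError("ssb_ratio must be positive")
    if spores_per_m2 < 0:
        raise ValueError("spore density must be non-negative")
    return spores_per_m2 * ssb_ratio


def observed_ratio(
    viable_measured_per_m2: float,
    spores_per_m2: float,
    ssb_ratio: float = SSB_RATIO,
) -> BioburdenEstimate:
    """Observed viable:spore ratio and its fraction of the SSB constant.

    A zero spore density leaves the ratio undefined (flagged as None)
    rather than infinite.
    """
    if viable_measured_per_m2 < 0 or spores_per_m2 < 0:
        raise ValueError("densities must be non-negative")
    predicted = ssb_viable_estimate(spores_per_m2, ssb_ratio)
    if spores_per_m2 == 0:
        return BioburdenEstimate(
            spores_per_m2=0.0,
            viable_measured_per_m2=viable_measured_per_m2,
            ssb_predicted_viable_per_m2=0.0,
            observed_ratio=None,
            fraction_of_ssb=None,
            ssb_ratio=ssb_ratio,
        )
    ratio = viable_measured_per_m2 / spores_per_m2
    return BioburdenEstimate(
        spores_per_m2=spores_per_m2,
        viable_measured_per_m2=viable_measured_per_m2,
        ssb_predicted_viable_per_m2=predicted,
        observed_ratio=ratio,
        fraction_of_ssb=ratio / ssb_ratio,
        ssb_ratio=ssb_ratio,
    )


def cultivable_from_fraction(spores_per_m2: float, spore_fraction: float) -> float:
    """Total cultivable density implied by the spore share of cultivables.

    E.g. 36 spores/m² at a 20% spore share implies 180 cultivable/m².
    """
    if not 0.0 < spore_fraction <= 1.0:
        raise ValueError("spore_fraction must be in (0, 1]")
    if spores_per_m2 < 0:
        raise ValueError("spore density must be non-negative")
    return spores_per_m2 / spore_fraction
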