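"""Closed-form cytometry and clinical response formulas."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["MfiQuartet", "LesionSeries", "facs_log2_change", "recist_percent_change"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MfiQuartet:
    """Mean fluorescence intensities for one marker: antibody and
    isotype control under treated and mock conditions."""

    antibody_treated: float
    isotype_treated: float
    antibody_mock: float
    isotype_mock: float

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def flagged(self) -> bool:
        """True when an isotype control exceeds its antibody signal —
        a physically suspect measurement."""
        return (self.antibody_treated < self.isotype_treated
                or self.antibody_mock < self.isotype_mock)


@dataclass(frozen=True)
class LesionSeries:
    """Summed target-lesion diameters (mm) at baseline and at each
    radiographic evaluation."""

    baseline_sum: float
    timepoint_sums: tuple

    def __post_init__(self) -> None:
        if self.baseline_sum <= 0:
            raise ValueError("baseline lesion sum must be positive")
        if any(s <= 0 for s in self.timepoint_sums):
            raise ValueError("timepoint lesion sums must be positive")


def facs_log2_change(q: MfiQuartet) -> float:
    """log2 of the background-subtracted MFI ratio:
    log2[(antibody − isotype)_treated / (antibody − isotype)_mock].

    A non-positive background-subtracted difference yields NaN with a
    logged flag rather than an error, so batch runs survive noisy
    measurements.
    """
    num = q.antibody_treated - q.isotype_treated
    den = q.antibody_mock - q.isotype_mock
    if num <= 0 or den <= 0:
        log.warning("non-positive background-subtracted MFI (num=%g, den=%g); "
                    "value flagged missing", num, den)
        return float("nan")
    return float(np.log2(num / den))


def recist_percent_change(series: LesionSeries) -> list[float]:
    """Percent change of the target-lesion sum from baseline at each
    timepoint: ((sum_t / sum_baseline) − 1) × 100, evaluated in the
    algebraically identical better-conditioned form
    (sum_t − sum_baseline) / sum_baseline × 100."""
    return [float((s - series.baseline_sum) / series.baseline_sum * 100.0)
            for s in series.timepoint_sums]
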