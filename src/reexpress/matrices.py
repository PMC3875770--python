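"""Core in-memory containers for probe/gene × sample matrices.

All matrices are pandas DataFrames of floats; missing (masked) cells are
NaN and every operation propagates NaN — a masked cell never contributes
to a downstream statistic and never silently becomes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = ["IntensityTable", "MethMatrix", "ExprMatrix"]

MethScale = Literal["beta", "mvalue"]
ExprScale = Literal["log_ratio", "log_rpkm", "linear"]
FeatureLevel = Literal["probe", "gene"]


@dataclass
class IntensityTable:
    """Probe × sample methylated/unmethylated bead intensities plus
    negative-control intensities used to estimate background signal.

    Parameters
    ----------
    methylated, unmethylated
        Probe × sample non-negative intensities with identical indexes.
    negative_controls
        Control-probe × sample non-negative intensities; columns must
        match the signal columns.
    """

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    negative_controls: pd.DataFrame

    def __post_init__(self) -> None:
        m, u = self.methylated, self.unmethylated
        if not m.index.equals(u.index) or not m.columns.equals(u.columns):
            raise ValueError("methylated/unmethylated must share probe and sample indexes")
        if not self.negative_controls.columns.equals(m.columns):
            raise ValueError("negative-control columns must match signal sample columns")
        for name, df in (("methylated", m), ("unmethylated", u),
                         ("negative_controls", self.negative_controls)):
            if (df.to_numpy() < 0).any():
                raise ValueError(f"{name} intensities must be non-negative")

    @property
    def probes(self) -> pd.Index:
        return self.methylated.index

    @property
    def samples(self) -> pd.Index:
        return self.methylated.columns

    @property
    def total(self) -> pd.DataFrame:
        """Total signal M + U per cell."""
        return self.methylated + self.unmethylated


@dataclass
class MethMatrix:
    """Probe × sample methylation values on the beta or M-value scale.

    Beta values are methylation proportions in [0, 1]; M values are the
    unbounded log2 ratio of methylated to unmethylated intensity.
    """

    values: pd.DataFrame
    scale_tag: MethScale = "beta"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("beta", "mvalue"):
            raise ValueError(f"unknown methylation scale {self.scale_tag!r}")
        if self.scale_tag == "beta":
            arr = self.values.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                bad = (arr < -1e-12) | (arr > 1 + 1e-12)
            if np.nansum(bad):
                raise ValueError("beta-scale values must lie in [0, 1]")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the cell is masked (missing)."""
        return self.values.isna()

    def n_masked(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class ExprMatrix:
    """Feature × sample expression values.

    ``feature_level`` records whether rows are array probes or genes;
    ``scale_tag`` records the unit (treated/mock log2 ratio, log2 RPKM,
    or linear).
    """

    values: pd.DataFrame
    feature_level: FeatureLevel = "gene"
    scale_tag: ExprScale = "linear"

    def __post_init__(self) -> None:
        if self.feature_level not in ("probe", "gene"):
            raise ValueError(f"unknown feature level {self.feature_level!r}")
        if self.scale_tag not in ("log_ratio", "log_rpkm", "linear"):
            raise ValueError(f"unknown expression scale {self.scale_tag!r}")
        if self.values.index.has_duplicates:
            raise ValueError("feature IDs must be unique")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns
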