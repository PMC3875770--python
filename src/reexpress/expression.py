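"""Expression processing for the treatment experiment and the cohort.

Treatment arrays yield per-probe log2(treated/mock) ratios that are
median-aggregated per gene; cohort RPKM values are zero-masked,
log2-transformed and stripped of sex-chromosome genes before any
correlation or clustering step.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrices import ExprMatrix

__all__ = [
    "treatment_log_ratio",
    "aggregate_probes_to_genes",
    "fold_change_signature",
    "preprocess_cohort_rpkm",
]

log = logging.getLogger(__name__)


def treatment_log_ratio(treated: ExprMatrix, mock: ExprMatrix) -> ExprMatrix:
    """Cellwise log2(treated / mock). Non-positive linear inputs are
    masked rather than producing infinities."""
    if treated.scale_tag != "linear" or mock.scale_tag != "linear":
        raise ValueError("treatment_log_ratio expects linear-scale inputs")
    t, m = treated.values, mock.values
    if not t.index.equals(m.index) or not t.columns.equals(m.columns):
        raise ValueError("treated and mock matrices must share features and samples")
    ta, ma = t.to_numpy(dtype=float), m.to_numpy(dtype=float)
    ok = (ta > 0) & (ma > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ok, np.log2(np.where(ok, ta, 1.0) / np.where(ok, ma, 1.0)), np.nan)
    return ExprMatrix(pd.DataFrame(ratio, index=t.index, columns=t.columns),
                      feature_level=treated.feature_level, scale_tag="log_ratio")


def aggregate_probes_to_genes(probe_matrix: ExprMatrix,
                              mapping: pd.Series) -> ExprMatrix:
    """Per-gene, per-sample median over each gene's unmasked probe
    values (even counts take the midpoint of the central pair).

    ``mapping`` is a probe → gene Series; probes absent from it are
    dropped with a logged count. A gene is masked in a sample where all
    of its probes are masked.
    """
    if probe_matrix.feature_level != "probe":
        raise ValueError("input matrix must be probe-level")
    vals = probe_matrix.values
    unmapped = vals.index.difference(mapping.index)
    if len(unmapped):
        log.info("dropping %d probes with no gene mapping", len(unmapped))
    kept = vals.loc[vals.index.intersection(mapping.index)]
    genes = mapping.loc[kept.index]
    agg = kept.groupby(genes.to_numpy()).median()
    agg.index.name = vals.index.name
    return ExprMatrix(agg.sort_index(), feature_level="gene",
                      scale_tag=probe_matrix.scale_tag)


def fold_change_signature(gene_matrix: ExprMatrix, sample: str,
                          threshold_fold: float = 4.0) -> list[str]:
    """Genes induced ``threshold_fold``-fold or more (inclusive) in the
    named sample, sorted by descending log ratio.

    Mirrors selecting the genes most strongly up-regulated by the drug
    in a single cell line (e.g. all genes ≥4-fold up).
    """
    if gene_matrix.scale_tag != "log_ratio":
        raise ValueError("fold_change_signature expects a log-ratio matrix")
    if sample not in gene_matrix.values.columns:
        raise KeyError(f"unknown sample {sample!r}")
    col = gene_matrix.values[sample].dropna()
    cutoff = np.log2(threshold_fold)
    hits = col[col >= cutoff].sort_values(ascending=False, kind="stable")
    return list(hits.index)


def preprocess_cohort_rpkm(rpkm: ExprMatrix,
                           gene_chromosomes: pd.Series) -> ExprMatrix:
    """Prepare cohort gene-level RPKM values for correlation/clustering:
    zeros become NA (no reads observed), remaining values are log2
    transformed, and X/Y-chromosome genes are removed.

    ``gene_chromosomes`` maps gene → chromosome name; genes without an
    entry are dropped with a logged count.
    """
    if rpkm.scale_tag != "linear" or rpkm.feature_level != "gene":
        raise ValueError("expects a linear gene-level RPKM matrix")
    vals = rpkm.values
    if (vals.to_numpy(dtype=float) < 0).any():
        raise ValueError("RPKM values must be non-negative")
    missing = vals.index.difference(gene_chromosomes.index)
    if len(missing):
        log.info("dropping %d genes lacking chromosome annotation", len(missing))
    keep = vals.index.intersection(gene_chromosomes.index)
    chroms = gene_chromosomes.loc[keep].astype(str).str.lower().str.removeprefix("chr")
    autosomal = keep[~chroms.isin(("x", "y"))]
    out = vals.loc[autosomal].mask(vals.loc[autosomal] == 0)
    with np.errstate(divide="ignore"):
        out = np.log2(out)
    return ExprMatrix(out, feature_level="gene", scale_tag="log_rpkm")
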