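"""The core integrative filter cascade.

Finds genes silenced by promoter CpG-island hypermethylation that are
demethylated and re-expressed after treatment with a demethylating drug,
then validates them against a tumour cohort: a methylation probe is
*informative* when its beta values correlate negatively (FDR-controlled)
with its gene's expression across the cohort, and a candidate gene is
retained only if one of its passing promoter probes is informative with
a sufficiently strong negative correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrices import ExprMatrix, MethMatrix

__all__ = [
    "FilterThresholds",
    "GeneSignature",
    "spearman_rho",
    "bh_adjust",
    "informative_probes",
    "reexpression_filter",
    "cohort_validation",
    "annotate_transcription_factors",
    "overlap_fraction",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    """Every cutoff of the filter cascade, with the defaults used in
    the analysis this package implements.

    Inequality conventions follow the rules as stated: expression
    median M strictly above ``expr_m_min``; mock beta strictly above
    ``beta_mock_min``; demethylation (mock − treated) at least
    ``delta_beta_min`` (inclusive); cohort rho strictly below
    ``cohort_rho_max``; FDR q-values strictly below their caps.
    """

    expr_m_min: float = 0.5          # log2 units; 1.4-fold induction
    beta_mock_min: float = 0.5       # high baseline promoter methylation
    delta_beta_min: float = 0.25     # demethylation of 25 percentage points
    tss_window: int = 1000           # bp either side of the TSS
    require_island: bool = True      # promoter CpG-island probes only
    cohort_rho_max: float = -0.25    # validation correlation cutoff
    cohort_fdr_max: float = 0.05     # validation FDR cap
    informative_fdr_max: float = 0.01  # informative-probe FDR cap

    def __post_init__(self) -> None:
        if not 0 < self.cohort_fdr_max <= 1 or not 0 < self.informative_fdr_max <= 1:
            raise ValueError("FDR caps must lie in (0, 1]")
        if self.tss_window < 0:
            raise ValueError("tss_window must be non-negative")
        if not -1 <= self.cohort_rho_max <= 1:
            raise ValueError("cohort_rho_max must be a correlation")


@dataclass
class GeneSignature:
    """An ordered gene list with per-gene provenance of which probes,
    timepoints and cohort statistics carried it through the cascade."""

    gene_ids: list[str]
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        """Flat TSV-friendly view: one row per gene with provenance
        fields JSON-ish stringified."""
        rows = []
        for g in self.gene_ids:
            prov = self.provenance.get(g, {})
            rows.append({
                "gene_id": g,
                "expr_days": ",".join(prov.get("expr_days", [])),
                "passing_probes": ",".join(
                    f"{p['probe_id']}@{p['day']}" for p in prov.get("probes", [])),
                "rho": prov.get("rho", np.nan),
                "q": prov.get("q", np.nan),
            })
        return pd.DataFrame(rows)


def spearman_rho(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> float:
    """Spearman rank correlation over jointly unmasked pairs, with
    average-rank tie handling. Returns NaN (with a warning) when fewer
    than 3 complete pairs remain."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    ok = np.isfinite(xa) & np.isfinite(ya)
    if ok.sum() < 3:
        log.warning("spearman_rho: fewer than 3 complete pairs; returning NaN")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(xa[ok], ya[ok]).statistic
    return float(rho)


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _rank_corr_and_p(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Spearman rho over complete pairs via Pearson on average ranks.
    Returns (rho, n_pairs); p is computed in bulk by the caller."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, n
    rx = stats.rankdata(x[ok])
    ry = stats.rankdata(y[ok])
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:  # constant after ranking (all ties)
        return np.nan, n
    return float((rx @ ry) / denom), n


def _t_approx_pvalues(rho: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for Spearman rho via the t approximation with
    n − 2 degrees of freedom (|rho| = 1 gives p = 0)."""
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.full(rho.shape, np.nan)
    ok = np.isfinite(rho) & (n > 2)
    r = np.clip(rho[ok], -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n[ok] - 2) / (1 - r * r))
    pv = 2 * stats.t.sf(np.abs(t), df=n[ok] - 2)
    pv[np.abs(r) >= 1.0] = 0.0
    p[ok] = np.minimum(pv, 1.0)
    return p


def informative_probes(cohort_beta: MethMatrix,
                       cohort_expr: ExprMatrix,
                       annotation: pd.DataFrame,
                       thresholds: FilterThresholds = FilterThresholds(),
                       ) -> pd.DataFrame:
    """Correlate every methylation probe with its gene's cohort
    expression and flag the informative ones.

    A probe is informative when its Spearman rho is negative and its BH
    q-value is below ``thresholds.informative_fdr_max``. Returns one
    row per tested probe (``gene_id``, ``tss_distance``, ``n``,
    ``rho``, ``p``, ``q``, ``informative``), indexed by probe.
    """
    if cohort_beta.scale_tag != "beta":
        raise ValueError("cohort methylation must be on the beta scale")
    if cohort_expr.feature_level != "gene":
        raise ValueError("cohort expression must be gene-level")
    shared = cohort_beta.samples.intersection(cohort_expr.samples)
    if len(shared) < 3:
        raise ValueError("need at least 3 samples present on both platforms")
    beta = cohort_beta.values[shared]
    expr = cohort_expr.values[shared]

    probes = beta.index.intersection(annotation.index)
    gene_of = annotation.loc[probes, "gene_id"]
    probes = probes[gene_of.isin(expr.index).to_numpy()]
    if len(probes) == 0:
        return pd.DataFrame(columns=["gene_id", "tss_distance", "n", "rho",
                                     "p", "q", "informative"])

    beta_arr = beta.loc[probes].to_numpy(dtype=float)
    expr_by_gene = {g: expr.loc[g].to_numpy(dtype=float)
                    for g in annotation.loc[probes, "gene_id"].unique()}
    rhos = np.empty(len(probes))
    ns = np.empty(len(probes), dtype=int)
    for i, probe in enumerate(probes):
        g = annotation.at[probe, "gene_id"]
        rhos[i], ns[i] = _rank_corr_and_p(beta_arr[i], expr_by_gene[g])
    pvals = _t_approx_pvalues(rhos, ns)
    qvals = bh_adjust(pvals)
    out = pd.DataFrame({
        "gene_id": annotation.loc[probes, "gene_id"].to_numpy(),
        "tss_distance": annotation.loc[probes, "tss_distance"].to_numpy(),
        "n": ns,
        "rho": rhos,
        "p": pvals,
        "q": qvals,
    }, index=probes)
    out["informative"] = (out["rho"] < 0) & (out["q"] < thresholds.informative_fdr_max)
    out.loc[~np.isfinite(out["rho"]), "informative"] = False
    return out


def _passing_probes_one_day(day: str,
                            beta_mock: MethMatrix,
                            delta: pd.DataFrame,
                            sample: str,
                            annotation: pd.DataFrame,
                            thresholds: FilterThresholds) -> pd.DataFrame:
    """Probes that are promoter CpG-island probes near the TSS, highly
    methylated in mock, and demethylated by at least the cutoff at one
    timepoint. ``delta`` is treated − mock, so demethylation = −delta."""
    probes = beta_mock.probes.intersection(annotation.index).intersection(delta.index)
    ann = annotation.loc[probes]
    bm = beta_mock.values.loc[probes, sample]
    dem = -delta.loc[probes, sample]  # mock − treated
    keep = (
        (np.abs(ann["tss_distance"]) <= thresholds.tss_window)
        & (bm > thresholds.beta_mock_min)
        & (dem >= thresholds.delta_beta_min)
    )
    if thresholds.require_island:
        keep &= ann["island_flag"].astype(bool)
    keep &= bm.notna() & dem.notna()
    hit = ann.loc[keep.to_numpy(dtype=bool)]
    return pd.DataFrame({
        "probe_id": hit.index,
        "gene_id": hit["gene_id"].to_numpy(),
        "day": day,
        "beta_mock": bm.loc[hit.index].to_numpy(),
        "demethylation": dem.loc[hit.index].to_numpy(),
    })


def reexpression_filter(expr_by_day: dict[str, ExprMatrix],
                        beta_mock_by_day: dict[str, MethMatrix],
                        delta_by_day: dict[str, pd.DataFrame],
                        annotation: pd.DataFrame,
                        thresholds: FilterThresholds = FilterThresholds(),
                        sample: str | None = None) -> GeneSignature:
    """Demethylated-and-re-expressed gene filter for one cell line.

    A gene enters the signature iff

    * its median expression log2 ratio exceeds ``expr_m_min`` at any
      timepoint (re-expression), and
    * at least one of its probes is a CpG-island probe within
      ``tss_window`` bp of the TSS with mock beta above
      ``beta_mock_min`` and mock − treated demethylation of at least
      ``delta_beta_min`` at any timepoint.

    ``expr_by_day`` holds gene-level log-ratio matrices keyed by
    timepoint (e.g. ``day3``/``day10``); ``delta_by_day`` holds
    treated − mock beta differences on the same keys. ``sample`` names
    the cell-line column; it may be omitted when every matrix has a
    single column.
    """
    if len(annotation) == 0:
        raise ValueError("empty probe annotation")
    if set(expr_by_day) != set(beta_mock_by_day) or set(expr_by_day) != set(delta_by_day):
        raise ValueError("expression, mock-beta and delta inputs must share timepoints")

    days = list(expr_by_day)
    if sample is None:
        cols = {tuple(m.values.columns) for m in expr_by_day.values()}
        cols |= {tuple(m.values.columns) for m in beta_mock_by_day.values()}
        only = {c for cs in cols for c in cs}
        if len(only) != 1:
            raise ValueError("multiple sample columns present; pass sample=")
        sample = next(iter(only))

    # expression rule: median M above the cutoff at day 3 OR day 10
    expr_days: dict[str, list[str]] = {}
    for day in days:
        mat = expr_by_day[day]
        if mat.feature_level != "gene" or mat.scale_tag != "log_ratio":
            raise ValueError("expression matrices must be gene-level log ratios")
        col = mat.values[sample]
        for g in col.index[(col > thresholds.expr_m_min).to_numpy(dtype=bool)]:
            expr_days.setdefault(g, []).append(day)

    probe_hits = pd.concat(
        [_passing_probes_one_day(day, beta_mock_by_day[day], delta_by_day[day],
                                 sample, annotation, thresholds)
         for day in days],
        ignore_index=True)

    genes, prov = [], {}
    hit_by_gene = dict(tuple(probe_hits.groupby("gene_id", sort=False))) if len(probe_hits) else {}
    for g in sorted(expr_days):
        if g not in hit_by_gene:
            continue
        recs = hit_by_gene[g].to_dict(orient="records")
        genes.append(g)
        prov[g] = {"expr_days": sorted(expr_days[g]), "probes": recs}
    return GeneSignature(genes, prov)


def cohort_validation(candidates: GeneSignature,
                      informative: pd.DataFrame,
                      thresholds: FilterThresholds = FilterThresholds(),
                      ) -> GeneSignature:
    """Retain candidate genes whose passing promoter probes are backed
    by the cohort: the probe must be informative (negative rho at the
    informative FDR) with rho below ``cohort_rho_max`` and q below
    ``cohort_fdr_max``. Probes absent from the cohort are treated as
    non-informative.
    """
    genes, prov = [], {}
    for g in candidates.gene_ids:
        rec = candidates.provenance.get(g, {})
        best = None
        for p in rec.get("probes", []):
            pid = p["probe_id"]
            if pid not in informative.index:
                continue
            row = informative.loc[pid]
            if (bool(row["informative"])
                    and row["rho"] < thresholds.cohort_rho_max
                    and row["q"] < thresholds.cohort_fdr_max):
                if best is None or row["rho"] < best[1]:
                    best = (pid, float(row["rho"]), float(row["q"]))
        if best is not None:
            genes.append(g)
            prov[g] = dict(rec, validated_probe=best[0], rho=best[1], q=best[2])
    return GeneSignature(genes, prov)


def _norm(symbols) -> set[str]:
    return {str(s).strip().upper() for s in symbols if str(s).strip()}


def annotate_transcription_factors(signature: GeneSignature,
                                   tf_list) -> tuple[list[str], float]:
    """Intersect the signature with a (deduplicated, case-normalised)
    transcription-factor list. Returns the TF subset in signature order
    and the fraction of the signature it represents (NaN when the
    signature is empty)."""
    tfs = _norm(tf_list)
    subset = [g for g in signature.gene_ids if g.strip().upper() in tfs]
    if len(signature) == 0:
        log.warning("empty signature: TF fraction undefined")
        return subset, float("nan")
    return subset, len(subset) / len(signature)


def overlap_fraction(signature: GeneSignature, reference_list) -> float:
    """Fraction of signature genes present in a reference list (e.g. an
    interferon-regulated gene database export). NaN for an empty
    signature."""
    if len(signature) == 0:
        log.warning("empty signature: overlap fraction undefined")
        return float("nan")
    ref = _norm(reference_list)
    return sum(g.strip().upper() in ref for g in signature.gene_ids) / len(signature)
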