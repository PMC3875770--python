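"""Synthetic fixtures with known ground truth.

Emulates the data shapes of a demethylating-drug experiment and a
tumour cohort: paired mock/treated bead-array intensities at two
timepoints with planted promoter demethylation, probe-level expression
log ratios with induction coupled to the demethylation, a cohort with a
low-expression/high-methylation subgroup, and the auxiliary inputs
(gene sets, TF and reference lists, PWMs, promoter sequences).

Intensities are generated by fixing the target beta and a log-normal
total intensity T and setting M = beta·T, U = (1 − beta)·T, so betas
recomputed from emitted intensities reproduce the targets exactly.
Detection dropout swaps a cell's total intensity for a draw from the
negative-control distribution (beta is preserved; the detection p-value
becomes background-like). Identical configs give bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrices import ExprMatrix, IntensityTable, MethMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CellLineExperiment",
    "CohortData",
    "AuxiliaryFixtures",
    "select_planted",
    "generate_annotation",
    "generate_cell_line_experiment",
    "generate_cohort",
    "generate_auxiliary",
    "generate_metrics_fixtures",
    "gene_chromosome_map",
    "write_fixture_dir",
]

log = logging.getLogger(__name__)

CELL_LINE = "CL1"
DAYS = ("day3", "day10")

_STREAMS = {"planted": 0, "annotation": 1, "experiment": 2,
            "cohort": 3, "aux": 4, "metrics": 5}


@dataclass(frozen=True)
class SimConfig:
    """Study-scale simulation parameters.

    The headline knobs (first block) are the planted effects the
    pipeline must recover; the second block are nuisance parameters of
    the array/cohort emulation.
    """

    n_genes: int = 2000
    probes_per_gene: tuple[int, int] = (2, 5)
    n_planted: int = 50
    n_samples_cohort: int = 60
    subgroup_fraction: float = 0.3
    delta_beta_effect: float = 0.4       # beta-scale demethylation of planted promoters
    expr_effect: float = 1.5             # log2 induction of planted genes at day 10
    noise_sd_beta: float = 0.05
    noise_sd_expr: float = 0.05
    seed: int = 0

    snp_fraction: float = 0.05
    sex_chrom_fraction: float = 0.03
    dropout_fraction: float = 0.01       # detection-failure rate per cell
    zero_expr_fraction: float = 0.05     # cohort RPKM zeros
    expr_probes_per_gene: int = 2
    planted_tf_fraction: float = 0.2
    day3_effect_fraction: float = 0.5    # fraction of the day-10 effect present at day 3
    mean_total_intensity: float = 4000.0
    control_mean_intensity: float = 200.0
    n_control_probes: int = 50
    cohort_expr_span: float = 4.0        # log2 range of planted-gene cohort expression
    n_background_promoters: int = 400
    promoter_window: tuple[int, int] = (-450, 50)

    def __post_init__(self) -> None:
        if self.probes_per_gene[0] < 1:
            raise ValueError("probes_per_gene lower bound must be >= 1")
        if self.probes_per_gene[0] > self.probes_per_gene[1]:
            raise ValueError("probes_per_gene range inverted")
        if not 0 < self.n_planted <= self.n_genes:
            raise ValueError("need 0 < n_planted <= n_genes")
        if not 0 < self.subgroup_fraction < 1:
            raise ValueError("subgroup_fraction must lie in (0, 1)")
        for name in ("snp_fraction", "sex_chrom_fraction", "dropout_fraction",
                     "zero_expr_fraction", "planted_tf_fraction",
                     "day3_effect_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.noise_sd_beta < 0 or self.noise_sd_expr < 0:
            raise ValueError("noise SDs must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        """Named child generator; each stream is independent of the
        others but fully determined by (seed, stream)."""
        ss = np.random.SeedSequence(entropy=self.seed,
                                    spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    planted_gene_ids: list[str]
    planted_tf_ids: list[str]
    cohort_subgroup_labels: pd.Series | None = None
    enriched_set_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not set(self.planted_tf_ids) <= set(self.planted_gene_ids):
            raise ValueError("planted TFs must be a subset of planted genes")

    def to_dict(self) -> dict:
        d = {
            "planted_gene_ids": list(self.planted_gene_ids),
            "planted_tf_ids": list(self.planted_tf_ids),
            "enriched_set_names": list(self.enriched_set_names),
        }
        if self.cohort_subgroup_labels is not None:
            d["cohort_subgroup_labels"] = {
                str(k): int(v) for k, v in self.cohort_subgroup_labels.items()}
        return d


@dataclass
class CellLineExperiment:
    """Paired mock/treated arrays at two timepoints for one cell line."""

    intensities: dict[str, IntensityTable]          # mock_day3, aza_day3, ...
    expr_log_ratios: dict[str, ExprMatrix]          # probe-level, per day
    probe_gene_map: pd.Series                       # expression probe -> gene
    target_betas: dict[str, pd.DataFrame]           # noise-free check values
    truth: GroundTruth


@dataclass
class CohortData:
    expr_rpkm: ExprMatrix            # gene-level, linear
    meth_beta: MethMatrix            # probe-level
    truth: GroundTruth


@dataclass
class AuxiliaryFixtures:
    gene_sets: dict[str, list[str]]
    tf_list: list[str]
    reference_list: list[str]
    pwm_counts: np.ndarray
    promoters: dict[str, str]        # header "gene|window:-450..50" -> sequence
    truth: GroundTruth


def _gene_ids(config: SimConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(config.n_genes)]


def select_planted(config: SimConfig) -> tuple[list[str], list[str]]:
    """Planted (silenced-then-reactivated) genes and the subset flagged
    as transcription factors — a pure function of the config, so every
    generator agrees without sharing state."""
    rng = config.rng("planted")
    genes = _gene_ids(config)
    idx = rng.choice(config.n_genes, size=config.n_planted, replace=False)
    planted = sorted(genes[i] for i in idx)
    n_tf = max(1, int(round(config.planted_tf_fraction * config.n_planted)))
    tf_idx = rng.choice(config.n_planted, size=n_tf, replace=False)
    return planted, sorted(planted[i] for i in tf_idx)


def generate_annotation(config: SimConfig) -> pd.DataFrame:
    """Probe annotation: per gene at least one CpG-island probe within
    1000 bp of the TSS (a candidate promoter probe) and at least one
    probe that is either non-island or outside that window; a fraction
    of probes carry SNP flags; genes sit on autosomes except for a
    small fraction on chrX/chrY. Planted genes are kept autosomal so
    the planted signal survives sex-chromosome filtering.
    """
    rng = config.rng("annotation")
    genes = _gene_ids(config)
    planted, _ = select_planted(config)
    planted_set = set(planted)

    rows = []
    counter = 0
    lo, hi = config.probes_per_gene
    for g in genes:
        if g in planted_set:
            chrom = f"chr{rng.integers(1, 23)}"
        else:
            if rng.random() < config.sex_chrom_fraction:
                chrom = "chrX" if rng.random() < 0.5 else "chrY"
            else:
                chrom = f"chr{rng.integers(1, 23)}"
        tss = int(rng.integers(1_000_000, 100_000_000))
        k = max(int(rng.integers(lo, hi + 1)), 2)
        for j in range(k):
            if j == 0:  # guaranteed promoter island probe
                dist = int(rng.integers(-1000, 1001))
                island = True
            elif j == 1:  # guaranteed non-promoter probe
                if rng.random() < 0.5:
                    dist = int(rng.integers(-1000, 1001))
                    island = False
                else:
                    sign = -1 if rng.random() < 0.5 else 1
                    dist = sign * int(rng.integers(1001, 5001))
                    island = True
            else:
                dist = int(rng.integers(-5000, 5001))
                island = bool(rng.random() < 0.4)
            rows.append({
                "probe_id": f"cg{counter:07d}",
                "gene_id": g,
                "chrom": chrom,
                "pos": tss + dist,
                "tss_distance": dist,
                "island_flag": island,
                "snp_flag": bool(rng.random() < config.snp_fraction),
            })
            counter += 1
    return pd.DataFrame(rows).set_index("probe_id")


def gene_chromosome_map(annotation: pd.DataFrame) -> pd.Series:
    """Gene → chromosome Series derived from the probe annotation."""
    return annotation.groupby("gene_id")["chrom"].first()


def _promoter_probe_mask(annotation: pd.DataFrame, window: int = 1000) -> pd.Series:
    return annotation["island_flag"].astype(bool) & (
        annotation["tss_distance"].abs() <= window)


def _intensities_from_beta(beta: pd.DataFrame, rng: np.random.Generator,
                           config: SimConfig) -> IntensityTable:
    """Back-compute bead intensities so M / (U + M) reproduces the
    target beta exactly; simulate detection dropout by replacing a
    cell's total intensity with a negative-control draw."""
    shape = beta.shape
    total = rng.lognormal(mean=np.log(config.mean_total_intensity),
                          sigma=0.3, size=shape)
    drop = rng.random(shape) < config.dropout_fraction
    bg_draws = rng.lognormal(mean=np.log(config.control_mean_intensity),
                             sigma=0.25, size=shape)
    total = np.where(drop, bg_draws, total)
    b = beta.to_numpy(dtype=float)
    m = b * total
    u = (1.0 - b) * total
    ctrl = rng.lognormal(mean=np.log(config.control_mean_intensity),
                         sigma=0.25,
                         size=(config.n_control_probes, shape[1]))
    mk = lambda arr: pd.DataFrame(arr, index=beta.index, columns=beta.columns)
    controls = pd.DataFrame(
        ctrl, index=[f"neg{i:03d}" for i in range(config.n_control_probes)],
        columns=beta.columns)
    return IntensityTable(mk(m), mk(u), controls)


def generate_cell_line_experiment(config: SimConfig,
                                  annotation: pd.DataFrame,
                                  ) -> CellLineExperiment:
    """Paired mock/treated methylation arrays and expression log ratios
    at day 3 and day 10 for one cell line.

    Planted genes carry high mock beta on their promoter island probes,
    treated beta lowered by ``delta_beta_effect`` (half the effect at
    day 3), and expression induced by ``expr_effect`` at day 10; all
    other genes are null. Betas pushed outside [0, 1] are clipped with
    a logged warning.
    """
    rng = config.rng("experiment")
    planted, planted_tfs = select_planted(config)
    planted_set = set(planted)
    probes = annotation.index
    promoter = _promoter_probe_mask(annotation)
    is_planted_probe = (annotation["gene_id"].isin(planted_set) & promoter).to_numpy()

    # noise-free target betas in mock
    base = rng.beta(1.5, 6.0, size=len(probes))          # mostly unmethylated
    high = rng.uniform(0.6, 0.95, size=len(probes))      # silenced promoters
    mock_target = np.where(is_planted_probe, high, base)

    intensities: dict[str, IntensityTable] = {}
    target_betas: dict[str, pd.DataFrame] = {}
    for day in DAYS:
        eff = config.delta_beta_effect * (
            config.day3_effect_fraction if day == "day3" else 1.0)
        aza_target = mock_target - np.where(is_planted_probe, eff, 0.0)
        n_clip = int(((aza_target < 0) | (aza_target > 1)).sum())
        if n_clip:
            log.warning("clipping %d treated target betas to [0, 1]", n_clip)
            aza_target = np.clip(aza_target, 0.0, 1.0)
        for cond, target in (("mock", mock_target), ("aza", aza_target)):
            noisy = target + rng.normal(0.0, config.noise_sd_beta, size=len(probes)) \
                if config.noise_sd_beta > 0 else target.copy()
            noisy = np.clip(noisy, 0.0, 1.0)
            frame = pd.DataFrame({CELL_LINE: noisy}, index=probes)
            key = f"{cond}_{day}"
            target_betas[key] = frame
            intensities[key] = _intensities_from_beta(frame, rng, config)

    # probe-level expression log ratios with a probe -> gene mapping
    genes = _gene_ids(config)
    probe_ids, gene_of = [], []
    for gi, g in enumerate(genes):
        for j in range(config.expr_probes_per_gene):
            probe_ids.append(f"ep{gi:05d}_{j}")
            gene_of.append(g)
    mapping = pd.Series(gene_of, index=pd.Index(probe_ids, name="probe_id"))
    planted_expr_probe = mapping.isin(planted_set).to_numpy()

    expr: dict[str, ExprMatrix] = {}
    for day in DAYS:
        eff = config.expr_effect * (
            config.day3_effect_fraction if day == "day3" else 1.0)
        target = np.where(planted_expr_probe, eff, 0.0)
        noisy = target + rng.normal(0.0, config.noise_sd_expr, size=len(target)) \
            if config.noise_sd_expr > 0 else target
        expr[day] = ExprMatrix(
            pd.DataFrame({CELL_LINE: noisy}, index=mapping.index),
            feature_level="probe", scale_tag="log_ratio")

    truth = GroundTruth(planted, planted_tfs)
    return CellLineExperiment(intensities, expr, mapping, target_betas, truth)


def generate_cohort(config: SimConfig, annotation: pd.DataFrame) -> CohortData:
    """Tumour cohort with a planted subgroup.

    For planted genes a per-sample latent silencing level couples
    promoter beta (increasing) to expression (strictly decreasing on
    the log2 scale), so planted promoter probes correlate negatively
    with expression — exactly −1 in the zero-noise limit. The subgroup
    draws high latent values (high methylation, low expression); other
    samples draw low ones. Non-planted genes are independent noise. A
    configurable fraction of expression values is zeroed to exercise
    the zeros-to-missing rule.
    """
    rng = config.rng("cohort")
    planted, planted_tfs = select_planted(config)
    planted_set = set(planted)
    genes = _gene_ids(config)
    samples = [f"S{i:03d}" for i in range(config.n_samples_cohort)]
    n_sub = int(round(config.subgroup_fraction * config.n_samples_cohort))
    sub_idx = rng.choice(config.n_samples_cohort, size=n_sub, replace=False)
    labels = pd.Series(0, index=samples)
    labels.iloc[sorted(sub_idx)] = 1

    # latent silencing level per (planted gene, sample)
    z = rng.uniform(0.0, 0.35, size=(len(planted), len(samples)))
    z_sub = rng.uniform(0.65, 1.0, size=(len(planted), len(samples)))
    z = np.where(labels.to_numpy()[None, :] == 1, z_sub, z)

    # gene-level expression (linear RPKM)
    log2_expr = rng.normal(4.0, 1.0, size=(len(genes), len(samples)))
    if config.noise_sd_expr > 0:
        planted_noise = rng.normal(0.0, config.noise_sd_expr,
                                   size=z.shape)
    else:
        planted_noise = np.zeros_like(z)
    base_level = rng.uniform(4.0, 6.0, size=(len(planted), 1))
    planted_log2 = base_level - config.cohort_expr_span * z + planted_noise
    expr = pd.DataFrame(log2_expr, index=genes, columns=samples)
    expr.loc[planted] = planted_log2
    rpkm = np.power(2.0, expr)

    zeros = rng.random(rpkm.shape) < config.zero_expr_fraction
    rpkm = rpkm.mask(pd.DataFrame(zeros, index=rpkm.index, columns=rpkm.columns),
                     0.0)

    # probe-level beta values
    probes = annotation.index
    promoter = _promoter_probe_mask(annotation)
    planted_probe = (annotation["gene_id"].isin(planted_set) & promoter)
    beta = rng.beta(2.0, 5.0, size=(len(probes), len(samples)))
    planted_rows = np.flatnonzero(planted_probe.to_numpy())
    gene_pos = {g: i for i, g in enumerate(planted)}
    for row in planted_rows:
        gi = gene_pos[annotation["gene_id"].iloc[row]]
        beta[row] = 0.15 + 0.7 * z[gi]
    if config.noise_sd_beta > 0:
        beta = beta + rng.normal(0.0, config.noise_sd_beta, size=beta.shape)
    beta = np.clip(beta, 0.0, 1.0)

    truth = GroundTruth(planted, planted_tfs, cohort_subgroup_labels=labels)
    return CohortData(
        ExprMatrix(rpkm, feature_level="gene", scale_tag="linear"),
        MethMatrix(pd.DataFrame(beta, index=probes, columns=samples), "beta"),
        truth,
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def generate_auxiliary(config: SimConfig) -> AuxiliaryFixtures:
    """Gene sets, TF and reference lists, a PWM and promoter sequences.

    Three gene sets are enriched (≈80% planted members, ground-truth
    positives) and ten are random. Planted genes' promoters carry an
    embedded PWM consensus site inside the scan window; background
    promoters are random sequence.
    """
    rng = config.rng("aux")
    planted, planted_tfs = select_planted(config)
    genes = _gene_ids(config)
    non_planted = [g for g in genes if g not in set(planted)]

    gene_sets: dict[str, list[str]] = {}
    enriched_names = []
    for i in range(3):
        n_from_planted = min(20, len(planted))
        n_filler = min(5, len(non_planted))
        members = list(rng.choice(planted, size=n_from_planted, replace=False))
        members += list(rng.choice(non_planted, size=n_filler, replace=False))
        name = f"ENRICHED_{i + 1}"
        gene_sets[name] = sorted(set(members))
        enriched_names.append(name)
    n_rand = min(25, max(2, len(genes) // 2))
    for i in range(10):
        name = f"RANDOM_{i + 1}"
        gene_sets[name] = sorted(rng.choice(genes, size=n_rand, replace=False))

    n_tf_bg = min(100, len(non_planted))
    tf_list = sorted(set(planted_tfs)
                     | set(rng.choice(non_planted, size=n_tf_bg, replace=False)))
    n_ref = max(1, int(round(0.6 * len(planted))))
    n_ref_bg = min(150, len(non_planted))
    reference = sorted(set(rng.choice(planted, size=n_ref, replace=False))
                       | set(rng.choice(non_planted, size=n_ref_bg, replace=False)))

    width = 8
    consensus_idx = rng.integers(0, 4, size=width)
    counts = np.full((4, width), 2.0)
    counts[consensus_idx, np.arange(width)] = 30.0
    consensus = "".join("ACGT"[i] for i in consensus_idx)

    lo, hi = config.promoter_window
    length = hi - lo
    n_bg = min(config.n_background_promoters, len(non_planted))
    bg_genes = list(rng.choice(non_planted, size=n_bg, replace=False))
    promoters: dict[str, str] = {}
    for g in planted + bg_genes:
        seq = _random_seq(rng, length)
        if g in set(planted):
            at = int(rng.integers(0, length - width + 1))
            seq = seq[:at] + consensus + seq[at + width:]
        promoters[f"{g}|window:{lo}..{hi}"] = seq

    truth = GroundTruth(planted, planted_tfs, enriched_set_names=enriched_names)
    return AuxiliaryFixtures(gene_sets, tf_list, reference, counts, promoters, truth)


def generate_metrics_fixtures(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Small cytometry-quartet and lesion-series tables for the
    closed-form metrics stage."""
    rng = config.rng("metrics")
    quartets = []
    for i in range(5):
        iso_t, iso_m = rng.uniform(10, 30, size=2)
        quartets.append({
            "marker": f"marker{i + 1}",
            "antibody_treated": iso_t + rng.uniform(20, 300),
            "isotype_treated": iso_t,
            "antibody_mock": iso_m + rng.uniform(20, 300),
            "isotype_mock": iso_m,
        })
    lesions = []
    for i in range(4):
        baseline = rng.uniform(40, 120)
        sums = baseline * rng.uniform(0.4, 1.3, size=3)
        lesions.append({"patient": f"P{i + 1}", "baseline_sum": baseline,
                        **{f"timepoint_{t + 1}": s for t, s in enumerate(sums)}})
    return pd.DataFrame(quartets), pd.DataFrame(lesions)


def write_fixture_dir(config: SimConfig, outdir) -> dict[str, str]:
    """Generate every fixture and write it in the plain-text exchange
    formats; returns a name → path map. The ground-truth sidecar lands
    in ``ground_truth.json``."""
    from pathlib import Path

    from . import io as rio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    ann = generate_annotation(config)
    rio.write_annotation(ann, out / "annotation.tsv")
    paths["annotation"] = str(out / "annotation.tsv")

    exp = generate_cell_line_experiment(config, ann)
    for key, tab in exp.intensities.items():
        for channel, df in (("methylated", tab.methylated),
                            ("unmethylated", tab.unmethylated),
                            ("controls", tab.negative_controls)):
            p = out / f"intensity_{key}_{channel}.tsv"
            rio.write_matrix(df, p)
            paths[f"intensity_{key}_{channel}"] = str(p)
    for day, mat in exp.expr_log_ratios.items():
        p = out / f"expr_log_ratio_{day}.tsv"
        rio.write_matrix(mat.values, p)
        paths[f"expr_log_ratio_{day}"] = str(p)
    exp.probe_gene_map.rename("gene_id").to_csv(out / "expr_probe_map.tsv", sep="\t")
    paths["expr_probe_map"] = str(out / "expr_probe_map.tsv")

    coh = generate_cohort(config, ann)
    rio.write_matrix(coh.expr_rpkm.values, out / "cohort_rpkm.tsv")
    rio.write_matrix(coh.meth_beta.values, out / "cohort_beta.tsv")
    paths["cohort_rpkm"] = str(out / "cohort_rpkm.tsv")
    paths["cohort_beta"] = str(out / "cohort_beta.tsv")

    aux = generate_auxiliary(config)
    rio.write_gmt(aux.gene_sets, out / "gene_sets.gmt")
    rio.write_gene_list(aux.tf_list, out / "tf_list.txt")
    rio.write_gene_list(aux.reference_list, out / "reference_list.txt")
    rio.write_pwm(aux.pwm_counts, out / "motif.pwm")
    rio.write_fasta(aux.promoters, out / "promoters.fa")
    paths.update(gene_sets=str(out / "gene_sets.gmt"),
                 tf_list=str(out / "tf_list.txt"),
                 reference_list=str(out / "reference_list.txt"),
                 pwm=str(out / "motif.pwm"),
                 promoters=str(out / "promoters.fa"))

    quartets, lesions = generate_metrics_fixtures(config)
    quartets.to_csv(out / "mfi_quartets.tsv", sep="\t", index=False)
    lesions.to_csv(out / "lesion_series.tsv", sep="\t", index=False)
    paths["mfi_quartets"] = str(out / "mfi_quartets.tsv")
    paths["lesion_series"] = str(out / "lesion_series.tsv")

    truth = coh.truth.to_dict()
    truth["enriched_set_names"] = aux.truth.enriched_set_names
    rio.write_ground_truth(truth, out / "ground_truth.json")
    paths["ground_truth"] = str(out / "ground_truth.json")
    return paths
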