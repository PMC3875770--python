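import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reexpress import expression as expr_mod
from reexpress import integration as integ
from reexpress import synthetic as syn
from reexpress.integration import FilterThresholds, GeneSignature
from reexpress.matrices import ExprMatrix, MethMatrix


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert integ.spearman_rho(x, -x) == pytest.approx(-1.0)
        assert integ.spearman_rho(x, x ** 3) == pytest.approx(1.0)

    def test_tied_instance_matches_hand_ranks(self):
        # ranks of x: [1, 2.5, 2.5, 4]; Pearson on average ranks = 3/sqrt(22.5)
        rho = integ.spearman_rho([1, 2, 2, 3], [2, 1, 3, 4])
        assert rho == pytest.approx(3 / np.sqrt(22.5))

    def test_too_few_pairs_gives_nan(self, caplog):
        with caplog.at_level("WARNING"):
            rho = integ.spearman_rho([1, 2, np.nan], [1, np.nan, 3])
        assert np.isnan(rho)

    def test_bulk_rank_path_matches_scipy(self):
        """The vectorised rho/p used for the probe scan agrees with
        scipy.stats.spearmanr on random data with ties."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.integers(0, 8, size=30).astype(float)
            y = rng.normal(size=30)
            rho, n = integ._rank_corr_and_p(x, y)
            p = integ._t_approx_pvalues(np.array([rho]), np.array([n]))[0]
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)


class TestBHAdjust:
    def test_single_p_identity(self):
        assert integ.bh_adjust([0.02])[0] == pytest.approx(0.02)

    def test_step_up_hand_example(self):
        q = integ.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(integ.bh_adjust([0.3] * 5), [0.3] * 5)

    def test_monotone_with_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        q = integ.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            integ.bh_adjust([0.5, 1.5])


def _single_col_meth(values: dict, col=syn.CELL_LINE) -> MethMatrix:
    return MethMatrix(pd.DataFrame({col: values}), "beta")


def _gene_expr(values: dict, col=syn.CELL_LINE) -> ExprMatrix:
    return ExprMatrix(pd.DataFrame({col: values}), feature_level="gene",
                      scale_tag="log_ratio")


def _cascade_inputs(tss=-500, beta_mock=0.8, demeth=0.3, expr_m=0.7,
                    island=True):
    """One gene, one probe, both timepoints carrying the same values."""
    ann = pd.DataFrame({
        "gene_id": ["g1"], "chrom": ["chr1"], "pos": [1000 + tss],
        "tss_distance": [tss], "island_flag": [island], "snp_flag": [False],
    }, index=pd.Index(["cg1"], name="probe_id"))
    expr = {d: _gene_expr({"g1": expr_m}) for d in ("day3", "day10")}
    mock = {d: _single_col_meth({"cg1": beta_mock}) for d in ("day3", "day10")}
    delta = {d: pd.DataFrame({syn.CELL_LINE: {"cg1": -demeth}})
             for d in ("day3", "day10")}
    return expr, mock, delta, ann


class TestReexpressionFilter:
    def test_passing_gene_included_with_provenance(self):
        sig = integ.reexpression_filter(*_cascade_inputs())
        assert sig.gene_ids == ["g1"]
        prov = sig.provenance["g1"]
        assert prov["expr_days"] == ["day10", "day3"]
        assert prov["probes"][0]["probe_id"] == "cg1"
        assert prov["probes"][0]["demethylation"] == pytest.approx(0.3)

    @pytest.mark.parametrize("kwargs", [
        {"tss": -1500},          # probe outside the 1000 bp TSS window
        {"beta_mock": 0.45},     # baseline methylation not high enough
        {"beta_mock": 0.5},      # boundary: strictly greater required
        {"demeth": 0.2},         # demethylation below 0.25
        {"expr_m": 0.5},         # expression boundary: strictly greater
        {"island": False},       # non-island promoter probe
    ])
    def test_failing_variants_excluded(self, kwargs):
        sig = integ.reexpression_filter(*_cascade_inputs(**kwargs))
        assert sig.gene_ids == []

    def test_demethylation_boundary_inclusive(self):
        sig = integ.reexpression_filter(*_cascade_inputs(demeth=0.25))
        assert sig.gene_ids == ["g1"]

    def test_or_over_timepoints(self):
        """Expression only at day 3 and demethylation only at day 10
        still qualifies the gene."""
        expr, mock, delta, ann = _cascade_inputs()
        expr["day10"] = _gene_expr({"g1": 0.0})
        delta["day3"] = pd.DataFrame({syn.CELL_LINE: {"cg1": 0.0}})
        sig = integ.reexpression_filter(expr, mock, delta, ann)
        assert sig.gene_ids == ["g1"]
        assert sig.provenance["g1"]["expr_days"] == ["day3"]
        assert sig.provenance["g1"]["probes"][0]["day"] == "day10"

    def test_empty_annotation_rejected(self):
        expr, mock, delta, ann = _cascade_inputs()
        with pytest.raises(ValueError, match="annotation"):
            integ.reexpression_filter(expr, mock, delta, ann.iloc[:0])

    def test_threshold_monotonicity(self, experiment, annotation):
        """Tightening any threshold never adds a gene."""
        from reexpress import methylation as meth
        mock, delta = {}, {}
        for day in syn.DAYS:
            bm = meth.compute_beta(experiment.intensities[f"mock_{day}"])
            ba = meth.compute_beta(experiment.intensities[f"aza_{day}"])
            mock[day] = bm
            delta[day] = meth.delta_beta(ba, bm)
        gene = {day: expr_mod.aggregate_probes_to_genes(
            experiment.expr_log_ratios[day], experiment.probe_gene_map)
            for day in syn.DAYS}
        base = set(integ.reexpression_filter(gene, mock, delta, annotation,
                                             FilterThresholds()).gene_ids)
        tighter = [
            FilterThresholds(expr_m_min=0.9),
            FilterThresholds(beta_mock_min=0.7),
            FilterThresholds(delta_beta_min=0.35),
            FilterThresholds(tss_window=400),
        ]
        for thr in tighter:
            sub = set(integ.reexpression_filter(gene, mock, delta, annotation,
                                                thr).gene_ids)
            assert sub <= base


class TestInformativeProbes:
    def test_planted_anticorrelated_probe_retained(self, small_config, annotation):
        from dataclasses import replace
        cfg = replace(small_config, noise_sd_beta=0.0, noise_sd_expr=0.0,
                      zero_expr_fraction=0.0)
        ann = syn.generate_annotation(cfg)
        coh = syn.generate_cohort(cfg, ann)
        cohort_expr = expr_mod.preprocess_cohort_rpkm(
            coh.expr_rpkm, syn.gene_chromosome_map(ann))
        table = integ.informative_probes(coh.meth_beta, cohort_expr, ann)
        planted = set(coh.truth.planted_gene_ids)
        promoter = ann["island_flag"] & (ann["tss_distance"].abs() <= 1000)
        planted_probes = ann.index[(ann["gene_id"].isin(planted) & promoter)]
        sub = table.loc[table.index.intersection(planted_probes)]
        assert (sub["rho"] == -1.0).all()
        assert sub["informative"].all()

    def test_positive_rho_never_informative(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=30)
        beta = MethMatrix(pd.DataFrame([x], index=["cg1"],
                                       columns=[f"s{i}" for i in range(30)]))
        expr = ExprMatrix(pd.DataFrame([x * 2 + 1], index=["g1"],
                                       columns=beta.samples),
                          feature_level="gene", scale_tag="log_rpkm")
        ann = pd.DataFrame({"gene_id": ["g1"], "tss_distance": [-10],
                            "island_flag": [True], "snp_flag": [False],
                            "chrom": ["chr1"], "pos": [0]}, index=["cg1"])
        table = integ.informative_probes(beta, expr, ann)
        assert table.loc["cg1", "rho"] > 0.9
        assert not table.loc["cg1", "informative"]


class TestCohortValidation:
    def _candidates(self):
        return GeneSignature(["g1", "g2"], {
            "g1": {"expr_days": ["day10"],
                   "probes": [{"probe_id": "cg1", "gene_id": "g1",
                               "day": "day10", "beta_mock": 0.8,
                               "demethylation": 0.3}]},
            "g2": {"expr_days": ["day10"],
                   "probes": [{"probe_id": "cg2", "gene_id": "g2",
                               "day": "day10", "beta_mock": 0.7,
                               "demethylation": 0.4}]},
        })

    def _informative(self, rho2=-0.20, q2=0.001):
        return pd.DataFrame({
            "gene_id": ["g1", "g2"],
            "tss_distance": [-100, 200],
            "n": [50, 50],
            "rho": [-0.8, rho2],
            "p": [1e-6, 0.3],
            "q": [0.001, q2],
            "informative": [True, rho2 < 0 and q2 < 0.01],
        }, index=["cg1", "cg2"])

    def test_strong_probe_retained_weak_dropped(self):
        out = integ.cohort_validation(self._candidates(), self._informative())
        assert out.gene_ids == ["g1"]  # rho = -0.20 fails the < -0.25 rule
        assert out.provenance["g1"]["rho"] == pytest.approx(-0.8)

    def test_probe_absent_from_cohort_is_noninformative(self):
        informative = self._informative().drop(index="cg2")
        out = integ.cohort_validation(self._candidates(), informative)
        assert out.gene_ids == ["g1"]

    def test_tightening_cutoffs_shrinks(self):
        cand = self._candidates()
        informative = self._informative(rho2=-0.5, q2=0.001)
        base = integ.cohort_validation(cand, informative)
        strict = integ.cohort_validation(
            cand, informative, FilterThresholds(cohort_rho_max=-0.9))
        assert set(strict.gene_ids) <= set(base.gene_ids)


class TestSignatureAnnotation:
    def test_tf_fraction(self):
        sig = GeneSignature([f"g{i}" for i in range(100)])
        tfs = [f"g{i}" for i in range(19)]
        subset, frac = integ.annotate_transcription_factors(sig, tfs)
        assert len(subset) == 19 and frac == pytest.approx(0.19)

    def test_case_insensitive_and_dedup(self):
        sig = GeneSignature(["Irf7", "STAT1"])
        subset, frac = integ.annotate_transcription_factors(
            sig, ["IRF7", "irf7", "GATA1"])
        assert subset == ["Irf7"] and frac == pytest.approx(0.5)

    def test_disjoint_gives_zero(self):
        sig = GeneSignature(["a", "b"])
        _, frac = integ.annotate_transcription_factors(sig, ["c"])
        assert frac == 0.0

    def test_empty_signature_missing(self):
        _, frac = integ.annotate_transcription_factors(GeneSignature([]), ["a"])
        assert np.isnan(frac)
        assert np.isnan(integ.overlap_fraction(GeneSignature([]), ["a"]))

    def test_overlap_fraction_recount(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(60)]
        sig = GeneSignature(genes)
        ref = list(rng.choice(genes, size=17, replace=False)) + ["other"]
        frac = integ.overlap_fraction(sig, ref)
        expected = len(set(genes) & set(ref)) / len(genes)
        assert frac == pytest.approx(expected) == pytest.approx(17 / 60)
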