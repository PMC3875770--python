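import numpy as np
import pandas as pd
import pytest

from reexpress import enrichment as enr
from reexpress.enrichment import PWM, EnrichmentResult, RankedList


def brute_force_es(genes, scores, members, weight=1.0):
    """Independent step-by-step enumeration of the weighted KS running
    sum; the signed extremum (first occurrence on ties)."""
    hits = [g in members for g in genes]
    nh, n = sum(hits), len(genes)
    nr = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    cur, running = 0.0, []
    for s, h in zip(scores, hits):
        if h:
            cur += (abs(s) ** weight) / nr if nr > 0 else 1.0 / nh
        else:
            cur -= 1.0 / (n - nh)
        running.append(cur)
    best = running[0]
    for v in running[1:]:
        if abs(v) > abs(best):
            best = v
    return best, running


def _ranked(n, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(size=n))[::-1]
    return RankedList([f"g{i}" for i in range(n)], scores)


class TestEnrichmentScore:
    def test_top_prefix_weight_zero_reaches_one(self):
        """All set members leading the list: the unweighted running sum
        peaks at exactly +1 on the last hit."""
        ranked = _ranked(8)
        es, running = enr.enrichment_score(ranked, {"g0", "g1", "g2"},
                                           weight_exponent=0.0)
        assert es == pytest.approx(1.0)
        assert np.argmax(running) == 2

    def test_whole_list_set_rejected(self):
        ranked = _ranked(4)
        with pytest.raises(ValueError, match="cover"):
            enr.enrichment_score(ranked, set(ranked.gene_ids))

    def test_empty_intersection_missing(self):
        es, running = enr.enrichment_score(_ranked(4), {"absent"})
        assert np.isnan(es) and running.size == 0

    def test_matches_brute_force_on_small_lists(self):
        """Exact agreement with independent enumeration for every
        random list of up to 10 genes."""
        rng = np.random.default_rng(42)
        for trial in range(60):
            n = int(rng.integers(3, 11))
            ranked = _ranked(n, seed=trial)
            k = int(rng.integers(1, n))
            members = set(rng.choice(ranked.gene_ids, size=k, replace=False))
            for w in (0.0, 1.0, 2.0):
                es, running = enr.enrichment_score(ranked, members, w)
                es_bf, running_bf = brute_force_es(ranked.gene_ids,
                                                   ranked.scores, members, w)
                np.testing.assert_allclose(running, running_bf, atol=1e-12)
                assert es == pytest.approx(es_bf, abs=1e-12)

    def test_scale_invariance_weight_one(self):
        """Multiplying all scores by a positive constant leaves the
        weight-1 ES unchanged (hit increments are normalised)."""
        ranked = _ranked(30, seed=5)
        members = set(ranked.gene_ids[::4])
        es1, _ = enr.enrichment_score(ranked, members, 1.0)
        # a power-of-two factor commutes with fp rounding: bit-exact
        scaled = RankedList(ranked.gene_ids, ranked.scores * 8.0)
        es2, _ = enr.enrichment_score(scaled, members, 1.0)
        assert es1 == es2
        # an arbitrary factor agrees to rounding error
        scaled75 = RankedList(ranked.gene_ids, ranked.scores * 7.5)
        es3, _ = enr.enrichment_score(scaled75, members, 1.0)
        assert es3 == pytest.approx(es1, rel=1e-12)

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RankedList(["a", "a"], [2.0, 1.0])

    def test_from_scores_stable_tie_break(self):
        s = pd.Series({"x": 1.0, "y": 2.0, "z": 1.0})
        ranked = RankedList.from_scores(s)
        assert ranked.gene_ids == ["y", "x", "z"]  # ties keep input order


class _FixedRng:
    """Stand-in generator returning scripted position draws."""

    def __init__(self, draws):
        self.draws = list(draws)

    def choice(self, n, size, replace):
        return np.array(self.draws.pop(0)[:size])


class TestPermutationNes:
    def test_shortcut_null_matches_full_running_sum(self):
        """The position-based null-ES shortcut gives the same ES as the
        full running-sum computation for scripted random sets."""
        ranked = _ranked(40, seed=9)
        rng = np.random.default_rng(1)
        draws = [sorted(rng.choice(40, size=6, replace=False)) for _ in range(30)]
        null = enr._null_es(ranked, 6, len(draws), _FixedRng(draws), 1.0)
        for d, es_null in zip(draws, null):
            members = {ranked.gene_ids[i] for i in d}
            es, _ = enr.enrichment_score(ranked, members, 1.0)
            assert es_null == pytest.approx(es, abs=1e-12)

    def test_nes_normalization_identity(self):
        """An ES equal to the same-sign null mean maps to NES = 1."""
        ranked = _ranked(50, seed=2)
        null = enr._null_es(ranked, 5, 500, np.random.default_rng(0), 1.0)
        target = float(np.mean(np.abs(null[null >= 0])))
        nes, p = enr.permutation_nes(target, ranked, 5, null=null)
        assert nes == pytest.approx(1.0)

    def test_seeded_determinism(self):
        ranked = _ranked(100, seed=3)
        members = set(ranked.gene_ids[:8])
        es, _ = enr.enrichment_score(ranked, members)
        a = enr.permutation_nes(es, ranked, 8, n_perm=200, seed=11)
        b = enr.permutation_nes(es, ranked, 8, n_perm=200, seed=11)
        assert a == b

    def test_p_floor_and_flag(self, caplog):
        """No same-sign null values: p collapses to 1/(n_perm+1)."""
        ranked = _ranked(30, seed=4)
        null = np.full(200, -0.4)
        with caplog.at_level("WARNING"):
            nes, p = enr.permutation_nes(0.5, ranked, 5, null=null)
        assert p == pytest.approx(1 / 201)
        assert np.isnan(nes)

    def test_min_permutations_enforced(self):
        with pytest.raises(ValueError, match="100"):
            enr.permutation_nes(0.5, _ranked(10), 2, n_perm=50)


class TestNesMatrix:
    def _results(self):
        return [
            EnrichmentResult("l1", "sA", 0.7, 2.0, 0.001, 0.01, True),
            EnrichmentResult("l2", "sA", 0.3, 1.1, 0.40, 0.60, False),
            EnrichmentResult("l1", "sB", 0.2, 0.9, 0.70, 0.90, False),
            EnrichmentResult("l2", "sB", 0.1, 0.5, 0.90, 0.95, False),
        ]

    def test_zero_substitution_and_selection(self):
        mat = enr.assemble_nes_matrix(self._results())
        assert list(mat.index) == ["sA"]     # sB significant nowhere -> absent
        assert mat.loc["sA", "l1"] == pytest.approx(2.0)
        assert mat.loc["sA", "l2"] == 0.0    # not significant -> NES 0

    def test_all_significant_passthrough(self):
        res = [EnrichmentResult("l1", "s1", 0.5, 1.5, 0.01, 0.1, True),
               EnrichmentResult("l1", "s2", -0.5, -1.4, 0.02, 0.1, True)]
        mat = enr.assemble_nes_matrix(res)
        assert mat.loc["s1", "l1"] == 1.5 and mat.loc["s2", "l1"] == -1.4

    def test_empty_results(self):
        assert enr.assemble_nes_matrix([]).empty


def brute_force_best_score(seq, pwm):
    comp = str.maketrans("ACGT", "TGCA")
    best = -np.inf
    for s in (seq.upper(), seq.upper().translate(comp)[::-1]):
        for i in range(len(s) - pwm.width + 1):
            score = sum(pwm.weights["ACGT".index(c), j] if c in "ACGT" else 0.0
                        for j, c in enumerate(s[i:i + pwm.width]))
            best = max(best, score)
    return best


class TestPwmScan:
    @pytest.fixture()
    def pwm(self):
        counts = np.full((4, 6), 1.0)
        counts[[0, 2, 0, 3, 1, 2], np.arange(6)] = 20.0  # consensus AGATCG
        return PWM.from_counts(counts)

    def test_embedded_consensus_is_maximum(self, pwm):
        seq = "TTTTTT" + pwm.consensus + "TTTTTT"
        assert enr.pwm_best_score(seq, pwm) == pytest.approx(pwm.max_score())

    def test_strand_symmetry(self, pwm):
        rng = np.random.default_rng(8)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        assert enr.pwm_best_score(seq, pwm) == pytest.approx(
            enr.pwm_best_score(rc, pwm))

    def test_matches_brute_force_scan(self, pwm):
        rng = np.random.default_rng(17)
        for _ in range(10):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
            assert enr.pwm_best_score(seq, pwm) == pytest.approx(
                brute_force_best_score(seq, pwm), abs=1e-12)

    def test_short_sequence_missing(self, pwm):
        assert np.isnan(enr.pwm_best_score("ACG", pwm))


class TestMotifOverrepresentation:
    def _seqs(self, rng, n, length=80, plant=None):
        out = []
        for _ in range(n):
            s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
            if plant:
                at = int(rng.integers(0, length - len(plant)))
                s = s[:at] + plant + s[at + len(plant):]
            out.append(s)
        return out

    def test_identity_foreground_z_zero(self):
        rng = np.random.default_rng(21)
        counts = np.full((4, 8), 1.0)
        counts[0] = 15.0
        pwm = PWM.from_counts(counts)
        bg = self._seqs(rng, 40)
        z, p = enr.motif_overrepresentation(bg, bg, pwm)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)

    def test_planted_sites_highly_significant(self):
        rng = np.random.default_rng(22)
        counts = np.full((4, 8), 1.0)
        counts[[0, 1, 2, 3, 0, 1, 2, 3], np.arange(8)] = 25.0
        pwm = PWM.from_counts(counts)
        fg = self._seqs(rng, 12, plant=pwm.consensus)
        bg = fg + self._seqs(rng, 100)
        z, p = enr.motif_overrepresentation(fg, bg, pwm)
        assert p < 1e-3

    def test_small_foreground_rejected(self):
        pwm = PWM.from_counts(np.full((4, 4), 5.0))
        with pytest.raises(ValueError, match="at least 5"):
            enr.motif_overrepresentation(["ACGTACGT"] * 3, ["ACGTACGT"] * 10, pwm)
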