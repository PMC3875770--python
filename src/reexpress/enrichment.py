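"""Preranked gene-set enrichment and promoter motif over-representation.

Enrichment uses the weighted Kolmogorov–Smirnov running-sum statistic:
walking down a ranked gene list, the sum rises by a hit gene's
normalised |score|^weight and falls by 1/(N − Nh) at misses; the
enrichment score (ES) is the signed extremum. Significance comes from a
gene-set-permutation null (random sets of the same size), NES rescales
the ES against the same-sign null mean, and FDR across sets is
Benjamini–Hochberg on nominal p-values. A set is significant at
p < 0.05 and FDR < 0.25; NES matrices substitute 0 where significance
fails and keep only sets significant in at least one list.

The motif test scores each promoter with a PWM's best log-odds hit on
either strand and compares foreground and background best-hit means
with a one-sided z-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .integration import bh_adjust

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "PWM",
    "enrichment_score",
    "permutation_nes",
    "run_preranked",
    "assemble_nes_matrix",
    "pwm_best_score",
    "motif_overrepresentation",
]

log = logging.getLogger(__name__)

P_SIGNIFICANT = 0.05
FDR_SIGNIFICANT = 0.25

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class RankedList:
    """Genes ordered by decreasing score; ties keep input order."""

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in ranked list")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")

    @classmethod
    def from_scores(cls, scores: pd.Series) -> "RankedList":
        """Build from an unordered gene → score Series (stable
        descending sort; ties broken by input order)."""
        s = scores.dropna()
        order = np.argsort(-s.to_numpy(), kind="stable")
        return cls([s.index[i] for i in order], s.to_numpy()[order])

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    list_id: str
    set_id: str
    es: float
    nes: float
    p_nominal: float
    fdr: float
    significant: bool


def _running_sum(scores: np.ndarray, hit_mask: np.ndarray,
                 weight_exponent: float) -> np.ndarray:
    n = len(scores)
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must hit the list but not cover it entirely")
    w = np.abs(scores) ** weight_exponent
    w_hit = np.where(hit_mask, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # all hit scores are zero: fall back to equal hit weights
        w_hit = hit_mask / nh
        total = 1.0
    steps = w_hit / total - (~hit_mask) / (n - nh)
    return np.cumsum(steps)


def enrichment_score(ranked: RankedList, gene_set,
                     weight_exponent: float = 1.0) -> tuple[float, np.ndarray]:
    """Enrichment score of ``gene_set`` in ``ranked``.

    Returns the signed extremum of the running sum together with the
    full running-sum curve (one value per list position). A set with no
    member in the list yields ``(nan, empty)``, logged; a set covering
    the whole list is rejected as degenerate.
    """
    members = set(gene_set)
    hit_mask = np.fromiter((g in members for g in ranked.gene_ids),
                           dtype=bool, count=len(ranked))
    if not hit_mask.any():
        log.info("gene set has empty intersection with ranked list")
        return float("nan"), np.empty(0)
    running = _running_sum(ranked.scores, hit_mask, weight_exponent)
    es = running[int(np.argmax(np.abs(running)))]
    return float(es), running


def _null_es(ranked: RankedList, set_size: int, n_perm: int,
             rng: np.random.Generator, weight_exponent: float) -> np.ndarray:
    """Null ES distribution from random gene sets of a fixed size.

    Exploits the piecewise shape of the running sum: it only rises at
    hits, so the extrema lie just after/before hit positions.
    """
    n = len(ranked)
    w = np.abs(ranked.scores) ** weight_exponent
    dm = 1.0 / (n - set_size)
    out = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=set_size, replace=False))
        wh = w[pos]
        total = wh.sum()
        cum = np.cumsum(wh / total) if total > 0 else (np.arange(set_size) + 1) / set_size
        misses_before = pos - np.arange(set_size)
        after = cum - misses_before * dm          # value just after each hit
        before = np.concatenate(([0.0], cum[:-1])) - misses_before * dm
        hi, lo = after.max(), min(before.min(), 0.0)
        out[i] = hi if hi >= -lo else lo
    return out


def permutation_nes(es: float, ranked: RankedList, set_size: int,
                    n_perm: int = 1000,
                    seed: int | np.random.Generator = 0,
                    weight_exponent: float = 1.0,
                    null: np.ndarray | None = None) -> tuple[float, float]:
    """Normalised enrichment score and nominal p from a random-gene-set
    permutation null.

    NES divides the observed ES by the mean |null ES| of matching sign;
    p is the fraction of same-sign null ES at least as extreme, floored
    at 1/(n_perm + 1). When no null value shares the sign, NES is NaN
    and p = 1/(n_perm + 1), logged.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if null is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        null = _null_es(ranked, set_size, n_perm, rng, weight_exponent)
    n_perm = len(null)
    same = null >= 0 if es >= 0 else null < 0
    m = int(same.sum())
    if m == 0:
        log.warning("no same-sign null ES values; p floored")
        return float("nan"), 1.0 / (n_perm + 1)
    nes = es / np.mean(np.abs(null[same]))
    p = max(float(np.sum(np.abs(null[same]) >= abs(es))) / m, 1.0 / (n_perm + 1))
    return float(nes), p


def run_preranked(ranked_lists: dict[str, RankedList],
                  gene_sets: dict[str, set],
                  n_perm: int = 1000,
                  seed: int = 0,
                  weight_exponent: float = 1.0) -> list[EnrichmentResult]:
    """Full preranked enrichment of every gene set in every ranked list.

    The permutation null is shared across sets of identical size within
    a list. FDR is BH across sets within each list; significance is
    p < 0.05 and FDR < 0.25.
    """
    results: list[EnrichmentResult] = []
    rng = np.random.default_rng(seed)
    for list_id, ranked in ranked_lists.items():
        per_list: list[tuple[str, float, float, float]] = []
        null_cache: dict[int, np.ndarray] = {}
        for set_id, members in gene_sets.items():
            mem = set(members)
            es, running = enrichment_score(ranked, mem, weight_exponent)
            if not np.isfinite(es):
                continue
            k = int(sum(g in mem for g in ranked.gene_ids))
            if k not in null_cache:
                null_cache[k] = _null_es(ranked, k, n_perm, rng, weight_exponent)
            nes, p = permutation_nes(es, ranked, k, n_perm, null=null_cache[k],
                                     weight_exponent=weight_exponent)
            per_list.append((set_id, es, nes, p))
        if not per_list:
            continue
        qs = bh_adjust([r[3] for r in per_list])
        for (set_id, es, nes, p), q in zip(per_list, qs):
            sig = bool(p < P_SIGNIFICANT and q < FDR_SIGNIFICANT)
            results.append(EnrichmentResult(list_id, set_id, es, nes, p, float(q), sig))
    return results


def assemble_nes_matrix(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Set × list NES matrix for heat-map display.

    A set appears iff it is significant in at least one list; where it
    is not significant, its NES is replaced by 0.
    """
    if not results:
        return pd.DataFrame()
    lists = list(dict.fromkeys(r.list_id for r in results))
    keep_sets = list(dict.fromkeys(r.set_id for r in results if r.significant))
    mat = pd.DataFrame(0.0, index=keep_sets, columns=lists)
    for r in results:
        if r.set_id in mat.index and r.significant:
            mat.at[r.set_id, r.list_id] = r.nes
    return mat


@dataclass
class PWM:
    """Position weight matrix as per-position log2-odds weights over
    A, C, G, T against a background base composition."""

    weights: np.ndarray                 # shape (4, width), rows A,C,G,T
    background: np.ndarray = None
    name: str = "pwm"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != 4:
            raise ValueError("weights must have 4 rows (A, C, G, T)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def from_counts(cls, counts: np.ndarray, background=None,
                    pseudocount: float = 0.5, name: str = "pwm") -> "PWM":
        """Log-odds weights from a 4 × width base-count matrix with a
        pseudocount."""
        counts = np.asarray(counts, dtype=float)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        freqs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
        return cls(np.log2(freqs / bg[:, None]), bg, name=name)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.weights.argmax(axis=0))

    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to base indices; non-ACGT positions get −1."""
    return np.array([_BASE_INDEX.get(c, -1) for c in seq.upper()], dtype=int)


def _scan_one_strand(idx: np.ndarray, pwm: PWM) -> float:
    w = pwm.width
    n = len(idx)
    if n < w:
        return -np.inf
    # pad unknown bases with a neutral 0 contribution
    padded = np.vstack([pwm.weights, np.zeros(pwm.width)])
    safe = np.where(idx >= 0, idx, 4)
    windows = np.lib.stride_tricks.sliding_window_view(safe, w)
    scores = padded[windows, np.arange(w)].sum(axis=1)
    return float(scores.max())


def pwm_best_score(sequence: str, pwm: PWM) -> float:
    """Maximum log-odds score over every position on both strands.
    NaN when the sequence is shorter than the motif."""
    if len(sequence) < pwm.width:
        log.warning("sequence shorter than motif width; no score")
        return float("nan")
    fwd = _scan_one_strand(_encode(sequence), pwm)
    rc = sequence.upper().translate(_COMPLEMENT)[::-1]
    rev = _scan_one_strand(_encode(rc), pwm)
    return max(fwd, rev)


def motif_overrepresentation(foreground: dict[str, str] | list[str],
                             background: dict[str, str] | list[str],
                             pwm: PWM) -> tuple[float, float]:
    """One-sided z-test for the PWM's best-hit scores being higher in
    foreground promoters than in the background universe.

    z = (mean_fg − mean_bg) / (SD_bg / sqrt(n_fg)); p is the upper
    normal tail.
    """
    fg = list(foreground.values()) if isinstance(foreground, dict) else list(foreground)
    bg = list(background.values()) if isinstance(background, dict) else list(background)
    if len(fg) < 5:
        raise ValueError("need at least 5 foreground promoters")
    fg_scores = np.array([pwm_best_score(s, pwm) for s in fg])
    bg_scores = np.array([pwm_best_score(s, pwm) for s in bg])
    fg_scores = fg_scores[np.isfinite(fg_scores)]
    bg_scores = bg_scores[np.isfinite(bg_scores)]
    sd = bg_scores.std(ddof=1)
    if sd == 0:
        raise ValueError("background best-hit scores have zero variance")
    z = (fg_scores.mean() - bg_scores.mean()) / (sd / np.sqrt(len(fg_scores)))
    return float(z), float(stats.norm.sf(z))
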