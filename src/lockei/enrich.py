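"""Length-matched random-interval permutation tests for feature enrichment.

The observed statistic (fraction of query intervals overlapping a feature
set, or fraction of query bp covered by it) is compared against a null
distribution built by repeatedly sampling random interval sets whose number
and multiset of lengths exactly match the query. Each random interval is
placed uniformly at random wholly inside a universe segment, with segments
weighted by their number of valid start positions for that interval's
length, so placement is uniform over all admissible positions. By default
sampled intervals are kept pairwise disjoint (the query sets are disjoint),
via rejection sampling with a per-interval attempt cap.

Empirical p-values use the add-one estimator p = (1 + #{null >= obs}) /
(n_permutations + 1), so p is never exactly zero; with 1,000 permutations
the smallest reportable p is 1/1001, i.e. "< 10^-3". Fold enrichment is
observed / null mean. Bonferroni correction multiplies p by the family size
and clamps at 1.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .intervals import IntervalSet, merge_intervals

__all__ = ["EnrichParams", "EnrichmentResult", "sample_matched",
           "permutation_enrichment", "bonferroni", "domain_base_overlap_test"]

INTERVAL_OVERLAP = "interval-overlap"
BASE_OVERLAP = "base-overlap"


@dataclass(frozen=True)
class EnrichParams:
    n_permutations: int = 1_000
    universe: str = "whole-genome"  # label recorded in results
    statistic: str = INTERVAL_OVERLAP
    seed: int = 0
    allow_overlap_in_null: bool = False
    max_attempts_per_interval: int = 1_000

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.statistic not in (INTERVAL_OVERLAP, BASE_OVERLAP):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass
class EnrichmentResult:
    feature: str
    observed: float
    null_mean: float
    null_sd: float
    fold: float
    p_raw: float
    p_bonferroni: float | None
    n_permutations: int
    seed: int
    universe: str = ""
    statistic: str = INTERVAL_OVERLAP

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "observed_pct": 100 * self.observed,
            "null_mean_pct": 100 * self.null_mean,
            "fold": self.fold,
            "p_raw": self.p_raw,
            "p_bonferroni": self.p_bonferroni,
            "n_permutations": self.n_permutations,
            "universe": self.universe,
            "statistic": self.statistic,
        }


# ---------------------------------------------------------------------------
# Sampling


class _Universe:
    """Merged universe segments flattened for fast weighted placement."""

    def __init__(self, universe: IntervalSet):
        merged = merge_intervals(universe)
        self.chroms = merged.df["chrom"].to_numpy()
        self.starts = merged.df["start"].to_numpy()
        self.ends = merged.df["end"].to_numpy()
        self.seg_lens = self.ends - self.starts
        if len(self.seg_lens) == 0:
            raise ValueError("empty universe")
        self.max_seg = int(self.seg_lens.max())
        self._cum_cache: dict[int, tuple[np.ndarray, int]] = {}

    def _valid_cum(self, length: int) -> tuple[np.ndarray, int]:
        cached = self._cum_cache.get(length)
        if cached is None:
            valid = np.clip(self.seg_lens - length + 1, 0, None)
            cum = np.cumsum(valid)
            cached = (cum, int(cum[-1]))
            self._cum_cache[length] = cached
        return cached

    def place(self, length: int, rng: np.random.Generator) -> tuple[int, int]:
        """One uniform placement; returns (segment index, start position)."""
        cum, total = self._valid_cum(length)
        if total <= 0:
            raise ValueError(
                f"interval of length {length} exceeds every universe segment "
                f"(max {self.max_seg} bp)")
        pos = int(rng.integers(total))
        seg = int(np.searchsorted(cum, pos, side="right"))
        offset = pos - (int(cum[seg - 1]) if seg else 0)
        return seg, int(self.starts[seg]) + offset


def _sample_matched_arrays(lengths: np.ndarray, uni: _Universe,
                           rng: np.random.Generator, allow_overlap: bool,
                           max_attempts: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sample length-matched intervals; returns chrom -> (starts, ends)."""
    placed: dict[str, list[tuple[int, int]]] = {}
    out_chrom, out_start, out_len = [], [], []
    for L in lengths:
        L = int(L)
        for _ in range(max_attempts):
            seg, start = uni.place(L, rng)
            chrom = uni.chroms[seg]
            if not allow_overlap:
                lst = placed.setdefault(chrom, [])
                i = bisect_left(lst, (start + L, -1))
                # neighbors around insertion point; overlap iff prev end > start
                if i < len(lst) and lst[i][0] < start + L:
                    continue
                if i > 0 and lst[i - 1][1] > start:
                    continue
                insort(lst, (start, start + L))
            out_chrom.append(chrom)
            out_start.append(start)
            out_len.append(L)
            break
        else:
            raise ValueError(
                "could not place a disjoint random interval after "
                f"{max_attempts} attempts; consider allow_overlap_in_null=True")
    result: dict[str, list[tuple[int, int]]] = {}
    for c, s, L in zip(out_chrom, out_start, out_len):
        result.setdefault(c, []).append((s, s + L))
    return {c: (np.array([p[0] for p in sorted(v)], dtype=np.int64),
                np.array([p[1] for p in sorted(v)], dtype=np.int64))
            for c, v in result.items()}


def sample_matched(query, universe: IntervalSet,
                   rng: np.random.Generator, *,
                   allow_overlap: bool = False,
                   max_attempts: int = 1_000) -> IntervalSet:
    """Random interval set with exactly the query's number and lengths."""
    q = _as_interval_set(query)
    if len(q) == 0:
        raise ValueError("sample_matched: empty query")
    uni = _Universe(universe)
    arrays = _sample_matched_arrays(q.lengths, uni, rng,
                                    allow_overlap, max_attempts)
    rows = [(c, int(s), int(e))
            for c, (ss, ee) in arrays.items() for s, e in zip(ss, ee)]
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                       name="matched-random")


# ---------------------------------------------------------------------------
# Statistics on raw arrays (hot path: no pandas inside the permutation loop)


class _FeatureIndex:
    def __init__(self, features: IntervalSet):
        merged = merge_intervals(features) if len(features) else features
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in merged.chroms():
            fs, fe = merged.arrays(chrom)
            cum = np.concatenate([[0], np.cumsum(fe - fs)])
            self.by_chrom[chrom] = (fs, fe, cum)

    def n_hits(self, chrom: str, qs: np.ndarray, qe: np.ndarray) -> int:
        if chrom not in self.by_chrom or len(qs) == 0:
            return 0
        fs, fe, _ = self.by_chrom[chrom]
        idx = np.searchsorted(fs, qe, side="left") - 1
        hit = idx >= 0
        hit[hit] = fe[idx[hit]] > qs[hit]
        return int(hit.sum())

    def covered_bp(self, chrom: str, qs: np.ndarray, qe: np.ndarray) -> int:
        if chrom not in self.by_chrom or len(qs) == 0:
            return 0
        fs, fe, cum = self.by_chrom[chrom]
        lo = np.searchsorted(fe, qs, side="right")
        hi = np.searchsorted(fs, qe, side="left")
        m = hi > lo
        if not m.any():
            return 0
        lo, hi = lo[m], hi[m]
        cov = cum[hi] - cum[lo]
        cov = cov - np.maximum(0, qs[m] - fs[lo])
        cov = cov - np.maximum(0, fe[hi - 1] - qe[m])
        return int(cov.sum())


def _statistic(arrays: dict[str, tuple[np.ndarray, np.ndarray]],
               fidx: _FeatureIndex, statistic: str) -> float:
    n = hits = covered = total = 0
    for chrom, (qs, qe) in arrays.items():
        n += len(qs)
        if statistic == INTERVAL_OVERLAP:
            hits += fidx.n_hits(chrom, qs, qe)
        else:
            covered += fidx.covered_bp(chrom, qs, qe)
            total += int((qe - qs).sum())
    if statistic == INTERVAL_OVERLAP:
        return hits / n
    return covered / total


def _as_interval_set(query) -> IntervalSet:
    if isinstance(query, IntervalSet):
        return query
    return query.intervals  # EISet / DomainSet


# ---------------------------------------------------------------------------
# Permutation test


def permutation_enrichment(query, features: IntervalSet, universe: IntervalSet,
                           params: EnrichParams = EnrichParams(),
                           ) -> EnrichmentResult:
    """Length-matched permutation test of query-vs-feature overlap.

    ``query`` may be an EISet/DomainSet or a bare IntervalSet; ``universe``
    is the interval set within which random intervals are placed (e.g. the
    probe-covered genome, or the LOCKs themselves for the within-LOCK null).
    One-sided, upper tail (enrichment).
    """
    q = _as_interval_set(query)
    if len(q) == 0:
        raise ValueError("permutation_enrichment: empty query")
    rng = np.random.default_rng(params.seed)
    uni = _Universe(universe)
    fidx = _FeatureIndex(features)
    lengths = q.lengths

    q_arrays = {c: q.arrays(c) for c in q.chroms()}
    observed = _statistic(q_arrays, fidx, params.statistic)

    null = np.empty(params.n_permutations)
    for i in range(params.n_permutations):
        arrays = _sample_matched_arrays(
            lengths, uni, rng, params.allow_overlap_in_null,
            params.max_attempts_per_interval)
        null[i] = _statistic(arrays, fidx, params.statistic)

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if len(null) > 1 else 0.0
    if null_mean == 0.0:
        fold = 1.0 if observed == 0.0 else float("inf")
    else:
        fold = observed / null_mean
    p_raw = (1 + int((null >= observed).sum())) / (params.n_permutations + 1)
    if null_mean == 0.0 and observed > 0.0:
        p_raw = 1 / (params.n_permutations + 1)
    return EnrichmentResult(
        feature=features.name, observed=observed, null_mean=null_mean,
        null_sd=null_sd, fold=fold, p_raw=p_raw, p_bonferroni=None,
        n_permutations=params.n_permutations, seed=params.seed,
        universe=params.universe, statistic=params.statistic)


def bonferroni(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Bonferroni-correct one family of results; order preserved."""
    m = len(results)
    return [replace(r, p_bonferroni=min(1.0, r.p_raw * m)) for r in results]


def domain_base_overlap_test(locks, blocks: IntervalSet,
                             universe: IntervalSet,
                             params: EnrichParams = EnrichParams(),
                             ) -> EnrichmentResult:
    """Base-level overlap of LOCKs with large blocks (e.g. PMDs), with a
    length-matched whole-genome null."""
    params = replace(params, statistic=BASE_OVERLAP)
    return permutation_enrichment(locks, blocks, universe, params)


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
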