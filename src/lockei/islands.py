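"""Euchromatin-island (EI) detection inside LOCK bodies.

EIs are short (~1-10 kb) regions within a LOCK whose smoothed H3K9me2
signal falls below the low tail (default bottom 1%) of the smoothed-value
distribution. The algorithm, in order:

1. restrict the track to probes lying inside LOCKs;
2. smooth those probes with a 5 kb window, per LOCK (the smoothing window
   never crosses a LOCK boundary, so values outside the LOCK cannot leak in);
3. set the threshold t at the ``low_percentile`` quantile of the smoothed
   values in the chosen universe (within-LOCK probes by default);
4. take maximal runs of consecutive probes with smoothed value strictly
   below t;
5. merge runs whose genomic gap is < ``merge_gap_bp``;
6. drop merged runs shorter than ``min_length_bp`` or with fewer than
   ``min_probes`` probes;
7. drop runs whose nearest edge lies within ``boundary_margin_bp`` of the
   parent LOCK's edge — log-ratios decay at LOCK boundaries, and without
   this margin boundary decay would masquerade as islands.

EI coordinates span from the first to the last probe of the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet, ProbeTrack, interval_overlap_fraction
from .locks import DomainSet, _merge_runs, _runs_above, smooth

__all__ = ["EIParams", "EISet", "detect_eis", "ei_summary", "ei_concordance"]

WITHIN_LOCK = "within-LOCK probes"
ALL_PROBES = "all probes"


@dataclass(frozen=True)
class EIParams:
    window_bp: int = 5_000
    low_percentile: float = 0.01
    min_length_bp: int = 1_000
    min_probes: int = 10
    merge_gap_bp: int = 1_000
    boundary_margin_bp: int = 20_000
    percentile_universe: str = WITHIN_LOCK

    def __post_init__(self) -> None:
        if not (0.0 < self.low_percentile < 0.5):
            raise ValueError("low_percentile must be in (0, 0.5)")
        if min(self.window_bp, self.min_length_bp, self.min_probes,
               self.merge_gap_bp, self.boundary_margin_bp) <= 0:
            raise ValueError("all EI parameters must be positive")
        if self.percentile_universe not in (WITHIN_LOCK, ALL_PROBES):
            raise ValueError(f"unknown percentile_universe "
                             f"{self.percentile_universe!r}")


@dataclass
class EISet:
    """Detected euchromatin islands with per-EI stats and provenance.

    ``intervals.df`` columns: chrom, start, end, name (parent LOCK id),
    n_probes, min_smoothed, length_bp.
    """

    intervals: IntervalSet
    params: EIParams | None = None
    threshold: float | None = None
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def df(self) -> pd.DataFrame:
        return self.intervals.df


_EMPTY_EI_COLUMNS = {
    "chrom": str, "start": np.int64, "end": np.int64, "name": str,
    "n_probes": np.int64, "min_smoothed": float, "length_bp": np.int64,
}


def _empty_ei_frame() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t)
                         for c, t in _EMPTY_EI_COLUMNS.items()})


def _lock_probe_slices(track: ProbeTrack, locks: DomainSet):
    """Yield (lock row, chrom, index slice) of probes inside each LOCK."""
    for lock in locks.df.itertuples(index=False):
        if lock.chrom not in track.probes:
            raise ValueError(f"LOCK on {lock.chrom} but track has no probes "
                             "there (grid mismatch)")
        a = track.probes[lock.chrom]
        i0 = int(np.searchsorted(a["start"], lock.start, side="left"))
        i1 = int(np.searchsorted(a["end"], lock.end, side="right"))
        yield lock, lock.chrom, slice(i0, i1)


def detect_eis(track: ProbeTrack, locks: DomainSet,
               params: EIParams = EIParams()) -> EISet:
    """Detect EIs in a (normalized) track given called LOCKs."""
    if len(locks) == 0:
        return EISet(IntervalSet(_empty_ei_frame(), name="EIs"),
                     params=params, threshold=None)

    per_lock = []  # (lock, chrom, starts, ends, smoothed values)
    for lock, chrom, sl in _lock_probe_slices(track, locks):
        a = track.probes[chrom]
        sub = ProbeTrack({chrom: {"start": a["start"][sl],
                                  "end": a["end"][sl],
                                  "value": a["value"][sl]}},
                         median_spacing_bp=track.median_spacing_bp)
        if sub.n_probes == 0:
            continue
        sm = smooth(sub, params.window_bp).probes[chrom]
        per_lock.append((lock, chrom, sm["start"], sm["end"], sm["value"]))

    if not per_lock:
        return EISet(IntervalSet(_empty_ei_frame(), name="EIs"),
                     params=params, threshold=None)

    if params.percentile_universe == WITHIN_LOCK:
        universe = np.concatenate([v for *_, v in per_lock])
    else:
        universe = smooth(track, params.window_bp).values_pooled()
    t = float(np.quantile(universe, params.low_percentile))

    rows = []
    for lock, chrom, starts, ends, values in per_lock:
        runs = _runs_above(values < t)
        runs = _merge_runs(runs, starts, ends, params.merge_gap_bp, strict=True)
        for i0, i1 in runs:
            start, end = int(starts[i0]), int(ends[i1])
            if end - start < params.min_length_bp:
                continue
            if i1 - i0 + 1 < params.min_probes:
                continue
            if (start - lock.start < params.boundary_margin_bp
                    or lock.end - end < params.boundary_margin_bp):
                continue
            rows.append({
                "chrom": chrom,
                "start": start,
                "end": end,
                "name": lock.name,
                "n_probes": int(i1 - i0 + 1),
                "min_smoothed": float(values[i0:i1 + 1].min()),
                "length_bp": end - start,
            })
    df = pd.DataFrame(rows) if rows else _empty_ei_frame()
    return EISet(IntervalSet(df, name="EIs"), params=params, threshold=t)


def ei_summary(eis: EISet) -> dict:
    """Count, mean size and per-LOCK counts of an EISet."""
    if len(eis) == 0:
        return {"count": 0, "mean_size_bp": float("nan"), "per_lock": {}}
    sizes = eis.intervals.lengths
    per_lock = eis.df["name"].value_counts().to_dict()
    return {
        "count": int(len(sizes)),
        "mean_size_bp": float(sizes.mean()),
        "per_lock": {str(k): int(v) for k, v in per_lock.items()},
    }


def ei_concordance(a: EISet, b: EISet) -> float:
    """Fraction of a's EIs overlapping (>= 1 bp) any EI of b."""
    if len(a) == 0:
        raise ValueError("ei_concordance: empty first set")
    return interval_overlap_fraction(a.intervals, b.intervals)
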