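"""Core coordinate model: genome layout, interval sets, probe tracks, overlap
primitives, and BED / bedGraph-style readers and writers.

All coordinates are 0-based half-open (BED convention), both in memory and
on disk. ``IntervalSet`` stores intervals sorted by (chrom, start); overlap
statistics are computed against the *merged* feature set so that split or
duplicated feature intervals never double-count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "Interval",
    "IntervalSet",
    "ProbeTrack",
    "read_probe_track",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "merge_intervals",
    "interval_overlap_fraction",
    "base_overlap_fraction",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths defining the coordinate frame."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))

    def as_interval_set(self, name: str = "genome") -> "IntervalSet":
        """Whole chromosome spans as an IntervalSet (the raw-span universe)."""
        df = pd.DataFrame(
            {
                "chrom": list(self.chrom_names),
                "start": 0,
                "end": list(self.chrom_lengths),
            }
        )
        return IntervalSet(df, name=name)


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A named, sorted collection of genomic intervals.

    Backed by a pandas DataFrame with at least columns ``chrom``, ``start``,
    ``end`` (int); extra columns (name, score, per-interval metadata) ride
    along. Sorting by (chrom, start, end) is enforced on construction.
    """

    def __init__(self, df: pd.DataFrame | None = None, name: str = "", *,
                 layout: GenomeLayout | None = None):
        if df is None:
            df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                               "start": pd.Series(dtype=np.int64),
                               "end": pd.Series(dtype=np.int64)})
        df = df.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"IntervalSet frame missing column {col!r}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            bad = df[(df["start"] < 0) | (df["start"] >= df["end"])].iloc[0]
            raise ValueError(
                f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}")
        if layout is not None:
            lens = layout.lengths
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in lens:
                    raise ValueError(f"chromosome {chrom!r} not in layout")
                if (sub["end"] > lens[chrom]).any():
                    raise ValueError(f"interval beyond end of {chrom}")
        self.df = df.sort_values(["chrom", "start", "end"],
                                 kind="mergesort").reset_index(drop=True)
        self.name = name

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield Interval(row.chrom, int(row.start), int(row.end))

    @property
    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["end"].to_numpy()

    def is_disjoint(self) -> bool:
        for chrom in self.chroms():
            starts, ends = self.arrays(chrom)
            if np.any(starts[1:] < ends[:-1]):
                return False
        return True

    def merged(self, name: str | None = None) -> "IntervalSet":
        return merge_intervals(self, name=name or self.name)

    @classmethod
    def from_intervals(cls, intervals, name: str = "") -> "IntervalSet":
        df = pd.DataFrame(
            [(iv.chrom, iv.start, iv.end) for iv in intervals],
            columns=["chrom", "start", "end"],
        )
        return cls(df, name=name)


@dataclass
class ProbeTrack:
    """Per-chromosome probe intervals with one log2(ChIP/Input) value each.

    ``probes`` maps chromosome name to a dict of numpy arrays with keys
    ``start``, ``end``, ``value``, sorted by start. ``median_spacing_bp``
    records the array design's probe spacing for validation/reporting.
    """

    probes: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    median_spacing_bp: float | None = None

    def __post_init__(self) -> None:
        for chrom, arr in self.probes.items():
            if not np.all(np.diff(arr["start"]) >= 0):
                raise ValueError(f"probes on {chrom} not sorted by start")
            if not np.all(np.isfinite(arr["value"])):
                raise ValueError(f"non-finite probe value on {chrom}")

    def chroms(self) -> list[str]:
        return list(self.probes)

    @property
    def n_probes(self) -> int:
        return sum(len(a["start"]) for a in self.probes.values())

    def values_pooled(self) -> np.ndarray:
        if not self.probes:
            return np.empty(0)
        return np.concatenate([a["value"] for a in self.probes.values()])

    def midpoints(self, chrom: str) -> np.ndarray:
        a = self.probes[chrom]
        return (a["start"] + a["end"]) / 2.0

    def with_values(self, new_values: dict[str, np.ndarray]) -> "ProbeTrack":
        """Same probe grid, replacement values (e.g. after normalization)."""
        probes = {}
        for chrom, a in self.probes.items():
            probes[chrom] = {
                "start": a["start"],
                "end": a["end"],
                "value": np.asarray(new_values[chrom], dtype=float),
            }
        return ProbeTrack(probes, median_spacing_bp=self.median_spacing_bp)

    def covered_intervals(self, name: str = "probe-covered") -> IntervalSet:
        """Union of probe footprints, gaps <= 10x median spacing bridged.

        This is the default permutation universe: random intervals should
        only be placed where the array could in principle have called an EI.
        """
        gap = 10 * (self.median_spacing_bp or 200)
        rows = []
        for chrom, a in self.probes.items():
            if len(a["start"]) == 0:
                continue
            start = int(a["start"][0])
            end = int(a["end"][0])
            for s, e in zip(a["start"][1:], a["end"][1:]):
                if s - end <= gap:
                    end = max(end, int(e))
                else:
                    rows.append((chrom, start, end))
                    start, end = int(s), int(e)
            rows.append((chrom, start, end))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return IntervalSet(df, name=name)


# ---------------------------------------------------------------------------
# Readers / writers


class BedParseError(ValueError):
    pass


def _parse_coord_table(path, n_value_cols: int):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3 + n_value_cols:
                raise BedParseError(f"{path}: line {lineno}: expected >= "
                                    f"{3 + n_value_cols} columns, got {len(parts)}")
            try:
                chrom = parts[0]
                start = int(parts[1])
                end = int(parts[2])
                extra = [float(parts[3 + i]) for i in range(n_value_cols)]
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from None
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval "
                    f"{chrom}:{start}-{end} (need 0 <= start < end)")
            rows.append((chrom, start, end, *extra, lineno))
    return rows


def read_probe_track(path, layout: GenomeLayout,
                     median_spacing_bp: float | None = None) -> ProbeTrack:
    """Read a 4-column bedGraph-like TSV (chrom, start, end, value)."""
    rows = _parse_coord_table(path, n_value_cols=1)
    lens = layout.lengths
    probes: dict[str, dict[str, list]] = {}
    for chrom, start, end, value, lineno in rows:
        if chrom not in lens:
            raise BedParseError(
                f"{path}: line {lineno}: chromosome {chrom!r} not in layout")
        if end > lens[chrom]:
            raise BedParseError(
                f"{path}: line {lineno}: probe beyond end of {chrom}")
        d = probes.setdefault(chrom, {"start": [], "end": [], "value": []})
        d["start"].append(start)
        d["end"].append(end)
        d["value"].append(value)
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom in layout.chrom_names:
        if chrom not in probes:
            continue
        d = probes[chrom]
        starts = np.asarray(d["start"], dtype=np.int64)
        order = np.argsort(starts, kind="mergesort")
        out[chrom] = {
            "start": starts[order],
            "end": np.asarray(d["end"], dtype=np.int64)[order],
            "value": np.asarray(d["value"], dtype=float)[order],
        }
    return ProbeTrack(out, median_spacing_bp=median_spacing_bp)


def write_probe_track(track: ProbeTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            a = track.probes[chrom]
            for s, e, v in zip(a["start"], a["end"], a["value"]):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bed(path, name: str = "", layout: GenomeLayout | None = None) -> IntervalSet:
    """Read BED3+ (0-based half-open; extra columns kept as name/score)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from None
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval "
                    f"{parts[0]}:{start}-{end}")
            rec = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) > 3:
                rec["name"] = parts[3]
            if len(parts) > 4:
                rec["score"] = parts[4]
            if len(parts) > 5:
                rec["strand"] = parts[5]
            rows.append(rec)
    df = pd.DataFrame(rows) if rows else None
    return IntervalSet(df, name=name or str(path), layout=layout)


def write_bed(iv_set: IntervalSet, path) -> None:
    cols = ["chrom", "start", "end"]
    for extra in ("name", "score", "strand"):
        if extra in iv_set.df.columns:
            cols.append(extra)
        else:
            break
    iv_set.df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeLayout(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))


# ---------------------------------------------------------------------------
# Overlap primitives


def merge_intervals(iv_set: IntervalSet, name: str | None = None) -> IntervalSet:
    """Union of intervals: overlapping or book-ended intervals coalesce."""
    rows = []
    for chrom in iv_set.chroms():
        starts, ends = iv_set.arrays(chrom)
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"]) if rows else None
    return IntervalSet(df, name=name if name is not None else iv_set.name)


def _overlap_flags(q_starts: np.ndarray, q_ends: np.ndarray,
                   f_starts: np.ndarray, f_ends: np.ndarray) -> np.ndarray:
    """Boolean per query interval: shares >= 1 bp with a merged feature.

    Features must be disjoint and sorted. A query [s, e) hits a feature
    [fs, fe) iff fs < e and fe > s; with disjoint sorted features the only
    candidate is the last feature with fs < e.
    """
    if len(f_starts) == 0 or len(q_starts) == 0:
        return np.zeros(len(q_starts), dtype=bool)
    idx = np.searchsorted(f_starts, q_ends, side="left") - 1
    hit = idx >= 0
    hit[hit] = f_ends[idx[hit]] > q_starts[hit]
    return hit


def interval_overlap_fraction(query: IntervalSet, features: IntervalSet) -> float:
    """Fraction of query intervals sharing >= 1 bp with any feature."""
    if len(query) == 0:
        raise ValueError("interval_overlap_fraction: empty query set")
    features = merge_intervals(features) if len(features) else features
    n_hit = 0
    for chrom in query.chroms():
        qs, qe = query.arrays(chrom)
        fs, fe = features.arrays(chrom)
        n_hit += int(_overlap_flags(qs, qe, fs, fe).sum())
    return n_hit / len(query)


def base_overlap_fraction(query: IntervalSet, features: IntervalSet) -> float:
    """Fraction of query bp covered by the union of the features."""
    if len(query) == 0:
        raise ValueError("base_overlap_fraction: empty query set")
    features = merge_intervals(features) if len(features) else features
    covered = 0
    for chrom in query.chroms():
        qs, qe = query.arrays(chrom)
        fs, fe = features.arrays(chrom)
        if len(fs) == 0:
            continue
        # cumulative feature bp up to each feature end
        cum = np.concatenate([[0], np.cumsum(fe - fs)])
        for s, e in zip(qs, qe):
            lo = np.searchsorted(fe, s, side="right")
            hi = np.searchsorted(fs, e, side="left")
            if hi <= lo:
                continue
            total = cum[hi] - cum[lo]
            total -= max(0, s - fs[lo])
            total -= max(0, fe[hi - 1] - e)
            covered += total
    return covered / query.total_bp
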