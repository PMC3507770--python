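"""Synthetic tiling-array data with planted LOCKs, EIs and feature sets.

The generator emulates a NimbleGen-style whole-genome tiling design: a
probe grid at configurable spacing (default 200 bp, jittered +-25 bp to
avoid aliasing against the smoothing windows) carrying Gaussian
log2(ChIP/Input) ratios. Large blocks with an elevated mean are planted as
LOCKs (log-normal lengths, placed disjoint until a target genome coverage
is reached); short rectangular dips of configurable depth are planted
inside LOCK bodies as EIs, kept away from LOCK edges. Feature intervals can
be placed inside planted EIs at a configurable per-EI probability against a
uniform background density, giving a designed, closed-form-computable
enrichment for validating the permutation machinery.

Everything is reproducible from the spec's seed, and the returned
``SyntheticTruth`` carries all planted coordinates so every downstream
statistic has a known expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .intervals import GenomeLayout, IntervalSet, ProbeTrack

__all__ = ["LockSpec", "EISpec", "FeatureSpec", "SimSpec", "SyntheticTruth",
           "simulate_track", "simulate_features", "default_demo_spec",
           "expected_fold", "tune_p_in_ei_for_fold"]


@dataclass(frozen=True)
class LockSpec:
    """Planted heterochromatin blocks: target genome coverage, mean shift
    (in units of noise SD) and a log-normal length distribution.

    The default block length (median 2 Mb) sits at the top of the
    10^2-10^3 kb domain scale. Together with the ~3 dips per block of the
    EI spec it keeps planted-dip mass near 1% of block mass, matching the
    real abundance of euchromatin islands (thousands of ~5 kb islands
    against >1 Gb of domains); a bottom-percentile detector can only ever
    flag about that share of the within-domain signal, so a benchmark that
    plants much more ceases to describe the method's regime.
    """

    coverage: float = 0.40
    shift_sd: float = 1.5
    median_length_bp: float = 2_000_000.0
    sigma_log: float = 0.25
    min_length_bp: int = 500_000
    max_length_fraction: float = 0.45

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage < 1.0):
            raise ValueError("coverage must be in (0, 1)")


@dataclass(frozen=True)
class EISpec:
    """Planted dips inside LOCK bodies (counts Poisson per LOCK, lengths
    uniform, rectangular depth in noise-SD units, kept off the edges)."""

    dips_per_lock: float = 3.0
    min_length_bp: int = 3_000
    max_length_bp: int = 8_000
    depth_sd: float = 2.5
    min_edge_distance_bp: int = 30_000
    min_separation_bp: int = 5_000
    tapered: bool = False
    taper_bp: int = 500


@dataclass(frozen=True)
class FeatureSpec:
    """Feature placement: one centered feature per planted EI with
    probability p_in_ei, plus uniform background at a per-Mb density."""

    p_in_ei: float = 0.5
    background_per_mb: float = 5.0
    feature_length_bp: int = 500


@dataclass(frozen=True)
class SimSpec:
    n_chromosomes: int = 2
    chrom_length_bp: int = 10_000_000
    probe_spacing_bp: int = 200
    probe_length_bp: int = 50
    jitter_bp: int = 25
    background_mean: float = 0.0
    noise_sd: float = 1.0
    lock_spec: LockSpec = field(default_factory=LockSpec)
    ei_spec: EISpec = field(default_factory=EISpec)
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    seed: int = 0

    def layout(self) -> GenomeLayout:
        names = tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))
        return GenomeLayout(names, (self.chrom_length_bp,) * self.n_chromosomes)


@dataclass
class SyntheticTruth:
    locks: IntervalSet
    eis: IntervalSet          # columns include parent, depth_sd
    features: IntervalSet | None
    spec: SimSpec

    def as_dict(self) -> dict:
        return {"spec": asdict(self.spec),
                "n_locks": len(self.locks), "n_eis": len(self.eis)}


def default_demo_spec(seed: int = 0) -> SimSpec:
    """The default demo conditions: 2 x 10 Mb chromosomes, 40% LOCK
    coverage with a 1.5-SD shift, ~3 dips per LOCK of depth 2.5 SD and
    length 3-8 kb planted >= 25 kb from LOCK edges."""
    return SimSpec(seed=seed)


def _plant_locks(spec: SimSpec, chrom_len: int,
                 rng: np.random.Generator) -> list[tuple[int, int]]:
    """Disjoint blocks until target coverage; rejection placement.

    Blocks keep >= 50 kb of clearance from each other so independently
    planted LOCKs stay distinct after downstream gap-merging; the last
    block is trimmed to land within ~1% of the coverage target.
    """
    ls = spec.lock_spec
    target_bp = ls.coverage * chrom_len
    mu = np.log(ls.median_length_bp)
    max_len = ls.max_length_fraction * chrom_len
    placed: list[tuple[int, int]] = []
    covered = 0
    attempts = 0
    sep = 50_000
    while target_bp - covered > 0.01 * target_bp:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("LOCK coverage target unreachable; "
                             "lower coverage or shorten blocks")
        remaining = target_bp - covered
        length = int(rng.lognormal(mu, ls.sigma_log))
        length = int(np.clip(length, ls.min_length_bp, max_len))
        if length > remaining:
            length = max(100_000, int(remaining))
        start = int(rng.integers(0, chrom_len - length))
        end = start + length
        if any(start - sep < e and end + sep > s for s, e in placed):
            continue
        placed.append((start, end))
        covered += length
    return sorted(placed)


def _plant_eis(spec: SimSpec, lock: tuple[int, int],
               rng: np.random.Generator) -> list[tuple[int, int]]:
    es = spec.ei_spec
    s, e = lock
    usable_lo = s + es.min_edge_distance_bp
    usable_hi = e - es.min_edge_distance_bp
    if usable_hi - usable_lo < es.max_length_bp:
        return []
    n = int(rng.poisson(es.dips_per_lock))
    dips: list[tuple[int, int]] = []
    for _ in range(n):
        for _ in range(50):  # rejection against separation
            length = int(rng.integers(es.min_length_bp, es.max_length_bp + 1))
            if usable_hi - usable_lo - length <= 0:
                break
            start = int(rng.integers(usable_lo, usable_hi - length))
            end = start + length
            if all(start - es.min_separation_bp >= de
                   or end + es.min_separation_bp <= ds
                   for ds, de in dips):
                dips.append((start, end))
                break
    return sorted(dips)


def simulate_track(spec: SimSpec, noise_seed: int | None = None,
                   ) -> tuple[ProbeTrack, SyntheticTruth]:
    """Generate the probe track and its ground truth from a SimSpec.

    ``noise_seed`` redraws only the measurement noise while keeping the
    probe grid and all planted structure fixed — two calls with the same
    spec and different noise seeds emulate replicate hybridizations of the
    same underlying chromatin state.
    """
    rng = np.random.default_rng(spec.seed)
    noise_rng = (rng if noise_seed is None
                 else np.random.default_rng(noise_seed))
    layout = spec.layout()
    probes: dict[str, dict[str, np.ndarray]] = {}
    lock_rows, ei_rows = [], []

    for ci, chrom in enumerate(layout.chrom_names):
        chrom_len = layout.chrom_lengths[ci]
        grid = np.arange(spec.probe_spacing_bp // 2,
                         chrom_len - spec.probe_length_bp,
                         spec.probe_spacing_bp, dtype=np.int64)
        if spec.jitter_bp:
            grid = grid + rng.integers(-spec.jitter_bp, spec.jitter_bp + 1,
                                       size=len(grid))
            grid = np.clip(grid, 0, chrom_len - spec.probe_length_bp)
            grid.sort(kind="mergesort")
        starts = grid
        ends = grid + spec.probe_length_bp
        mids = (starts + ends) / 2.0

        mean = np.full(len(grid), spec.background_mean)
        locks = _plant_locks(spec, chrom_len, rng)
        shift = spec.lock_spec.shift_sd * spec.noise_sd
        for li, (ls_, le_) in enumerate(locks):
            in_lock = (mids >= ls_) & (mids < le_)
            mean[in_lock] += shift
            lock_rows.append({"chrom": chrom, "start": ls_, "end": le_,
                              "name": f"true_lock_{ci}_{li}"})
            for ds, de in _plant_eis(spec, (ls_, le_), rng):
                depth = spec.ei_spec.depth_sd * spec.noise_sd
                if spec.ei_spec.tapered:
                    taper = spec.ei_spec.taper_bp
                    core = (mids >= ds + taper) & (mids < de - taper)
                    left = (mids >= ds) & (mids < ds + taper)
                    right = (mids >= de - taper) & (mids < de)
                    mean[core] -= depth
                    mean[left] -= depth * (mids[left] - ds) / taper
                    mean[right] -= depth * (de - mids[right]) / taper
                else:
                    in_dip = (mids >= ds) & (mids < de)
                    mean[in_dip] -= depth
                ei_rows.append({"chrom": chrom, "start": ds, "end": de,
                                "parent": f"true_lock_{ci}_{li}",
                                "depth_sd": spec.ei_spec.depth_sd,
                                "length_bp": de - ds})
        values = mean + noise_rng.normal(0.0, spec.noise_sd, size=len(grid))
        probes[chrom] = {"start": starts, "end": ends, "value": values}

    track = ProbeTrack(probes, median_spacing_bp=spec.probe_spacing_bp)
    truth = SyntheticTruth(
        locks=IntervalSet(pd.DataFrame(lock_rows), name="true-LOCKs"),
        eis=IntervalSet(pd.DataFrame(ei_rows), name="true-EIs")
        if ei_rows else IntervalSet(name="true-EIs"),
        features=None,
        spec=spec,
    )
    return track, truth


def simulate_features(truth: SyntheticTruth, spec: SimSpec,
                      rng: np.random.Generator) -> tuple[IntervalSet, dict]:
    """Place features inside planted EIs (prob. p_in_ei, centered) plus a
    uniform background; returns the set and closed-form expectations.

    The returned dict carries the analytically expected observed overlap
    fraction and the expected null mean for an interval-overlap test of the
    planted EIs against this feature set, treating feature left-ends as a
    Poisson process: a query of length L is hit by background features of
    length f at rate d*(L+f).
    """
    fs = spec.feature_spec
    layout = spec.layout()
    rows = []
    f_len = fs.feature_length_bp
    n_in_ei = 0
    for ei in truth.eis.df.itertuples(index=False):
        if rng.random() < fs.p_in_ei:
            center = (ei.start + ei.end) // 2
            rows.append((ei.chrom, center - f_len // 2,
                         center - f_len // 2 + f_len, "ei-linked"))
            n_in_ei += 1
    for ci, chrom in enumerate(layout.chrom_names):
        chrom_len = layout.chrom_lengths[ci]
        n_bg = rng.poisson(fs.background_per_mb * chrom_len / 1e6)
        bg_starts = rng.integers(0, chrom_len - f_len, size=int(n_bg))
        for s in np.sort(bg_starts):
            rows.append((chrom, int(s), int(s) + f_len, "background"))
    features = IntervalSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]),
        name="synthetic-features")

    genome_bp = layout.total_bp
    mean_ei_len = (float(truth.eis.lengths.mean())
                   if len(truth.eis) else 0.0)
    bg_density = fs.background_per_mb / 1e6
    total_density = bg_density + n_in_ei / genome_bp
    p_bg_hit = 1.0 - np.exp(-bg_density * (mean_ei_len + f_len))
    expectations = {
        "expected_observed": fs.p_in_ei + (1 - fs.p_in_ei) * p_bg_hit,
        "expected_null_mean": 1.0 - np.exp(-total_density
                                           * (mean_ei_len + f_len)),
        "n_ei_linked": n_in_ei,
    }
    expectations["expected_fold"] = (
        expectations["expected_observed"] / expectations["expected_null_mean"]
        if expectations["expected_null_mean"] > 0 else float("inf"))
    return features, expectations


def expected_fold(p_in_ei: float, n_eis: int, mean_ei_len: float,
                  genome_bp: int, background_per_mb: float,
                  feature_length_bp: int) -> float:
    """Closed-form expected fold enrichment of planted EIs vs features.

    Feature left-ends are treated as a Poisson process: a query of length L
    is hit at rate density*(L+f). The null density includes both background
    features and the EI-linked features themselves; the observed fraction
    is p_in_ei plus the background hit probability on the rest.
    """
    d_bg = background_per_mb / 1e6
    reach = mean_ei_len + feature_length_bp
    p_bg = 1.0 - np.exp(-d_bg * reach)
    obs = p_in_ei + (1.0 - p_in_ei) * p_bg
    d_total = d_bg + p_in_ei * n_eis / genome_bp
    null = 1.0 - np.exp(-d_total * reach)
    return obs / null if null > 0 else float("inf")


def tune_p_in_ei_for_fold(truth: SyntheticTruth, spec: SimSpec,
                          target_fold: float) -> float:
    """Solve for the per-EI feature probability giving a target expected
    fold under the closed-form model; raises if unreachable."""
    from scipy.optimize import brentq

    fs = spec.feature_spec
    layout = spec.layout()
    n = len(truth.eis)
    L = float(truth.eis.lengths.mean())

    def gap(p):
        return expected_fold(p, n, L, layout.total_bp,
                             fs.background_per_mb,
                             fs.feature_length_bp) - target_fold

    return float(brentq(gap, 1e-6, 1.0 - 1e-6))
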