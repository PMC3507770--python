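# Methods

## The signal model

The substrate is a probe-level log2(ChIP/Input) track from a whole-genome
tiling array (~100–200 bp probe spacing) for H3K9me2, a histone mark that
organizes into very large enriched domains in differentiated mammalian
cells. Three structures matter:

* **LOCKs** (large organized chromatin K9-modification domains): contiguous
  regions, 10² to 10³ kb, where the log-ratio mean is shifted upward.
* **Euchromatin islands (EIs)**: short regions (~1–10 kb) *inside* a LOCK
  body where the smoothed signal drops into the extreme low tail —
  candidate regulatory elements (CTCF sites, DHSs, TSSs) embedded in
  heterochromatin.
* **Feature sets**: external interval annotations whose co-location with
  EIs is the scientific question, answered with length-matched permutation
  tests.

All coordinates are 0-based half-open (BED convention) throughout.

## Normalization

`partial_quantile_normalize` makes arrays comparable by mapping the lower
`lower_fraction` (default 0.75) of each track's value distribution onto a
reference quantile curve — the pointwise mean of the per-track empirical
quantile functions, or a designated reference track. Values above the
boundary are shifted by the transform's value at the largest mapped data
point, which keeps the mapping continuous and strictly monotone and makes
the transform exactly idempotent against a fixed reference. Ranks are
computed with average ties so tied values stay tied; interpolation between
order statistics is linear. With `lower_fraction = 1` the procedure is
standard full quantile normalization. The intent is that the non-enriched
background (the majority of probes) is aligned across arrays while the
enrichment tail keeps its between-array differences.

## LOCK calling

The track is smoothed by a windowed mean on probe midpoints
(`window_bp = 10 kb`; truncated windows at chromosome ends, no padding),
and maximal runs of probes with smoothed value ≥ a genome-wide threshold
`t` become candidate domains. Runs separated by ≤ `merge_gap_bp` are
merged, and merged runs shorter than `min_length_bp = 10 kb` are dropped.
Domains span first probe start to last probe end; ties are included
(≥ t) for determinism.

**Threshold.** Three sources are implemented and recorded in provenance:

* `"raw"` — the `quantile` (default 0.90) of the pooled raw probe values;
* `"smoothed"` — the same quantile of the smoothed values;
* `"background"` (default) — the quantile of a Gaussian *background* fitted
  to the data: `t = m + z_q·σ̂`, with the background location `m` taken as
  the histogram mode of the smoothed distribution (smoothing shrinks
  within-component spread by ~√(probes per window), so the background and
  enriched modes separate there even when the raw mixture is unimodal) and
  `σ̂` the raw-value second moment reflected around `m`.

The background mode exists because a quantile of the data itself caps the
selected probe fraction at `1 − quantile`: a 90th-percentile cutoff on raw
or smoothed values can never yield domains covering ~40% of a genome, which
is the regime these domains actually reach in differentiated cells.
Referencing the quantile to the non-enriched background makes the cutoff a
statement about signal ("above what background produces") rather than
about rank. On a pure-noise track the background fit coincides with the
raw quantile and essentially nothing is called; on a constant track
`σ̂ = 0` and each chromosome becomes one domain (documented degenerate
case).

**Merge gap (20 kb).** A euchromatin island of length `L` depresses the
`w`-smoothed curve over roughly `L + w` of flanking domain, so with
`w = 10 kb` a dip up to ~10 kb opens a sub-threshold gap of up to ~16 kb
inside an otherwise solid domain. The merge gap must bridge that footprint
or domains fragment at their own islands — which would then place the
islands at domain edges, inside the boundary margin, and make them
undetectable. 20 kb bridges island-scale gaps while leaving genuinely
separate domains (which sit much further apart) distinct.

## EI detection

Inside called LOCKs, in order:

1. restrict to probes within each LOCK;
2. smooth per LOCK with a 5 kb window — the window never crosses a LOCK
   boundary, so outside signal cannot leak in;
3. threshold `t` = the 1st percentile (`low_percentile = 0.01`) of the
   smoothed values, pooled over within-LOCK probes by default
   (`percentile_universe`; the all-probes variant is implemented);
4. maximal runs of probes with smoothed value strictly `< t`;
5. merge runs with genomic gaps `< 1 kb`;
6. drop merged runs shorter than 1 kb or with fewer than 10 probes (probe
   count includes every probe in the merged span, gap probes included —
   the span is contiguous within the LOCK);
7. drop runs whose nearest edge is `< 20 kb` from the parent LOCK's edge,
   measured edge-to-edge: log-ratios decay at LOCK boundaries and the
   margin prevents boundary decay from masquerading as islands.

EI coordinates span first to last probe of the run. Merging precedes the
length/probe filters so a noise-fragmented dip is not spuriously rejected;
the boundary filter runs last, on final EI edges.

**The 1% quota.** A bottom-percentile detector can flag at most ~`q` of the
within-LOCK probe mass. This is the method's operating regime in real
data: on the order of a couple thousand ~5 kb islands against >1 Gb of
domains is ~1% of domain mass. Any benchmark that plants substantially
more island mass than the quota forces the threshold below the shallower
dips and sensitivity collapses — not a defect of the detector but an
identity about quantiles. The synthetic defaults are chosen to respect it
(see below).

## Permutation enrichment

The observed statistic is either the fraction of query intervals sharing
≥ 1 bp with the (merged) feature set, or the fraction of query bp covered
by it. The null resamples `n_permutations` (default 1,000) interval sets
whose lengths match the query's exactly (multiset equality, checked in
tests), each interval placed uniformly among all admissible positions in a
universe — segments are chosen with probability proportional to their
count of valid starts for that length. Sampled intervals are pairwise
disjoint by default (rejection with a 1,000-attempt cap per interval),
since the query sets are disjoint; overlap can be allowed explicitly.

The default whole-genome universe is the probe-covered genome (union of
tiled regions with small gaps bridged), not raw chromosome spans: EIs can
only exist where probes exist, and the null must share that support. The
within-LOCK null uses the called domains as the universe.

`p_raw = (1 + #{null ≥ observed}) / (n_permutations + 1)` (add-one
estimator): p is never 0 and the smallest reportable value at n = 1,000 is
1/1001, i.e. "< 10⁻³". Fold = observed / null mean, with 0/0 → 1 and
x/0 → +∞ conventions. Tests are one-sided (enrichment); Bonferroni
multiplies by the family size and clamps at 1.

**Calibration and discreteness.** With the base-overlap statistic
(continuous at bp resolution) the attained level at nominal 0.05 is the
theoretical 10/201 ≈ 0.0498 with 200 permutations (measured 0.042–0.054
over 500-test sweeps). The interval-overlap statistic lives on a lattice
of 1/|query|; ties between observed and null values make the add-one
estimator strictly conservative — the attained level is roughly half
nominal for queries of a few dozen intervals. Conservative, never
anti-conservative; worth remembering when interpreting marginal p-values
from small EI sets.

## Synthetic data

`simulate_track` emulates the array: a probe grid at 200 bp spacing,
jittered ±25 bp to avoid aliasing against the smoothing windows, with
Gaussian values — N(0, 1) background, +1.5 SD inside planted LOCKs,
−2.5 SD dips (rectangular; tapered edges optional) inside planted EIs.
LOCK lengths are log-normal (median 2 Mb, σ_log 0.25, clipped to
[500 kb, 0.45×chromosome]), placed disjoint with ≥ 50 kb clearance until a
40% coverage target is met within ~1%; EIs are Poisson(3) per LOCK,
uniform 3–8 kb, ≥ 30 kb from LOCK edges and ≥ 5 kb apart. The default
demo genome is 2 × 10 Mb.

The LOCK length default is deliberately at the top of the domain scale so
that ~3 dips per domain keeps planted EI mass at ~0.8% of LOCK mass — at
or below the 1% quota, matching the rarity of islands in real domains.

`simulate_features` gives each planted EI a centered feature with
probability `p_in_ei` plus a uniform background (default 5/Mb, 500 bp).
Treating feature left-ends as a Poisson process gives closed forms for the
expected observed overlap and null mean (a query of length L is hit at
rate `density·(L + f)`), so designed-enrichment experiments have an
analytic target; `tune_p_in_ei_for_fold` inverts the closed form for a
target fold.

A `noise_seed` argument redraws measurement noise while keeping the grid
and all planted structure fixed, emulating replicate hybridizations of one
chromatin state.

**What the generator does not emulate:** dye bias, GC/probe-sequence
effects, spatial artifacts, copy-number structure, heavy-tailed or
correlated noise, and replicate correlation beyond shared truth. Passing
the recovery tests shows the algorithms are correct and calibrated under
the stated signal model, not that the biological conclusions transfer to
any particular real dataset.

## Annotation conventions

TSS association uses the strand-aware 5' end as a point with 0 bp slop
(configurable); an EI "contains" a gene iff the TSS point lies in the EI
interval (half-open, so a TSS at the exclusive end does not count). Gene
stratification assigns EI membership precedence over LOCK membership; the
three categories partition the gene set. Three-way EI comparisons are
reported set-relative (each set's intervals classified by which other sets
they touch) because ≥1 bp overlap is not transitive and a single Venn
partition is not well defined. Signal meta-profiles bin probe midpoints by
distance from anchor midpoints; empty bins are NaN, not zero.

## Problem sizes

The demo analyses run on 2 × 10 Mb genomes (100,000 probes), 1,000
permutations per enrichment test, and 500 × 200 permutations for the
calibration sweep; these sizes make every stage's expected behavior
computable in closed form or by brute-force oracle while exercising the
same code paths a full-genome run would.

## Known limitations

* The LOCK background fit assumes the smoothed distribution separates
  background from enrichment; shifts ≲ 1 noise SD leave the mixture
  unimodal after smoothing and no 90th-percentile rule of any kind can
  recover such domains.
* The EI threshold is a pooled per-track quantile; cross-track joint
  calling and FDR control are out of scope.
* Null placement is uniform within the universe; GC-, gap- or
  feature-length-aware nulls (GAT-style) are not implemented.
* BigWig/BigBed are not read; tracks are plain bedGraph-like TSVs.
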