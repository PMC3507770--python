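# lockei

Domain-level analysis of H3K9me2 tiling-array data: calling **LOCKs**
(large organized chromatin K9-modification domains), detecting
**euchromatin islands (EIs)** inside them, and testing EI co-location with
genomic features by length-matched permutation.

## The problem

In differentiated mammalian cells, H3K9me2 occupies enormous contiguous
domains — hundreds of kb to Mb — covering ~40% of the genome. Embedded in
these repressive blocks are rare, kb-scale windows where the signal drops
to the extreme low tail: euchromatin islands, which coincide with CTCF
sites, DNase hypersensitive sites, TSSs and differentially methylated
regions, and mark putative regulatory elements surviving inside
heterochromatin. This package implements the full computational path from
probe-level log2(ChIP/Input) tracks to enrichment statistics, plus a
synthetic-data generator that plants known domains, islands and features
so every stage can be validated against ground truth.

## Method at a glance

1. **Normalization** — partial quantile normalization: the lower 75% of
   each array's log-ratio distribution is mapped onto a common quantile
   curve; the enrichment tail is shifted continuously, preserving ranks.
2. **LOCK calling** — smooth with a 10 kb windowed mean; threshold the
   smoothed curve at t = m + z₀.₉·σ̂, the 90th quantile of a Gaussian
   background fitted to the data (mode m, reflected-tail σ̂); take maximal
   runs ≥ t, merge gaps ≤ 20 kb, drop domains < 10 kb.
3. **EI detection** — within LOCK bodies, smooth with a 5 kb window (never
   crossing a LOCK edge); flag runs strictly below the 1st percentile of
   within-LOCK smoothed values; merge runs < 1 kb apart; require ≥ 1 kb,
   ≥ 10 probes, and ≥ 20 kb from the LOCK boundary.
4. **Enrichment** — observed overlap of EIs with a feature set vs a null
   of 1,000 random interval sets with exactly matched lengths, placed
   uniformly in the probe-covered genome (or within LOCKs);
   p = (1 + #{null ≥ obs})/(n + 1), fold = obs/mean(null), Bonferroni
   across the feature family.

See `docs/methods.md` for parameter-by-parameter rationale.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
demo simulation (2 × 10 Mb chromosomes, 100,000 probes, 40% planted LOCK
coverage, ~3 planted dips per LOCK) and write their tables to `results/`:

```sh
python analysis/01_simulate.py
python analysis/03_call_locks.py
python analysis/04_detect_eis.py
python analysis/05_enrichment.py
```

prints, in order:

```
planted 5 LOCKs covering 40.0% of the genome (target 40%)
planted 14 EIs (mean 6098 bp), 116 features ...

threshold (background q90): 1.237
called 5 LOCKs, coverage 39.8% (planted 40.0%), mean size 1592 kb
base-level Jaccard vs planted domains: 0.995

detected 14 EIs (mean 5560 bp) at low-tail threshold 0.193
recovery vs planted dips: sensitivity 1.00, precision 1.00
replicate concordance (two noise realizations): 100.0%

         feature  observed_pct  null_mean_pct   fold    p_raw ...
planted-features          57.1            3.6   16.0  0.000999
planted-features          57.1            4.4   13.1  0.000999
```

Reading: the caller recovers the planted domains almost exactly
(Jaccard 0.995, coverage within 0.2 points), every planted island is found
with no false calls, and the features planted into half the islands come
out ~16-fold enriched over the length-matched whole-genome null (p at the
1/1001 floor), with a similar fold under the stricter within-LOCK null.

The same machinery is exposed as a CLI (`lockei simulate|normalize|
call-locks|call-eis|enrich|annotate|run-all`) operating on bedGraph/BED
files with YAML configs and JSON provenance sidecars.

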