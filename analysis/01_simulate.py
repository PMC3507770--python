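#!/usr/bin/env python
"""Generate the demo genome and report what was planted.

Two 10 Mb chromosomes tiled at ~200 bp; ~40% of the genome covered by
planted H3K9me2 blocks (LOCKs) with a +1.5 SD mean shift; ~3 euchromatin
island dips per block (3-8 kb, depth 2.5 SD, >= 30 kb from block edges);
features planted in half the dips against a 5/Mb background. Probe-level
data are regenerated deterministically by downstream scripts from the same
seed, so only the planted truth tables are written here.
"""

from pathlib import Path

import lockei as lk
import numpy as np

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = lk.default_demo_spec(seed=SEED)
    track, truth = lk.simulate_track(spec)
    features, expect = lk.simulate_features(truth, spec,
                                            np.random.default_rng(SEED + 1))

    truth.locks.df.to_csv(OUT / "planted_locks.tsv", sep="\t", index=False)
    truth.eis.df.to_csv(OUT / "planted_eis.tsv", sep="\t", index=False)
    features.df.to_csv(OUT / "planted_features.tsv", sep="\t", index=False)

    layout = spec.layout()
    cov = truth.locks.total_bp / layout.total_bp
    print(f"simulated {track.n_probes:,} probes on "
          f"{len(layout.chrom_names)} x {layout.chrom_lengths[0] / 1e6:.0f} Mb")
    print(f"planted {len(truth.locks)} LOCKs covering {100 * cov:.1f}% "
          f"of the genome (target {100 * spec.lock_spec.coverage:.0f}%)")
    print(f"planted {len(truth.eis)} EIs "
          f"(mean {truth.eis.lengths.mean():.0f} bp), "
          f"{len(features)} features "
          f"(closed-form expected enrichment fold "
          f"{expect['expected_fold']:.1f})")


if __name__ == "__main__":
    main()
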