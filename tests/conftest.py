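import numpy as np
import pytest

import lockei as lk


def make_track(values, spacing=200, probe_len=50, chrom="chr1", start0=100):
    """Probe track on a regular grid from a value array."""
    v = np.asarray(values, dtype=float)
    starts = start0 + np.arange(len(v), dtype=np.int64) * spacing
    return lk.ProbeTrack(
        {chrom: {"start": starts, "end": starts + probe_len, "value": v}},
        median_spacing_bp=spacing)


@pytest.fixture(scope="session")
def demo_run():
    """One full pipeline run on the default demo conditions."""
    spec = lk.default_demo_spec(seed=1)
    track, truth = lk.simulate_track(spec)
    smoothed = lk.smooth(track, lk.LockParams().window_bp)
    domains = lk.call_locks(smoothed, track)
    eis = lk.detect_eis(track, domains)
    return {"spec": spec, "track": track, "truth": truth,
            "domains": domains, "eis": eis}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
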