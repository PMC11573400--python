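import numpy as np
import pytest

from hypnohrv import pphrv, synth
from hypnohrv.ecg import BeatSeries
from hypnohrv.hypnogram import Hypnogram


def make_hypnogram(codes, subject_id="s", group="CG", meta=None):
    return Hypnogram(subject_id=subject_id, group=group,
                     stages=np.asarray(codes, dtype=np.int8), meta=meta)


@pytest.fixture(scope="session")
def renewal_beats():
    """20 minutes of renewal (intercept-only) IG beats: mu=0.9 s, shape=800."""
    sp = {i: synth.StageHDIG(mean_rr=0.9, theta_ar=np.zeros(1), shape=800.0)
          for i in range(5)}
    h = synth.gen_hypnogram(np.full((5, 5), 0.2), 2400, seed=7)
    return synth.gen_rr(h, sp, seed=77, t_end=1200.0)


@pytest.fixture(scope="session")
def renewal_fit(renewal_beats):
    """HDIG fit of the renewal fixture at test grid resolution."""
    return pphrv.fit_hdig(renewal_beats, delta=0.25)


@pytest.fixture(scope="session")
def twenty_beat_series():
    """Small fixed beat series for likelihood-oracle comparisons."""
    rng = np.random.default_rng(3)
    rr = 0.9 + 0.05 * rng.standard_normal(20)
    return BeatSeries(times=np.concatenate([[0.0], np.cumsum(rr)]))
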