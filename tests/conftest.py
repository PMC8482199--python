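import numpy as np
import pytest
from hypothesis import settings

from mpragekit import PhantomSpec, SequenceParams, build_lut

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def seq():
    """The finalized 0.7 mm protocol: 8 deg readout, TR 8 ms, TI 1200 ms,
    TF 288, cycle 3.5 s, inversion efficiency 0.96, 3 deg reference GRE."""
    return SequenceParams()


@pytest.fixture(scope="session")
def protocol_lut(seq):
    """Full default lookup table (T1 1 ms - 5 s at 1 ms, fT 0.4 - 1.6 at 0.01)."""
    return build_lut(seq)


@pytest.fixture(scope="session")
def small_lut(seq):
    """Coarse table for fast structural tests."""
    return build_lut(seq, t1_range=(0.5, 5.0), t1_step=0.01,
                     ft_range=(0.8, 1.2), ft_step=0.05)


@pytest.fixture()
def noise_free_spec():
    return PhantomSpec(shape=(32, 32, 32), noise_sigma=0.0, seed=0)


def per_pulse_center(seq: SequenceParams, t1, f_t, n_cycles=12):
    """Independent per-pulse oracle for Mz at the central k-space line.

    Each readout pulse instantaneously scales Mz by cos(local flip angle);
    Mz relaxes freely toward +1 with rate 1/T1 over every TR and over the
    gaps before and after the train; inversion scales by -f_inv.  The value
    at the centre line is Mz just before pulse tf//2 of the last cycle.
    """
    t1 = np.atleast_1d(np.asarray(t1, dtype=float))
    r1 = 1.0 / t1
    ca = np.cos(np.deg2rad(seq.alpha_mp * f_t))
    e_tr = np.exp(-seq.tr * r1)
    t_start = seq.ti - (seq.tf // 2) * seq.tr
    e_pre = np.exp(-t_start * r1)
    e_post = np.exp(-(seq.t_cycle - t_start - seq.tf * seq.tr) * r1)
    mz = np.ones_like(t1)
    center = None
    for _ in range(n_cycles):
        mz = 1.0 + (-seq.f_inv * mz - 1.0) * e_pre
        for k in range(seq.tf):
            if k == seq.tf // 2:
                center = mz.copy()
            mz = 1.0 + (mz * ca - 1.0) * e_tr
        mz = 1.0 + (mz - 1.0) * e_post
    return center
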