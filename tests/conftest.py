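import numpy as np
import pytest

from granulekit.frap import IntensityTrace


@pytest.fixture
def flat_trace():
    """Constant channels: I_F == I_R, zero background -> I_F_norm == 1."""
    n = 20
    return IntensityTrace(
        time=np.arange(n, dtype=float),
        I_F=np.full(n, 100.0),
        I_R=np.full(n, 100.0),
        I_B=np.zeros(n),
        bleach_index=5,
    )


def make_recovery_trace(t_half=22.0, plateau=0.8, n_pre=5, n_post=300, dt=1.0,
                        focus=1000.0, ref=800.0, bg=50.0, ref_decay=0.0):
    """Noiseless analytic trace following the generative model exactly."""
    n = n_pre + n_post
    t = np.arange(n) * dt
    tb = n_pre * dt
    S = np.ones(n)
    post = t >= tb
    S[post] = plateau * (1.0 - np.exp(-np.log(2.0) * (t[post] - tb) / t_half))
    D = np.exp(-ref_decay * t)
    return IntensityTrace(
        time=t,
        I_F=bg + D * focus * S,
        I_R=bg + D * ref,
        I_B=np.full(n, bg),
        bleach_index=n_pre,
    )
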