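import numpy as np
import pytest

from gelmri.phantoms import invitro_inversion_times, tube_spec
from gelmri.t1fit import InversionRecoverySeries, forward_look_locker, t1_star_from_t1

IN_VITRO_TR = 0.025
IN_VITRO_FLIP = 5.0


def make_voxel_series(t1_s, m0=1.0, times=None, flip=IN_VITRO_FLIP, tr=IN_VITRO_TR):
    """Noiseless single-voxel Look-Locker magnitude curve from a true T1."""
    if times is None:
        times = invitro_inversion_times()
    tau = t1_star_from_t1(t1_s, flip, tr)
    m0_star = m0 * tau / t1_s
    sig = forward_look_locker(m0_star, m0 + m0_star, tau, times)
    return InversionRecoverySeries(sig, times, tr, flip)


@pytest.fixture(scope="session")
def small_tube():
    """Noiseless LC-like tube phantom, shortened time axis for speed."""
    from gelmri.phantoms import generate_tube_phantom

    spec = tube_spec(
        "LC",
        seed=7,
        times_h=np.array([0.0, 4.0, 12.0, 24.0]),
        volumes_uL=np.array([39.6, 40.0, 40.2, 40.4]),
        refresh_times_h=(),
    )
    series_list, truth = generate_tube_phantom(spec)
    return spec, series_list, truth
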