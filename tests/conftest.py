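import numpy as np
import pytest

from lrrwind import RunConfig, SolenoidSpec, make_solenoid


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def clean_solenoid():
    """Noiseless 10-turn, period-24 solenoid with no flanks (241 residues)."""
    return make_solenoid(SolenoidSpec(turns=10, period=24))


@pytest.fixture(scope="session")
def flanked_solenoid():
    """10-turn solenoid with 40-residue flanks and 0.3 Å coordinate noise."""
    return make_solenoid(
        SolenoidSpec(turns=10, period=24, flank_n=40, flank_c=40, noise_sd=0.3, seed=11)
    )


def unwrapped_angle_winding(xy, sigma=1.0):
    """Independent winding oracle: cumulative unwrapped atan2 of the
    sigma-mollified planar curve, in turns, anchored at the first point."""
    from scipy import ndimage

    xs = ndimage.gaussian_filter1d(
        np.asarray(xy, float), sigma, axis=0, mode="reflect", radius=4
    )
    ang = np.unwrap(np.arctan2(xs[:, 1], xs[:, 0]))
    return (ang - ang[0]) / (2.0 * np.pi)
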