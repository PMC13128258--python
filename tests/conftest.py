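import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_admissible_iso(rng):
    """Random (E, nu) in the physically common range."""
    return float(rng.uniform(0.5, 5.0)), float(rng.uniform(-0.2, 0.48))


def random_admissible_ti(rng):
    """Random admissible TI engineering constants (resampled until the
    compliance is positive definite)."""
    from elunet.constitutive import AdmissibilityError, EngineeringTI

    while True:
        try:
            return EngineeringTI(
                Exx=float(rng.uniform(0.5, 8.0)),
                Eyy=float(rng.uniform(0.2, 2.0)),
                nu_xy=float(rng.uniform(0.05, 0.45)),
                nu_yz=float(rng.uniform(0.05, 0.45)),
                Gxy=float(rng.uniform(0.1, 1.0)),
            )
        except AdmissibilityError:
            continue
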