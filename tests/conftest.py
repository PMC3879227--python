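import numpy as np
import pytest

import hpaxis as h


@pytest.fixture(scope="session")
def default_params():
    return h.ExtendedParams()


@pytest.fixture(scope="session")
def unit_params():
    """All kinetic constants 1, volumes 1 (k_bar = 1/2), h = 2."""
    from hpaxis.params import FREE_PARAM_NAMES

    kw = {n: 1.0 for n in FREE_PARAM_NAMES}
    kw.update(V_in=1.0, V_ex=1.0, V_nu=1.0, kGRdim=1.0, h=2.0)
    return h.ExtendedParams(**kw)


@pytest.fixture(scope="session")
def zero_production_params():
    """All production/source rates effectively zero; only decay remains."""
    tiny = 1e-300
    return h.ExtendedParams(
        v1=tiny, v2=tiny, v3=tiny, v4=tiny, v5=tiny, v6=tiny, v7=tiny,
        v8=tiny, ks=tiny, ksb=tiny, ktl1=tiny, ktl2=tiny,
    )


@pytest.fixture(scope="session")
def fixture_regimes():
    from hpaxis.synthetic import make_fixture_regimes

    return make_fixture_regimes()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_state(rng, lo=-2.0, hi=2.0, n=15):
    return 10 ** rng.uniform(lo, hi, n)


def random_params(rng, spread=0.8):
    """Log-uniform draw around the default parameter set."""
    from hpaxis.params import FREE_PARAM_NAMES

    base = h.ExtendedParams()
    kw = {
        n: getattr(base, n) * 10 ** rng.uniform(-spread, spread)
        for n in FREE_PARAM_NAMES
    }
    kw["kGRdim"] = base.kGRdim * 10 ** rng.uniform(-spread, spread)
    return base.replace(**kw)
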