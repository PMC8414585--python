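import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrkit import HarmonizedPair, VariantAssociation, ad_design_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_pair(x, y, sx=0.05, sy=0.05, vid="rs000001", flipped=False):
    return HarmonizedPair(vid, x, sx, y, sy, flipped=flipped)


def make_pairs(xs, ys, sys_=None, sxs=None):
    k = len(xs)
    sys_ = sys_ if sys_ is not None else [0.05] * k
    sxs = sxs if sxs is not None else [0.05] * k
    return [
        HarmonizedPair(f"rs{i + 1:06d}", float(x), float(sx), float(y), float(sy))
        for i, (x, sx, y, sy) in enumerate(zip(xs, sxs, ys, sys_))
    ]


def make_assoc(vid="rs000001", ea="A", oa="G", beta=0.1, se=0.02,
               pvalue=1e-9, eaf=0.3, **kw):
    return VariantAssociation(vid, ea, oa, beta, se, pvalue, eaf=eaf, **kw)


@pytest.fixture(scope="session")
def ad_shaped_study():
    """Fixed-seed five-instrument study with the GDF-15 -> AD dimensions."""
    return ad_design_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
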