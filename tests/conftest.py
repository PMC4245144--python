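import numpy as np
import pytest

from floralres.density import DistanceSample


@pytest.fixture
def simple_sample() -> DistanceSample:
    """Small fully-observed distance sample with hand-checkable values."""
    pd_ = np.array([0.05, 0.08, 0.10, 0.04, 0.12, 0.06])
    nd = np.array([0.03, 0.05, 0.07, 0.02, 0.09, 0.04])
    no = np.zeros(6, dtype=bool)
    return DistanceSample(pd_, no, nd, no.copy(), field_limit=0.15)


def make_sample(point, neighbor, field_limit=0.15, point_cens=None, nb_cens=None):
    point = np.asarray(point, dtype=float)
    neighbor = np.asarray(neighbor, dtype=float)
    if point_cens is None:
        point_cens = np.isnan(point)
    if nb_cens is None:
        nb_cens = np.isnan(neighbor)
    return DistanceSample(point, np.asarray(point_cens, bool),
                          neighbor, np.asarray(nb_cens, bool),
                          field_limit=field_limit)
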