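import pytest

from ringstoich import MarkerSet, RingModel, calibrate


@pytest.fixture(scope="session")
def anchor_markers() -> MarkerSet:
    """BSA (66 kDa) and beta-amylase (200 kDa) gradient anchors."""
    return MarkerSet(((66.0, 23.0), (200.0, 15.0)))


@pytest.fixture(scope="session")
def two_point_fit(anchor_markers):
    return calibrate(anchor_markers)


@pytest.fixture(scope="session")
def hexamer() -> RingModel:
    """Hexameric ring with single-poison blocking, random assembly."""
    return RingModel(z=6, k=1)
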