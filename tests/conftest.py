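import pytest

from quatmass.stoichiometry import SubunitCatalog, SubunitEntry
from quatmass.synthetic import mnx_ground_truth
from quatmass.topology import ObservationSet

#: Fragment classes from high-energy SID of the hexamer: the six observed
#: mixed multimers, the conspicuously missing homo-oligomers, and the two
#: trace species attributable to secondary dissociation.
SID_HEXAMER_OBSERVATIONS = {
    "E1F1": "major",
    "E1F2": "major",
    "E2F1": "major",
    "E2F2": "major",
    "E2F3": "major",
    "E3F3": "major",
    "E2": "absent",
    "E3": "absent",
    "F3": "absent",
    "E3F1": "absent",
    "F2": "trace",
    "E1F3": "trace",
}


@pytest.fixture
def sid_observations() -> ObservationSet:
    return ObservationSet(dict(SID_HEXAMER_OBSERVATIONS))


@pytest.fixture
def coarse_catalog() -> SubunitCatalog:
    """Catalog at the printed approximate masses (no adducts)."""
    return SubunitCatalog(
        entries=[
            SubunitEntry("MnxG", 139000.0, 0, 1, symbol="G"),
            SubunitEntry("MnxE", 12000.0, 0, 8, symbol="E"),
            SubunitEntry("MnxF", 12000.0, 0, 8, symbol="F"),
        ]
    )


@pytest.fixture
def truth():
    return mnx_ground_truth()
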