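import hypothesis
import pytest

from omegamap.lipids import FattyAcyl, LipidMolecularSpecies
from omegamap.rtdb import RTDB, RTDBEntry

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def pc_omega_pair_db():
    """Small mapped RT-DB with an omega-isomer pair and a coeluting species.

    PC 18:0_22:5(n-3) at 21.9 min, its n-6 isomer more than a minute later,
    and the distinct molecular species PC 16:0_24:5(n-6) coeluting at
    21.9 min.
    """
    def entry(cls, chains, rt, evidence="SIL-experiment"):
        return RTDBEntry(
            LipidMolecularSpecies(cls, chains, sn_resolved=False),
            rt, frozenset({"batchA"}), evidence,
        )

    entries = [
        entry("PC", (FattyAcyl(18, 0), FattyAcyl(22, 5, omega=3)), 21.9),
        entry("PC", (FattyAcyl(18, 0), FattyAcyl(22, 5, omega=6)), 23.1),
        entry("PC", (FattyAcyl(16, 0), FattyAcyl(24, 5, omega=6)), 21.9),
    ]
    return RTDB(entries=entries, meta={"gradient_span_min": 35.0, "t0_min": 0.5})
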