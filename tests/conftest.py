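import numpy as np
import pytest

from iodoscreen.screen_model import KineticWell, Role, WellAddress


def make_well(plate, well, role=Role.DRUG, drug_id=None, yfp0=100.0,
              yfp4=75.0, viability=1.0, dose=10.0):
    """Construct a well with a linear trace ending at yfp4."""
    addr = WellAddress.parse(plate, well)
    cycles = tuple(yfp0 + (yfp4 - yfp0) * k / 4 for k in (1, 2, 3, 4))
    return KineticWell(address=addr, role=role, drug_id=drug_id,
                       dose=dose if role is Role.DRUG else None,
                       yfp0=yfp0, yfp_cycles=cycles, viability=viability)


@pytest.fixture
def tiny_screen():
    """Two 8-well plates: 2 NaI, 2 PBS, 2 DMSO, 2 drug wells each, with
    enough spread to make every statistic well defined."""
    rng = np.random.default_rng(7)
    wells = []
    for p, plate in enumerate(("P1", "P2")):
        scale = 1.0 + 0.1 * p
        for i, (well, role, drug) in enumerate([
            ("A01", Role.NAI_POSITIVE, None),
            ("B01", Role.NAI_POSITIVE, None),
            ("C01", Role.PBS_NEGATIVE, None),
            ("D01", Role.PBS_NEGATIVE, None),
            ("A02", Role.DMSO_CONTROL, None),
            ("B02", Role.DMSO_CONTROL, None),
            ("A03", Role.DRUG, f"D{p}1"),
            ("B03", Role.DRUG, f"D{p}2"),
        ]):
            base_q = {Role.NAI_POSITIVE: 0.8, Role.PBS_NEGATIVE: 0.0,
                      Role.DMSO_CONTROL: 0.25, Role.DRUG: 0.3 + 0.1 * i}[role]
            yfp0 = 1000.0 * scale * (1 + 0.02 * rng.standard_normal())
            yfp4 = yfp0 * (1 - base_q) * (1 + 0.02 * rng.standard_normal())
            wells.append(make_well(plate, well, role, drug, yfp0, yfp4))
    return wells
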