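import pytest
from hypothesis import settings

from clusterdld import flowfield as F
from clusterdld import geometry as G

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")

# per-gap flows at the 0.5 mL/hr operating point
STAGE1_PER_GAP = (8.3 + 31.6) / 8
STAGE2_PER_GAP = ((2.0 / 3.0) * (8.3 + 31.6) + 40.0) / 32


@pytest.fixture(scope="session")
def device():
    return G.build_reference_device()


@pytest.fixture(scope="session")
def stage1_cell(device):
    st = device.stage1
    return F.rasterize_pillar(st.pillar, 1.0, st.pitch, st.pitch,
                              st.ceiling_height, st.row_shift)


@pytest.fixture(scope="session")
def stage2_cell(device):
    st = device.stage2
    return F.rasterize_pillar(st.pillar, 1.0, st.pitch, st.pitch,
                              st.ceiling_height, st.row_shift)


@pytest.fixture(scope="session")
def stage1_field(stage1_cell):
    return F.solve_unit_cell(stage1_cell, STAGE1_PER_GAP)


@pytest.fixture(scope="session")
def stage2_field(stage2_cell):
    return F.solve_unit_cell(stage2_cell, STAGE2_PER_GAP)


@pytest.fixture(scope="session")
def stage1_plug(stage1_cell):
    return F.plug_flow_field(stage1_cell, STAGE1_PER_GAP)
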