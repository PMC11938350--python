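import pandas as pd
import pytest

from gcplasma import PerturbationSchedule, SimConfig
from gcplasma.tables import REQUIRED_COLUMNS


def make_cell_row(
    cell_id: int,
    clone_id: str = "clone0",
    mouse_id: str = "m0",
    compartment: str = "LZ",
    v_call: str = "IGHV1-72",
    junction: str = "TGTGCAAGA" * 2 + "TGT",
    junction_light: str = "TGTCAGCAA" * 2 + "TGT",
    mutations_heavy: str = "",
    mutations_light: str = "",
    label_dilution: float = 1.0,
    division_count: int = 0,
    affinity: float = 10.0,
    **extra,
) -> dict:
    row = {
        "sequence_id": f"{mouse_id}_{cell_id}",
        "cell_id": cell_id,
        "clone_id": clone_id,
        "mouse_id": mouse_id,
        "compartment": compartment,
        "v_call": v_call,
        "j_call": "IGHJ2",
        "junction": junction,
        "junction_aa": "CAR",
        "v_call_light": "IGLV1",
        "j_call_light": "IGLJ1",
        "junction_light": junction_light,
        "junction_aa_light": "CQQ",
        "zsg_s1pr2": 0,
        "zsg_blimp1": 0,
        "label_dilution": label_dilution,
        "division_count": division_count,
        "affinity": affinity,
        "mutations_heavy": mutations_heavy,
        "mutations_light": mutations_light,
        "hotspot_mutations": "",
    }
    row.update(extra)
    return row


def make_table(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


@pytest.fixture
def tiny_config() -> SimConfig:
    """A small, fast simulation: 40 founders, 4 days."""
    return SimConfig(founder_count=40, tfh_capacity=40.0, duration_days=4.0, seed=11)


@pytest.fixture
def labeled_config() -> SimConfig:
    """Small 8-day run with GC fate-map labeling at day 2."""
    return SimConfig(
        founder_count=60,
        tfh_capacity=60.0,
        duration_days=8.0,
        seed=5,
        perturbations=PerturbationSchedule.of((48.0, "tamoxifen_s1pr2")),
    )
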