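import numpy as np
import pytest

from reporterscreen import (
    PlateLayout,
    PlateRead,
    ScreenDataset,
    WellAddress,
    WellRole,
)
import pandas as pd


def make_layout(plate_id="P1", n_m0=3, n_solvent=3, n_tsa=2, compounds=("C1", "C2", "C3")):
    """Small hand-built layout: controls in column 1-2, compounds after."""
    wells = {}
    addresses = [WellAddress(r, c) for c in range(1, 25) for r in "ABCDEFGHIJKLMNOP"]
    i = 0
    for role, n in ((WellRole.M0_CONTROL, n_m0), (WellRole.M1_SOLVENT, n_solvent), (WellRole.M1_TSA, n_tsa)):
        for _ in range(n):
            wells[addresses[i]] = (role, None)
            i += 1
    for cid in compounds:
        wells[addresses[i]] = (WellRole.COMPOUND, cid)
        i += 1
    return PlateLayout(plate_id, wells)


def make_dataset(layout, signals_by_read, viability_by_read=None):
    """Assemble a dataset from per-read {well_str: value} signal maps."""
    reads = {}
    for idx, sig in signals_by_read.items():
        viab = (viability_by_read or {}).get(idx)
        reads[(layout.plate_id, idx)] = PlateRead(
            layout.plate_id,
            idx,
            {WellAddress.parse(w): v for w, v in sig.items()},
            {WellAddress.parse(w): v for w, v in viab.items()} if viab else None,
        )
    registry = pd.DataFrame(
        [
            {"compound_id": cid, "library": "LIB", "plate_id": layout.plate_id, "well": str(w)}
            for w, cid in layout.compound_wells().items()
        ],
        columns=["compound_id", "library", "plate_id", "well"],
    )
    return ScreenDataset({layout.plate_id: layout}, reads, registry)


@pytest.fixture
def tiny_layout():
    return make_layout()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
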