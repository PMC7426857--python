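import numpy as np
import pandas as pd
import pytest

from sigscreen import SimulationConfig, simulate_screen


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down screen: 2 plates, 60 compounds, 20 probes."""
    return SimulationConfig(
        n_plates=2,
        wells_per_plate=96,
        n_compounds=60,
        n_probes=20,
        n_housekeeping=4,
        n_signature_true=5,
        n_wt_controls_per_plate=8,
        n_ko_controls_per_plate=8,
        frac_rescuers=0.1,
        frac_toxic=0.1,
        frac_lowread=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    return simulate_screen(small_config)


@pytest.fixture(scope="session")
def default_screen():
    """Full-size screen at the study's layout (4 plates, 1,120 compounds)."""
    return simulate_screen(SimulationConfig(seed=11))


def toy_bundle():
    """Hand-built two-plate bundle for exact-arithmetic QC/normalize tests.

    Probes: HK1, HK2 (housekeeping), GA, GB, Tgt (target).  Each plate has
    2 WT + 2 KO untreated wells and 2 compound wells.
    """
    panel = pd.DataFrame({
        "probe_id": ["HK1", "HK2", "GA", "GB", "Tgt"],
        "gene_symbol": ["HK1", "HK2", "GA", "GB", "Tgt"],
        "category": ["housekeeping", "housekeeping", "inflammatory", "lysosomal", "target"],
        "is_housekeeping": [True, True, False, False, False],
    })
    panel = panel.set_index("probe_id", drop=False)

    rows = []
    for plate in ("p1", "p2"):
        rows += [
            (plate, "A01", "WT", "untreated", "", 1.0),
            (plate, "A02", "WT", "untreated", "", 1.1),
            (plate, "A03", "KO", "untreated", "", 0.9),
            (plate, "A04", "KO", "untreated", "", 1.0),
            (plate, "A05", "KO", "compound", f"CMP-{plate}-1", 1.0),
            (plate, "A06", "KO", "compound", f"CMP-{plate}-2", 0.95),
        ]
    wells = pd.DataFrame(rows, columns=["plate_id", "well_id", "genotype",
                                        "treatment", "compound_id", "cell_count"])
    wells = wells.set_index(["plate_id", "well_id"])

    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(20_000, 40_000, size=(len(wells), 5)),
        index=wells.index, columns=panel.index,
    ).astype(np.int64)
    return counts, wells, panel


@pytest.fixture()
def toy():
    return toy_bundle()
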