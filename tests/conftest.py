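import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bovicnv import synthetic_data as sd
from bovicnv.array_io import IntensityTable, MarkerMap

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_marker_map(n=5, chromosome=1, spacing=50_000):
    rows = [
        (f"SNP-{chromosome:02d}-{i + 1:06d}", chromosome, (i + 1) * spacing)
        for i in range(n)
    ]
    return MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position"]))


def make_table(lrr, baf, r, gt, markers=None):
    """Build an IntensityTable from 2-D lists (samples x markers)."""
    lrr = np.asarray(lrr, dtype=float)
    markers = markers or make_marker_map(lrr.shape[1])
    samples = [f"S{i + 1}" for i in range(lrr.shape[0])]
    cols = markers.marker_ids
    return IntensityTable(
        markers=markers,
        lrr=pd.DataFrame(lrr, index=samples, columns=cols),
        baf=pd.DataFrame(np.asarray(baf, dtype=float), index=samples, columns=cols),
        r_total=pd.DataFrame(np.asarray(r, dtype=float), index=samples, columns=cols),
        genotype=pd.DataFrame(np.asarray(gt, dtype=object), index=samples, columns=cols),
    )


@pytest.fixture
def small_table():
    """3 samples x 5 markers with one NC genotype (call rate 14/15)."""
    rng = np.random.default_rng(0)
    lrr = rng.normal(0, 0.1, (3, 5))
    baf = np.clip(rng.normal(0.5, 0.05, (3, 5)), 0, 1)
    r = rng.uniform(0.8, 1.2, (3, 5))
    gt = np.full((3, 5), "AB", dtype=object)
    gt[1, 2] = "NC"
    return make_table(lrr, baf, r, gt)


@pytest.fixture(scope="session")
def cohort():
    """A small synthetic cohort with embedded deletions and a duplication,
    shared across tests that only read it."""
    specs = [
        sd.CNVEventSpec(1, 2_000_000, 2_400_000, 1, 0.2),
        sd.CNVEventSpec(2, 5_000_000, 5_400_000, 3, 0.2),
        sd.CNVEventSpec(3, 1_000_000, 1_400_000, 1, 0.3),
    ]
    cfg = sd.SimulationConfig(
        seed=7, n_sires=5, n_steers=45, n_chromosomes=3, n_markers=1800,
        event_specs=specs,
    )
    return sd.simulate_dataset(cfg)


def true_six_genotype(ds, sample, marker):
    """Ground-truth six-cluster label from the truth table and B dosage."""
    c = int(ds.truth.copy.at[sample, marker])
    b = int(ds.b_dosage.at[sample, marker])
    if c == 0:
        return "null_del"
    if c == 1:
        return "A_del" if b == 0 else "B_del"
    if b == 0:
        return "AA"
    if b == c:
        return "BB"
    return "AB"
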