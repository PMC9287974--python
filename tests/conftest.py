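import numpy as np
import pandas as pd
import pytest

from methylhet.io_formats import BetaMatrix, ProbeManifest
from methylhet.synthetic_data import SimulationDesign, simulate


@pytest.fixture(scope="session")
def small_study():
    """A small but complete cohort: 3 spatial patients, 4 temporal pairs."""
    design = SimulationDesign(
        n_probes=4000,
        spatial_groups={"LGG": (2, 1.0), "MB": (1, 2.0)},
        temporal_groups={"LGG": (2, 1.0), "HGG": (2, 2.0)},
        spatial_dmps_per_biopsy=(20, 60),
        dmp_rate_per_day=0.15,
        relapse_interval_range=(100, 600),
    )
    return simulate(design, seed=11)


@pytest.fixture(scope="session")
def clean_study():
    """Noiseless, fully pure cohort: injected alterations are exactly
    recoverable, so calls can be compared with ground truth at equality."""
    design = SimulationDesign(
        n_probes=3000,
        spatial_groups={"LGG": (3, 1.0)},
        temporal_groups={"LGG": (3, 1.0)},
        spatial_dmps_per_biopsy=(30, 80),
        dmp_rate_per_day=0.2,
        relapse_interval_range=(100, 500),
        noise_sd=0.0,
        purity_range=(1.0, 1.0),
    )
    return simulate(design, seed=7)


@pytest.fixture()
def tiny_manifest():
    """Six regular probes spanning the annotation space plus one SNP probe."""
    return ProbeManifest.from_records([
        ("cg01", "chr1", 100, {"TSS200"}, "Island", False),
        ("cg02", "chr1", 150, {"Body"}, "OpenSea", False),
        ("cg03", "chr1", 250, set(), "OpenSea", False),
        ("cg04", "chr2", 100, {"Body", "3UTR"}, "Shore", False),
        ("cg05", "chr2", 200, set(), "Shelf", False),
        ("cg06", "chr2", 300, {"1stExon"}, "Island", False),
        ("rs01", "chr2", 400, set(), "OpenSea", True),
    ])


@pytest.fixture()
def tiny_beta():
    values = pd.DataFrame(
        {
            "S1": [0.0, 0.50, 0.20, 0.10, 0.90, 0.40, 0.05],
            "S2": [1.0, 0.60, 0.50, 0.10, 0.20, 0.45, 0.06],
        },
        index=pd.Index(
            ["cg01", "cg02", "cg03", "cg04", "cg05", "cg06", "rs01"],
            name="probe_id",
        ),
    )
    return BetaMatrix(values)


def random_beta(rng, n_probes, samples):
    values = pd.DataFrame(
        rng.random((n_probes, len(samples))),
        index=pd.Index([f"cg{i:05d}" for i in range(n_probes)], name="probe_id"),
        columns=list(samples),
    )
    return BetaMatrix(values)
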