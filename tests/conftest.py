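import numpy as np
import pandas as pd
import pytest

from octempo import CountMatrix, SimulationConfig, generate_timecourse


def make_count_matrix(counts: np.ndarray, donors, days, genes=None) -> CountMatrix:
    counts = np.asarray(counts)
    samples = [f"D{d}_T{t:g}" for d, t in zip(donors, days)]
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        pd.DataFrame(
            {"donor": [f"D{d}" for d in donors], "day": list(days)},
            index=pd.Index(samples, name="sample"),
        ),
    )


@pytest.fixture(scope="session")
def planted_world():
    """The reference synthetic time course: 2000 genes, 8 donors, days
    0/2/5/9, NB dispersion 0.05, peak effect 2 log2 units, half null."""
    cfg = SimulationConfig(
        n_genes=2000,
        n_donors=8,
        effect_log2fc=2.0,
        nb_dispersion=0.05,
        frac_null=0.5,
        seed=1,
    )
    cm, truth = generate_timecourse(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def null_world():
    """A fully null time course for calibration checks."""
    cfg = SimulationConfig(
        n_genes=5000,
        n_donors=8,
        effect_log2fc=0.0,
        frac_null=1.0,
        frac_discordant=0.0,
        nb_dispersion=0.05,
        seed=7,
    )
    cm, truth = generate_timecourse(cfg)
    return cfg, cm, truth
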