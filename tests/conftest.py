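import numpy as np
import pandas as pd
import pytest

from mirpair import PairedExpressionSet, SimulationConfig, simulate_paired_counts


def make_paired_set(values: np.ndarray, n_subjects: int, feature_ids=None) -> PairedExpressionSet:
    """Wrap a (features x 2*n) array as a paired set, columns ordered N,T per subject."""
    subjects = [f"S{i:02d}" for i in range(n_subjects)]
    samples = [f"{s}-{t}" for s in subjects for t in ("N", "T")]
    if feature_ids is None:
        feature_ids = [f"F{i:03d}" for i in range(values.shape[0])]
    return PairedExpressionSet(
        values=pd.DataFrame(values, index=feature_ids, columns=samples),
        subject_of=pd.Series({s: s.rsplit("-", 1)[0] for s in samples}),
        tissue_of=pd.Series({s: ("normal" if s.endswith("N") else "carcinoma") for s in samples}),
    )


@pytest.fixture(scope="session")
def small_study():
    """A 30-subject study with one planted DE gene and one planted association."""
    config = SimulationConfig(
        n_subjects=30,
        n_genes=40,
        n_mirnas=12,
        seed=101,
        tumor_log_fc=np.r_[np.log(3.0), np.zeros(39)],
        planted_beta={("G0000", "hsa-miR-1000"): -0.6},
        noise_sd=0.8,
    )
    counts, truth = simulate_paired_counts(config)
    return config, counts, truth
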