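import numpy as np
import pandas as pd
import pytest

from dielprot.io import LfqMatrix, SampleMeta, log_normalize, make_log_matrix
from dielprot.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort with every protein class represented."""
    cfg = SimConfig(n_proteins=300, seed=42)
    raw, meta, truth = generate(cfg)
    return cfg, raw, meta, truth


@pytest.fixture(scope="session")
def control_norm(small_cohort):
    """Log2 matrix restricted to control runs, with control metadata."""
    _, raw, meta, _ = small_cohort
    cm = meta.select(group="control")
    keep = [r for r in raw.run_ids if r in set(cm.run_ids)]
    return log_normalize(LfqMatrix(raw.intensity[keep])), cm


def toy_meta(n_day=3, n_night=3, n_reps=2):
    rows = []
    for i in range(n_day + n_night):
        dn = "day" if i < n_day else "night"
        tod = 13.0 + i if dn == "day" else (1.0 + i) % 24
        for r in range(n_reps):
            rows.append({"run_id": f"S{i}_r{r}", "subject_id": f"S{i}",
                         "group": "control", "daynight": dn,
                         "time_of_death": tod})
    return SampleMeta(pd.DataFrame(rows))


def toy_log_matrix(meta, n_proteins=20, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(27, 2, (n_proteins, len(meta.run_ids)))
    idx = pd.Index([f"P{i:03d}" for i in range(n_proteins)], name="protein_id")
    return make_log_matrix(pd.DataFrame(vals, index=idx, columns=meta.run_ids))
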