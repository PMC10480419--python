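import numpy as np
import pandas as pd
import pytest

import modelfidelity as mf


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (3 tissues, 2000 genes) at seed 1, with TPM."""
    counts, meta, truth = mf.simulate_cohort(mf.default_config(seed=1))
    tpm = mf.counts_to_tpm(counts)
    return {"counts": counts, "meta": meta, "truth": truth, "tpm": tpm,
            "log": mf.log_transform(tpm)}


@pytest.fixture(scope="session")
def zero_drift_cohort():
    """Noise-free, zero-drift cohort: models equal their origin tumor-cell
    profile up to near-Poisson counting noise."""
    counts, meta, truth = mf.simulate_cohort(mf.zero_drift_config(seed=1))
    return {"counts": counts, "meta": meta, "truth": truth,
            "tpm": mf.counts_to_tpm(counts)}


@pytest.fixture()
def tiny_counts():
    """A small hand-made counts matrix with lengths."""
    values = pd.DataFrame(
        [[10.0, 0.0, 3.0], [10.0, 5.0, 1.0], [0.0, 5.0, 2.0]],
        index=["ENSG1", "ENSG2", "ENSG3"],
        columns=["s1", "s2", "s3"],
    )
    lengths = pd.Series([1000.0, 2000.0, 500.0], index=values.index)
    return mf.ExpressionMatrix(values, mf.Unit.counts, lengths)


def make_metadata(rows):
    return mf.SampleMetadata(pd.DataFrame(rows))
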