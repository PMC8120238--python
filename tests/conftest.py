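import warnings

import numpy as np
import pandas as pd
import pytest

from smirnet import datagen, normalize
from smirnet.matrix import ExpressionMatrix


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across tests (seed 7)."""
    config = datagen.SimConfig(seed=7)
    counts, annotation, samples, truth = datagen.simulate_dataset(config)
    mirnas, targets, truth = datagen.simulate_sequences(config, truth)
    return {
        "config": config,
        "counts": counts,
        "annotation": annotation,
        "samples": samples,
        "truth": truth,
        "mirnas": mirnas,
        "targets": targets,
    }


@pytest.fixture(scope="session")
def normalized_default(default_dataset):
    """Normalized expression for the shared dataset."""
    d = default_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = normalize.rpkm(
            d["counts"],
            d["annotation"],
            mapped_reads_millions=d["samples"]["mapped_reads"] / 1e6,
        )
        log2 = normalize.log2_transform(r)
        fit, norm = normalize.fit_mixed_model(log2, d["samples"])
    return {"rpkm": r, "log2": log2, "fit": fit, "normalized": norm}


def toy_matrix(values, stage="normalized", transcripts=None, samples=None):
    values = np.asarray(values, dtype=float)
    transcripts = transcripts or [f"t{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=transcripts, columns=samples), stage
    )
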