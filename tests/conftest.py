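import numpy as np
import pandas as pd
import pytest

from humisig import (
    ExpressionMatrix,
    MixtureDesign,
    generate_annotation,
    generate_bulk,
    generate_profiles,
    generate_purified,
)


@pytest.fixture(scope="session")
def small_design():
    """Small but structurally faithful design for fast module tests."""
    return MixtureDesign(n_genes=600, markers_per_type=20, n_bulk_samples=60,
                         seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_design):
    """Profiles/annotation/bulk/purified plus truth for the small design."""
    ann = generate_annotation(small_design)
    profiles, truth = generate_profiles(small_design)
    bulk, proportions = generate_bulk(profiles, small_design, ann, truth=truth)
    purified = generate_purified(profiles, small_design)
    return {
        "design": small_design,
        "annotation": ann,
        "profiles": profiles,
        "truth": truth,
        "bulk": bulk,
        "proportions": proportions,
        "purified": purified,
    }


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(0)
    vals = rng.gamma(2.0, 2.0, size=(30, 6))
    genes = [f"g{i:02d}" for i in range(30)]
    samples = [f"s{i}" for i in range(6)]
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))


def make_log_matrix(values, prefix="s"):
    """Wrap a 2-D array as a log2-scale ExpressionMatrix with generated ids."""
    values = np.asarray(values, dtype=float)
    genes = [f"g{i:03d}" for i in range(values.shape[0])]
    samples = [f"{prefix}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale="log2"
    )
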