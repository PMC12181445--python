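import anndata as ad
import numpy as np
import pandas as pd
import pytest

from senskin import SignedGeneSet, builtin_senskin


@pytest.fixture(scope="session")
def senskin_set() -> SignedGeneSet:
    return builtin_senskin()


def make_adata(X, cell_types=None, conditions=None, samples=None, genes=None):
    """Build a small AnnData from a dense array plus optional metadata."""
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    obs["cell_type"] = cell_types if cell_types is not None else ["t"] * n
    obs["condition"] = conditions if conditions is not None else ["a"] * n
    obs["sample_id"] = samples if samples is not None else ["s1"] * n
    var = pd.DataFrame(index=genes if genes is not None else [f"g{j}" for j in range(g)])
    return ad.AnnData(X=X, obs=obs, var=var)
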