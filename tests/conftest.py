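import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from aspen.datasets import ExpressionDataset, GeneSetCollection, lognormalize


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """4 genes x 6 cells, 3 donors with known ages, 2 cell types."""
    counts = sp.csr_matrix(
        np.array(
            [
                [2, 0, 8, 1, 0, 3],
                [0, 5, 0, 2, 1, 0],
                [1, 1, 1, 1, 1, 1],
                [7, 4, 1, 0, 6, 6],
            ]
        )
    )
    cells = pd.DataFrame(
        dict(
            barcode=[f"BC{i}" for i in range(1, 7)],
            donor_id=["D1", "D1", "D2", "D2", "D3", "D3"],
            celltype_major=["T"] * 4 + ["CAF"] * 2,
            celltype_minor=["CD4", "CD8", "CD4", "CD8", "iCAF", "iCAF"],
        )
    )
    donors = pd.DataFrame(
        dict(donor_id=["D1", "D2", "D3"], age=[40.0, 50.0, 60.0], subtype="TNBC")
    )
    return ExpressionDataset.from_parts(
        counts, ["GA", "GB", "GC", "GD"], cells["barcode"].tolist(), cells, donors
    )


@pytest.fixture
def toy_lognorm(toy_dataset) -> ExpressionDataset:
    return lognormalize(toy_dataset)


@pytest.fixture
def small_sets() -> GeneSetCollection:
    return GeneSetCollection({"S1": ["GA", "GB"], "S2": ["GC", "GD"]}, provenance="toy")
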