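import numpy as np
import pandas as pd
import pytest

from spotsplit import synthetic as syn


@pytest.fixture(scope="session")
def small_tissue():
    """A compact niche-structured tissue reused across modules."""
    return syn.generate_tissue(
        n_cells=1200, n_types=4, n_genes=60, n_markers=12,
        field_size=(300.0, 300.0), spatial_structure="niches", seed=7,
    )


@pytest.fixture(scope="session")
def small_grid():
    return syn.GridConfig(n_channels_a=10, n_channels_b=10, channel_width=16.0, pitch=20.0, origin=(60.0, 60.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_spot_matrix(counts, pixel_size=10.0, pitch=None, origin=(5.0, 5.0)):
    """Wrap a dense counts array in a SpotExpressionMatrix on a square grid."""
    from spotsplit.deconvolution import SpotExpressionMatrix

    counts = np.asarray(counts, dtype=float)
    n_spots, n_genes = counts.shape
    side = int(np.ceil(np.sqrt(n_spots)))
    pitch = pitch if pitch is not None else pixel_size
    rows = np.arange(n_spots) // side
    cols = np.arange(n_spots) % side
    spots = pd.DataFrame(
        {
            "spot_id": [f"s{i}" for i in range(n_spots)],
            "row": rows,
            "col": cols,
            "x": origin[0] + cols * pitch,
            "y": origin[1] + rows * pitch,
        }
    )
    genes = [f"G{j:03d}" for j in range(n_genes)]
    return SpotExpressionMatrix(counts=counts, spots=spots, genes=genes, pixel_size=pixel_size, pitch=pitch)
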