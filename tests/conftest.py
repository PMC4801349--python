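import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_tree_table(c130, ir5=None, weight=None, status=None, species=None,
                    plot_id="P0"):
    """Assemble a tree table from parallel per-tree value lists."""
    n = len(c130)
    return pd.DataFrame(
        {
            "plot_id": [plot_id] * n,
            "tree_id": [f"{plot_id}-T{i}" for i in range(n)],
            "species": species if species is not None else ["FagSyl"] * n,
            "c130_cm": np.asarray(c130, dtype=float),
            "ir5_cm": np.asarray(
                ir5 if ir5 is not None else [1.0] * n, dtype=float
            ),
            "weight_per_ha": np.asarray(
                weight if weight is not None else [100.0] * n, dtype=float
            ),
            "status": status if status is not None else ["alive"] * n,
        }
    )


@pytest.fixture
def toy_plot():
    """Four alive trees on one plot, round numbers."""
    return make_tree_table([40.0, 60.0, 80.0, 100.0], ir5=[0.5, 0.8, 1.0, 1.2])
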