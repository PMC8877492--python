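import io

import numpy as np
import pytest
from skbio import TreeNode

from haptonet import (
    SyntheticDesign,
    ZotuTable,
    generate_counts,
    generate_metadata,
)


@pytest.fixture
def toy_tree():
    """Three-leaf rooted tree: ((A:1,B:1):1,C:2);"""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture(scope="session")
def small_dataset():
    """28-sample, 60-ZOTU synthetic dataset with mild planted structure."""
    design = SyntheticDesign(
        n_stations=14,
        n_zotus=60,
        depth_range=(2000, 5000),
        habitat_effect=1.5,
        temperature_effect=0.8,
        n_surface_enriched=10,
        n_scm_enriched=5,
        module_spec=[("surface", [f"ZOTU_{k}" for k in range(1, 9)], 0.9)],
        seed=42,
    )
    meta = generate_metadata(design)
    table, truth = generate_counts(design, meta)
    return design, meta, table, truth


@pytest.fixture
def tiny_table():
    return ZotuTable(
        counts=np.array([[6, 4], [3, 7]]),
        sample_ids=["s1", "s2"],
        zotu_ids=["ZOTU_1", "ZOTU_2"],
        taxonomy=["k;p;c;g1", "k;p;c;g2"],
    )
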