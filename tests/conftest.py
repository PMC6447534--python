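import numpy as np
import pandas as pd
import pytest

from spatcorr import TranscriptTable
from spatcorr.strauss import PointPattern, Window
from spatcorr.synthetic import GeneSpec, TissueSpec, make_tissue


@pytest.fixture
def small_table() -> TranscriptTable:
    """Six transcripts of three genes plus one negative control read."""
    records = pd.DataFrame(
        {
            "x": [0.0, 10.0, 20.0, 30.0, 40.0, 50.0],
            "y": [0.0, 0.0, 5.0, 5.0, 10.0, 10.0],
            "gene": ["A", "A", "B", "B", "C", "NC1"],
            "quality": [0.54, 0.55, 0.90, 0.20, 1.0, 0.8],
        }
    )
    return TranscriptTable(records, ("A", "B", "C"), frozenset({"NC1"}))


@pytest.fixture(scope="session")
def planted_tissue():
    """Five well-separated islets, a proximal gene, and a uniform gene."""
    spec = TissueSpec(
        window=Window.square(0.0, 0.0, 2000.0),
        islets=(
            (-700.0, -700.0, 60.0),
            (-650.0, 650.0, 45.0),
            (0.0, 0.0, 80.0),
            (700.0, -650.0, 50.0),
            (650.0, 700.0, 70.0),
        ),
        genes=(
            GeneSpec("SST", "islet_marker", 200),
            GeneSpec("GLUC", "islet_marker", 200),
            GeneSpec("INS", "islet_marker", 200),
            GeneSpec("NEAR", "islet_proximal", 1200, scale=25.0),
            GeneSpec("FAR", "uniform", 1200),
        ),
        nuclei_count=300,
        seed=12,
    )
    return spec, make_tissue(spec)


@pytest.fixture
def null_pattern() -> PointPattern:
    """Two independent uniform types in a disc: the no-interaction case."""
    win = Window.circle(0.0, 0.0, 150.0)
    rng = np.random.default_rng(42)
    xy = np.vstack([win.sample_uniform(500, rng), win.sample_uniform(500, rng)])
    types = np.array(["A"] * 500 + ["B"] * 500, dtype=object)
    return PointPattern(xy, types, win)
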