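import numpy as np
import pandas as pd
import pytest

from elementdm import qc_filter, segmentation
from elementdm.data_io import BetaMatrix
from elementdm.synthetic_data import SimulationConfig, generate_all


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at the default 5 vs 5 design."""
    return generate_all(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def qc_dataset(default_dataset):
    """The default dataset after detection masking and probe filtering."""
    ds = default_dataset
    bm = qc_filter.mask_low_detection(ds.beta)
    bm, report = qc_filter.filter_probes(bm, ds.annotation.manifest)
    return ds, bm, report


@pytest.fixture(scope="session")
def segmented_dataset(qc_dataset):
    """QC'd dataset with merged elements, segments and segment means."""
    ds, bm, _ = qc_dataset
    elements = segmentation.merge_states(ds.annotation.tracks)
    segments = segmentation.build_segments(
        elements, ds.annotation.manifest, set(bm.beta.index)
    )
    seg_meth = segmentation.summarize_segments(bm, segments)
    return ds, bm, elements, segments, seg_meth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def small_beta_matrix(values, groups=None, detection_p=None):
    """Helper building a BetaMatrix from a plain dict/array."""
    beta = pd.DataFrame(values)
    if groups is None:
        half = len(beta.columns) // 2
        groups = pd.Series(
            ["case"] * half + ["control"] * (len(beta.columns) - half),
            index=beta.columns,
        )
    detp = None if detection_p is None else pd.DataFrame(detection_p, index=beta.index, columns=beta.columns)
    return BetaMatrix(beta, detp, groups)
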