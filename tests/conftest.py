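import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")

from metabosig import io  # noqa: E402


@pytest.fixture
def tiny_study() -> io.PeakAreaStudy:
    """3 metabolites x 4 samples, one missing cell, one batch."""
    raw = pd.DataFrame(
        {
            "s1": [2.0, 1.0, 5.0],
            "s2": [4.0, 1.2, 5.0],
            "s3": [6.0, np.nan, 5.0],
            "s4": [8.0, 0.5, 5.0],
        },
        index=pd.Index(["m1", "m2", "m3"], name="metabolite_id"),
    )
    idx = pd.Index(raw.columns)
    return io.PeakAreaStudy(
        tissue="diaphragm",
        raw=raw,
        group=pd.Series(["D0", "D0", "D5", "D5"], index=idx),
        batch=pd.Series(["B1", "B1", "B1", "B1"], index=idx),
    )


@pytest.fixture
def tiny_annotations() -> pd.DataFrame:
    ann = pd.DataFrame(
        {
            "name": ["leucine", "X-23639", "citrate"],
            "super_pathway": ["Amino Acid", "Xenobiotics", "Energy"],
            "sub_pathway": [
                "Leucine, Isoleucine and Valine Metabolism",
                "Chemical",
                "TCA Cycle",
            ],
            "is_named": [True, False, True],
        },
        index=pd.Index(["m1", "m2", "m3"], name="metabolite_id"),
    )
    return ann
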