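import numpy as np
import pandas as pd
import pytest

from ecmetab import Feature, FeatureTable, SampleInfo


@pytest.fixture
def toy_table() -> FeatureTable:
    """3 features x 4 samples (2 biological, 1 blank, 1 QC)."""
    feats = [
        Feature("F1", 180.0634, 2.5, "HILIC+"),
        Feature("F2", 228.0746, 3.1, "HILIC+", annotation="2'-deoxyuridine"),
        Feature("F3", 760.5851, 8.2, "RPLC+"),
    ]
    samps = [
        SampleInfo("B1", "biological", dose_uM=0.0, experiment_id="E1",
                   injection_order=2),
        SampleInfo("B2", "biological", dose_uM=0.0, experiment_id="E1",
                   injection_order=3),
        SampleInfo("K1", "blank", experiment_id="E1", injection_order=4),
        SampleInfo("Q1", "qc", experiment_id="E1", injection_order=1),
    ]
    ab = np.array([
        [100.0, 110.0, 50.0, 90.0],
        [200.0, 210.0, np.nan, 180.0],
        [10.0, 12.0, 11.0, 11.0],
    ])
    return FeatureTable.from_records(feats, samps, ab)


def make_blank_table(bio: np.ndarray, blank: np.ndarray,
                     mode: str = "HILIC+") -> FeatureTable:
    """Build a biological-vs-blank table from two (features x reps) blocks."""
    bio = np.atleast_2d(np.asarray(bio, dtype=float))
    blank = np.atleast_2d(np.asarray(blank, dtype=float))
    n = bio.shape[0]
    feats = [Feature(f"F{i}", 100.0 + i, 1.0 + 0.1 * i, mode)
             for i in range(n)]
    samps = ([SampleInfo(f"B{j}", "biological", dose_uM=0.0,
                         injection_order=j + 1)
              for j in range(bio.shape[1])]
             + [SampleInfo(f"K{j}", "blank",
                           injection_order=bio.shape[1] + j + 1)
                for j in range(blank.shape[1])])
    return FeatureTable.from_records(feats, samps, np.hstack([bio, blank]))
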