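import numpy as np
import pandas as pd
import pytest

from nascentflow.synthetic import (
    InteractomeSpikeDesign,
    LabelingModel,
    TranscriptAnnotation,
    simulate_interactome,
)


@pytest.fixture
def three_class_annotation():
    """One representative gene per length class at the default boundaries."""
    return [
        TranscriptAnnotation("G_short", 100, 1),
        TranscriptAnnotation("G_medium", 5000, 4, introns=((1000, 2000), (3000, 3500))),
        TranscriptAnnotation("G_long", 50000, 40),
    ]


@pytest.fixture
def labeling_model():
    return LabelingModel(
        labeling_time_min=10.0,
        conversion_rate_per_min=1e-3,
        background_error_rate=1e-4,
        labeled_fraction=1.0,
        seed=7,
    )


@pytest.fixture
def small_intensity_matrix():
    design = InteractomeSpikeDesign(
        n_proteins=50,
        bait_id="BAIT",
        n_replicates_per_condition=3,
        lognormal_sigma=0.15,
        spiked={"P01": -2.0, "P02": 2.0},
        seed=11,
    )
    return simulate_interactome(design)


def make_counts(records, sample="s1"):
    """records: iterable of (gene_id, readCount, tcReadCount)."""
    return pd.DataFrame(
        [(g, sample, rc, tc) for g, rc, tc in records],
        columns=["gene_id", "sample", "readCount", "tcReadCount"],
    )


def make_diff_table(log2fc, prefix="G", p=None):
    log2fc = np.asarray(log2fc, dtype=float)
    n = len(log2fc)
    if p is None:
        p = np.ones(n)
    sig = (np.asarray(p) < 0.05) & (np.abs(log2fc) >= 1)
    return pd.DataFrame(
        {
            "transcript_id": [f"{prefix}{i:04d}" for i in range(n)],
            "log2FC": log2fc,
            "p_value": p,
            "significant": sig,
            "direction": np.where(~sig, "none", np.where(log2fc > 0, "up", "down")),
        }
    )
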