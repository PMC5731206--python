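import numpy as np
import pandas as pd
import pytest

import sertoliseq as sq


@pytest.fixture(scope="session")
def small_truth() -> sq.SyntheticTruth:
    """Small default-configuration transcript universe."""
    return sq.generate_truth(400, seed=11)


@pytest.fixture(scope="session")
def noiseless_truth() -> sq.SyntheticTruth:
    cfg = sq.TruthConfig(cv=0.0)
    return sq.generate_truth(400, cfg, seed=11)


@pytest.fixture(scope="session")
def ablation_matrix(small_truth) -> sq.ExpressionMatrix:
    return sq.simulate_ablation_study(small_truth, n_replicates=5, seed=12)


@pytest.fixture(scope="session")
def ablation_contrasts(ablation_matrix):
    bus = sq.compute_group_contrast(ablation_matrix, "control", "busulfan")
    dtx = sq.compute_group_contrast(ablation_matrix, "busulfan", "busulfan_dtx")
    return bus, dtx


@pytest.fixture()
def tiny_matrix() -> sq.ExpressionMatrix:
    """3 transcripts x 2 groups x 3 replicates with hand-set values."""
    rng = np.random.default_rng(5)
    values = pd.DataFrame(
        rng.uniform(1, 100, size=(3, 6)),
        index=pd.Index(["T1", "T2", "T3"], name="transcript_id"),
        columns=["c1", "c2", "c3", "t1", "t2", "t3"],
    )
    meta = pd.DataFrame(
        {
            "group": ["control"] * 3 + ["treated"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=pd.Index(["c1", "c2", "c3", "t1", "t2", "t3"], name="sample_id"),
    )
    symbols = pd.Series(["Amh", "Sox9", pd.NA], index=values.index, dtype="string")
    return sq.ExpressionMatrix(values, meta, symbols)


def make_contrast_frame(rows: dict) -> pd.DataFrame:
    """Build a standard contrast frame from {id: (mean_ref, mean_alt, p, q)}."""
    ids = pd.Index(list(rows), name="transcript_id")
    mean_ref = np.array([rows[t][0] for t in ids], dtype=float)
    mean_alt = np.array([rows[t][1] for t in ids], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_ref > 0, mean_alt / mean_ref, np.nan)
        l2 = np.where((mean_ref > 0) & (mean_alt > 0), np.log2(fc), np.nan)
    return pd.DataFrame(
        {
            "gene_symbol": pd.Series(list(ids), index=ids, dtype="string"),
            "mean_ref": mean_ref,
            "mean_alt": mean_alt,
            "fold_change": fc,
            "log2fc": l2,
            "p_value": [rows[t][2] for t in ids],
            "q_value": [rows[t][3] for t in ids],
        },
        index=ids,
    )
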