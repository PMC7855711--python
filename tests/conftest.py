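import numpy as np
import pandas as pd
import pytest

from cernax.datatypes import ContrastSpec, ExpressionDataset


def make_dataset(values: np.ndarray, feature_ids, sample_ids, biotypes=None,
                 severity=None, dataset_id="DS1") -> ExpressionDataset:
    """Assemble an ExpressionDataset from raw pieces (test helper)."""
    values = pd.DataFrame(np.asarray(values, dtype=float),
                          index=list(feature_ids), columns=list(sample_ids))
    if biotypes is None:
        biotypes = {f: "mRNA" for f in feature_ids}
    ann = {}
    if severity is not None:
        ann["severity"] = list(severity)
    annotations = pd.DataFrame(ann, index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionDataset(
        dataset_id=dataset_id, values=values,
        sample_annotations=annotations,
        feature_biotypes=pd.Series(biotypes),
    )


@pytest.fixture
def severity_contrast():
    return ContrastSpec(clinical_feature="severity",
                        severe_levels=frozenset({"severe"}),
                        mild_levels=frozenset({"mild"}))


@pytest.fixture
def small_dataset():
    rng = np.random.default_rng(11)
    n = 40
    samples = [f"S{i:02d}" for i in range(n)]
    values = rng.normal(8, 1, size=(4, n))
    return make_dataset(
        values, ["G1", "G2", "L1", "M1"], samples,
        biotypes={"G1": "mRNA", "G2": "mRNA", "L1": "lncRNA", "M1": "miRNA"},
        severity=["severe"] * (n // 2) + ["mild"] * (n // 2),
    )
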