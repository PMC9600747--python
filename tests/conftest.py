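import numpy as np
import pandas as pd
import pytest

import ercdc
from ercdc import nsc, scoring
from ercdc.batch import combat_merge
from ercdc.preprocess import filter_informative


@pytest.fixture(scope="session")
def default_cfg() -> ercdc.SimConfig:
    """The default study conditions, seeded."""
    return ercdc.SimConfig(seed=1)


@pytest.fixture(scope="session")
def small_cfg() -> ercdc.SimConfig:
    """A scaled-down configuration for fast structural tests."""
    return ercdc.SimConfig(n_genes=400, n_celltypes=3, n_replicates_per_type=8,
                           n_signature_genes_per_type=12, n_tumors=120, seed=7)


@pytest.fixture(scope="session")
def discovery(default_cfg):
    """The marker-discovery chain run once at the default conditions."""
    expr, ann, truth = ercdc.generate_reference_profiles(default_cfg)
    merged = combat_merge([filter_informative(expr)], ann)
    labels = ann.loc[merged.columns, "cell_type"]
    model = nsc.train_centroids(merged, labels)
    cv = nsc.cross_validate(merged, labels, k_folds=10, seed=default_cfg.seed)
    delta = nsc.select_threshold(cv, "ercDC")
    markers = nsc.extract_markers(model, delta, "ercDC")
    ref_cols = merged.columns[(labels == "ercDC").to_numpy()]
    signature = scoring.build_reference_signature(merged[ref_cols], markers)
    return {
        "cfg": default_cfg, "expr": expr, "ann": ann, "truth": truth,
        "merged": merged, "labels": labels, "model": model, "cv": cv,
        "delta": delta, "markers": markers, "signature": signature,
    }


@pytest.fixture(scope="session")
def cohort(discovery):
    """Bulk cohort scored with the discovered signature, plus ground truth."""
    cfg = discovery["cfg"]
    bulk, ann, truth = ercdc.generate_bulk_cohort(cfg, discovery["truth"])
    scores = scoring.ercdc_score(bulk, discovery["signature"])
    return {"bulk": bulk, "ann": ann, "truth": truth, "scores": scores}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_expr(values, genes=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=samples)
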