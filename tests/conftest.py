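import warnings

import numpy as np
import pandas as pd
import pytest

import molo

# the gamma-family identity link is the intended noise-curve model; statsmodels
# flags it as outside the family's canonical domain
warnings.filterwarnings("ignore", message="The Identity link function does not respect.*")


def make_ct_matrix(values, detected=None, populations=None, housekeepers=("HK1",)):
    """Small hand-built CtMatrix for unit tests."""
    values = pd.DataFrame(values)
    values.index = [f"cell{i}" for i in range(values.shape[0])] if values.index.dtype.kind == "i" else values.index
    if detected is None:
        detected = pd.DataFrame(True, index=values.index, columns=values.columns)
    else:
        detected = pd.DataFrame(detected, index=values.index, columns=values.columns)
    cell_meta = pd.DataFrame(
        {
            "population_label": populations if populations is not None else "pop",
            "well_id": list(values.index),
        },
        index=values.index,
    )
    assay_meta = pd.DataFrame(
        {"is_housekeeper": [c in set(housekeepers) for c in values.columns]},
        index=pd.Index(values.columns, name="gene_name"),
    )
    return molo.CtMatrix(values, detected, cell_meta, assay_meta, lod_ct=40.0)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced design for fast unit tests: 5 strategies x 60 cells."""
    return molo.SimSpec(cells_per_strategy=60, seed=11)


@pytest.fixture(scope="session")
def qpcr_pipeline(small_spec):
    """Simulated panel run through ΔCt, exclusions, embedding and MolO call."""
    ct, truth = molo.simulate_qpcr(small_spec)
    dct = molo.delta_ct_normalize(ct, housekeepers=["Ubc", "Polr2a"])
    dct = molo.apply_gene_exclusions(dct, ["Cdkn2a", "Egfl7"])
    emb = molo.embed_tsne(dct.values, perplexity=20, seed=0)
    weights = molo.WeightVector(pd.Series(0.5, index=small_spec.strategies))
    assign = molo.identify_molo(emb, dct.populations, weights, k=15, n_perm=500, seed=0)
    return {"spec": small_spec, "ct": ct, "truth": truth, "dct": dct, "emb": emb,
            "weights": weights, "assign": assign}


@pytest.fixture(scope="session")
def default_pipeline():
    """One full-size pipeline run (the study conditions) shared across tests.

    Trains the cross-platform MolO classifier on the qPCR side so that
    transfer-dependent tests can score fresh RNA-seq cohorts.
    """
    spec = molo.SimSpec(seed=1)
    ct, truth = molo.simulate_qpcr(spec)
    dct = molo.delta_ct_normalize(ct, housekeepers=["Ubc", "Polr2a"])
    dct = molo.apply_gene_exclusions(dct, ["Cdkn2a", "Egfl7"])
    emb = molo.embed_tsne(dct.values, perplexity=30, seed=0)
    weights = molo.WeightVector(pd.Series(0.5, index=spec.strategies))
    assign = molo.identify_molo(emb, dct.populations, weights, seed=0)

    truth_seq = molo.simulate_cell_truth(spec, 92, prefix="SEQ")
    cm = molo.simulate_counts(spec, truth_seq)
    sf = molo.size_factors(cm)
    fit = molo.fit_technical_noise(cm, sf, min_mean=10)
    hvg = molo.call_variable_genes(cm, sf, fit, fdr=0.1)
    panel = [g for g in dct.values.columns if g in set(hvg.index[hvg["variable"]])]
    clf = molo.train_molo_classifier(dct, assign, panel, n_trees=500, seed=0, strategy="HSC1")
    return {"spec": spec, "ct": ct, "truth": truth, "dct": dct, "emb": emb,
            "weights": weights, "assign": assign, "truth_seq": truth_seq,
            "counts": cm, "sf": sf, "fit": fit, "hvg": hvg, "panel": panel, "clf": clf}
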