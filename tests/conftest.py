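"""Shared fixtures: small synthetic datasets and one mid-size fitted atlas.

Everything is generated at test time from the package's own simulator;
expensive artifacts (the embedded, clustered, curve-fitted atlas) are
session-scoped so the trajectory and statistics tests share one fit.
"""

import numpy as np
import pandas as pd
import pytest

from morphotraj.simulate import (
    AtlasSimConfig,
    CompoundEffect,
    PlateSimConfig,
    Treatment,
    simulate_atlas,
    simulate_plate,
)


@pytest.fixture(scope="session")
def small_atlas():
    """Light atlas for unit tests: 20 timepoints x 60 cells, 60 features."""
    cfg = AtlasSimConfig(n_timepoints=20, cells_per_timepoint=60, n_features=60, seed=11)
    table, truth = simulate_atlas(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_plate():
    """Screening plate with a differentiation-mimicking hit, an inert
    compound, doublets and QC-failing images."""
    cfg = AtlasSimConfig(n_timepoints=20, cells_per_timepoint=60, n_features=60, seed=11)
    plate_cfg = PlateSimConfig(
        treatments=(
            Treatment("mimic", 10.0, CompoundEffect(accel=1.0, ec50=0.01), n_wells=3),
            Treatment("null", 10.0, CompoundEffect(), n_wells=3),
        ),
        cells_per_well=80,
        doublet_rate=0.05,
        qc_fail_rate=0.1,
        seed=5,
    )
    table, truth = simulate_plate(cfg, plate_cfg)
    return plate_cfg, table, truth


@pytest.fixture(scope="session")
def fitted_atlas():
    """Mid-size atlas taken through embedding, clustering and curve fitting.

    Shared by trajectory-recovery, projection-contract and statistics
    tests; 20 timepoints x 250 cells, 200 features.
    """
    from morphotraj.preprocess import anchor_standardize, fit_embedding
    from morphotraj.trajectory import (
        PrincipalTrajectory,
        cluster_cells,
        infer_lineages,
        select_backbone,
    )

    cfg = AtlasSimConfig(n_timepoints=20, cells_per_timepoint=250, n_features=200, seed=1)
    table, truth = simulate_atlas(cfg)
    merged, _ = anchor_standardize([table], ["tc"])
    emb_model, emb = fit_embedding(merged, n_pcs=10, seed=7)
    cm = cluster_cells(emb, seed=7)
    timepoints = merged.data["timepoint"].to_numpy(dtype=float)
    start, ends = select_backbone(cm, timepoints)
    tree = infer_lineages(cm, start, ends)
    results = PrincipalTrajectory(emb, cm, tree).fit()
    return {
        "config": cfg,
        "table": merged,
        "truth": truth,
        "embedding_model": emb_model,
        "embedding": emb,
        "cluster_model": cm,
        "tree": tree,
        "results": results,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
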