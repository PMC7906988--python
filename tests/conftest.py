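"""Shared fixtures: simulated studies reused across test modules.

Heavy simulations are session-scoped so each is generated once. Shuffle
counts use a 200-shuffle smoke setting for speed (the production default is
1,000); the calibration fixture keeps the full 1,000 shuffles because it
examines the null distribution itself.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import placecode as pc


@pytest.fixture(scope="session")
def smoke_params() -> pc.AnalysisParams:
    return pc.AnalysisParams(n_shuffles=200)


@pytest.fixture(scope="session")
def track_study(smoke_params):
    """Default synthetic study: 30-min track session, 100 tuned + 100
    untuned cells, classified."""
    cfg = dataclasses.replace(pc.SimConfig(), duration_s=1800.0, rng_seed=7)
    session, gt = pc.simulate_session(cfg)
    stats, full = pc.classify_population(session, smoke_params, seed=0)
    return {"session": session, "gt": gt, "stats": stats, "full": full,
            "config": cfg}


@pytest.fixture(scope="session")
def short_track_session():
    """Small 10-min track session (20 tuned + 20 untuned cells)."""
    cfg = dataclasses.replace(
        pc.SimConfig(), duration_s=600.0, n_place_cells=20,
        n_untuned_cells=20, rng_seed=1,
    )
    session, gt = pc.simulate_session(cfg)
    return session, gt


@pytest.fixture(scope="session")
def calibration_percentiles():
    """Shuffle percentiles of 200 untuned (homogeneous) cells, 1,000
    shuffles each, on a 10-min session."""
    cfg = dataclasses.replace(
        pc.SimConfig(), duration_s=600.0, n_place_cells=0,
        n_untuned_cells=200, rng_seed=21,
    )
    session, _ = pc.simulate_session(cfg)
    params = pc.AnalysisParams(n_shuffles=1000)
    stats, _ = pc.classify_population(session, params, seed=3)
    return stats["shuffle_percentile"].to_numpy()


@pytest.fixture(scope="session")
def remap_pair(smoke_params):
    """Two 15-min sessions in different environments with independent
    (remapped) fields; 103 tuned + 10 untuned cells, analyzed."""
    cfg = dataclasses.replace(
        pc.SimConfig(), duration_s=900.0, n_place_cells=103,
        n_untuned_cells=10, remap=True, recurrence_prob=1.0, rng_seed=13,
    )
    study = pc.simulate_study(cfg, 2, environments=["A", "B"])
    results = [
        pc.analyze_session(s, smoke_params, seed=100 + i)
        for i, (s, _) in enumerate(study)
    ]
    return {"study": study, "results": results}


@pytest.fixture(scope="session")
def ring_embedding():
    """Noiseless ring-tiling population (64 cells) embedded by cosine MDS."""
    theta = np.mod(np.arange(1500) * 0.24 * 360.0 / 86.4, 360.0)
    x = pc.noiseless_ring_population(theta, 64)
    emb = pc.embed_population(x)
    return {"theta": theta[emb.kept_frames], "emb": emb, "x": x}
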