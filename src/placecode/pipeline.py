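"""Pipeline composition: run every analysis stage on a (simulated or loaded)
study and collect a tidy results table.

Stages run in method order — rate maps and classification, cross-session
stability, lap-to-lap reliability, manifold embedding and decoding — each
gated by a flag. All randomness flows from a single seed; per-stage
sub-seeds are drawn from a seed sequence and recorded in a manifest, so the
same configuration and seed reproduce the table exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import AlignedSession
from .config import AnalysisParams
from .manifold import decode_position_cv, embed_population, manifold_dimensionality
from .ratemap import per_lap_maps
from .reliability import cell_rates, fit_cell_exponent
from .stability import SessionResult, analyze_session, cross_track_remapping, \
    pairwise_stats_table
from .errors import InsufficientDataError

logger = logging.getLogger("placecode")


@dataclass
class PipelineConfig:
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    run_stability: bool = True
    run_reliability: bool = True
    run_manifold: bool = True
    manifold_max_frames: int = 1500   # frames subsampled for the T x T MDS
    decode_dims: int = 3


@dataclass
class PipelineResult:
    table: pd.DataFrame               # long format: session, cell, metric, value
    session_results: list[SessionResult]
    pair_stats: pd.DataFrame | None
    seed_manifest: dict


def run_pipeline(
    sessions: list[AlignedSession],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run all enabled stages over a list of registered sessions."""
    config = config or PipelineConfig()
    params = config.params
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2 ** 31))
        for name, child in zip(
            ("classify", "manifold"), ss.spawn(2)
        )
    }
    records: list[dict] = []
    session_results: list[SessionResult] = []

    for s_idx, session in enumerate(sessions):
        logger.info("session %d: classifying %d cells", s_idx, session.n_cells)
        res = analyze_session(session, params, seed=stage_seeds["classify"] + s_idx)
        session_results.append(res)
        for _, row in res.stats.iterrows():
            for metric in ("spatial_info_bits_per_event", "shuffle_percentile",
                           "is_place_cell", "field_location_cm", "field_size"):
                records.append({
                    "session": s_idx, "cell": int(row["cell"]),
                    "metric": metric, "value": float(row[metric])
                    if not isinstance(row[metric], (bool, np.bool_))
                    else float(bool(row[metric])),
                })
        n_pc = int(res.stats["is_place_cell"].sum())
        logger.info("session %d: %d/%d place cells", s_idx, n_pc, len(res.stats))

        if config.run_reliability and session.arena == "circular_track":
            rates = cell_rates(session)
            laps = session.laps()
            for cell in range(session.n_cells):
                try:
                    fit = fit_cell_exponent(
                        per_lap_maps(session, cell, laps, params)
                    )
                    records.append({"session": s_idx, "cell": cell,
                                    "metric": "beta", "value": fit.beta})
                except InsufficientDataError:
                    pass
                records.append({
                    "session": s_idx, "cell": cell, "metric": "event_rate",
                    "value": float(rates["event_rate"][cell]),
                })

        if config.run_manifold:
            moving_idx = np.nonzero(session.moving)[0]
            stride = max(1, len(moving_idx) // config.manifold_max_frames)
            use = moving_idx[::stride]
            x = session.activity[use].T
            theta = session.theta[use]
            try:
                emb = embed_population(x)
                dim = manifold_dimensionality(emb, params.variance_threshold)
                records.append({"session": s_idx, "cell": -1,
                                "metric": "manifold_dim", "value": float(dim)})
                dec = decode_position_cv(
                    emb, theta[emb.kept_frames],
                    n_dims=min(config.decode_dims, emb.n_components),
                    k_folds=params.k_folds,
                )
                records.append({"session": s_idx, "cell": -1,
                                "metric": "decode_r", "value": dec.pearson_r})
            except InsufficientDataError as exc:
                logger.warning("session %d: manifold stage skipped (%s)",
                               s_idx, exc)

    pair_stats = None
    if config.run_stability and len(session_results) > 1:
        pair_stats = pairwise_stats_table(session_results)
        envs = [s.environment for s in sessions]
        for i in range(len(sessions)):
            for j in range(i + 1, len(sessions)):
                if envs[i] != envs[j]:
                    try:
                        rm = cross_track_remapping(
                            session_results[i], session_results[j], params
                        )
                        records.append({
                            "session": j, "cell": -1,
                            "metric": "cross_env_activity_correlation",
                            "value": rm.mean_activity_correlation,
                        })
                    except InsufficientDataError:
                        pass

    return PipelineResult(
        table=pd.DataFrame(records),
        session_results=session_results,
        pair_stats=pair_stats,
        seed_manifest={"seed": config.seed, **stage_seeds},
    )
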