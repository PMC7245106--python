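"""Per-patient end-to-end orchestration.

Sequences the stages in analysis order — connectivity, NMF denoising,
dissimilarity, temporal statistics, model classification — records the
parameters and input hashes of every stage, and persists intermediates.
Deterministic stages are bit-identical across reruns with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import dissimilarity as dsm
from . import models as mdl
from . import nmf
from . import temporal as tmp
from .connectivity import ConnectivityTimeSeries, assemble_cohort_matrix

logger = logging.getLogger("szpath")

__all__ = ["DEFAULT_CONFIG", "PatientRun", "run_patient"]

#: Analysis defaults: 10-s windows at 1-s steps, 2-s/1-s Welch segments,
#: 10,000 Mantel permutations, 0.25-d timescale grid with a 7-pair minimum,
#: 1,000 model simulations, and the 0.02185 good-match MSE threshold.
DEFAULT_CONFIG: dict[str, Any] = {
    "window_s": 10.0,
    "step_s": 1.0,
    "welch_win_s": 2.0,
    "welch_overlap_s": 1.0,
    "nmf_rank_min": 2,
    "nmf_rank_max": 20,
    "nmf_runs": 20,
    "nmf_max_iter": 500,
    "nmf_tol": 1e-6,
    "renorm_mode": "band",
    "mantel_permutations": 10000,
    "tcp_step_days": 0.25,
    "tcp_min_pairs": 7,
    "model_sims": 1000,
    "mse_threshold": mdl.MSE_GOOD_MATCH,
    "min_seizures": 6,
    "seed": 0,
}


@dataclass
class PatientRun:
    """All stage outputs of one per-patient run, plus provenance."""

    patient_id: str
    config: dict[str, Any]
    seizure_ids: list[str] = field(default_factory=list)
    times: np.ndarray | None = None
    nmf_model: nmf.NMFModel | None = None
    rank_selection: nmf.RankSelection | None = None
    denoised: list[ConnectivityTimeSeries] = field(default_factory=list)
    D: dsm.DissimilarityMatrix | None = None
    TD: tmp.TemporalDistanceMatrix | None = None
    mantel: tmp.MantelResult | None = None
    tcp: tmp.TemporalCorrelationPattern | None = None
    likelihoods: mdl.ModelLikelihoods | None = None
    classification: mdl.DynamicsClass | None = None
    input_hashes: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def summary(self) -> dict[str, Any]:
        out: dict[str, Any] = {"patient_id": self.patient_id, "config": self.config}
        if self.mantel is not None:
            out["mantel"] = {"rho": self.mantel.rho, "p": self.mantel.p, "n_perm": self.mantel.n_perm}
        if self.tcp is not None:
            out["tcp"] = {
                "timescales": self.tcp.timescales.tolist(),
                "rho": self.tcp.rho.tolist(),
                "valid": self.tcp.valid.astype(int).tolist(),
            }
        if self.likelihoods is not None:
            ml = self.likelihoods
            out["likelihoods"] = {"L_l": ml.L_l, "L_c": ml.L_c, "L_lc": ml.L_lc, "L_n": ml.L_n}
        if self.classification is not None:
            out["classification"] = self.classification.label
            out["rationale"] = self.classification.rationale
        if self.rank_selection is not None:
            out["nmf_rank"] = self.rank_selection.rank
        out["input_hashes"] = self.input_hashes
        return out


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _timed(run: PatientRun, stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            dt = time.perf_counter() - self.t0
            run.stage_seconds[stage] = dt
            logger.info("stage %s finished in %.2f s", stage, dt)

    return _Timer()


def run_patient(
    seizures: Sequence[ConnectivityTimeSeries],
    times_days: np.ndarray,
    patient_id: str = "patient",
    config: dict[str, Any] | None = None,
    allow_few: bool = False,
    denoise: bool = True,
    out_dir: str | Path | None = None,
) -> PatientRun:
    """Run the full per-patient analysis on connectivity time courses.

    ``seizures`` may come from `connectivity.seizure_connectivity` on real
    recordings or from the synthetic generator; ``times_days`` are onset
    times in fractional days since the first seizure.  Fewer than the
    configured minimum of six seizures is an inclusion error unless
    ``allow_few``.  Stage errors propagate with a stage-tagged message.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    seizures = list(seizures)
    times_days = np.asarray(times_days, dtype=float)
    if len(seizures) != times_days.size:
        raise ValueError("one onset time per seizure required")
    if len(seizures) < cfg["min_seizures"] and not allow_few:
        raise ValueError(
            f"inclusion: only {len(seizures)} seizures; at least "
            f"{cfg['min_seizures']} required (pass allow_few=True to override)"
        )
    run = PatientRun(patient_id=patient_id, config=cfg)
    run.times = times_days
    run.seizure_ids = [s.seizure_id or f"sz{i + 1:02d}" for i, s in enumerate(seizures)]

    def stage(name: str, fn):
        with _timed(run, name):
            try:
                return fn()
            except Exception as e:
                raise RuntimeError(f"stage {name}: {e}") from e

    V, labels = stage("assemble", lambda: assemble_cohort_matrix(seizures))
    run.input_hashes["V"] = _hash(V)
    run.input_hashes["times"] = _hash(times_days)

    if denoise:
        def _select():
            rmax = min(cfg["nmf_rank_max"], min(V.shape) - 1)
            return nmf.select_rank_stability(
                V, range(cfg["nmf_rank_min"], rmax + 1), n_runs=cfg["nmf_runs"],
                seed=cfg["seed"], max_iter=cfg["nmf_max_iter"], tol=cfg["nmf_tol"],
            )

        run.rank_selection = stage("nmf_rank", _select)
        run.nmf_model = stage(
            "nmf_fit",
            lambda: nmf.factorize(
                V, run.rank_selection.rank, seed=cfg["seed"],
                max_iter=cfg["nmf_max_iter"], tol=cfg["nmf_tol"],
            ),
        )
        V_star = stage(
            "nmf_reconstruct",
            lambda: nmf.denoise_reconstruct(
                run.nmf_model, seizures[0].band_block_index, mode=cfg["renorm_mode"]
            ),
        )
        denoised = []
        for i, s in enumerate(seizures):
            cols = labels == i
            denoised.append(
                ConnectivityTimeSeries(
                    features=V_star[:, cols],
                    band_block_index=s.band_block_index,
                    window_start_times=s.window_start_times,
                    edge_index=s.edge_index,
                    seizure_id=s.seizure_id,
                    onset_datetime=s.onset_datetime,
                )
            )
        run.denoised = denoised
    else:
        run.denoised = seizures

    run.D = stage("dissimilarity", lambda: dsm.dissimilarity_matrix(run.denoised))
    run.TD = stage("temporal_distances", lambda: tmp.temporal_distances(times_days))
    run.mantel = stage(
        "mantel",
        lambda: tmp.mantel_spearman(
            run.D, run.TD, n_perm=cfg["mantel_permutations"], seed=cfg["seed"]
        ),
    )
    run.tcp = stage(
        "tcp",
        lambda: tmp.compute_tcp(
            run.D, run.TD, step=cfg["tcp_step_days"], min_pairs=cfg["tcp_min_pairs"]
        ),
    )
    if run.tcp.any_valid:
        run.likelihoods = stage(
            "likelihood_scan",
            lambda: mdl.likelihood_scan(
                run.tcp, times_days, n_sims=cfg["model_sims"],
                mse_threshold=cfg["mse_threshold"], seed=cfg["seed"],
                step=cfg["tcp_step_days"], min_pairs=cfg["tcp_min_pairs"],
            ),
        )
        run.classification = stage(
            "classify", lambda: mdl.classify_dynamics(run.likelihoods)
        )
    else:
        logger.warning("no valid timescales; skipping model classification")

    if out_dir is not None:
        from . import io as szio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        szio.write_matrix_csv(out / "dissimilarity.csv", run.D.values, run.seizure_ids)
        szio.write_matrix_csv(out / "temporal_distances.csv", run.TD.values, run.seizure_ids)
        if run.tcp is not None:
            szio.write_tcp_csv(out / "tcp.csv", run.tcp)
        if run.nmf_model is not None:
            szio.write_nmf_h5(
                out / "nmf_model.h5", run.nmf_model,
                run.rank_selection.scores if run.rank_selection else None,
            )
        szio.save_json(out / "summary.json", run.summary())
    return run
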