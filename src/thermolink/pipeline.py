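"""Stage orchestration: simulate -> idealize -> dwell-fit -> linkage -> sensor analysis.

Each stage is a pure function of its serialized inputs; the pipeline records
the analysis configuration, its hash, and every seed in the results JSON so
a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .io import AnalysisConfig, config_hash, default_mthk_model, write_dose_response, write_events, write_trace
from .linkage import compare_temperatures
from .models import celsius_to_kelvin, chi_values
from .single_channel import (
    ActivitySample,
    bootstrap_npo_sem,
    compute_npo,
    fit_dwell_mixture,
    idealize,
    q10,
)
from .synthetic import build_rate_matrix, generate_dose_response, simulate_gating, synthesize_trace

logger = logging.getLogger("thermolink")


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and fingerprints its input."""

    def __init__(self, stage: str, fingerprint: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on input {fingerprint}: {cause}")
        self.stage = stage
        self.fingerprint = fingerprint
        self.__cause__ = cause


def _log_stage(stage: str, **params) -> None:
    logger.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in params.items()))


def run_demo(
    config: Optional[AnalysisConfig] = None,
    out_dir: Optional[Path] = None,
    temperatures_C: Sequence[float] = (21.0, 37.0),
    ca_grid_mM: Sequence[float] = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0),
    recording_s: float = 300.0,
    trace_s: float = 20.0,
) -> dict:
    """End-to-end synthetic scenario exercising every pipeline stage.

    Generates a two-temperature dose–response dataset from the shipped MthK
    model with a van't Hoff temperature-dependent theta_UC, runs the
    linkage analysis, and separately synthesizes one noisy single-channel
    trace which is idealized and reduced to nPo, dwell-time and Q10
    statistics.  Returns (and optionally writes) a results dict in which
    every number carries units and the provenance block records versions,
    seeds and the config hash.
    """
    cfg = config or AnalysisConfig()
    seed = cfg.seed
    model = default_mthk_model(vant_hoff=("theta_UC",))
    t_low, t_high = (celsius_to_kelvin(t) for t in temperatures_C)
    ca_grid = [c * 1e-3 for c in ca_grid_mM]

    results: dict = {
        "provenance": {
            "package": "thermolink",
            "version": __version__,
            "config": cfg.to_dict(),
            "config_hash": config_hash(cfg.to_dict()),
            "seed": seed,
        }
    }

    # --- dose-response + linkage ------------------------------------------
    stage = "simulate-dose-response"
    t0 = time.time()
    try:
        _log_stage(stage, seed=seed, recording_s=recording_s)
        points = generate_dose_response(
            model, [t_low, t_high], ca_grid, recording_s=recording_s,
            n_patches=3, seed=seed,
        )
    except Exception as exc:  # noqa: BLE001 - propagate with stage context
        raise StageError(stage, config_hash(cfg.to_dict()), exc) from exc

    stage = "linkage"
    try:
        _log_stage(stage, n_points=len(points))
        low_pts = [p for p in points if p.temperature == t_low]
        high_pts = [p for p in points if p.temperature == t_high]
        comparison = compare_temperatures(low_pts, high_pts)
    except Exception as exc:
        raise StageError(stage, config_hash(cfg.to_dict()), exc) from exc

    true_low = chi_values(model, t_low)
    true_high = chi_values(model, t_high)
    results["linkage"] = {
        "units": {"temperature": "K", "ec50": "mM", "coupling_energy": "kcal/mol"},
        "low": _linkage_block(comparison.low),
        "high": _linkage_block(comparison.high),
        "d_delta_chi": comparison.d_delta_chi,
        "dominant_asymptote": comparison.dominant_asymptote,
        "true_delta_chi_low": true_low.delta_chi,
        "true_delta_chi_high": true_high.delta_chi,
        "recovery_error_low": comparison.low.delta_chi - true_low.delta_chi,
        "recovery_error_high": comparison.high.delta_chi - true_high.delta_chi,
    }

    # --- single-channel branch --------------------------------------------
    stage = "simulate-trace"
    try:
        _log_stage(stage, seed=seed + 1, trace_s=trace_s)
        Q = build_rate_matrix(model, t_high, 1e-3)
        path = simulate_gating(Q, trace_s, seed=seed + 1)
        trace = synthesize_trace(
            path,
            open_current=cfg.open_current_pA,
            noise_sd=cfg.noise_sd_pA,
            fs=cfg.sampling_rate_Hz,
            fc=cfg.filter_fc_Hz,
            seed=seed + 2,
        )
    except Exception as exc:
        raise StageError(stage, config_hash(cfg.to_dict()), exc) from exc

    stage = "idealize"
    try:
        _log_stage(stage, fc_Hz=cfg.filter_fc_Hz)
        record = idealize(
            trace, 0.0, cfg.open_current_pA,
            min_duration=cfg.min_event_duration_s, n_channels=cfg.n_channels,
        )
        npo, po = compute_npo(record)
        open_mask = Q.open_states()
        true_po = path.open_fraction(open_mask)
        sem = bootstrap_npo_sem(record, n_boot=min(cfg.n_boot, 500), seed=seed + 3)
    except Exception as exc:
        raise StageError(stage, config_hash(cfg.to_dict()), exc) from exc

    stage = "dwell-fit"
    try:
        open_dwells = record.dwells(1)
        fit = (
            fit_dwell_mixture(open_dwells, k_max=cfg.k_max, confidence=cfg.confidence)
            if open_dwells.size >= 50
            else None
        )
        _log_stage(stage, n_dwells=int(open_dwells.size))
    except Exception as exc:
        raise StageError(stage, config_hash(cfg.to_dict()), exc) from exc

    results["single_channel"] = {
        "units": {"dwell": "s", "npo": "dimensionless", "current": "pA"},
        "npo": npo,
        "po": po,
        "true_po_from_path": true_po,
        "npo_bootstrap_sem": sem,
        "n_events": len(record.events),
        "dwell_fit": {
            "components": [{"fraction": p, "tau_s": t} for p, t in fit.components],
            "mean_dwell_s": fit.mean_dwell,
            "n_selected": fit.n_selected,
        }
        if fit
        else None,
    }

    # --- Q10 from analytic Po at the two temperatures ---------------------
    stage = "q10"
    try:
        po_low = comparison.low.fit.A  # low-calcium plateau activities
        po_high = comparison.high.fit.A
        q = q10(
            ActivitySample(t_low, po_low), ActivitySample(t_high, po_high)
        )
        _log_stage(stage, q10=f"{q:.3g}")
    except Exception as exc:
        raise StageError(stage, config_hash(cfg.to_dict()), exc) from exc
    results["q10_low_calcium_plateau"] = q
    logger.info("demo complete in %.1f s", time.time() - t0)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_dose_response(points, out_dir / "dose_response.csv")
        write_trace(trace, out_dir / "trace.tsv")
        write_events(record, out_dir / "events.tsv")
        (out_dir / "results.json").write_text(
            json.dumps(results, indent=2, sort_keys=True, default=float) + "\n"
        )
    return results


def _linkage_block(res) -> dict:
    return {
        "temperature_K": res.temperature,
        "chi_minus": res.chi_minus,
        "chi_plus": res.chi_plus,
        "delta_chi": res.delta_chi,
        "ec50_mM": res.fit.K * 1e3,
        "hill_n": res.fit.n,
        "coupling_energy_kcal_per_mol": res.coupling_energy_kcal,
        "coupling_energy_kJ_per_mol": res.coupling_energy_kJ,
    }
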