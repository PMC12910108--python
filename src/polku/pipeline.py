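"""Reproducible per-condition orchestration of the full analysis.

``run_pipeline`` executes, for every configured condition: colocalization
simulation → event calling → first-arrival and dwell fits, then FRET
simulation → factor calibration → efficiency correction → FRET event calling
→ incorporation-dwell and FRET-magnitude fits, and finally fold changes
between matching conditions with and without Ku. Outputs are a
machine-readable results JSON, per-stage CSV artifacts and a log recording
package versions, seeds and the configuration hash.

A single configured seed fans out deterministically to per-condition,
per-stage child seeds through :class:`numpy.random.SeedSequence` spawn keys,
so any stage can be rerun in isolation with an identical stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

import polku

from .corrections import CorrectionFactors, compute_efret, estimate_factors
from .events import (call_colocalization_set, call_fret_events, events_to_csv,
                     first_binding_times)
from .fitting import (fit_binding_cdf, fit_delta_e_gaussian,
                      fit_dwell_exponential, nucleotides_from_delta_e)
from .scenarios import KineticScenario
from .simulate import simulate_calibration, simulate_colocalization, simulate_fret

__all__ = ["RunConfig", "run_pipeline", "analyze_colocalization",
           "analyze_fret"]

_STAGE = {"coloc": 0, "fret": 1, "calibration": 2}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one reproducible pipeline run."""

    conditions: dict[str, KineticScenario]
    seed: int = 0
    output_dir: Path = Path("polku_run")
    coloc_threshold: float = 50.0
    fret_band: tuple[float, float] = (0.3, 0.8)
    fret_min_frames: int = 5
    fret_max_duration_s: float = 20.0
    coloc_min_frames: int = 2
    coloc_merge_gap: int = 2
    fret_merge_gap: int = 4
    delta_mode: str = "plateau"
    calibrate_factors: bool = True
    n_calibration: int = 50
    run_colocalization: bool = True
    run_fret: bool = True
    n_boot: int = 200

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("config needs at least one condition")
        object.__setattr__(self, "output_dir", Path(self.output_dir))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict) or "conditions" not in raw:
            raise ValueError(f"{path} is not a pipeline configuration")
        conditions: dict[str, KineticScenario] = {}
        for name, entry in raw["conditions"].items():
            if isinstance(entry, str):
                ref = Path(entry)
                if not ref.is_absolute():
                    ref = path.parent / ref
                if not ref.exists():
                    raise FileNotFoundError(
                        f"scenario file for condition {name!r} not found: {ref}")
                conditions[name] = KineticScenario.from_yaml(ref)
            elif isinstance(entry, dict):
                conditions[name] = KineticScenario.from_dict(entry)
            else:
                raise ValueError(f"condition {name!r} must be a path or mapping")
        kwargs: dict[str, Any] = {k: v for k, v in raw.items()
                                  if k != "conditions"}
        if "output_dir" in kwargs:
            kwargs["output_dir"] = Path(kwargs["output_dir"])
        if "fret_band" in kwargs:
            kwargs["fret_band"] = tuple(kwargs["fret_band"])
        return cls(conditions=conditions, **kwargs)

    def content_hash(self) -> str:
        payload = {
            "conditions": {k: v.to_dict() for k, v in self.conditions.items()},
            **{f.name: getattr(self, f.name)
               for f in dataclasses.fields(self)
               if f.name not in ("conditions", "output_dir")},
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _child_seed(base_seed: int, condition_index: int, stage: str) -> int:
    ss = np.random.SeedSequence([base_seed, condition_index, _STAGE[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def analyze_colocalization(scenario: KineticScenario, config: RunConfig,
                           seed: int) -> dict[str, Any]:
    """Simulate and analyze one colocalization condition."""
    scen = scenario.replace(seed=seed)
    trajset, _ = simulate_colocalization(scen)
    events = call_colocalization_set(
        trajset, config.coloc_threshold,
        min_frames=config.coloc_min_frames, merge_gap=config.coloc_merge_gap)
    firsts = first_binding_times(events, scen.movie_length)
    binding = fit_binding_cdf(firsts, n_boot=config.n_boot, seed=seed)
    durations = [ev.duration_s for evs in events.values() for ev in evs]
    dwell = fit_dwell_exponential(
        durations, cutoff=config.coloc_min_frames * scen.frame_interval,
        frame_interval=scen.frame_interval, n_boot=config.n_boot, seed=seed)
    flat_events = [ev for evs in events.values() for ev in evs]
    return {
        "k_obs_per_s": binding.param("k"),
        "k_obs_se": binding.stderr["k"],
        "percent_bound": 100.0 * binding.param("A"),
        "percent_bound_se": (100.0 * binding.stderr["A"]
                             if math.isfinite(binding.stderr["A"]) else None),
        "tau_dwell_s": dwell.param("tau"),
        "tau_dwell_se": dwell.stderr["tau"],
        "n_molecules": scen.n_molecules,
        "n_events": len(flat_events),
        "_events": flat_events,
    }


def analyze_fret(scenario: KineticScenario, config: RunConfig,
                 seed: int) -> dict[str, Any]:
    """Simulate and analyze one FRET incorporation condition."""
    scen = scenario.replace(seed=seed)
    trajset, _ = simulate_fret(scen)
    if config.calibrate_factors:
        cal_seed = _child_seed(seed, 0, "calibration")
        donor_only = simulate_calibration(
            scen, "donor_only", n_molecules=config.n_calibration, seed=cal_seed)
        acceptor_only = simulate_calibration(
            scen, "acceptor_only", n_molecules=config.n_calibration,
            seed=cal_seed + 1)
        factors = estimate_factors(donor_only, acceptor_only, trajset,
                                   background=scen.background)
    else:
        factors = CorrectionFactors(scen.leakage, scen.direct_excitation,
                                    scen.gamma)
    e_min, e_max = config.fret_band
    all_events = []
    for traj in trajset:
        trace = compute_efret(traj, factors, background=scen.background)
        all_events.extend(call_fret_events(
            trace, e_min=e_min, e_max=e_max,
            min_frames=config.fret_min_frames,
            max_duration_s=config.fret_max_duration_s,
            merge_gap=config.fret_merge_gap, delta_mode=config.delta_mode))
    # events cut short by signal loss (bleach/dissociation/movie end) have
    # censored durations; magnitudes keep all events (histogram fit is
    # robust to the censored tail)
    complete = [ev for ev in all_events if not ev.ends_at_signal_loss]
    if len(complete) < 20:
        complete = all_events
    durations = [ev.duration_s for ev in complete]
    deltas = [ev.delta_e for ev in all_events]
    # incorporation times are sums of several per-nucleotide steps, so the
    # exponential truncation correction does not apply (see methods note)
    dwell = fit_dwell_exponential(durations, cutoff=0.0,
                                  n_boot=config.n_boot, seed=seed)
    # the binned Gaussian fit tracks the modal magnitude, robust to the
    # left tail of sampling-censored events; MLE fallback at small n
    try:
        magnitude = fit_delta_e_gaussian(deltas, mode="histogram",
                                         n_boot=config.n_boot, seed=seed)
    except ValueError:
        magnitude = fit_delta_e_gaussian(deltas, n_boot=config.n_boot,
                                         seed=seed)
    return {
        "incorporation_dwell_s": dwell.param("tau"),
        "incorporation_dwell_se": dwell.stderr["tau"],
        "delta_e_mu": magnitude.param("mu"),
        "delta_e_mu_se": magnitude.stderr["mu"],
        "delta_e_sigma": magnitude.param("sigma"),
        "nucleotides": nucleotides_from_delta_e(magnitude.param("mu")),
        "factors": {"leakage": factors.leakage,
                    "direct_excitation": factors.direct_excitation,
                    "gamma": factors.gamma},
        "n_molecules": scen.n_molecules,
        "n_events": len(all_events),
        "_events": all_events,
    }


def _fold_changes(results: dict[str, dict]) -> dict[str, dict[str, float]]:
    folds: dict[str, dict[str, float]] = {}
    for name in results:
        partner = f"{name}_ku"
        if partner not in results:
            continue
        base, ku = results[name], results[partner]
        entry: dict[str, float] = {}
        cb, ck = base.get("colocalization"), ku.get("colocalization")
        if cb and ck:
            entry["binding_rate_fold"] = ck["k_obs_per_s"] / cb["k_obs_per_s"]
            entry["dwell_fold"] = ck["tau_dwell_s"] / cb["tau_dwell_s"]
        fb, fk = base.get("fret"), ku.get("fret")
        if fb and fk:
            entry["incorporation_stimulation_fold"] = (
                fb["incorporation_dwell_s"] / fk["incorporation_dwell_s"])
        if entry:
            folds[f"{name}_vs_{partner}"] = entry
    return folds


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages for every condition and write the report."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, dict] = {}
    for i, (name, scenario) in enumerate(sorted(config.conditions.items())):
        entry: dict[str, Any] = {}
        try:
            if config.run_colocalization:
                res = analyze_colocalization(
                    scenario, config, _child_seed(config.seed, i, "coloc"))
                events_to_csv(res.pop("_events"),
                              out / f"{name}_colocalization_events.csv")
                entry["colocalization"] = res
            if config.run_fret:
                res = analyze_fret(
                    scenario, config, _child_seed(config.seed, i, "fret"))
                events_to_csv(res.pop("_events"),
                              out / f"{name}_fret_events.csv")
                entry["fret"] = res
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed for condition {name!r} "
                f"(scenario {scenario.condition_label!r}): {exc}") from exc
        results[name] = entry

    report = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "conditions": results,
        "fold_changes": _fold_changes(results),
    }
    (out / "results.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    log_lines = [
        f"polku {polku.__version__}",
        f"python {platform.python_version()}",
        f"numpy {np.__version__}",
        f"pandas {pd.__version__}",
        f"seed {config.seed}",
        f"config_hash {config.content_hash()}",
        f"conditions {', '.join(sorted(config.conditions))}",
    ]
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
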