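"""End-to-end orchestration: data in, tables/figures/run-log out.

`run_pipeline` chains every stage -- read or simulate hypnograms, segment
into bouts, REM-split, bin, summary statistics (percent time, counts,
frequency ratios, duration models, NREM latency) and the transition
heatmap grid -- writing deterministic CSV outputs plus a machine-readable
run log.  Re-running with the same configuration reproduces every CSV
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .bouts import (
    LatencyParams,
    REMS_CUTOFF_EPOCHS,
    bout_table,
    bouts_by_subject,
    nrem_latency,
)
from .hypnogram import SPLIT_STATES, Hypnogram, read_hypnogram, write_hypnogram
from .simulate import SimConfig, default_config, simulate_study
from .stats import (
    count_bouts,
    estimate_frequency_ratios,
    fit_duration_model,
    percent_time,
)
from .transitions import heatmap_grid


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name and context."""


@dataclass
class RunConfig:
    """Everything `run_pipeline` needs; defaults mirror the study design."""

    input_path: Optional[str] = None  # None -> simulate
    sim_config: Optional[SimConfig] = None
    out_dir: str = "results"
    n_bins: int = 3
    bin_epochs: int = 900
    rems_cutoff_epochs: int = REMS_CUTOFF_EPOCHS
    min_count: int = 5
    residual_method: str = "pearson"
    latency: LatencyParams = field(default_factory=LatencyParams)
    reference: str = "VEH"
    percent_window_epochs: Optional[int] = None  # None -> n_bins * bin_epochs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_method not in ("pearson", "adjusted"):
            raise ValueError("residual_method must be 'pearson' or 'adjusted'")
        if min(self.n_bins, self.bin_epochs, self.rems_cutoff_epochs) <= 0:
            raise ValueError("numeric parameters must be positive")


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns a name -> path map of outputs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- load or simulate ------------------------------------------------
    if cfg.input_path is not None:
        hypnograms = _stage("read", read_hypnogram, cfg.input_path)
    else:
        sim = cfg.sim_config or default_config(seed=cfg.seed)
        if cfg.sim_config is None:
            sim = dataclasses.replace(sim, seed=cfg.seed)
        hypnograms = _stage("simulate", simulate_study, sim)
        paths["hypnograms"] = out / "hypnograms.csv"
        _stage("write", write_hypnogram, hypnograms, paths["hypnograms"])
        paths["sim_config"] = out / "sim_config.yaml"
        sim.to_yaml(paths["sim_config"])
    if not hypnograms:
        raise PipelineError("stage 'read': no hypnograms in input")

    window = cfg.percent_window_epochs or cfg.n_bins * cfg.bin_epochs

    # --- bouts ------------------------------------------------------------
    table = _stage(
        "bouts", bout_table, hypnograms,
        cutoff_epochs=cfg.rems_cutoff_epochs,
        bin_epochs=cfg.bin_epochs, n_bins=cfg.n_bins,
    )
    paths["bout_table"] = out / "bout_table.csv"
    table.to_csv(paths["bout_table"], index=False)

    # --- percent time -----------------------------------------------------
    pct_rows = []
    for h in hypnograms:
        try:
            pct = percent_time(h, window_epochs=window, rems_split=True)
        except Exception as exc:
            raise PipelineError(
                f"stage 'percent_time' failed for "
                f"({h.subject_id}, {h.treatment}): {exc}"
            ) from exc
        for state, value in pct.items():
            pct_rows.append(
                (h.subject_id, h.treatment, state, round(value, 10))
            )
    pct_df = pd.DataFrame(
        pct_rows, columns=["subject_id", "treatment", "state", "percent"]
    )
    paths["percent_time"] = out / "percent_time.csv"
    pct_df.to_csv(paths["percent_time"], index=False)

    # --- counts + frequency ratios ---------------------------------------
    counts = _stage("count_bouts", count_bouts, table, n_bins=cfg.n_bins)
    paths["bout_counts"] = out / "bout_counts.csv"
    counts.to_csv(paths["bout_counts"], index=False)

    ratio_rows = []
    for state in SPLIT_STATES:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                estimates = estimate_frequency_ratios(
                    counts, state, reference=cfg.reference
                )
        except ValueError:
            continue  # state absent or all-zero: nothing to estimate
        for e in estimates:
            ratio_rows.append(
                (e.state, e.dose, e.ratio, e.ci_low, e.ci_high,
                 e.n_obs, e.estimable, e.model)
            )
    ratios = pd.DataFrame(
        ratio_rows,
        columns=["state", "dose", "ratio", "ci_low", "ci_high",
                 "n_obs", "estimable", "model"],
    )
    paths["frequency_ratios"] = out / "frequency_ratios.csv"
    ratios.to_csv(paths["frequency_ratios"], index=False, float_format="%.10g")

    # --- duration models --------------------------------------------------
    cell_rows, test_rows = [], []
    for state in SPLIT_STATES:
        try:
            fit = fit_duration_model(table, state)
        except Exception:
            continue  # too few bouts for a model in this state
        test_rows.append(
            (state, fit.f_stat, fit.df_num, fit.df_den, fit.p_value)
        )
        for _, r in fit.cells.iterrows():
            cell_rows.append(
                (state, r["treatment"], int(r["bin"]), r["mean_log"],
                 r["ci_low"], r["ci_high"], int(r["n_obs"]))
            )
    paths["duration_cells"] = out / "duration_cells.csv"
    pd.DataFrame(
        cell_rows,
        columns=["state", "treatment", "bin", "mean_log",
                 "ci_low", "ci_high", "n_obs"],
    ).to_csv(paths["duration_cells"], index=False, float_format="%.10g")
    paths["duration_tests"] = out / "duration_tests.csv"
    pd.DataFrame(
        test_rows, columns=["state", "f_stat", "df_num", "df_den", "p_value"]
    ).to_csv(paths["duration_tests"], index=False, float_format="%.10g")

    # --- NREM latency -----------------------------------------------------
    lat_rows = []
    for h in hypnograms:
        lat = _stage("latency", nrem_latency, h, cfg.latency)
        lat_rows.append(
            (h.subject_id, h.treatment,
             "" if lat is None else lat,
             lat is None)
        )
    paths["nrem_latency"] = out / "nrem_latency.csv"
    pd.DataFrame(
        lat_rows,
        columns=["subject_id", "treatment", "latency_s", "not_reached"],
    ).to_csv(paths["nrem_latency"], index=False)

    # --- transition heatmaps ----------------------------------------------
    by_treatment: dict[str, dict] = {}
    for tr in dict.fromkeys(h.treatment for h in hypnograms):
        group = [h for h in hypnograms if h.treatment == tr]
        by_treatment[tr] = bouts_by_subject(
            group, cutoff_epochs=cfg.rems_cutoff_epochs
        )
    tables = _stage(
        "transitions", heatmap_grid, by_treatment,
        n_bins=cfg.n_bins, bin_epochs=cfg.bin_epochs,
        method=cfg.residual_method, min_count=cfg.min_count, out_dir=out,
    )
    for (tr, b) in tables:
        paths[f"transitions_{tr}_h{b + 1}"] = out / f"transitions_{tr}_h{b + 1}.csv"
    paths["transition_grid"] = out / "transition_grid.png"

    # --- run log ----------------------------------------------------------
    import numpy
    import statsmodels

    log = {
        "config": {
            # out_dir is where the results land, not part of the analysis
            **{k: v for k, v in dataclasses.asdict(cfg).items()
               if k not in ("sim_config", "out_dir")},
            "simulated": cfg.input_path is None,
        },
        "versions": {
            "sleepbouts": __version__,
            "numpy": numpy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "n_hypnograms": len(hypnograms),
        "outputs": sorted(str(p.name) for p in paths.values()),
    }
    paths["run_log"] = out / "run_log.json"
    paths["run_log"].write_text(
        json.dumps(log, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
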