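"""Readers, writers, run configuration and end-to-end orchestration.

All tables are tab-separated text with documented columns; expression
matrices may also arrive in the two-line-header GCT dialect.  Missing
clinical fields are empty strings, never sentinel numbers.  A run is a
pure function of its configuration (which carries one master seed), so
rerunning writes byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .selection import PipelineError, cohort_screen, records_to_frame, run_marker_selection
from .synthetic import (
    SimulationConfig,
    simulate_claims,
    simulate_expression_cohort,
    simulate_registry,
)
from .treatment import STRATUM_LABELS, default_code_map, derive_treatment_flags

REGISTRY_COLUMNS = [
    "patient_id", "time", "event", "death_cause", "t_stage", "n_stage",
    "m_stage", "grade", "surgery", "radiation", "preop_radiation", "chemo_agents",
]


def read_expression_matrix(path, orientation: str = "features_in_rows") -> pd.DataFrame:
    """Read a delimited expression matrix as features x samples.

    Plain TSV (first row sample names, first column feature names) and the
    GCT dialect (#1.2 version line, dimensions line, Name/Description
    columns) are auto-detected.  ``orientation="samples_in_rows"`` says the
    file is transposed; the return value is always features x samples.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty file")
    if first.startswith("#1."):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        df = df.drop(columns=[c for c in ("Description",) if c in df.columns])
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "features_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate feature names {dupes}")
    non_numeric = df.map(lambda v: not isinstance(v, (int, float, np.number)))
    if non_numeric.any().any():
        r, c = np.argwhere(non_numeric.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return df.astype(float)


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def write_registry(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["chemo_agents"] = out["chemo_agents"].map(lambda s: ",".join(sorted(s)))
    for col in ("surgery", "radiation", "preop_radiation"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_registry(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chemo_agents": str}, keep_default_na=False,
                     na_values=[""])
    df["chemo_agents"] = df["chemo_agents"].map(
        lambda s: frozenset() if (not isinstance(s, str) or not s) else frozenset(s.split(","))
    )
    for col in ("surgery", "radiation", "preop_radiation"):
        if col in df:
            df[col] = df[col].astype(bool)
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_survival_curve(curve, path) -> None:
    pd.DataFrame(
        {"time": curve.event_times, "survival": curve.survival_probs}
    ).to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Everything an end-to-end run needs; serializable to YAML."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    strata: tuple = STRATUM_LABELS
    chemo_agents: tuple = ("any",)
    min_registry_group: int = 10
    min_cohort_group: int = 1
    min_agent_subset: int = 50
    n_grid: int = 20
    population_rule: str = "both"
    out_dir: str = "mirlink_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        if "planted_mirna_effects" in sim and sim["planted_mirna_effects"] is None:
            sim["planted_mirna_effects"] = {}
        for key in ("hazard_loadings", "t_probs", "n_probs", "g_probs"):
            if key in sim:
                sim[key] = tuple(sim[key])
        for key in ("strata", "chemo_agents"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=SimulationConfig(**sim), **raw)

    def to_yaml(self, path) -> None:
        raw = {k: v for k, v in self.__dict__.items() if k != "simulation"}
        raw["strata"] = list(self.strata)
        raw["chemo_agents"] = list(self.chemo_agents)
        raw["simulation"] = self.simulation.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate -> derive treatment flags -> select markers, one reproducible run.

    Writes the simulated inputs, one selection table covering every
    (miRNA, stratum, agent) cell, and a JSON run summary into
    ``config.out_dir``.  Returns the summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    registry = simulate_registry(sim)
    expr, clinical = simulate_expression_cohort(sim)
    claims = simulate_claims(sim, registry)
    code_map = default_code_map()
    derived = derive_treatment_flags(claims, code_map)
    registry = registry.assign(
        chemo_agents=[derived.get(pid, frozenset()) for pid in registry["patient_id"]]
    )

    write_registry(registry, out / "registry.tsv")
    write_expression_matrix(expr.T, out / "cohort_expression.tsv")  # features x samples
    write_clinical(clinical, out / "cohort_clinical.tsv")
    claims.to_csv(out / "claims.tsv", sep="\t", index=False)

    screen = cohort_screen(expr, clinical, alpha=config.alpha, n_grid=config.n_grid)
    frames, summaries = [], []
    for stratum in config.strata:
        cells = [("prognostic", "none")] + [("chemo", a) for a in config.chemo_agents]
        for mode, agent in cells:
            try:
                records, summary = run_marker_selection(
                    expr, clinical, registry,
                    stratum=stratum, agent=agent, alpha=config.alpha, mode=mode,
                    min_registry_group=config.min_registry_group,
                    min_cohort_group=config.min_cohort_group,
                    min_agent_subset=config.min_agent_subset,
                    n_grid=config.n_grid,
                    population_rule=config.population_rule,
                    screen=screen,
                )
            except PipelineError as exc:
                summaries.append(
                    {"stratum": stratum, "mode": mode, "agent": agent,
                     "skipped": True, "reason": str(exc)}
                )
                continue
            summaries.append(summary)
            if records:
                frame = records_to_frame(records)
                frame.insert(1, "mode", mode)
                frames.append(frame)

    selection = (
        pd.concat(frames, ignore_index=True)
        if frames
        else records_to_frame([])
    )
    selection.to_csv(out / "selection.tsv", sep="\t", index=False)

    run_summary = {
        "config": {
            "alpha": config.alpha,
            "seed": sim.seed,
            "n_registry": sim.n_registry,
            "n_cohort": sim.n_cohort,
            "n_mirna": sim.n_mirna,
            "population_rule": config.population_rule,
        },
        "n_selected_total": int(selection["verdict"].ne("rejected").sum()) if len(selection) else 0,
        "cells": summaries,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(run_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return run_summary
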