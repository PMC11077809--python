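"""End-to-end pipeline: simulate -> select -> fit -> diagnose -> weights
-> capitation allocation, with every artifact stamped for reproducibility.

A single master seed expands deterministically into per-stage seeds
(SeedSequence spawn keys in a fixed order), so each stage can be rerun
in isolation and the whole bundle is byte-identical under a fixed
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .capitation import allocate_budget, area_cost_summary, need_index, render_allocation
from .diagnostics import diagnostics_report
from .effects import age_band_effects, weight_table
from .glm import ModelSpec, build_design, fit_glm, predict
from .selection import box_cox_lambda, modified_park_test, selection_grid
from .simulate import SimConfig, area_table, generate_population, summarize_groups

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "selection", "fit", "diagnostics", "allocation")


def stage_seeds(master_seed: int) -> dict:
    """Per-stage seeds derived from one master seed (all below 2^31)."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class PipelineConfig:
    """Settings for one pipeline run."""

    seed: int = 0
    n_persons: int = 50_000
    budget_eur_m: float = 1842.0
    model: ModelSpec = field(default_factory=ModelSpec)
    run_selection: bool = True
    diagnostics_repetitions: int = 10
    person_csv: str | None = None  # load instead of simulating when set
    area_csv: str | None = None
    out_dir: str = "amgcap_out"

    def validate(self):
        if not self.budget_eur_m > 0:
            raise ValueError("budget must be positive")
        if self.person_csv is None and self.n_persons <= 0:
            raise ValueError("n_persons must be positive when simulating")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "n_persons": self.n_persons,
                "budget_eur_m": self.budget_eur_m,
                "family": self.model.family,
                "link": self.model.link,
                "run_selection": self.run_selection,
                "diagnostics_repetitions": self.diagnostics_repetitions,
                "person_csv": self.person_csv,
                "area_csv": self.area_csv,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report bundle as a dict of
    DataFrames/dicts and writes artifacts under ``config.out_dir``.

    Any stage failure raises with the stage name; artifacts written by
    earlier stages persist.
    """
    config.validate()
    seeds = stage_seeds(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_hash": config.config_hash(),
        "version": __version__,
    }
    bundle: dict = {"stamp": stamp}
    stage = "setup"
    try:
        stage = "simulate"
        if config.person_csv:
            records = io.load_person_table(config.person_csv)
        else:
            sim = SimConfig(n_persons=config.n_persons, seed=seeds["simulate"])
            records = generate_population(sim)
            io.save_person_table(records, out / "persons.csv")
        if config.area_csv:
            areas = io.load_area_table(config.area_csv)
        else:
            sim_for_areas = SimConfig(n_persons=config.n_persons, seed=seeds["simulate"])
            areas = area_table(sim_for_areas, records)
            io.save_area_table(areas, out / "areas.csv")
        bundle["group_summary"] = summarize_groups(records)
        bundle["group_summary"].to_csv(out / "table1_groups.csv")

        stage = "selection"
        if config.run_selection:
            grid = selection_grid(records)
            X, y, _ = build_design(records)
            bc = box_cox_lambda(y, X)
            park = modified_park_test(records)
            bundle["selection"] = {
                "grid": grid,
                "box_cox": {
                    "lambda": bc.lam,
                    "ci95": list(bc.ci95),
                    "recommended_link": bc.recommended_link,
                },
                "park": {
                    "slope": park.slope,
                    "ci95": list(park.ci95),
                    "recommended_family": park.recommended_family,
                },
            }
            grid.to_csv(out / "table2_selection_grid.csv", index=False)
            (out / "selection.json").write_text(
                json.dumps(
                    {
                        **stamp,
                        "box_cox": bundle["selection"]["box_cox"],
                        "park": bundle["selection"]["park"],
                    },
                    indent=1,
                )
            )

        stage = "fit"
        X, y, encoding = build_design(records)
        model = fit_glm(X, y, config.model, encoding)
        model.require_converged()
        model.save(out / "model.json")
        bundle["model"] = model

        stage = "diagnostics"
        diag = diagnostics_report(
            model,
            records,
            repetitions=config.diagnostics_repetitions,
            seed=seeds["diagnostics"],
        )
        bundle["diagnostics"] = diag
        (out / "diagnostics.json").write_text(json.dumps({**stamp, **diag}, indent=1))

        stage = "weights"
        weights = weight_table(model, records)
        bundle["weights"] = weights
        weights.to_csv(out / "table3_weights.csv")
        bundle["age_effects"] = age_band_effects(model, records)

        stage = "allocation"
        mu = predict(model, X)["mu"]
        summary = area_cost_summary(records, mu)
        bundle["area_summary"] = summary
        summary.to_csv(out / "table4_area_summary.csv")
        finance_in = areas.copy()
        finance_in["need_index"] = need_index(summary)
        if finance_in["need_index"].isna().any():
            raise ValueError("area table and person table cover different areas")
        finance = allocate_budget(config.budget_eur_m, finance_in)
        bundle["finance"] = finance
        render_allocation(finance).to_csv(out / "table5_allocation.csv")
        (out / "stamp.json").write_text(json.dumps(stamp, indent=1))
    except Exception as exc:
        logger.error("pipeline failed in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle
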