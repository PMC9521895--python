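"""End-to-end orchestration: screen -> fit -> classify -> associate.

One call (or one CLI invocation) runs the full analysis on either user
data (CSV paths) or a synthetic cohort, with every exclusion counted
and logged, and emits machine-readable outputs: ``fits.csv``,
``exclusions.csv``, ``associations.csv`` and ``report.json``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .synth import CohortConfig, generate_cohort
from .stats import confirmatory_associations, kendall_tau, regress_peaks, sidak
from .wundt import WundtModel, liking_variance, peak_summary, screen_response_quality

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_REGRESSION_PREDICTORS = ("capep", "aq", "training_years", "baisv")


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full pipeline run.

    Exactly one input source must be set: either the three CSV paths or
    a :class:`~sweetspot.synth.CohortConfig` for simulation.  Defaults
    mirror the study's analysis: quadratic cutoff -0.1, vertex clipping,
    one-sided confirmatory tests against negative association,
    covariates ACE and mood, family-wise alpha 0.05.
    """

    cohort: CohortConfig | None = None
    liking_path: str | None = None
    stimuli_path: str | None = None
    traits_path: str | None = None
    threshold: float = -0.1
    clip_vertices: bool = True
    predictor: str = "complexity"
    window_ms: float = 50.0
    trait_names: tuple[str, ...] = ("capep", "aq")
    covariate_names: tuple[str, ...] = ("ace", "mood")
    sidedness: str = "one_sided_negative"
    alpha: float = 0.05
    midpoint_band: tuple[float, float] = (45.0, 55.0)
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        has_paths = self.liking_path is not None
        if has_paths == (self.cohort is not None):
            raise ValueError("set exactly one of (input paths, cohort config)")
        if has_paths and self.stimuli_path is None:
            raise ValueError("stimuli_path required alongside liking_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in raw and raw["cohort"] is not None:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        for key in ("trait_names", "covariate_names", "midpoint_band"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _round(v, nd=6):
    if isinstance(v, float):
        return round(v, nd)
    return v


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns (and optionally writes) the report."""
    report: dict = {"config": {"threshold": config.threshold,
                               "predictor": config.predictor,
                               "sidedness": config.sidedness,
                               "alpha": config.alpha,
                               "seed": config.seed},
                    "stages": []}

    # -- load / simulate -----------------------------------------------------
    if config.cohort is not None:
        cohort = dataclasses.replace(config.cohort, seed=config.seed)
        liking, traits, truth = generate_cohort(cohort)
        stimuli = cohort.stimulus_table if cohort.stimulus_table is not None else sio.load_table1()
        source = "synthetic"
    else:
        stimuli = sio.read_stimulus_table(config.stimuli_path)
        liking = sio.read_liking_matrix(config.liking_path, stimuli)
        traits = (
            sio.read_trait_table(config.traits_path)
            if config.traits_path
            else None
        )
        source = "files"
    n0 = len(liking)
    report["stages"].append({"stage": "input", "source": source, "n_in": n0,
                             "n_excluded": 0, "n_out": n0})
    logger.info("input: %d participants (%s)", n0, source)

    # -- screening -----------------------------------------------------------
    screen = screen_response_quality(liking, midpoint_band=config.midpoint_band)
    flagged = list(screen["participant_id"])
    kept = [p for p in liking.participant_ids if p not in set(flagged)]
    if not kept:
        raise RuntimeError("screening excluded every participant")
    liking_kept = sio.LikingMatrix(liking.df.loc[kept], stimuli)
    report["stages"].append(
        {"stage": "screen_midpoint", "n_in": n0, "n_excluded": len(flagged),
         "n_out": len(kept)}
    )
    logger.info("screening: excluded %d of %d", len(flagged), n0)

    # -- per-participant fits ------------------------------------------------
    model = WundtModel(
        liking_kept,
        stimuli,
        threshold=config.threshold,
        clip_vertices=config.clip_vertices,
        predictor=config.predictor,
    )
    results = model.fit(group_curve=len(liking_kept) >= 2)
    n_wundt = results.n_wundt
    report["stages"].append(
        {"stage": "wundt_classification", "n_in": len(kept),
         "n_excluded": len(kept) - n_wundt, "n_out": n_wundt}
    )
    logger.info("wundt classification: %d of %d retained", n_wundt, len(kept))
    report["peaks"] = {k: _round(v) for k, v in results.peak_summary().items()}
    if results.group is not None:
        g = results.group
        report["group_curve"] = {
            "beta_lin": _round(g.beta_lin), "beta_quad": _round(g.beta_quad),
            "p_lin": _round(g.p_lin, 8), "p_quad": _round(g.p_quad, 8),
            "converged": g.converged,
        }
    else:
        report["group_curve"] = {"skipped": "fewer than 2 participants"}

    # -- associations ----------------------------------------------------------
    assoc_df = None
    if traits is None:
        report["associations"] = {"skipped": "no trait table supplied"}
    else:
        peaks = results.peaks
        common = peaks.index.intersection(traits.df.index)
        min_n = 3 + len(config.covariate_names)
        if len(common) < min_n:
            report["associations"] = {
                "skipped": f"only {len(common)} wundt participants with traits "
                f"(need >= {min_n})"
            }
        else:
            assoc_df = confirmatory_associations(
                peaks.loc[common],
                traits.df,
                config.trait_names,
                config.covariate_names,
                sidedness=config.sidedness,
                alpha=config.alpha,
            )
            report["associations"] = assoc_df.to_dict(orient="records")
            preds = [p for p in _REGRESSION_PREDICTORS if p in traits.df.columns]
            if len(common) > len(preds) + 1:
                reg = regress_peaks(
                    peaks.loc[common].to_numpy(), traits.df.loc[common, preds]
                )
                report["regression"] = {
                    "F": _round(reg.f_stat, 3), "df": list(reg.df),
                    "p": _round(reg.p, 3), "r2": _round(reg.r2, 3),
                    "r2_adj": _round(reg.r2_adj, 3), "predictors": preds,
                }
            # exploratory: traits vs variability of liking responses
            lv = liking_variance(liking_kept)
            expl = []
            for t in config.trait_names:
                res = kendall_tau(
                    traits.df.loc[lv.index.intersection(traits.df.index), t],
                    lv.loc[lv.index.intersection(traits.df.index)],
                    sidedness="two_sided",
                )
                expl.append({"trait": t, "tau": round(res.tau, 3),
                             "p": round(res.p, 3), "n": res.n})
            report["liking_variance_associations"] = expl

    # -- outputs ---------------------------------------------------------------
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "fits.csv")
        screen.to_csv(out / "exclusions.csv", index=False)
        if assoc_df is not None:
            assoc_df.to_csv(out / "associations.csv", index=False)
        sio.write_report(report, out / "report.json")
    return report
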