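"""End-to-end analysis: adjustments table -> predicted vs measured
memory colour effects -> the three evaluation approaches.

For each stimulus x condition cell the pipeline

1. derives the typical-hue axis from the mean typical adjustment (per
   observer for individual-level analyses, across all observers for
   aggregate ones, configurable),
2. projects typical, disk-grey and object-grey adjustments onto it,
3. estimates prior and signal cues and fuses them into the predicted
   effect M, and
4. computes the measured effect as the negated mean projection of the
   object's grey adjustments,

then runs the individual, pooled and aggregated evaluation approaches,
the paired difference test, and (when several image conditions are
present) the relative-effect variants.  Cells or observers that cannot
support an estimate are skipped, each with a machine-readable reason
code, never silently.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import geometry, model
from ._version import __version__
from .errors import DegenerateAxisError, DegenerateCueError, InsufficientDataError
from .io import RunConfig, validate_adjustments

__all__ = ["ResultsBundle", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class ResultsBundle:
    """Everything one pipeline run produces."""

    pairs: pd.DataFrame
    correlations: pd.DataFrame
    difference_tests: pd.DataFrame
    skipped: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        """Write the bundle as CSV/JSON files into ``out_dir``."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(out / "effect_pairs.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.difference_tests.to_csv(out / "difference_tests.csv", index=False)
        pd.DataFrame(self.skipped).to_csv(out / "skipped.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))


def _group_xy(df: pd.DataFrame) -> dict:
    """Map group key -> (n, 2) coordinate array."""
    return {
        key: sub[["chroma_x", "chroma_y"]].to_numpy(dtype=float)
        for key, sub in df.groupby(["stimulus_id", "condition", "observer_id"],
                                   sort=True)
    }


def run_pipeline(data: pd.DataFrame, config: RunConfig | None = None) -> ResultsBundle:
    """Run the full analysis on a validated adjustments table.

    Raises
    ------
    InsufficientDataError
        If the table contains no disk grey adjustments (the sensory
        signal cannot be estimated without them).
    """
    config = config or RunConfig()
    data = validate_adjustments(data, disk_stimulus_id=config.disk_stimulus_id)
    if config.exclude:
        data = data[~data["stimulus_id"].isin(config.exclude)].reset_index(drop=True)

    disk = data[data["condition"] == "disk"]
    if disk.empty:
        raise InsufficientDataError("no disk grey adjustments in the data")
    objects = data[data["condition"] != "disk"]

    disk_by_obs = {
        obs: sub[["chroma_x", "chroma_y"]].to_numpy(dtype=float)
        for obs, sub in disk.groupby("observer_id", sort=True)
    }
    typ_xy = _group_xy(objects[objects["task"] == "typical"])
    grey_xy = _group_xy(objects[objects["task"] == "grey"])

    cells = sorted({(s, c) for (s, c, _o) in set(typ_xy) | set(grey_xy)})
    observers = sorted(objects["observer_id"].unique())
    conditions = sorted({c for (_s, c) in cells})

    skipped: list[dict] = []

    def skip(level: str, obs: str, stim: str, cond: str, reason: str) -> None:
        entry = {"level": level, "observer_id": obs, "stimulus_id": stim,
                 "condition": cond, "reason": reason}
        skipped.append(entry)
        logger.info("skipped: %s", entry)

    # global hue axes (all observers' typicals) per cell
    global_axis: dict[tuple[str, str], geometry.HueAxis] = {}
    for stim, cond in cells:
        allt = [typ_xy[k] for k in typ_xy if k[0] == stim and k[1] == cond]
        if not allt:
            skip("all", "*", stim, cond, "NO_TYPICALS")
            continue
        try:
            global_axis[(stim, cond)] = geometry.hue_axis_from_typicals(
                stim, np.vstack(allt)
            )
        except DegenerateAxisError:
            skip("all", "*", stim, cond, "DEGENERATE_AXIS")

    indiv_scope = (
        "per_observer" if config.hue_axis_scope == "auto" else config.hue_axis_scope
    )

    # ---- individual-level effect pairs ------------------------------------
    pair_rows: list[dict] = []
    if "individual" in config.levels or "pooled" in config.levels:
        for stim, cond in cells:
            if (stim, cond) not in global_axis:
                continue
            for obs in observers:
                typ = typ_xy.get((stim, cond, obs))
                grey = grey_xy.get((stim, cond, obs))
                dxy = disk_by_obs.get(obs)
                if typ is None or len(typ) < 2:
                    skip("individual", obs, stim, cond, "TOO_FEW_TYPICALS")
                    continue
                if grey is None or len(grey) < 1:
                    skip("individual", obs, stim, cond, "TOO_FEW_GREYS")
                    continue
                if dxy is None or len(dxy) < 2:
                    skip("individual", obs, stim, cond, "TOO_FEW_DISK_GREYS")
                    continue
                if indiv_scope == "per_observer":
                    try:
                        axis = geometry.hue_axis_from_typicals(stim, typ)
                    except DegenerateAxisError:
                        skip("individual", obs, stim, cond, "DEGENERATE_AXIS")
                        continue
                else:
                    axis = global_axis[(stim, cond)]
                try:
                    pred = model.predict_effect(
                        geometry.project_coords(typ, axis),
                        geometry.project_coords(dxy, axis),
                        level=model.AnalysisLevel.INDIVIDUAL,
                        epsilon=config.epsilon,
                        sd_mode=config.sd_mode,
                    )
                except DegenerateCueError:
                    skip("individual", obs, stim, cond, "DEGENERATE_CUE")
                    continue
                measured = geometry.measured_effect(
                    geometry.project_coords(grey, axis)
                )
                pair_rows.append({
                    "level": "individual", "observer_id": obs,
                    "stimulus_id": stim, "condition": cond,
                    "predicted": pred.M, "measured": measured,
                    "w_prior": pred.w_prior, "sd": pred.sd,
                })

    # ---- aggregate-level effect pairs -------------------------------------
    if "aggregated" in config.levels:
        for stim, cond in cells:
            axis = global_axis.get((stim, cond))
            if axis is None:
                continue
            typ_means, disk_means, effects = [], [], []
            for obs in observers:
                typ = typ_xy.get((stim, cond, obs))
                dxy = disk_by_obs.get(obs)
                grey = grey_xy.get((stim, cond, obs))
                if typ is not None and len(typ) >= 1 and dxy is not None and len(dxy) >= 1:
                    typ_means.append(float(geometry.project_coords(typ, axis).mean()))
                    disk_means.append(float(geometry.project_coords(dxy, axis).mean()))
                if grey is not None and len(grey) >= 1:
                    effects.append(
                        geometry.measured_effect(geometry.project_coords(grey, axis))
                    )
            if len(typ_means) < 2 or len(disk_means) < 2:
                skip("aggregate", "aggregate", stim, cond, "TOO_FEW_OBSERVERS")
                continue
            if not effects:
                skip("aggregate", "aggregate", stim, cond, "TOO_FEW_GREYS")
                continue
            try:
                pred = model.predict_effect(
                    typ_means, disk_means,
                    level=model.AnalysisLevel.AGGREGATE,
                    epsilon=config.epsilon,
                    sd_mode=config.sd_mode,
                )
            except DegenerateCueError:
                skip("aggregate", "aggregate", stim, cond, "DEGENERATE_CUE")
                continue
            pair_rows.append({
                "level": "aggregate", "observer_id": "aggregate",
                "stimulus_id": stim, "condition": cond,
                "predicted": pred.M, "measured": float(np.mean(effects)),
                "w_prior": pred.w_prior, "sd": pred.sd,
            })

    pairs = pd.DataFrame(
        pair_rows,
        columns=["level", "observer_id", "stimulus_id", "condition",
                 "predicted", "measured", "w_prior", "sd"],
    )

    # ---- evaluation approaches --------------------------------------------
    corr_rows: list[dict] = []
    diff_rows: list[dict] = []
    tail = config.tail

    def _to_pairs(df: pd.DataFrame) -> list[ev.EffectPair]:
        return [
            ev.EffectPair(r.observer_id, r.stimulus_id, r.condition,
                          r.predicted, r.measured)
            for r in df.itertuples()
        ]

    def add_corr(label_cond: str, effects: str, result) -> None:
        if isinstance(result, ev.IndividualSummary):
            corr_rows.append({
                "approach": "individual", "condition": label_cond,
                "effects": effects, "n": result.n_observers, "r": result.mean_r,
                "df": result.df, "t": result.t, "p": result.p,
                "tail": result.tail.value,
            })
        else:
            corr_rows.append({
                "approach": result.approach.value, "condition": label_cond,
                "effects": effects, "n": result.n, "r": result.r,
                "df": result.df, "t": result.t, "p": result.p,
                "tail": result.tail.value,
            })

    indiv = pairs[pairs["level"] == "individual"]
    if "individual" in config.levels and not indiv.empty:
        by_obs = ev.pairs_by_observer(_to_pairs(indiv))
        try:
            add_corr("all", "absolute", ev.individual_approach(
                by_obs, clamp=config.clamp_degenerate,
                by_condition=len(conditions) > 1, tail=tail))
        except InsufficientDataError as exc:
            skip("individual", "*", "*", "all", f"APPROACH_FAILED:{exc}")
        if len(conditions) > 1:
            for cond in conditions:
                sub = indiv[indiv["condition"] == cond]
                try:
                    add_corr(cond, "absolute", ev.individual_approach(
                        ev.pairs_by_observer(_to_pairs(sub)),
                        clamp=config.clamp_degenerate, tail=tail))
                except InsufficientDataError as exc:
                    skip("individual", "*", "*", cond, f"APPROACH_FAILED:{exc}")

    if "pooled" in config.levels and not indiv.empty:
        scopes = [("all", indiv)] + (
            [(c, indiv[indiv["condition"] == c]) for c in conditions]
            if len(conditions) > 1 else []
        )
        for cond, sub in scopes:
            try:
                add_corr(cond, "absolute", ev.pooled_approach(_to_pairs(sub), tail=tail))
            except InsufficientDataError as exc:
                skip("pooled", "*", "*", cond, f"APPROACH_FAILED:{exc}")
        if config.include_relative and len(conditions) > 1:
            rel = ev.relative_effects(_to_pairs(indiv),
                                      centre_predicted=config.centre_predicted)
            try:
                add_corr("all", "relative", ev.pooled_approach(rel, tail=tail))
            except InsufficientDataError as exc:
                skip("pooled", "*", "*", "all-relative", f"APPROACH_FAILED:{exc}")

    agg = pairs[pairs["level"] == "aggregate"]
    if "aggregated" in config.levels and not agg.empty:
        scopes = [("all", agg)] + (
            [(c, agg[agg["condition"] == c]) for c in conditions]
            if len(conditions) > 1 else []
        )
        for cond, sub in scopes:
            try:
                add_corr(cond, "absolute",
                         ev.aggregated_approach(_to_pairs(sub), tail=tail))
            except InsufficientDataError as exc:
                skip("aggregated", "*", "*", cond, f"APPROACH_FAILED:{exc}")
            try:
                d = ev.difference_test(_to_pairs(sub))
                diff_rows.append({
                    "condition": cond, "n": d.n, "delta": d.delta,
                    "t": d.t, "df": d.df, "p": d.p,
                })
            except InsufficientDataError as exc:
                skip("difference", "*", "*", cond, f"TEST_FAILED:{exc}")
        if config.include_relative and len(conditions) > 1:
            rel = ev.relative_effects(_to_pairs(agg),
                                      centre_predicted=config.centre_predicted)
            try:
                add_corr("all", "relative", ev.aggregated_approach(rel, tail=tail))
            except InsufficientDataError as exc:
                skip("aggregated", "*", "*", "all-relative",
                     f"APPROACH_FAILED:{exc}")

    correlations = pd.DataFrame(
        corr_rows,
        columns=["approach", "condition", "effects", "n", "r", "df", "t", "p", "tail"],
    )
    difference_tests = pd.DataFrame(
        diff_rows, columns=["condition", "n", "delta", "t", "df", "p"]
    )

    cfg_json = config.model_dump_json()
    provenance = {
        "package": "memcolour",
        "version": __version__,
        "config": config.model_dump(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "n_rows": int(len(data)),
        "n_observers": len(observers),
        "n_cells": len(cells),
    }
    return ResultsBundle(
        pairs=pairs,
        correlations=correlations,
        difference_tests=difference_tests,
        skipped=skipped,
        provenance=provenance,
    )
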