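"""End-to-end study replica: simulate -> detect -> summarize -> compare.

One seeded, fully configurable run reproduces the shape of the study's
analysis: a cohort of CON / LET / LET_TRF animals per diet is simulated,
LH pulses are detected with the three-criterion rule, pulsatility
parameters and estrous / qPCR endpoints are computed, and groups are
compared. Every stage writes a tidy CSV so each stage can be rerun
standalone; rerunning with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as lio
from .detect import (
    DetectionParams,
    compute_nadir,
    detect_pulses,
    find_candidate_peaks,
    passes_fall,
    passes_rise,
    summarize_profile,
)
from .estrous import EstrousLog, group_percent_diestrus, percent_diestrus
from .qpcr import fold_changes
from .simulate import (
    CtSimParams,
    EstrousSimParams,
    GroupPreset,
    animal_seed,
    default_presets,
    simulate_cohort,
    simulate_ct_table,
    simulate_estrous_log,
)
from .stats import ComparisonResult, two_group_t, two_way_anova

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

log = logging.getLogger(__name__)

PULSE_ENDPOINTS = ("freq_per_60min", "mean_amplitude", "mean_lh")


def _default_ct_tables() -> tuple[CtSimParams, ...]:
    ovary = {
        "L19": {},
        "Cyp17": {"LET": 1.0},
        "Cyp19": {"LET": 1.0},
        "Fshr": {"LET": 0.8},
    }
    poa = {"Gapdh": {}, "Kiss1r": {"LET": 0.8}, "Gnrh": {"LET": 0.8}}
    return tuple(
        CtSimParams(tissue=tissue, effects=effects, diet=diet)
        for diet in ("CHOW", "HF")
        for tissue, effects in (("ovary", ovary), ("hypothalamus_poa", poa))
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; fully serializable and hashable.

    estrous_arrest_bias inflates diestrus self-transition per group —
    letrozole arrests cycling whether or not feeding is time-restricted,
    so LET and LET_TRF share the elevated bias.
    """

    presets: tuple[GroupPreset, ...] = field(
        default_factory=lambda: tuple(default_presets("CHOW") + default_presets("HF"))
    )
    n_per_group: int = 10
    seed: int = 0
    detection: DetectionParams = field(default_factory=DetectionParams)
    estrous_days: int = 10
    estrous_arrest_bias: Mapping[str, float] = field(
        default_factory=lambda: {"CON": 0.0, "LET": 0.6, "LET_TRF": 0.6}
    )
    ct_tables: tuple[CtSimParams, ...] = field(default_factory=_default_ct_tables)
    stats_plan: Mapping[str, str] = field(default_factory=dict)
    control_group: str = "CON"

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        labels = [p.label for p in self.presets]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate preset labels")
        for design in self.stats_plan.values():
            if design not in ("two_group_t", "two_way_anova"):
                raise ValueError(f"unknown design {design!r} in stats plan")

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, Mapping):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return clean(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class RunReport:
    """Per-group endpoint summaries, comparisons and provenance.

    Every number here is recomputable from the CSVs in out_dir alone.
    """

    group_summary: pd.DataFrame
    comparisons: pd.DataFrame
    fold_changes: pd.DataFrame
    rejection_counts: dict[str, int]
    provenance: dict
    out_dir: Path


def _rejection_counts(profiles, params: DetectionParams) -> dict[str, int]:
    counts = {"candidates": 0, "rise": 0, "fall": 0, "amplitude": 0, "accepted": 0}
    for profile in profiles:
        for i in find_candidate_peaks(profile):
            counts["candidates"] += 1
            if not passes_rise(profile, i, params):
                counts["rise"] += 1
            elif not passes_fall(profile, i, params):
                counts["fall"] += 1
            elif profile.values[i] - compute_nadir(profile, i, params)[1] < params.min_amplitude:
                counts["amplitude"] += 1
            else:
                counts["accepted"] += 1
    return counts


def _group_summary(endpoints: pd.DataFrame) -> pd.DataFrame:
    out = (
        endpoints.dropna(subset=["value"])
        .groupby(["endpoint", "group", "diet"], sort=True)["value"]
        .agg(
            mean="mean",
            sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
            n="size",
        )
        .reset_index()
    )
    return out


def _compare_endpoints(
    endpoints: pd.DataFrame, config: PipelineConfig
) -> list[ComparisonResult]:
    results: list[ComparisonResult] = []
    diets = sorted(endpoints["diet"].unique())
    for endpoint, edf in endpoints.groupby("endpoint", sort=True):
        edf = edf.dropna(subset=["value"])
        design = config.stats_plan.get(endpoint, "two_group_t")
        if design == "two_way_anova" and len(diets) >= 2:
            results.extend(
                two_way_anova(edf, value_col="value", endpoint=endpoint)
            )
            continue
        for diet in diets:
            ddf = edf[edf["diet"] == diet]
            groups = sorted(ddf["group"].unique())
            ref = config.control_group
            for other in groups:
                if other == ref:
                    continue
                a = ddf.loc[ddf["group"] == other, "value"].to_numpy()
                b = ddf.loc[ddf["group"] == ref, "value"].to_numpy()
                if len(a) < 2 or len(b) < 2:
                    log.warning(
                        "skipping %s %s vs %s (%s): fewer than 2 values",
                        endpoint, other, ref, diet,
                    )
                    continue
                results.append(
                    two_group_t(
                        a, b, endpoint=endpoint, term=f"{other}_vs_{ref}:{diet}"
                    )
                )
    return results


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Run every stage, write all CSVs plus report.json, return the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), sort_keys=True, indent=1) + "\n"
    )

    # stage 1: simulate the LH cohort
    sims = simulate_cohort(config.presets, config.n_per_group, config.seed)
    profiles = [s.profile for s in sims]
    lio.write_profiles_csv(profiles, out / "profiles.csv")
    lio.write_truth_csv(sims, out / "true_pulses.csv")
    log.info("simulated %d profiles (%d presets x %d)", len(profiles),
             len(config.presets), config.n_per_group)

    # stage 2: detect pulses and summarize pulsatility
    peaks_by_animal = {
        p.animal_id: detect_pulses(p, config.detection) for p in profiles
    }
    lio.write_peaks_csv(peaks_by_animal, profiles, out / "peaks.csv")
    rejections = _rejection_counts(profiles, config.detection)
    log.info("peak filter audit: %s", rejections)
    summaries = [
        summarize_profile(p, peaks_by_animal[p.animal_id]) for p in profiles
    ]
    summary_df = lio.summaries_to_frame(summaries)
    summary_df.to_csv(out / "summaries.csv", index=False)

    # stage 3: estrous logs
    logs: list[EstrousLog] = []
    for preset in config.presets:
        bias = config.estrous_arrest_bias.get(preset.name, 0.0)
        eparams = EstrousSimParams(days=config.estrous_days, arrest_bias=bias)
        for i in range(config.n_per_group):
            logs.append(
                simulate_estrous_log(
                    eparams,
                    animal_id=f"{preset.name}-{preset.diet}-{i:03d}",
                    group=preset.name,
                    diet=preset.diet,
                    seed=animal_seed(config.seed, "estrous:" + preset.label, i),
                )
            )
    lio.write_estrous_csv(logs, out / "estrous.csv")
    group_percent_diestrus(logs).to_csv(out / "estrous_summary.csv")

    # stage 4: qPCR tables and fold changes
    ct_records = []
    for k, table in enumerate(config.ct_tables):
        sub = int(animal_seed(config.seed, f"ct:{table.tissue}:{table.diet}", k)
                  .generate_state(1)[0])
        ct_records.extend(simulate_ct_table(dataclasses.replace(table, seed=sub)))
    lio.ct_records_to_frame(ct_records).to_csv(out / "ct.csv", index=False)
    fc = fold_changes(ct_records, control_group=config.control_group)
    fc_df = lio.fold_changes_to_frame(fc)
    fc_df.to_csv(out / "fold_changes.csv", index=False)

    # stage 5: endpoint table and group comparisons
    pulse_rows = summary_df.melt(
        id_vars=["animal_id", "group", "diet"],
        value_vars=list(PULSE_ENDPOINTS),
        var_name="endpoint",
        value_name="value",
    )
    estrous_rows = pd.DataFrame(
        {
            "animal_id": [l.animal_id for l in logs],
            "group": [l.group for l in logs],
            "diet": [l.diet for l in logs],
            "endpoint": "pct_diestrus",
            "value": [percent_diestrus(l) for l in logs],
        }
    )
    endpoints = pd.concat([pulse_rows, estrous_rows], ignore_index=True)
    endpoints = endpoints[["animal_id", "group", "diet", "endpoint", "value"]]
    endpoints.to_csv(out / "endpoints.csv", index=False)

    comparisons = _compare_endpoints(endpoints, config)
    cmp_df = lio.comparisons_to_frame(comparisons)
    cmp_df.to_csv(out / "comparisons.csv", index=False)
    log.info("ran %d group comparisons (no multiplicity correction)", len(cmp_df))

    group_summary = _group_summary(endpoints)
    group_summary.to_csv(out / "group_summary.csv", index=False)

    from . import __version__

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_tests": int(len(cmp_df)),
    }
    report = {
        "provenance": provenance,
        "rejection_counts": rejections,
        "group_summary": group_summary.to_dict(orient="records"),
        "comparisons": cmp_df.to_dict(orient="records"),
        "fold_changes": fc_df.to_dict(orient="records"),
    }
    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1, allow_nan=True,
                   default=float) + "\n"
    )
    return RunReport(
        group_summary=group_summary,
        comparisons=cmp_df,
        fold_changes=fc_df,
        rejection_counts=rejections,
        provenance=provenance,
        out_dir=out,
    )
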