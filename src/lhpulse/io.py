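"""CSV readers and writers for every inter-stage table.

CSV is the single interchange format of the pipeline: profiles, ground
truth, peak tables, pulsatility summaries, estrous logs, Ct tables,
endpoint tables and comparison tables all round-trip through tidy CSVs
with fixed headers, so every stage can be rerun standalone from the
previous stage's files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import LHProfile, PulsePeak, PulseSummary
from .estrous import EstrousLog
from .qpcr import CtRecord, FoldChangeResult
from .stats import ComparisonResult

__all__ = [
    "profiles_to_frame",
    "frame_to_profiles",
    "write_profiles_csv",
    "read_profiles_csv",
    "write_truth_csv",
    "write_peaks_csv",
    "summaries_to_frame",
    "write_estrous_csv",
    "read_estrous_csv",
    "ct_records_to_frame",
    "frame_to_ct_records",
    "fold_changes_to_frame",
    "comparisons_to_frame",
]


def profiles_to_frame(profiles: Sequence[LHProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": p.animal_id,
                    "group": p.group,
                    "diet": p.diet,
                    "time_min": p.times,
                    "lh_ng_ml": p.values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_profiles(df: pd.DataFrame) -> list[LHProfile]:
    profiles = []
    for animal_id, g in df.groupby("animal_id", sort=False):
        g = g.sort_values("time_min")
        profiles.append(
            LHProfile(
                animal_id=str(animal_id),
                times=g["time_min"].to_numpy(float),
                values=g["lh_ng_ml"].to_numpy(float),
                group=str(g["group"].iloc[0]),
                diet=str(g["diet"].iloc[0]),
            )
        )
    return profiles


def write_profiles_csv(profiles: Sequence[LHProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles_csv(path: str | Path) -> list[LHProfile]:
    return frame_to_profiles(pd.read_csv(path))


def write_truth_csv(sims, path: str | Path) -> None:
    """Ground-truth pulse times and boluses for simulated cohorts."""
    rows = []
    for s in sims:
        for t, b in zip(s.true_pulse_times, s.true_boluses):
            rows.append((s.profile.animal_id, t, b))
    pd.DataFrame(
        rows, columns=["animal_id", "pulse_time_min", "bolus_ng_ml"]
    ).to_csv(path, index=False)


def write_peaks_csv(
    peaks_by_animal: dict[str, Sequence[PulsePeak]],
    profiles: Sequence[LHProfile],
    path: str | Path,
) -> None:
    times = {p.animal_id: p.times for p in profiles}
    rows = []
    for animal_id, peaks in peaks_by_animal.items():
        for pk in peaks:
            rows.append(
                (
                    animal_id,
                    pk.time,
                    pk.value,
                    times[animal_id][pk.nadir_index],
                    pk.nadir_value,
                    pk.amplitude,
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "animal_id",
            "peak_time_min",
            "peak_value",
            "nadir_time_min",
            "nadir_value",
            "amplitude",
        ],
    ).to_csv(path, index=False)


def summaries_to_frame(summaries: Sequence[PulseSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in summaries],
            "group": [s.group for s in summaries],
            "diet": [s.diet for s in summaries],
            "n_peaks": [s.n_peaks for s in summaries],
            "freq_per_60min": [s.frequency_per_60min for s in summaries],
            "mean_amplitude": [s.mean_amplitude for s in summaries],
            "mean_lh": [s.mean_lh for s in summaries],
        }
    )


def write_estrous_csv(logs: Sequence[EstrousLog], path: str | Path) -> None:
    rows = []
    for log in logs:
        for day, stage in enumerate(log.stages, start=1):
            rows.append((log.animal_id, log.group, log.diet, day, stage))
    pd.DataFrame(
        rows, columns=["animal_id", "group", "diet", "day", "stage"]
    ).to_csv(path, index=False)


def read_estrous_csv(path: str | Path) -> list[EstrousLog]:
    df = pd.read_csv(path)
    logs = []
    for animal_id, g in df.groupby("animal_id", sort=False):
        g = g.sort_values("day")
        logs.append(
            EstrousLog(
                animal_id=str(animal_id),
                stages=tuple(g["stage"]),
                group=str(g["group"].iloc[0]) if "group" in g else "",
                diet=str(g["diet"].iloc[0]) if "diet" in g else "",
            )
        )
    return logs


def ct_records_to_frame(records: Sequence[CtRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])[
        ["sample_id", "group", "diet", "tissue", "gene", "ct"]
    ]


def frame_to_ct_records(df: pd.DataFrame) -> list[CtRecord]:
    return [
        CtRecord(
            sample_id=str(r.sample_id),
            group=str(r.group),
            diet=str(r.diet),
            tissue=str(r.tissue),
            gene=str(r.gene),
            ct=float(r.ct),
        )
        for r in df.itertuples()
    ]


def fold_changes_to_frame(results: Sequence[FoldChangeResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])[
        ["tissue", "gene", "group", "mean_fold_change", "sem", "n"]
    ]


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "endpoint": [r.endpoint for r in results],
            "design": [r.design for r in results],
            "term": [r.term for r in results],
            "statistic": [r.statistic for r in results],
            "df": ["/".join(f"{d:g}" for d in r.df) for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
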