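"""Estrous-cyclicity metrics from daily stage logs.

Stages are coded P (proestrus), E (estrus), M (metestrus), D (diestrus).
The cyclicity endpoint is the percentage of days spent in diestrus over
the logging window (10 days in the study design); persistently elevated
diestrus occupancy indicates cycle arrest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STAGES = ("P", "E", "M", "D")

__all__ = ["STAGES", "EstrousLog", "percent_diestrus", "group_percent_diestrus"]


@dataclass(frozen=True)
class EstrousLog:
    """One animal's ordered daily stage sequence."""

    animal_id: str
    stages: tuple[str, ...]
    group: str = ""
    diet: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        if len(self.stages) < 1:
            raise ValueError("stage log must contain at least one day")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage code(s): {sorted(bad)}")


def percent_diestrus(log: EstrousLog) -> float:
    """Percentage of logged days in diestrus: 100 * #D / #days."""
    return 100.0 * sum(s == "D" for s in log.stages) / len(log.stages)


def group_percent_diestrus(
    logs: Sequence[EstrousLog],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group mean +/- SEM of per-animal diestrus percentages.

    labels defaults to each log's own group attribute. SEM uses the
    sample standard deviation (ddof=1) and is NaN for single-animal
    groups. Returns a DataFrame indexed by group with columns
    mean_pct_diestrus, sem, n.
    """
    if labels is None:
        labels = [log.group for log in logs]
    if len(labels) != len(logs):
        raise ValueError("labels and logs must have the same length")
    df = pd.DataFrame(
        {"group": list(labels), "pct": [percent_diestrus(log) for log in logs]}
    )
    out = df.groupby("group", sort=True)["pct"].agg(
        mean_pct_diestrus="mean",
        sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
        n="size",
    )
    if (out["n"] < 1).any():  # groupby cannot actually produce this
        raise ValueError("empty group")
    return out
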