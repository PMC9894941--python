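"""Relative gene expression by the 2^-ddCt method.

Each sample's target-gene Ct is normalized to a tissue-specific reference
gene (dCt = Ct_target - Ct_ref; L19 in ovary, Gapdh elsewhere), then
centered on the control group's mean dCt (ddCt), and expressed as the
fold change 2^-ddCt. Groups are reported as mean fold change relative to
control +/- SEM, the study's convention. Amplification efficiency is
fixed at 2 per cycle — that is what the method's name asserts — so no
standard-curve correction is applied.

Centering on the control-group *mean* dCt makes the geometric mean of the
control group's fold changes exactly 1 for every gene; the control group's
*arithmetic* mean fold is >= 1 by Jensen's inequality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Reference gene per tissue. The study names L19 for ovary and Gapdh for
#: pituitary/adipose; Gapdh is assumed for hypothalamus/POA, where the
#: reference is not stated.
REFERENCE_GENES = {
    "ovary": "L19",
    "adipose": "Gapdh",
    "pituitary": "Gapdh",
    "hypothalamus_poa": "Gapdh",
}

__all__ = [
    "REFERENCE_GENES",
    "CtRecord",
    "FoldChangeResult",
    "delta_ct",
    "sample_fold_changes",
    "fold_changes",
]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR threshold-cycle measurement."""

    sample_id: str
    group: str
    diet: str
    tissue: str
    gene: str
    ct: float

    def __post_init__(self) -> None:
        if self.tissue not in REFERENCE_GENES:
            raise ValueError(
                f"unknown tissue {self.tissue!r}; expected one of "
                f"{sorted(REFERENCE_GENES)}"
            )
        if not np.isfinite(self.ct) or self.ct <= 0:
            raise ValueError("ct must be a finite positive cycle number")


@dataclass(frozen=True)
class FoldChangeResult:
    """Group-level 2^-ddCt summary for one gene in one tissue."""

    tissue: str
    gene: str
    group: str
    mean_fold_change: float
    sem: float
    n: int


def delta_ct(ct_target: float, ct_ref: float) -> float:
    """dCt = Ct_target - Ct_ref (reference-gene normalization)."""
    return ct_target - ct_ref


def sample_fold_changes(
    records: Sequence[CtRecord], control_group: str = "CON"
) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold changes, one row per (sample, gene).

    ddCt = dCt_sample - mean(dCt over control samples of the same gene and
    tissue); fold = 2^-ddCt. Reference-gene rows are consumed for
    normalization and not themselves reported. Returns a tidy frame with
    columns sample_id, group, diet, tissue, gene, dct, ddct, fold.
    """
    if not records:
        raise ValueError("no Ct records")
    df = pd.DataFrame([vars(r) for r in records])
    if df.duplicated(["sample_id", "gene"]).any():
        raise ValueError("duplicate (sample, gene) Ct records")

    pieces = []
    for tissue, tdf in df.groupby("tissue", sort=True):
        ref_gene = REFERENCE_GENES[tissue]
        ref = tdf[tdf["gene"] == ref_gene].set_index("sample_id")["ct"]
        targets = tdf[tdf["gene"] != ref_gene]
        for gene, gdf in targets.groupby("gene", sort=True):
            missing = set(gdf["sample_id"]) - set(ref.index)
            if missing:
                raise ValueError(
                    f"no {ref_gene} reference Ct for sample(s) "
                    f"{sorted(missing)} in tissue {tissue!r}"
                )
            gdf = gdf.copy()
            gdf["dct"] = gdf["ct"].to_numpy() - ref.loc[gdf["sample_id"]].to_numpy()
            is_control = (gdf["group"] == control_group).to_numpy()
            if not is_control.any():
                raise ValueError(
                    f"gene {gene!r} ({tissue}) missing from control group "
                    f"{control_group!r}"
                )
            gdf["ddct"] = gdf["dct"] - gdf.loc[is_control, "dct"].mean()
            gdf["fold"] = np.power(2.0, -gdf["ddct"])
            pieces.append(
                gdf[["sample_id", "group", "diet", "tissue", "gene",
                     "dct", "ddct", "fold"]]
            )
    return pd.concat(pieces, ignore_index=True)


def fold_changes(
    records: Sequence[CtRecord], control_group: str = "CON"
) -> list[FoldChangeResult]:
    """Per-gene, per-group mean fold change vs the control group, +/- SEM.

    Per-sample folds come from sample_fold_changes and are averaged on the
    linear scale within each group, the study's reporting convention.
    """
    per_sample = sample_fold_changes(records, control_group)
    results: list[FoldChangeResult] = []
    for (tissue, gene, group), g in per_sample.groupby(
        ["tissue", "gene", "group"], sort=True
    ):
        f = g["fold"].to_numpy()
        results.append(
            FoldChangeResult(
                tissue=tissue,
                gene=gene,
                group=group,
                mean_fold_change=float(f.mean()),
                sem=float(f.std(ddof=1) / np.sqrt(len(f)))
                if len(f) > 1
                else float("nan"),
                n=len(f),
            )
        )
    return results
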