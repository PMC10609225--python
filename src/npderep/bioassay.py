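"""Turbidometric antibacterial screening statistics.

A 96-well plate (12 rows x 8 columns in this assay's orientation) is
read at OD600 before (t0) and after 24 h of incubation (t24). Row 1
holds four sterility wells (medium only) and four positive-control wells
(levofloxacin); rows 2-11 hold test extracts; row 12 holds the
negative-control wells (culture plus solvent). Growth inhibition of a
test well is

    inhibition % = [1 - (t24 - t0) / (C24 - C0)] x 100

against the plate's own negative-control growth, and a mean inhibition
strictly above 60% across triplicate plates calls an extract active.
Values are not clamped: lysis can exceed 100% and growth promotion can
go negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

N_ROWS, N_COLS = 12, 8

Role = Literal["sterility", "positive", "test", "negative"]


@dataclass(frozen=True)
class PlateLayout:
    """Role map for the 12x8 plate plus the (strain, medium) identity of
    each test well.

    ``roles[(row, col)]`` with 1-based coordinates; ``samples`` maps test
    wells to (strain, medium). The default layout puts sterility in row 1
    columns 1-4, positive controls in row 1 columns 5-8, tests in rows
    2-11 and negative controls in row 12.
    """

    roles: dict[tuple[int, int], Role]
    samples: dict[tuple[int, int], tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.roles) != N_ROWS * N_COLS:
            raise ValueError(f"layout must assign all {N_ROWS * N_COLS} wells")
        for well, role in self.roles.items():
            if role == "test" and well not in self.samples:
                raise ValueError(f"test well {well} has no (strain, medium) sample")

    @classmethod
    def default(cls, samples: dict[tuple[int, int], tuple[str, str]] | None = None) -> "PlateLayout":
        roles: dict[tuple[int, int], Role] = {}
        for row in range(1, N_ROWS + 1):
            for col in range(1, N_COLS + 1):
                if row == 1:
                    roles[(row, col)] = "sterility" if col <= 4 else "positive"
                elif row == N_ROWS:
                    roles[(row, col)] = "negative"
                else:
                    roles[(row, col)] = "test"
        if samples is None:
            samples = {(r, c): (f"strain_{(r - 2) * N_COLS + c}", "FM1")
                       for r in range(2, N_ROWS) for c in range(1, N_COLS + 1)}
        return cls(roles, samples)

    def wells(self, role: Role) -> list[tuple[int, int]]:
        return sorted(w for w, r in self.roles.items() if r == role)


@dataclass(frozen=True)
class ActivityCall:
    strain: str
    medium: str
    pathogen: str
    inhibition_pct: float
    active: bool
    n_replicates: int = 3


@dataclass(frozen=True)
class PlateValidation:
    plate_id: str
    valid: bool
    reasons: tuple[str, ...] = ()


def inhibition_percent(t0: float, t24: float, c0: float, c24: float) -> float:
    """[1 - (t24 - t0)/(C24 - C0)] x 100; errors if the control did not grow."""
    if c24 <= c0:
        raise ValueError(f"invalid control growth: C24={c24} <= C0={c0}")
    return (1.0 - (t24 - t0) / (c24 - c0)) * 100.0


def _plate_frame(readings: pd.DataFrame, plate_id: str) -> pd.DataFrame:
    return readings[readings["plate_id"] == plate_id]


def _require_complete(plate: pd.DataFrame, plate_id: str) -> None:
    have = {(int(r), int(c)) for r, c in zip(plate["row"], plate["col"])}
    expected = {(r, c) for r in range(1, N_ROWS + 1) for c in range(1, N_COLS + 1)}
    missing = sorted(expected - have)
    if missing:
        raise ValueError(f"plate {plate_id}: missing wells {missing}")


def negative_control_growth(plate: pd.DataFrame, layout: PlateLayout,
                            aggregate: Literal["mean", "median"] = "mean") -> tuple[float, float]:
    """(C0, C24) aggregated over the plate's negative-control wells."""
    neg = layout.wells("negative")
    sub = plate[[(int(r), int(c)) in set(neg) for r, c in zip(plate["row"], plate["col"])]]
    agg = np.mean if aggregate == "mean" else np.median
    return float(agg(sub["od_t0"])), float(agg(sub["od_t24"]))


def validate_plate(
    readings: pd.DataFrame,
    layout: PlateLayout,
    plate_id: str,
    sterility_max_delta: float = 0.05,
    positive_min_inhibition: float = 60.0,
    aggregate: Literal["mean", "median"] = "mean",
) -> PlateValidation:
    """Flag a plate invalid on contamination (any sterility well's delta-OD
    above ``sterility_max_delta``) or assay failure (mean positive-control
    inhibition below ``positive_min_inhibition``)."""
    plate = _plate_frame(readings, plate_id)
    _require_complete(plate, plate_id)
    reasons: list[str] = []
    by_well = {(int(r), int(c)): (t0, t24) for r, c, t0, t24 in
               zip(plate["row"], plate["col"], plate["od_t0"], plate["od_t24"])}
    for well in layout.wells("sterility"):
        t0, t24 = by_well[well]
        if t24 - t0 > sterility_max_delta:
            reasons.append(f"contamination: sterility well {well} grew {t24 - t0:.3f}")
    c0, c24 = negative_control_growth(plate, layout, aggregate)
    if c24 <= c0:
        reasons.append("assay failure: negative control did not grow")
    else:
        pos = [inhibition_percent(*by_well[w], c0, c24) for w in layout.wells("positive")]
        if float(np.mean(pos)) < positive_min_inhibition:
            reasons.append(f"assay failure: positive-control inhibition {np.mean(pos):.1f}%")
    return PlateValidation(plate_id, not reasons, tuple(reasons))


def call_activity(
    readings: pd.DataFrame,
    layout: PlateLayout,
    threshold: float = 60.0,
    aggregate: Literal["mean", "median"] = "mean",
    validate: bool = True,
) -> list[ActivityCall]:
    """Per (strain, medium, pathogen) activity calls across replicate plates.

    ``readings`` is long-format with columns plate_id, replicate, pathogen,
    row, col, od_t0, od_t24; each plate is one pathogen x one replicate.
    Each replicate's inhibition is computed against its own plate's
    negative-control aggregate, then replicates are averaged; ``active``
    requires mean inhibition strictly above ``threshold``.
    """
    required = {"plate_id", "replicate", "pathogen", "row", "col", "od_t0", "od_t24"}
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"readings missing columns {sorted(missing)}")
    per_well: dict[tuple[str, str, str], list[float]] = {}
    for plate_id in sorted(readings["plate_id"].unique()):
        plate = _plate_frame(readings, plate_id)
        pathogen = str(plate["pathogen"].iloc[0])
        if validate:
            report = validate_plate(readings, layout, plate_id, aggregate=aggregate)
            if not report.valid:
                continue
        c0, c24 = negative_control_growth(plate, layout, aggregate)
        by_well = {(int(r), int(c)): (t0, t24) for r, c, t0, t24 in
                   zip(plate["row"], plate["col"], plate["od_t0"], plate["od_t24"])}
        for well in layout.wells("test"):
            strain, medium = layout.samples[well]
            pct = inhibition_percent(*by_well[well], c0, c24)
            per_well.setdefault((strain, medium, pathogen), []).append(pct)
    calls = []
    for (strain, medium, pathogen), vals in sorted(per_well.items()):
        mean_pct = float(np.mean(vals))
        calls.append(ActivityCall(strain, medium, pathogen, mean_pct,
                                  mean_pct > threshold, len(vals)))
    return calls


def summarize_screen(calls: Sequence[ActivityCall]) -> dict[str, pd.DataFrame]:
    """Per-pathogen active-strain counts, per-medium active-strain counts,
    and per-strain best activity."""
    df = pd.DataFrame([c.__dict__ for c in calls],
                      columns=["strain", "medium", "pathogen", "inhibition_pct",
                               "active", "n_replicates"])
    if df.empty:
        empty = pd.DataFrame()
        return {"per_pathogen": pd.DataFrame(columns=["pathogen", "n_active_strains"]),
                "per_medium": pd.DataFrame(columns=["medium", "n_active_strains"]),
                "per_strain": pd.DataFrame(columns=["strain", "best_inhibition_pct",
                                                    "best_medium", "best_pathogen", "any_active"])}
    act = df[df["active"]]
    per_pathogen = (act.groupby("pathogen")["strain"].nunique()
                    .reindex(sorted(df["pathogen"].unique()), fill_value=0)
                    .rename("n_active_strains").reset_index())
    per_medium = (act.groupby("medium")["strain"].nunique()
                  .reindex(sorted(df["medium"].unique()), fill_value=0)
                  .rename("n_active_strains").reset_index())
    best_rows = []
    for strain, grp in df.groupby("strain"):
        top = grp.loc[grp["inhibition_pct"].idxmax()]
        best_rows.append({"strain": strain, "best_inhibition_pct": top["inhibition_pct"],
                          "best_medium": top["medium"], "best_pathogen": top["pathogen"],
                          "any_active": bool(grp["active"].any())})
    per_strain = pd.DataFrame(best_rows)
    return {"per_pathogen": per_pathogen, "per_medium": per_medium, "per_strain": per_strain}


def export_summary(summary: dict[str, pd.DataFrame], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in summary.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
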