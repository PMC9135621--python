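"""Within-participant fixed-effects combination of run-level beta maps.

Runs within an infusion phase are averaged without variance weighting;
within-day contrasts difference the on-drug phase (runs 4-6) against the
saline phase (runs 1-3); the between-day contrast differences the two
within-day contrasts, isolating the drug effect while cancelling run-order
effects by construction.  Any non-empty subset of a phase may be averaged,
which covers the degenerate single-run-per-phase fallback used when runs
are dropped for artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .config import DAYS
from .exceptions import ValidationError
from .maps import ConnectivityMap
from .utils import check_same_grid


@dataclass
class SessionLayout:
    """Run-to-phase assignment for one session day."""

    day: str
    phase_by_run: Dict[int, str] = field(default_factory=dict)  # run_index -> "early" | "late"

    def __post_init__(self):
        if self.day not in DAYS:
            raise ValidationError(f"unknown day label {self.day!r}; expected one of {DAYS}")
        phases = set(self.phase_by_run.values())
        if not phases <= {"early", "late"}:
            raise ValidationError("phases must be 'early' or 'late'")
        if "early" not in phases or "late" not in phases:
            raise ValidationError(f"day {self.day}: need at least one early and one late run")

    @classmethod
    def standard(cls, day: str, runs_per_phase: int = 3) -> "SessionLayout":
        mapping = {r: ("early" if r <= runs_per_phase else "late") for r in range(1, 2 * runs_per_phase + 1)}
        return cls(day=day, phase_by_run=mapping)

    def split(self, maps: Sequence[ConnectivityMap]):
        early = [m for m in maps if self.phase_by_run.get(m.run_index) == "early"]
        late = [m for m in maps if self.phase_by_run.get(m.run_index) == "late"]
        return early, late


def fixed_effects_average(maps: Sequence[ConnectivityMap]) -> ConnectivityMap:
    """Voxelwise unweighted mean of run-level maps."""
    maps = list(maps)
    if not maps:
        raise ValidationError("fixed_effects_average requires at least one map")
    check_same_grid([m.data for m in maps])
    data = np.mean([m.data for m in maps], axis=0)
    mask = None
    if any(m.mask is not None for m in maps):
        mask = np.logical_and.reduce([m.mask for m in maps if m.mask is not None])
    first = maps[0]
    return ConnectivityMap(
        data=data,
        participant_id=first.participant_id,
        condition=first.condition,
        run_index="combined",
        kind=first.kind,
        affine=first.affine,
        mask=mask,
    )


def within_day_contrast(
    late: Sequence[ConnectivityMap],
    early: Sequence[ConnectivityMap],
) -> ConnectivityMap:
    """mean(late, on-drug) - mean(early, saline) for one session day.

    Single-run lists are allowed on either side, covering the dropped-runs
    fallback where a day reduces to run 6 versus run 1.
    """
    if not late or not early:
        raise ValidationError("within_day_contrast requires non-empty late and early lists")
    late_mean = fixed_effects_average(late)
    early_mean = fixed_effects_average(early)
    check_same_grid([late_mean.data, early_mean.data], names=["late", "early"])
    mask = None
    if late_mean.mask is not None and early_mean.mask is not None:
        mask = late_mean.mask & early_mean.mask
    else:
        mask = late_mean.mask if late_mean.mask is not None else early_mean.mask
    return ConnectivityMap(
        data=late_mean.data - early_mean.data,
        participant_id=late_mean.participant_id,
        condition=late_mean.condition,
        run_index="combined",
        kind="beta",
        affine=late_mean.affine,
        mask=mask,
    )


def between_day_contrast(
    day_active: ConnectivityMap,
    day_placebo: ConnectivityMap,
) -> ConnectivityMap:
    """[active - saline] minus [placebo - saline] for one participant."""
    if (
        day_active.participant_id is not None
        and day_placebo.participant_id is not None
        and day_active.participant_id != day_placebo.participant_id
    ):
        raise ValidationError(
            "between_day_contrast: participant mismatch "
            f"({day_active.participant_id} vs {day_placebo.participant_id})"
        )
    check_same_grid([day_active.data, day_placebo.data], names=["active day", "placebo day"])
    mask = None
    if day_active.mask is not None and day_placebo.mask is not None:
        mask = day_active.mask & day_placebo.mask
    return ConnectivityMap(
        data=day_active.data - day_placebo.data,
        participant_id=day_active.participant_id,
        condition="active_vs_placebo_ketamine",
        run_index="combined",
        kind="beta",
        affine=day_active.affine,
        mask=mask,
    )


def session_contrasts(
    beta_maps_by_day: Dict[str, List[ConnectivityMap]],
    runs_per_phase: int = 3,
) -> Dict[str, ConnectivityMap]:
    """Within-day contrasts for PL-PK / PL-AK plus the between-day contrast.

    ``beta_maps_by_day`` maps day labels to run-level beta maps carrying
    their 1-based ``run_index``.  Also returns the fixed-effects average of
    the on-drug runs for every day present (used for ROI extraction across
    conditions).
    """
    out: Dict[str, ConnectivityMap] = {}
    for day, maps in beta_maps_by_day.items():
        layout = SessionLayout.standard(day, runs_per_phase)
        early, late = layout.split(maps)
        out[f"{day}:drug"] = fixed_effects_average(late)
        out[f"{day}:within"] = within_day_contrast(late, early)
    if "PL-AK:within" in out and "PL-PK:within" in out:
        out["between"] = between_day_contrast(out["PL-AK:within"], out["PL-PK:within"])
    return out
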