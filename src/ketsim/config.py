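"""Simulation and pipeline configuration.

``SimConfig`` fixes the generative conditions for the synthetic cohorts: the
voxel grid, session structure (two-phase drug sessions of three runs per
infusion phase, TR 2 s, 210 volumes per run), the group-wise template
loadings, and all noise amplitudes.  ``RunConfig`` wraps a ``SimConfig``
together with the inference thresholds used by the orchestrated pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import yaml

from .exceptions import ValidationError

#: Recognised diagnostic groups for the clinical arms.
GROUPS = ("HC", "SZ", "ESZ", "CHR-P")

#: Run-level drug conditions across the three session days.
CONDITIONS = ("saline", "placebo_ketamine", "active_ketamine", "lamotrigine_ketamine")

#: Session days: placebo-lamotrigine/placebo-ketamine, placebo-lamotrigine/
#: active-ketamine, active-lamotrigine/active-ketamine.
DAYS = ("PL-PK", "PL-AK", "AL-AK")

DAY_DRUG = {
    "PL-PK": "placebo_ketamine",
    "PL-AK": "active_ketamine",
    "AL-AK": "lamotrigine_ketamine",
}


def _default_groups() -> Dict[str, int]:
    return {"HC": 85, "CHR-P": 45, "ESZ": 74}


def _default_loadings() -> Dict[str, float]:
    return {"HC": 0.0, "CHR-P": 0.15, "ESZ": 0.3, "SZ": 0.3}


def _default_age_means() -> Dict[str, float]:
    return {"HC": 22.6, "CHR-P": 20.3, "ESZ": 21.9, "SZ": 38.7}


def _default_symptom_slopes() -> Dict[str, float]:
    # Only the hallucination domain is coupled to template expression by
    # default; all other domains are pure noise.
    return {"Hallucinations": 6.0}


@dataclass
class SimConfig:
    """Generative conditions for synthetic cohorts, sessions, and maps.

    Loadings are in connectivity-map units per spatial SD of the template
    pattern (the pattern is standardised to unit spatial SD); ``noise_sd``
    is the per-participant idiosyncratic map noise on the same scale, chosen
    so that patient-level similarity coefficients span roughly −0.4 … 0.6 as
    seen in clinical samples.
    """

    grid_dims: Tuple[int, int, int] = (24, 24, 24)
    n_participants_per_group: Dict[str, int] = field(default_factory=_default_groups)
    n_sites: int = 3
    tr_seconds: float = 2.0
    n_timepoints_per_run: int = 210
    runs_per_condition: int = 3
    template_loading: Dict[str, float] = field(default_factory=_default_loadings)
    loading_sd: float = 0.3          # between-participant SD of the loading within group
    site_offset_sd: float = 0.05     # voxelwise SD of each site's offset field
    age_slope_sd: float = 0.005      # voxelwise SD of the per-voxel age slope (units / year)
    baseline_sd: float = 0.2         # voxelwise SD of the shared baseline field
    noise_sd: float = 1.5            # per-participant map noise (map units)
    smooth_sigma: float = 1.5        # Gaussian sigma (voxels) for all smooth fields
    group_age_mean: Dict[str, float] = field(default_factory=_default_age_means)
    age_sd: float = 5.0
    # BOLD session generation
    n_ketamine: int = 18             # healthy volunteers in the drug study arm
    coupling_delta: float = 0.5      # peak seed-coupling increase under active ketamine
    lamotrigine_attenuation: float = 0.0  # fraction of the ketamine effect removed by pre-treatment
    bold_noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    # Symptom generation
    symptom_slopes: Dict[str, float] = field(default_factory=_default_symptom_slopes)
    symptom_slope: float = 6.0       # score units per unit Fisher-z (default coupled domain)
    symptom_intercept: float = 8.0
    symptom_noise_sd: float = 3.0
    subthreshold_global_fraction: float = 0.3
    rng_seed: int = 20220414

    def __post_init__(self):
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        # the scalar symptom_slope drives the default coupled domain unless a
        # full per-domain slope mapping was supplied
        if set(self.symptom_slopes) == {"Hallucinations"}:
            self.symptom_slopes = {"Hallucinations": float(self.symptom_slope)}
        self.validate()

    def validate(self) -> None:
        if len(self.grid_dims) != 3 or any(d < 1 for d in self.grid_dims):
            raise ValidationError("grid_dims must be three positive integers")
        n_vox = self.grid_dims[0] * self.grid_dims[1] * self.grid_dims[2]
        if n_vox < 64:
            raise ValidationError("grid too small to host seed and template regions")
        for g, n in self.n_participants_per_group.items():
            if g not in GROUPS:
                raise ValidationError(f"unknown group label {g!r}; expected one of {GROUPS}")
            if int(n) < 1:
                raise ValidationError(f"group {g}: count must be >= 1")
        for g in self.template_loading:
            if g not in GROUPS:
                raise ValidationError(f"unknown group label {g!r} in template_loading")
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if self.tr_seconds <= 0 or self.n_timepoints_per_run < 1:
            raise ValidationError("tr_seconds must be > 0 and n_timepoints_per_run >= 1")
        if self.runs_per_condition < 1:
            raise ValidationError("runs_per_condition must be >= 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        for name in ("site_offset_sd", "age_slope_sd", "baseline_sd", "loading_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0.0 <= self.subthreshold_global_fraction <= 1.0):
            raise ValidationError("subthreshold_global_fraction must be in [0, 1]")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_dims"] = list(self.grid_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunConfig:
    """Configuration for the orchestrated end-to-end pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    output_dir: str = "ketsim-run"
    cdt: float = 3.29                # cluster-defining |z| threshold (two-tailed p < 0.001)
    alpha: float = 0.05              # corrected cluster significance level
    fdr_q: float = 0.05
    seed_threshold: float = 0.80     # seed atlas probability threshold
    alpha_drop: float = 0.05         # interaction-dropping threshold
    skew_threshold: float = 1.0      # sample skewness above which scores are sqrt-transformed
    n_perm: int = 500

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.cdt <= 0:
            raise ValidationError("cdt must be > 0")
        for name in ("alpha", "fdr_q", "alpha_drop"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must be in (0, 1)")
        if not (0 < self.seed_threshold <= 1):
            raise ValidationError("seed_threshold must be in (0, 1]")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown RunConfig fields: {sorted(unknown)}")
        return cls(sim=SimConfig.from_dict(sim), **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # the hash identifies the analysis, not its location
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def demo_run_config(output_dir: str = "ketsim-demo", rng_seed: int = 20220414) -> RunConfig:
    """A desk-scale configuration that exercises every pipeline stage.

    Keeps the default 24^3 grid and full-length runs but shrinks the cohorts
    and the permutation count so a complete end-to-end run finishes in well
    under a minute.
    """
    sim = SimConfig(
        n_participants_per_group={"HC": 30, "CHR-P": 20, "ESZ": 25},
        n_ketamine=10,
        rng_seed=rng_seed,
    )
    return RunConfig(sim=sim, output_dir=output_dir, n_perm=300)
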