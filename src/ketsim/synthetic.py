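"""Synthetic cohorts, drug-session BOLD runs, connectivity maps, and symptom
tables.

The generator plants exactly the statistical structure the downstream
pipeline assumes:

* a seed region whose voxels share a latent time-series, with
  condition-dependent seed->voxel coupling that increases in designated
  "sensory" voxels under active ketamine, in proportion to a spatial
  template pattern;
* individual connectivity maps built from a shared smooth baseline,
  HC-referenced site offsets, per-voxel linear age trends, a group-specific
  loading of the template pattern, and smooth participant noise;
* symptom item scores linearly coupled to a participant's (Fisher-z)
  template expression, with a global severity rating that exercises the
  "at least mild (>= 2)" inclusion filter.

All randomness flows from ``SimConfig.rng_seed`` through keyed substreams
(:func:`ketsim.utils.substream`), so every output is bit-reproducible and
cohorts are extensible without reshuffling existing participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import CONDITIONS, DAY_DRUG, DAYS, GROUPS, SimConfig
from .exceptions import ValidationError
from .maps import BoldRun, ConnectivityMap, TemplateMap
from .utils import smooth_field, substream

SEXES = ("M", "F")

#: SAPS positive-symptom domains and SANS negative-symptom domains.
SAPS_DOMAINS = ("Hallucinations", "Delusions", "Thought Disorder", "Bizarre Behavior")
SANS_DOMAINS = ("Affective Flattening", "Alogia", "Avolition/Apathy", "Anhedonia/Asociality")
SOPS_DOMAINS = ("Positive", "Negative", "Disorganized", "General")

N_ITEMS = 5  # items per symptom domain in the generated tables


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class Participant:
    id: str
    group: str
    site: int
    age: float
    sex: str
    true_loading: float


@dataclass
class Cohort:
    participants: List[Participant]
    config: SimConfig

    def __iter__(self):
        return iter(self.participants)

    def __len__(self):
        return len(self.participants)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": p.id,
                    "group": p.group,
                    "site": p.site,
                    "age": p.age,
                    "sex": p.sex,
                    "true_loading": p.true_loading,
                }
                for p in self.participants
            ]
        )


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw a cohort with group-specific template loadings.

    Per participant the loading is Normal(lambda_g, ``loading_sd``); sites
    and sexes are assigned round-robin so groups are balanced across sites.
    """
    participants: List[Participant] = []
    idx = 0
    for group, n in config.n_participants_per_group.items():
        if group not in GROUPS:
            raise ValidationError(f"unknown group label {group!r}")
        lam_g = float(config.template_loading.get(group, 0.0))
        age_mean = float(config.group_age_mean.get(group, 30.0))
        for j in range(int(n)):
            rng = substream(config.rng_seed, "participant", idx)
            lam = lam_g + config.loading_sd * rng.standard_normal()
            age = max(16.0, age_mean + config.age_sd * rng.standard_normal())
            participants.append(
                Participant(
                    id=f"sub-{idx + 1:04d}",
                    group=group,
                    site=idx % config.n_sites,
                    age=float(age),
                    sex=SEXES[j % 2],
                    true_loading=float(lam),
                )
            )
            idx += 1
    return Cohort(participants=participants, config=config)


# ---------------------------------------------------------------------------
# Spatial structure: seed region and template pattern
# ---------------------------------------------------------------------------

def _bump(shape, center, radius) -> np.ndarray:
    """Smooth radial bump, 1 at the centre, 0 outside ``radius``."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    r2 = float(radius) ** 2
    out = np.clip(1.0 - d2 / r2, 0.0, None)
    return out**2


def make_seed_probability_map(config: SimConfig) -> np.ndarray:
    """Probabilistic atlas map for the seed: a central blob peaking at 1.

    Thresholding at the default 0.80 keeps a compact core of voxels
    (>= 8 voxels on the default grid), mimicking a stringent probability
    cut on a subcortical atlas.
    """
    shape = config.grid_dims
    center = tuple(s // 2 for s in shape)
    radius = max(3.5, min(shape) / 5.0)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    prob = np.clip(1.0 - d2 / radius**2, 0.0, None)
    core = prob >= 0.8
    if core.sum() < 8:
        raise ValidationError("grid too small to host an 8-voxel seed region")
    return prob


def make_template_pattern(config: SimConfig) -> TemplateMap:
    """Ground-truth dysconnectivity pattern, standardised to unit spatial SD.

    A positive "sensory" lobe (the hyper-connectivity planted under active
    ketamine) plus a weaker negative lobe, both offset from the seed.  The
    positive support defines the "sensory" voxels used by the BOLD
    simulator.  Loadings elsewhere in the package are expressed per spatial
    SD of this pattern.
    """
    shape = config.grid_dims
    cx, cy, cz = (s // 2 for s in shape)
    r = max(3.0, min(shape) / 5.0)
    pos = _bump(shape, (int(cx + shape[0] * 0.25), cy, cz), r * 1.2)
    neg = _bump(shape, (int(max(0, cx - shape[0] * 0.25)), cy, cz), r)
    raw = pos - 0.5 * neg
    sd = raw.std()
    if sd == 0:
        raise ValidationError("grid too small to host the template pattern")
    data = raw / sd
    if int((data > 0).sum()) < 8:
        raise ValidationError("grid too small: sensory region under 8 voxels")
    return TemplateMap(data=data, provenance="synthetic-truth")


# ---------------------------------------------------------------------------
# BOLD sessions
# ---------------------------------------------------------------------------

def _latent_series(rng: np.random.Generator, t: int) -> np.ndarray:
    s = gaussian_filter1d(rng.standard_normal(t), sigma=2.0, mode="wrap")
    s -= s.mean()
    sd = s.std()
    return s / sd if sd > 0 else s


def _coupling_map(
    participant: Participant,
    condition: str,
    config: SimConfig,
    seed_mask: np.ndarray,
    template: np.ndarray,
) -> np.ndarray:
    rng = substream(config.rng_seed, "coupling", participant.id)
    w = 0.2 * smooth_field(rng, config.grid_dims, config.smooth_sigma, 1.0)
    w[seed_mask] = 1.0
    if condition in ("active_ketamine", "lamotrigine_ketamine"):
        sensory = template > 0
        delta = config.coupling_delta
        if condition == "lamotrigine_ketamine":
            delta *= 1.0 - config.lamotrigine_attenuation
        peak = template.max()
        if peak > 0:
            w = w + np.where(sensory, delta * template / peak, 0.0)
    return w


def simulate_bold_session(
    participant: Participant,
    condition: str,
    config: SimConfig,
    template: Optional[TemplateMap] = None,
    seed_prob: Optional[np.ndarray] = None,
    noise_sd: Optional[float] = None,
) -> List[BoldRun]:
    """Simulate one two-phase session: runs 1-3 saline, runs 4-6 on-drug.

    Every voxel follows ``w_v(condition) * s(t) + drift + noise`` where
    ``s(t)`` is the latent seed series of that run; the coupling ``w_v``
    switches from the saline map to the condition map between phases.
    ``condition`` names the double-blind infusion of the session's second
    phase (or ``"saline"`` for an all-saline session).
    """
    if condition not in CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    template = template if template is not None else make_template_pattern(config)
    seed_prob = seed_prob if seed_prob is not None else make_seed_probability_map(config)
    seed_mask = seed_prob >= 0.8
    sigma = config.bold_noise_sd if noise_sd is None else noise_sd

    w_saline = _coupling_map(participant, "saline", config, seed_mask, template.data)
    w_drug = _coupling_map(participant, condition, config, seed_mask, template.data)

    n_runs = 2 * config.runs_per_condition
    t = config.n_timepoints_per_run
    runs: List[BoldRun] = []
    for run_index in range(1, n_runs + 1):
        late = run_index > config.runs_per_condition
        w = w_drug if late else w_saline
        run_condition = condition if late else "saline"
        rng = substream(config.rng_seed, "bold", participant.id, condition, run_index)
        s = _latent_series(rng, t)
        drift_slope = config.drift_amplitude * rng.standard_normal(config.grid_dims)
        ramp = np.linspace(-0.5, 0.5, t)
        data = (
            w[..., None] * s[None, None, None, :]
            + drift_slope[..., None] * ramp[None, None, None, :]
        )
        if sigma > 0:
            data = data + sigma * rng.standard_normal(data.shape)
        runs.append(
            BoldRun(
                data=data,
                tr_seconds=config.tr_seconds,
                run_index=run_index,
                condition=run_condition,
                participant_id=participant.id,
            )
        )
    return runs


def simulate_drug_study(
    config: SimConfig,
    days: Sequence[str] = DAYS,
    noise_sd: Optional[float] = None,
):
    """Yield ``(participant, day, runs)`` for the healthy-volunteer drug arm."""
    template = make_template_pattern(config)
    seed_prob = make_seed_probability_map(config)
    for idx in range(config.n_ketamine):
        rng = substream(config.rng_seed, "ketamine-participant", idx)
        participant = Participant(
            id=f"ket-{idx + 1:03d}",
            group="HC",
            site=0,
            age=float(max(18.0, 28.0 + 4.0 * rng.standard_normal())),
            sex="M",
            true_loading=0.0,
        )
        for day in days:
            runs = simulate_bold_session(
                participant,
                DAY_DRUG[day],
                config,
                template=template,
                seed_prob=seed_prob,
                noise_sd=noise_sd,
            )
            yield participant, day, runs


# ---------------------------------------------------------------------------
# Connectivity maps (clinical arms)
# ---------------------------------------------------------------------------

@dataclass
class CohortFields:
    """Cohort-level smooth fields shared by every participant's map."""

    baseline: np.ndarray
    site_offsets: np.ndarray  # (n_sites, x, y, z)
    age_slopes: np.ndarray
    age_reference: float


def make_cohort_fields(config: SimConfig) -> CohortFields:
    rng = substream(config.rng_seed, "fields")
    baseline = smooth_field(rng, config.grid_dims, config.smooth_sigma, config.baseline_sd)
    site_offsets = np.stack(
        [
            smooth_field(rng, config.grid_dims, config.smooth_sigma, config.site_offset_sd)
            for _ in range(config.n_sites)
        ]
    )
    age_slopes = smooth_field(rng, config.grid_dims, config.smooth_sigma, config.age_slope_sd)
    weights = np.array(
        [config.n_participants_per_group.get(g, 0) for g in config.group_age_mean], dtype=float
    )
    means = np.array([config.group_age_mean[g] for g in config.group_age_mean], dtype=float)
    age_reference = float(np.average(means, weights=weights)) if weights.sum() else float(means.mean())
    return CohortFields(baseline, site_offsets, age_slopes, age_reference)


def simulate_connectivity_map(
    participant: Participant,
    template: TemplateMap,
    config: SimConfig,
    fields: Optional[CohortFields] = None,
) -> ConnectivityMap:
    """One participant's Fisher-z connectivity map.

    ``map = baseline + site offset + age slope * (age - reference)
    + loading * template + smooth noise``; continuous in every parameter.
    """
    if tuple(template.data.shape) != tuple(config.grid_dims):
        from .exceptions import GridMismatchError

        raise GridMismatchError(
            f"template grid {template.data.shape} != config grid {config.grid_dims}"
        )
    fields = fields if fields is not None else make_cohort_fields(config)
    rng = substream(config.rng_seed, "map", participant.id)
    noise = smooth_field(rng, config.grid_dims, config.smooth_sigma, config.noise_sd)
    data = (
        fields.baseline
        + fields.site_offsets[participant.site]
        + fields.age_slopes * (participant.age - fields.age_reference)
        + participant.true_loading * template.data
        + noise
    )
    return ConnectivityMap(
        data=data,
        participant_id=participant.id,
        condition=None,
        run_index="combined",
        kind="fisher_z",
    )


def simulate_connectivity_cohort(
    cohort: Cohort,
    template: Optional[TemplateMap] = None,
    config: Optional[SimConfig] = None,
) -> List[ConnectivityMap]:
    config = config or cohort.config
    template = template if template is not None else make_template_pattern(config)
    fields = make_cohort_fields(config)
    return [simulate_connectivity_map(p, template, config, fields) for p in cohort]


def simulate_between_day_contrasts(
    n: int,
    config: SimConfig,
    delta: float = 0.0,
    template: Optional[TemplateMap] = None,
    contrast_noise_sd: float = 0.1,
    replicate: int = 0,
) -> List[ConnectivityMap]:
    """Directly draw per-participant between-day contrast maps.

    Used for replicate studies of the group cluster test where simulating
    full BOLD sessions would add nothing: each map is smooth zero-mean noise
    plus ``delta * template``.  With ``delta = 0`` the drug effect is absent,
    so any surviving cluster is a false positive.
    """
    template = template if template is not None else make_template_pattern(config)
    maps = []
    for i in range(int(n)):
        rng = substream(config.rng_seed, "contrast", replicate, i)
        noise = smooth_field(rng, config.grid_dims, config.smooth_sigma, contrast_noise_sd)
        maps.append(
            ConnectivityMap(
                data=noise + delta * template.data,
                participant_id=f"ket-{i + 1:03d}",
                kind="beta",
            )
        )
    return maps


# ---------------------------------------------------------------------------
# Symptoms
# ---------------------------------------------------------------------------

def _domains_for_group(group: str):
    if group == "CHR-P":
        return [("SOPS", d) for d in SOPS_DOMAINS]
    if group in ("SZ", "ESZ"):
        return [("SAPS", d) for d in SAPS_DOMAINS] + [("SANS", d) for d in SANS_DOMAINS]
    return []


def simulate_symptoms(
    participant: Participant,
    true_fisher_z: float,
    config: SimConfig,
) -> pd.DataFrame:
    """Symptom item table for one participant.

    Each domain's item sum is ``round(max(0, intercept + slope * fisher_z
    + noise))`` with the slope taken from ``config.symptom_slopes`` (zero for
    uncoupled domains); the sum is split across five items.  The global
    rating is drawn independently, with ``subthreshold_global_fraction`` of
    ratings below 2 so the inclusion filter has something to exclude.
    """
    rng = substream(config.rng_seed, "symptoms", participant.id)
    rows = []
    for scale, domain in _domains_for_group(participant.group):
        slope = float(config.symptom_slopes.get(domain, 0.0))
        latent = (
            config.symptom_intercept
            + slope * float(true_fisher_z)
            + config.symptom_noise_sd * rng.standard_normal()
        )
        item_sum = int(round(max(0.0, latent)))
        items = rng.multinomial(item_sum, np.full(N_ITEMS, 1.0 / N_ITEMS))
        if rng.uniform() < config.subthreshold_global_fraction:
            global_rating = int(rng.integers(0, 2))
        else:
            global_rating = int(rng.integers(2, 6))
        row = {"id": participant.id, "scale": scale, "domain": domain}
        row.update({f"item{k + 1}": int(v) for k, v in enumerate(items)})
        row["global"] = global_rating
        rows.append(row)
    cols = ["id", "scale", "domain"] + [f"item{k + 1}" for k in range(N_ITEMS)] + ["global"]
    return pd.DataFrame(rows, columns=cols)


def simulate_symptom_table(
    cohort: Cohort,
    fisher_z_by_id: Dict[str, float],
    config: Optional[SimConfig] = None,
) -> pd.DataFrame:
    """Stack per-participant symptom tables for every clinical participant."""
    config = config or cohort.config
    frames = [
        simulate_symptoms(p, fisher_z_by_id.get(p.id, 0.0), config)
        for p in cohort
        if _domains_for_group(p.group)
    ]
    if not frames:
        return pd.DataFrame(
            columns=["id", "scale", "domain"] + [f"item{k + 1}" for k in range(N_ITEMS)] + ["global"]
        )
    return pd.concat(frames, ignore_index=True)
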