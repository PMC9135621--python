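"""Seed definition and first-level voxelwise GLM.

The seed is the set of atlas voxels at or above a probability threshold
(default 0.80).  Each run's voxel time-series is regressed by ordinary least
squares on the seed's mean time-series plus nuisance regressors (intercept
and linear drift by default); the map of seed coefficients is the run's
connectivity beta map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import EstimationError, GridMismatchError, ThresholdError, ValidationError
from .maps import BoldRun, ConnectivityMap


@dataclass
class SeedDefinition:
    """Probabilistic seed map thresholded into a binary mask."""

    probability_map: np.ndarray
    threshold: float = 0.80
    binary_mask: np.ndarray = field(init=False)

    def __post_init__(self):
        p = np.asarray(self.probability_map, dtype=float)
        if p.min() < 0 or p.max() > 1:
            raise ValidationError("seed probability map values must lie in [0, 1]")
        if not (0 < self.threshold <= 1):
            raise ValidationError("seed threshold must be in (0, 1]")
        self.probability_map = p
        self.binary_mask = p >= self.threshold
        if not self.binary_mask.any():
            raise ThresholdError(
                f"seed mask empty at threshold {self.threshold}; max probability {p.max():.3f}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.binary_mask.sum())


def threshold_seed(probability_map: np.ndarray, threshold: float = 0.80) -> SeedDefinition:
    """Binary seed mask from a probabilistic atlas map (``p >= threshold``)."""
    return SeedDefinition(probability_map=probability_map, threshold=threshold)


def extract_seed_timeseries(
    run: BoldRun,
    seed: SeedDefinition,
    smoothing_fwhm_voxels: float = 0.0,
) -> np.ndarray:
    """Unweighted spatial mean over seed voxels at each timepoint.

    The seed series is always taken from the unsmoothed input; the optional
    spatial smoothing applies to voxel series only (see
    :func:`smooth_run`), matching the convention of extracting the seed
    before smoothing.
    """
    del smoothing_fwhm_voxels  # the seed is never smoothed; kept for signature clarity
    if run.grid != seed.binary_mask.shape:
        raise GridMismatchError(
            f"run grid {run.grid} does not match seed grid {seed.binary_mask.shape}"
        )
    return run.data[seed.binary_mask].mean(axis=0)


def smooth_run(run: BoldRun, fwhm_voxels: float) -> BoldRun:
    """Gaussian-smooth each volume of a run (spatial axes only)."""
    if fwhm_voxels <= 0:
        return run
    sigma = fwhm_voxels / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    data = gaussian_filter(run.data, sigma=(sigma, sigma, sigma, 0.0))
    return BoldRun(
        data=data,
        tr_seconds=run.tr_seconds,
        run_index=run.run_index,
        condition=run.condition,
        participant_id=run.participant_id,
        affine=run.affine,
    )


@dataclass
class FirstLevelDesign:
    """Seed regressor plus nuisance matrix (intercept + linear drift by default)."""

    seed_regressor: np.ndarray
    nuisance_regressors: np.ndarray
    nuisance_names: list = field(default_factory=list)

    def __post_init__(self):
        self.seed_regressor = np.asarray(self.seed_regressor, dtype=float).ravel()
        self.nuisance_regressors = np.atleast_2d(np.asarray(self.nuisance_regressors, dtype=float))
        if self.nuisance_regressors.shape[0] != self.seed_regressor.size:
            self.nuisance_regressors = self.nuisance_regressors.T
        if self.nuisance_regressors.shape[0] != self.seed_regressor.size:
            raise ValidationError("nuisance matrix rows must match the seed regressor length")
        if not np.all(np.isfinite(self.seed_regressor)) or not np.all(
            np.isfinite(self.nuisance_regressors)
        ):
            raise ValidationError("design contains non-finite values")
        if not self.nuisance_names:
            self.nuisance_names = [f"nuisance{i}" for i in range(self.nuisance_regressors.shape[1])]

    @property
    def n_timepoints(self) -> int:
        return self.seed_regressor.size

    @property
    def matrix(self) -> np.ndarray:
        """Full design: seed regressor first, nuisance columns after."""
        return np.column_stack([self.seed_regressor, self.nuisance_regressors])

    @property
    def column_names(self) -> list:
        return ["seed"] + list(self.nuisance_names)


def default_design(
    seed_timeseries: np.ndarray,
    extra_nuisance: Optional[np.ndarray] = None,
    extra_names: Optional[list] = None,
) -> FirstLevelDesign:
    """Seed + intercept + linear drift, plus optional user-supplied columns.

    Task-related activity to be removed (as in task-regressed connectivity)
    enters as additional nuisance columns here.
    """
    t = np.asarray(seed_timeseries).size
    cols = [np.ones(t), np.linspace(-0.5, 0.5, t)]
    names = ["intercept", "drift"]
    if extra_nuisance is not None:
        extra = np.atleast_2d(np.asarray(extra_nuisance, dtype=float))
        if extra.shape[0] != t:
            extra = extra.T
        for j in range(extra.shape[1]):
            cols.append(extra[:, j])
            names.append(
                extra_names[j] if extra_names and j < len(extra_names) else f"extra{j}"
            )
    return FirstLevelDesign(
        seed_regressor=seed_timeseries,
        nuisance_regressors=np.column_stack(cols),
        nuisance_names=names,
    )


def fit_first_level(run: BoldRun, design: FirstLevelDesign) -> ConnectivityMap:
    """Voxelwise OLS of each voxel's series on [seed | nuisance].

    Returns the map of seed coefficients.  Voxels whose series has zero
    variance are assigned beta 0 and flagged out of the analysis mask.
    """
    if run.n_timepoints != design.n_timepoints:
        raise ValidationError(
            f"run has {run.n_timepoints} timepoints but design has {design.n_timepoints}"
        )
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by checking each against the rest
        offenders = []
        for j, name in enumerate(design.column_names):
            rest = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(X):
                offenders.append(name)
        raise EstimationError(
            "design matrix is rank-deficient; collinear columns: " + ", ".join(offenders)
        )
    grid = run.grid
    Y = run.data.reshape(-1, run.n_timepoints).T  # (t, V)
    variance = Y.var(axis=0)
    in_mask = variance > 0
    beta_all = np.linalg.solve(X.T @ X, X.T @ Y)  # (k, V)
    seed_beta = np.where(in_mask, beta_all[0], 0.0)
    return ConnectivityMap(
        data=seed_beta.reshape(grid),
        participant_id=run.participant_id,
        condition=run.condition,
        run_index=run.run_index,
        kind="beta",
        affine=run.affine,
        mask=in_mask.reshape(grid),
    )


def run_to_beta_map(
    run: BoldRun,
    seed: SeedDefinition,
    extra_nuisance: Optional[np.ndarray] = None,
    smoothing_fwhm_voxels: float = 0.0,
) -> ConnectivityMap:
    """Convenience: seed extraction + default design + first-level fit."""
    seed_ts = extract_seed_timeseries(run, seed)
    if smoothing_fwhm_voxels > 0:
        run = smooth_run(run, smoothing_fwhm_voxels)
    design = default_design(seed_ts, extra_nuisance=extra_nuisance)
    return fit_first_level(run, design)
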