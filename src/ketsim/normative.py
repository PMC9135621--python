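"""Normative reference modelling against healthy controls.

Per voxel, an OLS regression is fitted on HC participants only — either on
site (dummy-coded factor) or on linear age — and every individual map is
re-expressed as a deviation z-map: ``(observed - predicted) / residual SE``,
where the residual SE is ``sqrt(RSS / (n_hc - k))`` from the HC fit.  The
result puts each voxel in standard-deviation units relative to a healthy
control at the same site (or of the same age).  Patient maps never enter
the fit; fitting rejects non-HC rows outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import EstimationError, GridMismatchError, ValidationError
from .maps import ConnectivityMap, ZScoreMap
from .utils import check_same_grid

KINDS = ("site", "age")


@dataclass
class NormativeModel:
    """Per-voxel HC regression coefficients and residual SE."""

    kind: str                      # "site" | "age"
    coef: np.ndarray               # (k, x, y, z)
    resid_se: np.ndarray           # (x, y, z); NaN where masked
    mask: np.ndarray               # True where the model is usable
    n_hc: int
    site_levels: Optional[List[int]] = None  # site kind only
    age_mean: Optional[float] = None         # age kind only

    @property
    def k(self) -> int:
        return self.coef.shape[0]

    @property
    def grid(self) -> tuple:
        return self.resid_se.shape


def _design_row(model_kind: str, covariates_row: pd.Series, site_levels, age_mean) -> np.ndarray:
    if model_kind == "site":
        site = int(covariates_row["site"])
        if site not in site_levels:
            raise ValidationError(
                f"site {site} was not present in the HC reference fit (levels: {site_levels})"
            )
        row = np.zeros(len(site_levels))
        row[site_levels.index(site)] = 1.0
        return row
    age = float(covariates_row["age"])
    return np.array([1.0, age - age_mean])


def fit_normative_model(
    hc_maps: Sequence[ConnectivityMap],
    covariates: pd.DataFrame,
    kind: str = "site",
) -> NormativeModel:
    """Fit the per-voxel HC reference regression.

    ``covariates`` must align row-for-row with ``hc_maps`` and carry a
    ``group`` column (all rows must be HC) plus ``site`` or ``age``.  The
    site design is a saturated cell-means coding (one dummy per site); the
    age design is intercept + centred linear age.  Voxels with (near-)zero
    residual variance in the HC fit are masked out.
    """
    if kind not in KINDS:
        raise ValidationError(f"kind must be one of {KINDS}")
    maps = list(hc_maps)
    if len(maps) != len(covariates):
        raise ValidationError("covariates table must align with hc_maps")
    if "group" not in covariates.columns:
        raise ValidationError("covariates must include a 'group' column")
    non_hc = covariates.loc[covariates["group"] != "HC"]
    if len(non_hc):
        raise ValidationError(
            f"normative fitting accepts HC rows only; found groups {sorted(non_hc['group'].unique())}"
        )
    grid = check_same_grid([m.data for m in maps])
    n = len(maps)

    site_levels = None
    age_mean = None
    if kind == "site":
        counts = covariates["site"].value_counts()
        thin = counts[counts < 2]
        if len(thin):
            raise EstimationError(
                "each site needs >= 2 HC for a residual SE; offending sites: "
                + ", ".join(str(s) for s in sorted(thin.index))
            )
        site_levels = sorted(int(s) for s in counts.index)
        X = np.zeros((n, len(site_levels)))
        for i, s in enumerate(covariates["site"]):
            X[i, site_levels.index(int(s))] = 1.0
    else:
        ages = covariates["age"].to_numpy(dtype=float)
        age_mean = float(ages.mean())
        X = np.column_stack([np.ones(n), ages - age_mean])

    k = X.shape[1]
    if n <= k + 1:
        raise EstimationError(f"need n_hc > k + 1 (n_hc={n}, k={k})")

    Y = np.stack([m.data for m in maps]).reshape(n, -1)  # (n, V)
    finite = np.all(np.isfinite(Y), axis=0)
    Yf = np.where(finite, Y, 0.0)
    beta = np.linalg.solve(X.T @ X, X.T @ Yf)  # (k, V)
    resid = Yf - X @ beta
    rss = np.sum(resid**2, axis=0)
    dof = n - k
    se = np.sqrt(rss / dof)
    usable = finite & (se > 1e-12)
    se = np.where(usable, se, np.nan)
    return NormativeModel(
        kind=kind,
        coef=beta.reshape((k,) + grid),
        resid_se=se.reshape(grid),
        mask=usable.reshape(grid),
        n_hc=n,
        site_levels=site_levels,
        age_mean=age_mean,
    )


def predict_map(model: NormativeModel, covariates_row: pd.Series) -> np.ndarray:
    row = _design_row(model.kind, covariates_row, model.site_levels, model.age_mean)
    return np.tensordot(row, model.coef, axes=1)


def zscore_map(
    cmap: ConnectivityMap,
    covariates_row: pd.Series,
    model: NormativeModel,
) -> ZScoreMap:
    """Deviation z-map: (observed - predicted) / residual SE, NaN outside mask."""
    if cmap.grid != model.grid:
        raise GridMismatchError(f"map grid {cmap.grid} != model grid {model.grid}")
    predicted = predict_map(model, covariates_row)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (cmap.data - predicted) / model.resid_se
    z = np.where(model.mask, z, np.nan)
    return ZScoreMap(
        data=z,
        participant_id=cmap.participant_id or "",
        reference=model.kind,
        affine=cmap.affine,
        mask=model.mask.copy(),
    )


def zscore_cohort(
    maps: Sequence[ConnectivityMap],
    covariates: pd.DataFrame,
    model: NormativeModel,
) -> List[ZScoreMap]:
    """Score every participant's map against the fitted HC reference."""
    if len(maps) != len(covariates):
        raise ValidationError("covariates table must align with maps")
    return [
        zscore_map(m, covariates.iloc[i], model)
        for i, m in enumerate(maps)
    ]
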