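"""Template similarity scoring.

Each participant's deviation z-map and the group template are flattened in
one fixed voxel order over a common mask, and their Pearson correlation is
the participant's "ketamine similarity coefficient"; the coefficient is
Fisher r-to-z transformed for group statistics.  The correlation mask is the
intersection of the template's finite voxels with every participant's
finite voxels, computed once per cohort, so vectors have identical length
and ordering for everyone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import GridMismatchError, UndefinedStatisticError, ValidationError
from .maps import TemplateMap, ZScoreMap


@dataclass
class SimilarityResult:
    participant_id: str
    r: float
    fisher_z: float
    n_voxels: int


def vectorize(map_or_array, mask: np.ndarray) -> np.ndarray:
    """Values at mask voxels in fixed lexicographic order (first axis fastest).

    Any consistent ordering yields the same correlations; fixing one makes
    intermediate vectors reproducible.  The first-axis-fastest convention is
    Fortran-order raveling of the 3D array.
    """
    data = getattr(map_or_array, "data", map_or_array)
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if data.shape != mask.shape:
        raise GridMismatchError(f"map grid {data.shape} != mask grid {mask.shape}")
    return data.ravel(order="F")[mask.ravel(order="F")]


def scatter_back(vector: np.ndarray, mask: np.ndarray, fill=np.nan) -> np.ndarray:
    """Inverse of :func:`vectorize`: place vector values back on the mask."""
    mask = np.asarray(mask, dtype=bool)
    flat = np.full(mask.size, fill, dtype=float)
    flat[mask.ravel(order="F")] = np.asarray(vector, dtype=float)
    return flat.reshape(mask.shape, order="F")


def fisher_z(r: float) -> float:
    """Variance-stabilising transform atanh(r) = 0.5 ln((1+r)/(1-r))."""
    r = float(r)
    if abs(r) >= 1.0:
        raise UndefinedStatisticError(f"fisher_z undefined for |r| >= 1 (got {r})")
    return float(np.arctanh(r))


def similarity_coefficient(
    zmap: ZScoreMap,
    template: TemplateMap,
    mask: Optional[np.ndarray] = None,
) -> SimilarityResult:
    """Pearson correlation of a deviation map with the template over a mask."""
    if zmap.grid != template.grid:
        raise GridMismatchError(f"zmap grid {zmap.grid} != template grid {template.grid}")
    if mask is None:
        mask = zmap.finite_mask() & template.finite_mask()
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ValidationError("similarity requires at least 3 mask voxels")
    x = vectorize(zmap, mask)
    y = vectorize(template, mask)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values inside the correlation mask")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("correlation undefined: constant vector inside mask")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    fz = float(np.arctanh(r)) if abs(r) < 1 else float(np.sign(r) * np.inf)
    return SimilarityResult(
        participant_id=zmap.participant_id, r=r, fisher_z=fz, n_voxels=int(mask.sum())
    )


def cohort_mask(zmaps: Sequence[ZScoreMap], template: TemplateMap) -> np.ndarray:
    """Intersection of the template mask and every participant's finite mask."""
    mask = template.finite_mask()
    for zm in zmaps:
        if zm.grid != template.grid:
            raise GridMismatchError(
                f"participant {zm.participant_id}: grid {zm.grid} != template {template.grid}"
            )
        mask &= zm.finite_mask()
    if not mask.any():
        raise ValidationError("cohort correlation mask is empty")
    return mask


def similarity_table(zmaps: Sequence[ZScoreMap], template: TemplateMap) -> pd.DataFrame:
    """Per-participant similarity coefficients over one shared cohort mask."""
    mask = cohort_mask(zmaps, template)
    rows = []
    for zm in zmaps:
        res = similarity_coefficient(zm, template, mask)
        rows.append(
            {
                "id": res.participant_id,
                "r": res.r,
                "fisher_z": res.fisher_z,
                "n_voxels": res.n_voxels,
            }
        )
    return pd.DataFrame(rows)
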