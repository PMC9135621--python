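"""In-memory containers for volumetric data.

All volumes in one analysis live on a single shared voxel grid with one
affine (RAS+ by convention); no resampling is ever performed.  These are thin
dataclasses around numpy arrays — file I/O lives in :mod:`ketsim.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import GridMismatchError, ValidationError


def _default_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class BoldRun:
    """One run's 4D BOLD-like signal ``(x, y, z, t)`` with acquisition metadata."""

    data: np.ndarray
    tr_seconds: float
    run_index: int  # 1-based
    condition: str
    participant_id: str
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError("BoldRun.data must be 4D (x, y, z, t)")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("BoldRun.data contains non-finite values")

    @property
    def grid(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class ConnectivityMap:
    """One participant-condition 3D map of seed-coupling values.

    ``kind`` distinguishes first-level betas, Fisher-z correlation maps,
    normative-deviation z-scores, and derived statistic maps.
    """

    data: np.ndarray
    participant_id: Optional[str] = None
    condition: Optional[str] = None
    run_index: object = "combined"  # int or "combined"
    kind: str = "beta"
    affine: np.ndarray = field(default_factory=_default_affine)
    mask: Optional[np.ndarray] = None  # analysis mask (True = in analysis)

    KINDS = ("beta", "fisher_z", "zscore_deviation", "statistic")

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("ConnectivityMap.data must be 3D")
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown map kind {self.kind!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise GridMismatchError("mask grid does not match data grid")

    @property
    def grid(self) -> tuple:
        return self.data.shape

    def finite_mask(self) -> np.ndarray:
        m = np.isfinite(self.data)
        if self.mask is not None:
            m &= self.mask
        return m

    def with_data(self, data: np.ndarray, **changes) -> "ConnectivityMap":
        return replace(self, data=np.asarray(data, dtype=float), **changes)


@dataclass
class StatMap:
    """A 3D statistic map (one-sample t, or its z-transform)."""

    data: np.ndarray
    statistic: str  # "t" | "z"
    df: Optional[int] = None
    n: Optional[int] = None
    affine: np.ndarray = field(default_factory=_default_affine)
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.statistic not in ("t", "z"):
            raise ValidationError("statistic must be 't' or 'z'")
        if self.statistic == "t" and self.df is None:
            raise ValidationError("t maps require df")

    @property
    def grid(self) -> tuple:
        return self.data.shape

    def finite_mask(self) -> np.ndarray:
        m = np.isfinite(self.data)
        if self.mask is not None:
            m &= self.mask
        return m


@dataclass
class TemplateMap:
    """Unthresholded group-level contrast z-map used as a spatial template."""

    data: np.ndarray
    provenance: str = ""
    affine: np.ndarray = field(default_factory=_default_affine)
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("TemplateMap.data must be 3D")
        finite = self.data[np.isfinite(self.data)]
        if finite.size and np.all(finite == finite.flat[0]):
            raise ValidationError("template map is constant; similarity is undefined")

    @property
    def grid(self) -> tuple:
        return self.data.shape

    def finite_mask(self) -> np.ndarray:
        m = np.isfinite(self.data)
        if self.mask is not None:
            m &= self.mask
        return m


@dataclass
class ZScoreMap:
    """Normative-deviation map in standard-deviation units."""

    data: np.ndarray
    participant_id: str
    reference: str  # "site" | "age"
    affine: np.ndarray = field(default_factory=_default_affine)
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("ZScoreMap.data must be 3D")

    @property
    def grid(self) -> tuple:
        return self.data.shape

    def finite_mask(self) -> np.ndarray:
        m = np.isfinite(self.data)
        if self.mask is not None:
            m &= self.mask
        return m
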