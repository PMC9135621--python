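"""Shared numerical helpers: reproducible RNG substreams, smooth random
fields, and grid-consistency checks."""

from __future__ import annotations

import zlib
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import GridMismatchError


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(root_seed: int, *keys) -> np.random.Generator:
    """Return an independent RNG stream derived from a root seed and a key path.

    The same ``(root_seed, *keys)`` always yields the same stream, and streams
    with different key paths are statistically independent.  Keying streams by
    stable identifiers (participant id, stage name) rather than draw order
    makes cohorts extensible without reshuffling earlier participants.
    """
    entropy = [int(root_seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def smooth_field(
    rng: np.random.Generator,
    shape: Sequence[int],
    sigma: float,
    sd: float = 1.0,
) -> np.ndarray:
    """Gaussian-smoothed white-noise field rescaled to a target marginal SD.

    Smoothing introduces the short-range spatial autocorrelation that
    cluster-extent inference sees in real statistic maps; rescaling keeps the
    voxelwise standard deviation interpretable as a noise amplitude.  The
    field is zero-mean and sign-symmetric, so sign-flipping permutation
    schemes remain exact on it.
    """
    field = rng.standard_normal(tuple(int(s) for s in shape))
    if sigma > 0:
        field = gaussian_filter(field, sigma=sigma, mode="wrap")
    field -= field.mean()
    s = field.std()
    if s > 0 and sd > 0:
        field *= sd / s
    elif sd == 0:
        field *= 0.0
    return field


def check_same_grid(arrays: Iterable[np.ndarray], names: Iterable[str] | None = None) -> tuple:
    """Assert all arrays share one spatial grid; return that shape."""
    arrays = list(arrays)
    if not arrays:
        raise GridMismatchError("no volumes supplied")
    shapes = [tuple(a.shape[:3]) for a in arrays]
    ref = shapes[0]
    if any(s != ref for s in shapes):
        labels = list(names) if names is not None else [f"volume {i}" for i in range(len(shapes))]
        offenders = [f"{n}: {s}" for n, s in zip(labels, shapes) if s != ref]
        raise GridMismatchError(
            f"grid mismatch (expected {ref}): " + "; ".join(offenders)
        )
    return ref


def sample_skewness(x: np.ndarray) -> float:
    """Adjusted Fisher–Pearson sample skewness (the common g1 with n/( (n-1)(n-2) ) correction)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        return 0.0
    m = x.mean()
    s = x.std(ddof=1)
    if s == 0:
        return 0.0
    g = np.sum(((x - m) / s) ** 3)
    return float(n / ((n - 1) * (n - 2)) * g)
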