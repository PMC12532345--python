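"""B-scan reduction to averaged, smoothed A-scan channels.

The registration stage works on the lateral-mean A-scan of a whole B-scan.
The focus agent instead sees M laterally sub-divided channels per frame
(reference and target stacked to 2M channels), each averaged laterally and
Gaussian-smoothed along depth so that the broad intensity distribution —
the focus signature — survives while speckle-like noise is suppressed.

Normalization of a reference/target pair is *joint*: both arrays are
standardized by the mean and std of their concatenation.  This preserves
the relative brightness between reference and target, which is exactly the
defocus signal; per-array standardization would erase it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .simulator import BScan

__all__ = [
    "AScanChannels",
    "NormalizedPair",
    "DegenerateInputError",
    "average_ascan",
    "subregion_channels",
    "build_observation",
    "normalize_pair",
]


class DegenerateInputError(ValueError):
    """Raised when an input carries no usable signal (e.g. constant)."""


@dataclass
class AScanChannels:
    """M averaged A-scans, one per lateral sub-region of a B-scan."""

    channels: np.ndarray  # (M, depth)
    smoothing_sigma: float

    @property
    def M(self) -> int:
        return self.channels.shape[0]

    @property
    def n_depth(self) -> int:
        return self.channels.shape[1]


@dataclass
class NormalizedPair:
    """A reference/target A-scan pair standardized by their joint moments."""

    ref_norm: np.ndarray
    tgt_norm: np.ndarray


def _as_image(bscan) -> np.ndarray:
    # accept BScan, any frame-like object with .intensity, or a bare array
    img = getattr(bscan, "intensity", bscan)
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D B-scan (depth x lateral)")
    return img


def average_ascan(bscan) -> np.ndarray:
    """Lateral mean over all columns; returns a length-n_depth profile."""
    return _as_image(bscan).mean(axis=1)


def subregion_channels(bscan, M: int = 4, smoothing_sigma: float = 2.0) -> AScanChannels:
    """Divide a B-scan into M contiguous lateral blocks and reduce each to a
    smoothed averaged A-scan.

    Blocks are near-equal; remainder columns go to the last block.
    Smoothing is a 1D Gaussian along depth with 'reflect' boundaries
    (kernel-normalized, so channel means are preserved up to boundary
    effects).
    """
    img = _as_image(bscan)
    n_depth, n_lat = img.shape
    if M < 1:
        raise ValueError("M must be >= 1")
    if M > n_lat:
        raise ValueError(f"M={M} exceeds lateral width {n_lat}")
    base = n_lat // M
    channels = np.empty((M, n_depth))
    for m in range(M):
        lo = m * base
        hi = (m + 1) * base if m < M - 1 else n_lat
        channels[m] = img[:, lo:hi].mean(axis=1)
    if smoothing_sigma > 0:
        channels = gaussian_filter1d(channels, smoothing_sigma, axis=1, mode="reflect")
    return AScanChannels(channels=channels, smoothing_sigma=float(smoothing_sigma))


def normalize_pair(a_ref: np.ndarray, a_tgt: np.ndarray) -> NormalizedPair:
    """Standardize a reference/target pair by the mean and std of their
    concatenation.

    The joint statistics make the result invariant to a common positive
    rescaling of both inputs while keeping any brightness difference
    *between* them.  Constant (zero joint std) input pairs are rejected.
    """
    a_ref = np.asarray(a_ref, dtype=float)
    a_tgt = np.asarray(a_tgt, dtype=float)
    joint = np.concatenate([a_ref.ravel(), a_tgt.ravel()])
    mean = joint.mean()
    std = joint.std()
    if std < 1e-12:
        raise DegenerateInputError("pair has zero joint standard deviation")
    return NormalizedPair(ref_norm=(a_ref - mean) / std, tgt_norm=(a_tgt - mean) / std)


def build_observation(ref: AScanChannels, tgt: AScanChannels) -> np.ndarray:
    """Stack reference and target channels into the agent's (2M, depth)
    observation.

    Channel order is [ref_1..ref_M, tgt_1..tgt_M].  Each (ref_m, tgt_m)
    pair is jointly standardized so the per-sub-region brightness contrast
    between the two frames is preserved in the observation.
    """
    if ref.M != tgt.M or ref.n_depth != tgt.n_depth:
        raise ValueError("reference and target channel shapes must match")
    M, n_depth = ref.M, ref.n_depth
    obs = np.empty((2 * M, n_depth))
    for m in range(M):
        pair = normalize_pair(ref.channels[m], tgt.channels[m])
        obs[m] = pair.ref_norm
        obs[M + m] = pair.tgt_norm
    return obs
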