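"""Stage-drift correction and two-channel registration.

Drift is estimated by reconstructing coarse 2-D histograms of all
localizations in successive groups of frames (default 500 frames per group)
and locating the maximum of their cross-correlation.  The histograms are
lightly smoothed (one raster pixel) so the correlation peak is band-limited,
and the maximum is refined to sub-pixel precision by local DFT upsampling of
the cross-correlation.  The first group is the reference; later groups
accumulate the pairwise offsets.  Correction applies block-constant shifts
per group.

Channel registration fits a least-squares bivariate polynomial (default
degree 2) mapping fiducial bead positions observed in one emission channel to
the other, and applies it to the localizations of the channel to be mapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.registration import phase_cross_correlation

from .locdata import LocalizationTable

__all__ = [
    "DriftTrack",
    "ChannelTransform",
    "estimate_drift",
    "apply_drift",
    "fit_registration",
    "apply_registration",
]


@dataclass
class DriftTrack:
    """Cumulative per-group stage offsets (dx, dy) in nm.

    ``offsets[k]`` is the displacement of group ``k`` relative to group 0;
    the first entry is (0, 0) by construction.
    """

    group_size: int
    offsets: np.ndarray
    pixel_size: float

    def group_of(self, frames: np.ndarray) -> np.ndarray:
        g = np.asarray(frames) // self.group_size
        return np.clip(g, 0, len(self.offsets) - 1)


@dataclass
class ChannelTransform:
    """Bivariate polynomial map (x, y) -> (x', y') between emission channels.

    Coordinates are internally centred and scaled (``center``, ``scale``)
    before the monomial expansion, which keeps the least-squares system well
    conditioned over fields of view many micrometres wide.
    """

    degree: int
    coef_x: np.ndarray
    coef_y: np.ndarray
    rms_residual: float
    center: np.ndarray
    scale: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = (np.asarray(points, float) - self.center) / self.scale
        V = _poly_terms(p, self.degree)
        return np.column_stack([V @ self.coef_x, V @ self.coef_y])


def _poly_terms(points: np.ndarray, degree: int) -> np.ndarray:
    """Bivariate monomials x^i y^j with i + j <= degree, column per term."""
    x, y = points[:, 0], points[:, 1]
    cols = [x**i * y**j for total in range(degree + 1) for i in range(total + 1) for j in [total - i]]
    return np.column_stack(cols)


def _group_image(
    xy: np.ndarray, origin: np.ndarray, shape: tuple[int, int], pixel_size: float
) -> np.ndarray:
    col = np.floor((xy[:, 0] - origin[0]) / pixel_size).astype(int)
    row = np.floor((xy[:, 1] - origin[1]) / pixel_size).astype(int)
    ok = (row >= 0) & (row < shape[0]) & (col >= 0) & (col < shape[1])
    img = np.zeros(shape)
    np.add.at(img, (row[ok], col[ok]), 1.0)
    return img


def estimate_drift(
    table: LocalizationTable,
    group_size: int = 500,
    pixel_size: float = 50.0,
    upsample: int = 100,
) -> DriftTrack:
    """Estimate stage drift from successive groups of frames.

    Each group's localizations (both channels) are rastered at ``pixel_size``
    and smoothed by one pixel; the offset between consecutive groups is the
    maximum of their cross-correlation, refined to ``pixel_size/upsample``
    precision by local DFT upsampling.  Offsets accumulate from the first
    group.
    """
    n_frames = table.n_frames
    n_groups = int(np.ceil(n_frames / group_size))
    if n_groups < 2:
        raise ValueError("need at least 2 frame groups to estimate drift")
    xy = table.data[["x", "y"]].to_numpy(float)
    frames = table.data["frame"].to_numpy()
    # pad the raster so the correlation (circular in the FFT) cannot couple
    # opposite edges of the field of view
    margin = 16
    origin = xy.min(axis=0) - margin * pixel_size
    extent = xy.max(axis=0) - origin + margin * pixel_size
    shape = (int(np.ceil(extent[1] / pixel_size)) + 1, int(np.ceil(extent[0] / pixel_size)) + 1)

    images = []
    for g in range(n_groups):
        sel = (frames // group_size) == g
        img = _group_image(xy[sel], origin, shape, pixel_size)
        images.append(gaussian_filter(img, 1.0) if img.sum() else img)

    offsets = [np.zeros(2)]
    for g in range(1, n_groups):
        if images[g].sum() == 0 or images[g - 1].sum() == 0:
            warnings.warn(f"empty frame group {g}; carrying previous drift forward")
            offsets.append(offsets[-1].copy())
            continue
        shift, _, _ = phase_cross_correlation(
            images[g - 1], images[g], upsample_factor=upsample, normalization=None
        )
        # returned shift registers group g onto g-1; drift is its negative
        step = np.array([-shift[1], -shift[0]]) * pixel_size
        offsets.append(offsets[-1] + step)
    return DriftTrack(group_size=group_size, offsets=np.array(offsets), pixel_size=pixel_size)


def apply_drift(table: LocalizationTable, track: DriftTrack) -> LocalizationTable:
    """Undo stage drift: subtract each group's cumulative offset.

    After correction, re-estimating drift on the output yields residual
    offsets below half the drift raster pixel.
    """
    data = table.data.copy()
    g = track.group_of(data["frame"].to_numpy())
    data["x"] = data["x"].to_numpy() - track.offsets[g, 0]
    data["y"] = data["y"].to_numpy() - track.offsets[g, 1]
    return table.with_data(data)


def fit_registration(
    beads_near: np.ndarray, beads_far: np.ndarray, degree: int = 2
) -> ChannelTransform:
    """Fit the polynomial transform mapping near-channel bead positions onto
    their far-channel counterparts (least squares; control points paired by
    row)."""
    beads_near = np.asarray(beads_near, float)
    beads_far = np.asarray(beads_far, float)
    if beads_near.shape != beads_far.shape or beads_near.ndim != 2:
        raise ValueError("bead sets must be matching (n, 2) arrays")
    n_terms = (degree + 1) * (degree + 2) // 2
    if len(beads_near) < n_terms:
        raise ValueError(
            f"degree-{degree} transform needs >= {n_terms} bead pairs, got {len(beads_near)}"
        )
    center = beads_near.mean(axis=0)
    scale = float(max(np.abs(beads_near - center).max(), 1.0))
    V = _poly_terms((beads_near - center) / scale, degree)
    coef_x, *_ = np.linalg.lstsq(V, beads_far[:, 0], rcond=None)
    coef_y, *_ = np.linalg.lstsq(V, beads_far[:, 1], rcond=None)
    mapped = np.column_stack([V @ coef_x, V @ coef_y])
    rms = float(np.sqrt(np.mean(np.sum((mapped - beads_far) ** 2, axis=1))))
    return ChannelTransform(
        degree=degree, coef_x=coef_x, coef_y=coef_y, rms_residual=rms,
        center=center, scale=scale,
    )


def apply_registration(
    table: LocalizationTable, transform: ChannelTransform, channel: int
) -> LocalizationTable:
    """Map the named channel's coordinates through the fitted transform;
    the other channel is untouched."""
    data = table.data.copy()
    sel = data["channel"] == channel
    if sel.any():
        mapped = transform(data.loc[sel, ["x", "y"]].to_numpy(float))
        data.loc[sel, "x"] = mapped[:, 0]
        data.loc[sel, "y"] = mapped[:, 1]
    return table.with_data(data)
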