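"""Data model and I/O for point-localization (SMLM) data.

Localizations live in a continuous, y-up Cartesian frame with coordinates in
nanometres. Rasters (ROI masks, reconstructed images) index ``[row=y, col=x]``
with the origin at the lower-left corner of the mask; pixels are half-open, so
a localization sitting exactly on a pixel's right or top edge belongs to the
next pixel. Frame indices are 0-based integers; time lags are expressed in
frames internally and converted to seconds via ``frame_interval`` only for
presentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LocalizationTable",
    "RadialBinning",
    "ROIMask",
    "ReconstructedImage",
    "read_localizations",
    "write_localizations",
    "make_roi_mask",
    "read_roi",
    "reconstruct_image",
]

#: canonical column order for localization tables on disk
COLUMNS = ["x_nm", "y_nm", "frame", "channel", "precision_nm"]

_CHANNELS = (1, 2)


@dataclass
class LocalizationTable:
    """Time-stamped 2-D point localizations with channel labels.

    Parameters
    ----------
    data:
        DataFrame with columns ``x``, ``y`` (nm), ``frame`` (0-based int) and
        ``channel`` (1 or 2); an optional ``precision`` column carries the
        per-localization uncertainty in nm.
    frame_interval:
        Acquisition time per frame in seconds.
    """

    data: pd.DataFrame
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        required = {"x", "y", "frame", "channel"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"localization table missing columns: {sorted(missing)}")
        if len(self.data):
            if not np.all(np.isfinite(self.data[["x", "y"]].to_numpy(float))):
                raise ValueError("non-finite coordinates in localization table")
            frames = self.data["frame"].to_numpy()
            if frames.min() < 0:
                raise ValueError("negative frame index")
            bad = set(np.unique(self.data["channel"])) - set(_CHANNELS)
            if bad:
                raise ValueError(
                    f"channel labels {sorted(bad)} not supported; the "
                    "cross-correlation analysis is two-colour (labels 1 and 2)"
                )
        self.data = self.data.astype(
            {"x": float, "y": float, "frame": np.int64, "channel": np.int64}
        )

    def __len__(self) -> int:
        return len(self.data)

    def n(self, channel: int) -> int:
        """Number of localizations in a channel."""
        return int((self.data["channel"] == channel).sum())

    @property
    def n_frames(self) -> int:
        """1 + the largest frame index present (0 for an empty table)."""
        return 0 if not len(self.data) else int(self.data["frame"].max()) + 1

    def channel(self, channel: int) -> pd.DataFrame:
        return self.data[self.data["channel"] == channel]

    def counts_per_frame(self, channel: int, n_frames: int | None = None) -> np.ndarray:
        """Per-frame localization counts ``n_c,i`` for one channel."""
        if n_frames is None:
            n_frames = self.n_frames
        sub = self.channel(channel)
        return np.bincount(sub["frame"].to_numpy(), minlength=n_frames)[:n_frames]

    def positions_by_frame(self, channel: int) -> dict[int, np.ndarray]:
        """Map frame index -> (n_i, 2) array of (x, y) for one channel."""
        sub = self.channel(channel)
        out: dict[int, np.ndarray] = {}
        for f, grp in sub.groupby("frame"):
            out[int(f)] = grp[["x", "y"]].to_numpy(float)
        return out

    def with_data(self, data: pd.DataFrame) -> "LocalizationTable":
        return LocalizationTable(data, frame_interval=self.frame_interval)


@dataclass(frozen=True)
class RadialBinning:
    """Uniform radial bins, half-open ``[center - dr/2, center + dr/2)``.

    The first center defaults to ``dr/2`` so that zero separations fall in the
    first bin. ``ring_areas`` is the exact annulus area ``2*pi*r*dr`` at each
    bin center.
    """

    centers: np.ndarray
    width: float

    @classmethod
    def from_max(cls, dr: float, r_max: float) -> "RadialBinning":
        if dr <= 0 or r_max <= dr / 2:
            raise ValueError("need dr > 0 and r_max > dr/2")
        n = int(np.floor((r_max - dr / 2) / dr)) + 1
        return cls(centers=dr / 2 + dr * np.arange(n), width=float(dr))

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, float)
        object.__setattr__(self, "centers", c)
        if len(c) == 0 or np.any(np.diff(c) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if len(c) > 1 and not np.allclose(np.diff(c), self.width):
            raise ValueError("bin centers must be uniformly spaced by width")

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate(
            [self.centers - self.width / 2, [self.centers[-1] + self.width / 2]]
        )

    @property
    def ring_areas(self) -> np.ndarray:
        return 2.0 * np.pi * self.centers * self.width

    def __len__(self) -> int:
        return len(self.centers)

    def histogram(self, distances: np.ndarray) -> np.ndarray:
        """Histogram distances into the half-open bins (exact edge rule)."""
        d = np.asarray(distances, float).ravel()
        edges = self.edges
        idx = np.searchsorted(edges, d, side="right") - 1
        ok = (idx >= 0) & (idx < len(self))
        return np.bincount(idx[ok], minlength=len(self))


@dataclass
class ROIMask:
    """Binary region-of-interest raster.

    ``grid`` indexes [row=y, col=x]; ``origin`` is the (x, y) position in nm of
    the lower-left corner of pixel [0, 0].
    """

    grid: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, bool)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.grid.ndim != 2 or not self.grid.any():
            raise ValueError("ROI mask must be a non-empty 2-D raster")

    @property
    def area(self) -> float:
        """A_ROI in nm^2: count of occupied pixels times pixel area."""
        return float(self.grid.sum()) * self.pixel_size**2

    def pixel_indices(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        col = np.floor((np.asarray(x, float) - self.origin[0]) / self.pixel_size).astype(int)
        row = np.floor((np.asarray(y, float) - self.origin[1]) / self.pixel_size).astype(int)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.pixel_indices(x, y)
        ok = (row >= 0) & (row < self.grid.shape[0]) & (col >= 0) & (col < self.grid.shape[1])
        out = np.zeros(ok.shape, bool)
        out[ok] = self.grid[row[ok], col[ok]]
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": "raster",
                "pixel_size_nm": self.pixel_size,
                "origin_nm": list(self.origin),
                "grid": self.grid.astype(int).tolist(),
            }
        )


@dataclass
class ReconstructedImage:
    """Per-channel 2-D localization count images on a common raster."""

    pixels: dict[int, np.ndarray]
    pixel_size: float
    roi: ROIMask
    dropped: dict[int, int] = field(default_factory=dict)

    def density(self, channel: int) -> float:
        """Mean counts per pixel over the ROI."""
        return float(self.pixels[channel][self.roi.grid].mean())

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        stack = np.stack([self.pixels[c] for c in sorted(self.pixels)])
        tifffile.imwrite(str(path), np.clip(stack, 0, 2**16 - 1).astype(np.uint16))


# ---------------------------------------------------------------------------
# I/O

#: default header aliases accepted without an explicit column_map
_ALIASES = {
    "x": ["x_nm", "x", "x [nm]"],
    "y": ["y_nm", "y", "y [nm]"],
    "frame": ["frame", "frame_idx", "t"],
    "channel": ["channel", "color", "ch"],
    "precision": ["precision_nm", "precision", "uncertainty_xy [nm]", "sigma_nm"],
}


def _resolve_columns(header: list[str], column_map: dict[str, str] | None) -> dict[str, str]:
    resolved: dict[str, str] = {}
    lower = {h.lower(): h for h in header}
    for field_name in ("x", "y", "frame", "channel", "precision"):
        if column_map and field_name in column_map:
            name = column_map[field_name]
            if name not in header:
                raise ValueError(f"column {name!r} (mapped to {field_name!r}) not in header {header}")
            resolved[field_name] = name
            continue
        for alias in _ALIASES[field_name]:
            if alias.lower() in lower:
                resolved[field_name] = lower[alias.lower()]
                break
        else:
            if field_name != "precision":
                raise ValueError(
                    f"cannot resolve required column {field_name!r} from header "
                    f"{header}; pass column_map"
                )
    return resolved


def read_localizations(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    frame_interval: float = 1.0,
) -> LocalizationTable:
    """Read a delimited localization table (comma or tab separated, with header).

    ``column_map`` maps the canonical field names (``x``, ``y``, ``frame``,
    ``channel``, ``precision``) to the file's header names when they differ
    from the common aliases.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    resolved = _resolve_columns(list(df.columns), column_map)
    out = pd.DataFrame(
        {
            "x": pd.to_numeric(df[resolved["x"]], errors="coerce"),
            "y": pd.to_numeric(df[resolved["y"]], errors="coerce"),
            "frame": pd.to_numeric(df[resolved["frame"]], errors="coerce"),
            "channel": pd.to_numeric(df[resolved["channel"]], errors="coerce"),
        }
    )
    if "precision" in resolved:
        out["precision"] = pd.to_numeric(df[resolved["precision"]], errors="coerce")
    bad = out[["x", "y", "frame", "channel"]].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"non-numeric value in row {int(np.flatnonzero(bad)[0])} of {path}")
    return LocalizationTable(out, frame_interval=frame_interval)


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a table as CSV (columns x_nm, y_nm, frame, channel[, precision_nm]).

    Coordinates are written with enough digits for a lossless float round trip.
    """
    df = table.data.rename(
        columns={"x": "x_nm", "y": "y_nm", "precision": "precision_nm"}
    )
    cols = [c for c in COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# ROI construction


def make_roi_mask(
    shape: dict | np.ndarray,
    pixel_size: float,
    origin: tuple[float, float] | None = None,
) -> ROIMask:
    """Build a binary ROI raster from a shape description.

    ``shape`` is either a boolean raster, or a dict:
    ``{"type": "rectangle", "bounds": [x0, y0, x1, y1]}`` or
    ``{"type": "polygon", "vertices": [[x, y], ...]}`` (all nm).
    Rasterization tests pixel centers, so pixels are counted as inside when
    their center lies inside the shape.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if isinstance(shape, np.ndarray):
        return ROIMask(shape, pixel_size, origin or (0.0, 0.0))

    kind = shape["type"]
    if kind == "rectangle":
        x0, y0, x1, y1 = map(float, shape["bounds"])
        if x1 <= x0 or y1 <= y0:
            raise ValueError("rectangle has zero area")
        verts = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
    elif kind == "polygon":
        verts = np.asarray(shape["vertices"], float)
        if verts.ndim != 2 or len(verts) < 3:
            raise ValueError("polygon needs >= 3 vertices")
    elif kind == "raster":
        return ROIMask(
            np.asarray(shape["grid"], bool),
            pixel_size,
            tuple(shape.get("origin_nm", (0.0, 0.0))),
        )
    else:
        raise ValueError(f"unknown ROI type {kind!r}")

    import shapely

    poly = shapely.Polygon(verts)
    if poly.area <= 0:
        raise ValueError("shape has zero area")
    if origin is None:
        origin = (
            np.floor(verts[:, 0].min() / pixel_size) * pixel_size,
            np.floor(verts[:, 1].min() / pixel_size) * pixel_size,
        )
    n_col = int(np.ceil((verts[:, 0].max() - origin[0]) / pixel_size))
    n_row = int(np.ceil((verts[:, 1].max() - origin[1]) / pixel_size))
    xc = origin[0] + (np.arange(n_col) + 0.5) * pixel_size
    yc = origin[1] + (np.arange(n_row) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xc, yc)
    grid = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(n_row, n_col)
    if not grid.any():
        raise ValueError("shape rasterized to an empty mask; reduce pixel_size")
    return ROIMask(grid, pixel_size, (float(origin[0]), float(origin[1])))


def read_roi(path: str | Path, pixel_size: float | None = None) -> ROIMask:
    """Load an ROI from a JSON shape spec or a binary TIFF raster."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        if pixel_size is None:
            raise ValueError("pixel_size required for TIFF raster ROI")
        return ROIMask(tifffile.imread(str(path)) > 0, pixel_size)
    spec = json.loads(path.read_text())
    px = spec.get("pixel_size_nm", pixel_size)
    if px is None:
        raise ValueError("ROI spec has no pixel_size_nm and none was given")
    return make_roi_mask(spec, float(px))


# ---------------------------------------------------------------------------
# Image reconstruction


def reconstruct_image(
    table: LocalizationTable,
    roi: ROIMask,
    pixel_size: float | None = None,
) -> ReconstructedImage:
    """Reconstruct per-channel count images by incrementing the pixel under
    each localization (default 25 nm pixels via the ROI raster).

    Localizations outside the raster (or outside the mask) are dropped; the
    per-channel drop counts are recorded on the result.
    """
    if pixel_size is not None and not np.isclose(pixel_size, roi.pixel_size):
        # re-raster the ROI at the requested pixel size
        scale = roi.pixel_size / pixel_size
        reps = int(round(scale))
        if reps < 1 or not np.isclose(scale, reps):
            raise ValueError("pixel_size must evenly subdivide the ROI raster")
        grid = np.repeat(np.repeat(roi.grid, reps, axis=0), reps, axis=1)
        roi = ROIMask(grid, pixel_size, roi.origin)
    shape = roi.grid.shape
    pixels: dict[int, np.ndarray] = {}
    dropped: dict[int, int] = {}
    for ch in _CHANNELS:
        sub = table.channel(ch)
        img = np.zeros(shape, np.int64)
        if len(sub):
            row, col = roi.pixel_indices(sub["x"].to_numpy(), sub["y"].to_numpy())
            ok = (row >= 0) & (row < shape[0]) & (col >= 0) & (col < shape[1])
            ok[ok] &= roi.grid[row[ok], col[ok]]
            np.add.at(img, (row[ok], col[ok]), 1)
            dropped[ch] = int((~ok).sum())
        else:
            dropped[ch] = 0
        pixels[ch] = img
    return ReconstructedImage(pixels, roi.pixel_size, roi, dropped)
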