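"""Cardiac coordinate frames, helix-angle maps and transmural depth.

The left ventricle is treated as a stack of short-axis slices along the
third array axis (+z runs base to apex).  At every myocardial voxel a local
orthonormal basis is built from the slice-wise blood-pool centroid:

* radial ``r_hat`` — in-plane unit vector from the pool centre to the voxel,
* longitudinal ``l_hat`` — the long-axis direction (+z),
* circumferential ``c_hat = l_hat x r_hat`` — tangent to circles about the
  centre.

The helix angle (HA) of a fiber is the signed angle of its projection onto
the circumferential–longitudinal tangent plane, measured from ``c_hat``
toward ``l_hat`` and reported in ``(-90, 90]`` degrees; positive HA is a
right-handed (subendocardial) helix.  Transmural depth (TD) runs from 0 %
at the endocardium to 100 % at the epicardium, measured along in-plane
radial rays.

All voxel coordinates are 0-based indices; physical coordinates are
``index * spacing`` in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class LVFrame:
    """Per-slice blood-pool centres and the local cardiac basis.

    Attributes
    ----------
    centers : (nz, 2) float array
        In-plane (x, y) blood-pool centroid per slice, in voxel coordinates.
        NaN rows mark slices without a usable blood pool.
    spacing : (3,) float array
        Voxel spacing in micrometres.
    long_axis : (3,) float array
        Unit long-axis direction in physical space (+z by construction).
    """

    centers: np.ndarray
    spacing: np.ndarray
    long_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.long_axis = np.asarray(self.long_axis, dtype=float)
        self.long_axis = self.long_axis / np.linalg.norm(self.long_axis)

    @property
    def n_slices(self) -> int:
        return self.centers.shape[0]

    def valid_slices(self) -> np.ndarray:
        return ~np.isnan(self.centers).any(axis=1)

    def basis(self, shape: tuple[int, int, int]):
        """Return (r_hat, c_hat, l_hat) fields of shape ``shape + (3,)``.

        Vectors are unit length in physical space.  At voxels coinciding
        with the slice centre the radial direction is undefined and set to
        NaN.
        """
        nx, ny, nz = shape
        x = np.arange(nx, dtype=float)
        y = np.arange(ny, dtype=float)
        dx = (x[:, None, None] - self.centers[:, 0][None, None, :]) * self.spacing[0]
        dy = (y[None, :, None] - self.centers[:, 1][None, None, :]) * self.spacing[1]
        norm = np.hypot(dx, dy)
        with np.errstate(invalid="ignore", divide="ignore"):
            rx = np.where(norm > 0, dx / norm, np.nan)
            ry = np.where(norm > 0, dy / norm, np.nan)
        r_hat = np.stack([rx, ry, np.zeros_like(rx)], axis=-1)
        # c_hat = l_hat x r_hat with l_hat = +z
        c_hat = np.stack([-ry, rx, np.zeros_like(rx)], axis=-1)
        l_hat = np.broadcast_to(self.long_axis, r_hat.shape).copy()
        return r_hat, c_hat, l_hat


@dataclass
class WallBoundary:
    """Endo/epicardial crossing radii per slice on a fine azimuth grid.

    ``endo_radius`` / ``epi_radius`` are (nz, n_azimuth) arrays of physical
    in-plane radii (µm); ``valid`` flags azimuths whose ray crossed the wall
    in a single run (rays through mask gaps are excluded).
    """

    azimuths_deg: np.ndarray
    endo_radius: np.ndarray
    epi_radius: np.ndarray
    valid: np.ndarray

    def interp(self, slice_index: int, azimuth_deg: np.ndarray):
        """Interpolated (endo, epi) radii at arbitrary azimuths for a slice."""
        az = np.asarray(azimuth_deg, dtype=float) % 360.0
        grid = self.azimuths_deg
        step = grid[1] - grid[0]
        idx = np.clip((az / step).astype(int), 0, grid.size - 1)
        ok = self.valid[slice_index, idx]
        endo = np.where(ok, self.endo_radius[slice_index, idx], np.nan)
        epi = np.where(ok, self.epi_radius[slice_index, idx], np.nan)
        return endo, epi


def myocardium_mask(volume: np.ndarray, threshold: float):
    """Threshold a scalar volume into a myocardium mask and blood pool.

    Voxels at or above ``threshold`` are foreground; only the largest
    connected component is kept.  Interior cavities (background components
    not touching the x/y faces of the volume) form the blood pool.

    Returns
    -------
    mask, blood_pool : boolean arrays of the input shape.
    """
    volume = np.asarray(volume)
    raw = volume >= threshold
    if not raw.any():
        raise ValueError(
            f"empty myocardium mask: no voxel reaches threshold {threshold!r} "
            f"(volume max {volume.max()!r})"
        )
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    else:
        mask = raw
    # cavity: background components with no voxel on an x or y face
    bg_labels, n_bg = ndimage.label(~mask)
    pool = np.zeros_like(mask)
    if n_bg:
        edge = np.zeros(volume.shape, dtype=bool)
        edge[0, :, :] = edge[-1, :, :] = True
        edge[:, 0, :] = edge[:, -1, :] = True
        touching = np.unique(bg_labels[edge])
        for lab in range(1, n_bg + 1):
            if lab not in touching:
                pool |= bg_labels == lab
    return mask, pool


def build_frame(mask: np.ndarray, blood_pool: np.ndarray, spacing,
                long_axis=(0.0, 0.0, 1.0)) -> LVFrame:
    """Build the LV frame from per-slice blood-pool centroids.

    Slices without blood-pool voxels get NaN centres and are skipped by
    downstream consumers.
    """
    nz = mask.shape[2]
    centers = np.full((nz, 2), np.nan)
    for k in range(nz):
        pool = blood_pool[:, :, k]
        if pool.any():
            xs, ys = np.nonzero(pool)
            centers[k] = (xs.mean(), ys.mean())
    return LVFrame(centers=centers, spacing=np.asarray(spacing, float),
                   long_axis=np.asarray(long_axis, float))


def helix_angle(orientation: np.ndarray, frame: LVFrame,
                valid: np.ndarray | None = None,
                min_tangent_norm: float = 0.1):
    """Map an axial orientation field to helix angles.

    Parameters
    ----------
    orientation : (..., 3) array
        Per-voxel unit fiber directions in physical space (sign-free).
    valid : bool array, optional
        Voxels with a defined orientation; NaN vectors are also excluded.
    min_tangent_norm : float
        Fibers whose tangent-plane projection is shorter than this are
        considered radial and flagged undefined.

    Returns
    -------
    ha : float array, degrees in (-90, 90], NaN where undefined.
    ha_valid : bool array.
    """
    orientation = np.asarray(orientation)
    if orientation.dtype not in (np.float32, np.float64):
        orientation = orientation.astype(float)
    shape = orientation.shape[:-1]
    # c_hat = (-sin θ, cos θ, 0), l_hat = long axis: built from the slice
    # centres without materializing full basis fields
    nx, ny, nz = shape
    dtype = orientation.dtype
    x = np.arange(nx, dtype=dtype)
    y = np.arange(ny, dtype=dtype)
    dx = ((x[:, None, None] - frame.centers[:, 0][None, None, :])
          * frame.spacing[0]).astype(dtype)
    dy = ((y[None, :, None] - frame.centers[:, 1][None, None, :])
          * frame.spacing[1]).astype(dtype)
    norm = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_t = np.where(norm > 0, dy / norm, np.nan)
        cos_t = np.where(norm > 0, dx / norm, np.nan)
    ct = -orientation[..., 0] * sin_t + orientation[..., 1] * cos_t
    lt = np.einsum("...i,i->...", orientation,
                   frame.long_axis.astype(dtype))
    # antipodal canonicalization: circumferential component made >= 0;
    # purely longitudinal projections report +90
    flip = (ct < 0) | ((np.abs(ct) < 1e-12) & (lt < 0))
    ct = np.where(flip, -ct, ct)
    lt = np.where(flip, -lt, lt)
    tangent_norm = np.hypot(ct, lt)
    ha_valid = np.isfinite(tangent_norm) & (tangent_norm >= min_tangent_norm)
    if valid is not None:
        ha_valid &= np.asarray(valid, bool)
    ha = np.degrees(np.arctan2(lt, ct))
    ha = np.where(ha_valid, ha, np.nan)
    return ha, ha_valid


def transmural_depth(mask: np.ndarray, frame: LVFrame,
                     n_azimuth: int = 720, radial_step: float = 0.25):
    """Compute per-voxel transmural depth by in-plane radial ray casting.

    For every slice, rays from the blood-pool centre are cast on a fine
    azimuth grid; the endocardial and epicardial crossings are located with
    sub-voxel (midpoint) precision.  Rays whose mask cross-section is not a
    single run (gaps from infarct thinning) are flagged invalid.  Each
    myocardial voxel is then assigned
    ``TD = 100 * (r - r_endo) / (r_epi - r_endo)`` from its own azimuth.

    Returns
    -------
    td : float array, percent in [0, 100], NaN outside the wall or on
        invalid rays.
    boundary : WallBoundary
    """
    nx, ny, nz = mask.shape
    sx, sy = frame.spacing[:2]
    azim = np.arange(n_azimuth) * (360.0 / n_azimuth)
    endo = np.full((nz, n_azimuth), np.nan)
    epi = np.full((nz, n_azimuth), np.nan)
    valid = np.zeros((nz, n_azimuth), dtype=bool)
    rmax = float(np.hypot(nx * sx, ny * sy)) / 2.0
    step_um = radial_step * min(sx, sy)
    radii = np.arange(step_um, rmax, step_um)
    cos_a = np.cos(np.radians(azim))
    sin_a = np.sin(np.radians(azim))
    ok_slices = frame.valid_slices()
    for k in range(nz):
        if not ok_slices[k] or not mask[:, :, k].any():
            continue
        cx, cy = frame.centers[k]
        # sample every (azimuth, radius) pair by nearest voxel
        px = np.rint(cx + np.outer(cos_a, radii) / sx).astype(int)
        py = np.rint(cy + np.outer(sin_a, radii) / sy).astype(int)
        inb = (px >= 0) & (px < nx) & (py >= 0) & (py < ny)
        inside = np.zeros_like(inb)
        inside[inb] = mask[:, :, k][px[inb], py[inb]]
        # transitions along each ray
        d = np.diff(inside.astype(np.int8), axis=1)
        n_runs = (d == 1).sum(axis=1) + inside[:, 0].astype(int)
        has_wall = inside.any(axis=1)
        single = (n_runs == 1) & has_wall
        for a in np.nonzero(single)[0]:
            ins = inside[a]
            first = int(np.argmax(ins))
            last = len(ins) - 1 - int(np.argmax(ins[::-1]))
            # midpoint interpolation of the mask edge (half-voxel handling)
            endo[k, a] = radii[first] - step_um / 2.0
            epi[k, a] = radii[last] + step_um / 2.0
        valid[k, single] = True
    boundary = WallBoundary(azimuths_deg=azim, endo_radius=endo,
                            epi_radius=epi, valid=valid)

    td = np.full(mask.shape, np.nan)
    x = np.arange(nx, dtype=float)
    y = np.arange(ny, dtype=float)
    for k in range(nz):
        if not valid[k].any():
            continue
        cx, cy = frame.centers[k]
        dx = (x[:, None] - cx) * sx
        dy = (y[None, :] - cy) * sy
        r = np.hypot(dx, dy)
        theta = np.degrees(np.arctan2(dy, dx)) % 360.0
        m = mask[:, :, k]
        e0, e1 = boundary.interp(k, theta[m])
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = 100.0 * (r[m] - e0) / (e1 - e0)
        td_k = np.full((nx, ny), np.nan)
        td_k[m] = np.clip(vals, 0.0, 100.0)
        td[:, :, k] = td_k
    return td, boundary
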