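"""FACT streamline tractography through the primary-eigenvector field.

Fiber Assignment by Continuous Tracking: the orientation is held constant
within each voxel (nearest-voxel lookup, no interpolation); a streamline
steps bidirectionally from each seed, flipping the axial eigenvector's
sign per step to maintain forward continuity, and terminates on mask exit,
on an inter-voxel turning angle above the threshold, or at the maximum
length.  Tracking is fully deterministic.

Seeds subdivide each masked voxel into ``subdivisions**3`` uniformly
spaced sub-voxels (default 10 -> 1000 sub-voxels), which compensates the
coarse DTI resolution for dense visualization.  Points are physical µm
coordinates (index * spacing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TERM_MASK_EXIT = "mask exit"
TERM_ANGLE = "angle threshold"
TERM_MAX_LENGTH = "max length"


@dataclass
class Streamline:
    """Ordered track points with termination reasons for each end."""

    points: np.ndarray            # (n, 3) physical µm
    reasons: tuple[str, str]      # (backward end, forward end)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def seed_grid(mask: np.ndarray, subdivisions: int = 10,
              decimate: int = 1) -> np.ndarray:
    """Uniform sub-voxel seed points (continuous voxel coordinates).

    Each masked voxel contributes ``subdivisions**3`` seeds at the centres
    of a regular sub-grid (``subdivisions = 1`` gives voxel centres).
    ``decimate`` keeps every n-th seed for cheaper dense tracking.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty tracking mask")
    centers = np.argwhere(mask).astype(float)
    s = int(subdivisions)
    offs = (np.arange(s) + 0.5) / s - 0.5
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    seeds = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    if decimate > 1:
        seeds = seeds[::decimate]
    return seeds


def _track_one_way(e1, mask, spacing, start, direction, step_um,
                   cos_threshold, max_steps):
    shape = mask.shape
    points = []
    p = start.copy()
    prev = direction / np.linalg.norm(direction)
    prev_v = None
    reason = TERM_MAX_LENGTH
    for _ in range(max_steps):
        vox = np.rint(p).astype(int)
        if ((vox < 0).any() or (vox >= shape).any()
                or not mask[tuple(vox)]):
            reason = TERM_MASK_EXIT
            break
        v = e1[tuple(vox)]
        if not np.isfinite(v).all():
            reason = TERM_MASK_EXIT
            break
        if v @ prev < 0:          # antipodal: keep forward continuity
            v = -v
        if prev_v is not None and (v @ prev_v) < cos_threshold:
            reason = TERM_ANGLE
            break
        points.append(p * spacing)
        p = p + step_um * v / spacing
        prev = v
        prev_v = v
    return points, reason


def fact_track(e1: np.ndarray, seeds: np.ndarray, mask: np.ndarray,
               spacing, step_um: float | None = None,
               angle_threshold_deg: float = 60.0,
               max_steps: int = 5000) -> list[Streamline]:
    """Track streamlines bidirectionally from each seed.

    Parameters
    ----------
    e1 : (nx, ny, nz, 3) array
        Unit primary-eigenvector field (axial; sign handled per step).
    seeds : (n, 3) array
        Continuous voxel coordinates; seeds outside the mask are skipped.
    spacing : (3,) µm per voxel; ``step_um`` defaults to half the smallest
        voxel dimension and must not exceed the smallest one.
    """
    spacing = np.asarray(spacing, float)
    mask = np.asarray(mask, bool)
    if step_um is None:
        step_um = 0.5 * spacing.min()
    if step_um > spacing.min():
        raise ValueError(f"step {step_um} µm exceeds the smallest voxel "
                         f"dimension {spacing.min()} µm")
    cos_thr = np.cos(np.radians(angle_threshold_deg))
    out: list[Streamline] = []
    shape = mask.shape
    for seed in np.asarray(seeds, float):
        vox = np.rint(seed).astype(int)
        if ((vox < 0).any() or (vox >= shape).any()
                or not mask[tuple(vox)]):
            continue
        v0 = e1[tuple(vox)]
        if not np.isfinite(v0).all():
            continue
        fwd, r_fwd = _track_one_way(e1, mask, spacing, seed, v0,
                                    step_um, cos_thr, max_steps)
        bwd, r_bwd = _track_one_way(e1, mask, spacing, seed, -v0,
                                    step_um, cos_thr, max_steps)
        pts = bwd[::-1] + fwd[1:] if fwd else bwd[::-1]
        if len(pts) < 2:
            continue
        out.append(Streamline(points=np.asarray(pts), reasons=(r_bwd, r_fwd)))
    return out


def streamline_ha(tracks: list[Streamline], ha_map: np.ndarray,
                  spacing) -> list[np.ndarray]:
    """Per-point helix angle by nearest-voxel lookup into an HA map."""
    spacing = np.asarray(spacing, float)
    shape = ha_map.shape
    out = []
    for t in tracks:
        vox = np.rint(t.points / spacing).astype(int)
        vox = np.clip(vox, 0, np.asarray(shape) - 1)
        out.append(ha_map[vox[:, 0], vox[:, 1], vox[:, 2]])
    return out
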