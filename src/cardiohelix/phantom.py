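"""Ground-truthed synthetic left-ventricle phantoms.

The phantom is an annular myocardium around a blood pool, stacked along the
long axis (+z), carrying a transmurally ramping helical fiber field: helix
angle runs linearly from ``ha_endo`` at the endocardium (TD = 0 %) to
``ha_epi`` at the epicardium (TD = 100 %), emulating the right-handed to
left-handed transition of the ventricular wall.  An optional lesion (an
angular sector with elevated mean diffusivity and flattened helix angle,
surrounded by a tapered peri-lesion ring) emulates ischemic remodeling.

From the same fiber field two imaging modalities are synthesized:

* diffusion-weighted MRI volumes under the monoexponential tensor model
  with optional Rician (magnitude MRI) or Gaussian noise;
* a high-resolution optical volume with fiber-aligned striped texture,
  concentric laminar modulation, and optional light-sheet shadow-stripe
  artifacts.

Every stochastic step draws from a generator seeded by the spec, so all
outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .dti import DWIProtocol, DWIStack, default_protocol, _B_SCALE
from .geometry import LVFrame

#: MD zoning thresholds (µm^2/ms): infarct above, remote below.
MD_INFARCT = 1.12
MD_REMOTE = 0.9

LABEL_BACKGROUND = 0
LABEL_REMOTE = 1
LABEL_PERI = 2
LABEL_INFARCT = 3


@dataclass
class LesionSpec:
    """Angular-sector lesion with a tapered peri-lesion ring.

    ``md_multiplier`` scales the tensor eigenvalues (hence MD) in the core;
    ``ha_flattening`` in [0, 1] multiplies the helix angle (0 flattens the
    helix completely).  Both effects fade over ``taper_deg`` outside the
    core sector, producing a peri ring whose MD crosses the zoning
    thresholds.
    """

    azimuth_center_deg: float = 0.0
    azimuth_width_deg: float = 60.0
    taper_deg: float = 30.0
    md_multiplier: float = 1.5
    ha_flattening: float = 0.5
    transmural_extent: float = 1.0  # fraction of wall, from endocardium

    def weight(self, azimuth_deg: np.ndarray, td_frac: np.ndarray) -> np.ndarray:
        """Lesion weight in [0, 1]: 1 in the core, cosine taper outside."""
        d = np.abs((np.asarray(azimuth_deg) - self.azimuth_center_deg + 180.0)
                   % 360.0 - 180.0)
        half = self.azimuth_width_deg / 2.0
        w = np.clip((half + self.taper_deg - d) / max(self.taper_deg, 1e-9),
                    0.0, 1.0)
        w = 0.5 - 0.5 * np.cos(np.pi * w)
        if self.transmural_extent < 1.0:
            w = w * (np.asarray(td_frac) <= self.transmural_extent)
        return w


@dataclass
class PhantomSpec:
    """Geometry, fiber, tensor and noise parameters of a synthetic LV.

    Defaults mirror the reference acquisition: 125 x 125 x 300 µm voxels,
    b = 1000 s/mm^2, a +60° to -60° transmural helix ramp (true global HAT
    -1.2 °/%TD), and myocardial eigenvalues (1.2, 0.7, 0.5) µm^2/ms giving
    a remote MD of 0.8 µm^2/ms.
    """

    shape: tuple[int, int, int] = (64, 64, 20)
    spacing: tuple[float, float, float] = (125.0, 125.0, 300.0)
    center: tuple[float, float] | None = None  # voxel coords; default grid middle
    endo_radius_um: float | np.ndarray = 1250.0
    epi_radius_um: float | np.ndarray = 3250.0
    ha_endo_deg: float = 60.0
    ha_epi_deg: float = -60.0
    eigenvalues: tuple[float, float, float] = (1.2, 0.7, 0.5)
    s0: float = 1000.0
    background_s0: float = 0.0
    background_diffusivity: float = 2.0
    lesion: LesionSpec | None = None
    noise: str = "none"  # none | gaussian | rician
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        nz = self.shape[2]
        endo = np.broadcast_to(np.asarray(self.endo_radius_um, float), (nz,))
        epi = np.broadcast_to(np.asarray(self.epi_radius_um, float), (nz,))
        if not (endo < epi).all():
            raise ValueError("endocardial radius must be < epicardial radius "
                             "on every slice")
        l1, l2, l3 = self.eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError(f"eigenvalues must satisfy λ1 ≥ λ2 ≥ λ3 > 0, "
                             f"got {self.eigenvalues}")
        if abs(self.ha_endo_deg) > 90 or abs(self.ha_epi_deg) > 90:
            raise ValueError("|helix angle| at the wall surfaces must be ≤ 90°")
        if self.noise not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def endo_per_slice(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.endo_radius_um, float),
                               (self.shape[2],)).copy()

    @property
    def epi_per_slice(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.epi_radius_um, float),
                               (self.shape[2],)).copy()

    @property
    def true_global_hat(self) -> float:
        """Slope of the prescribed linear HA ramp, °/%TD."""
        return (self.ha_epi_deg - self.ha_endo_deg) / 100.0

    def refined(self, factor: tuple[int, int, int]) -> "PhantomSpec":
        """Same physical phantom on a grid ``factor`` times finer per axis."""
        f = np.asarray(factor, int)
        new = replace(
            self,
            shape=tuple(int(n * fi) for n, fi in zip(self.shape, f)),
            spacing=tuple(s / fi for s, fi in zip(self.spacing, f)),
        )
        cx, cy = self.center if self.center is not None else (
            (self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)
        # preserve the physical centre position: x_phys = index * spacing
        new.center = (cx * self.spacing[0] / new.spacing[0],
                      cy * self.spacing[1] / new.spacing[1])
        if int(f[2]) != 1:
            new.endo_radius_um = np.repeat(self.endo_per_slice, int(f[2]))
            new.epi_radius_um = np.repeat(self.epi_per_slice, int(f[2]))
        return new

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in list(d.items()):
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


@dataclass
class PhantomGeometry:
    """Masks, frame and analytic polar coordinates of a phantom."""

    myocardium: np.ndarray
    blood_pool: np.ndarray
    frame: LVFrame
    radius_um: np.ndarray       # in-plane distance to slice centre
    azimuth_deg: np.ndarray     # in [0, 360)
    td_percent: np.ndarray      # analytic TD, NaN outside the wall


@dataclass
class GroundTruth:
    """Per-voxel truth maps for parameter-recovery tests."""

    ha_deg: np.ndarray
    td_percent: np.ndarray
    labels: np.ndarray
    orientation: np.ndarray
    global_hat: float
    md: np.ndarray


@dataclass
class FiberField:
    """Axial (sign-free) unit fiber directions on the phantom grid."""

    vectors: np.ndarray
    valid: np.ndarray


def make_lv_geometry(spec: PhantomSpec) -> PhantomGeometry:
    """Rasterize the annular myocardium, blood pool and cardiac frame."""
    nx, ny, nz = spec.shape
    cx, cy = spec.center if spec.center is not None else (
        (nx - 1) / 2.0, (ny - 1) / 2.0)
    sx, sy, _ = spec.spacing
    x = (np.arange(nx) - cx) * sx
    y = (np.arange(ny) - cy) * sy
    r2d = np.hypot(x[:, None], y[None, :])
    az2d = np.degrees(np.arctan2(y[None, :], x[:, None])) % 360.0
    radius = np.repeat(r2d[:, :, None], nz, axis=2)
    azimuth = np.repeat(az2d[:, :, None], nz, axis=2)
    endo = spec.endo_per_slice
    epi = spec.epi_per_slice
    myo = (radius >= endo[None, None, :]) & (radius < epi[None, None, :])
    pool = radius < endo[None, None, :]
    if not myo.any():
        raise ValueError("degenerate radii produce an empty myocardium")
    with np.errstate(invalid="ignore", divide="ignore"):
        td = 100.0 * (radius - endo) / (epi - endo)
    td = np.where(myo, np.clip(td, 0.0, 100.0), np.nan)
    frame = LVFrame(centers=np.tile([cx, cy], (nz, 1)),
                    spacing=np.asarray(spec.spacing, float))
    return PhantomGeometry(myocardium=myo, blood_pool=pool, frame=frame,
                           radius_um=radius, azimuth_deg=azimuth,
                           td_percent=td)


def make_fiber_field(geometry: PhantomGeometry, spec: PhantomSpec
                     ) -> tuple[FiberField, GroundTruth]:
    """Build the helical fiber field and its ground truth.

    HA ramps linearly in TD from ``ha_endo`` to ``ha_epi``; the fiber lies
    in the circumferential–longitudinal tangent plane at angle HA from the
    circumferential direction.  Lesion voxels have HA multiplied by the
    flattening factor (weighted by the lesion taper) and their MD scaled by
    the MD multiplier.
    """
    myo = geometry.myocardium
    td = geometry.td_percent
    ha = spec.ha_endo_deg + (spec.ha_epi_deg - spec.ha_endo_deg) * td / 100.0

    md_base = float(np.mean(spec.eigenvalues))
    md = np.where(myo, md_base, np.nan)
    if spec.lesion is not None:
        w = spec.lesion.weight(geometry.azimuth_deg, td / 100.0)
        ha = ha * (1.0 - (1.0 - spec.lesion.ha_flattening) * w)
        md = md * (1.0 + (spec.lesion.md_multiplier - 1.0) * w)

    labels = np.full(spec.shape, LABEL_BACKGROUND, dtype=np.int8)
    labels[myo & (md > MD_INFARCT)] = LABEL_INFARCT
    labels[myo & (md > MD_REMOTE) & (md <= MD_INFARCT)] = LABEL_PERI
    labels[myo & (md <= MD_REMOTE)] = LABEL_REMOTE

    # fiber = cos(HA) c_hat + sin(HA) l_hat with c_hat = (-sin θ, cos θ, 0)
    # built directly from the azimuth to avoid materializing basis fields
    theta = np.radians(geometry.azimuth_deg)
    ha_rad = np.radians(np.where(myo, ha, 0.0))
    vec = np.full(spec.shape + (3,), np.nan)
    cos_ha = np.cos(ha_rad[myo])
    vec[myo, 0] = -cos_ha * np.sin(theta[myo])
    vec[myo, 1] = cos_ha * np.cos(theta[myo])
    vec[myo, 2] = np.sin(ha_rad[myo])
    ha = np.where(myo, ha, np.nan)
    gt = GroundTruth(ha_deg=ha, td_percent=td, labels=labels,
                     orientation=vec, global_hat=spec.true_global_hat, md=md)
    return FiberField(vectors=vec, valid=myo.copy()), gt


def _add_noise(signal: np.ndarray, model: str, sigma: float,
               rng: np.random.Generator) -> np.ndarray:
    if model == "none" or sigma == 0:
        return signal
    if model == "gaussian":
        return signal + rng.normal(0.0, sigma, signal.shape)
    if model == "rician":
        re = signal + rng.normal(0.0, sigma, signal.shape)
        im = rng.normal(0.0, sigma, signal.shape)
        return np.hypot(re, im)
    raise ValueError(f"unknown noise model {model!r}")


def synthesize_dwi(fibers: FiberField, geometry: PhantomGeometry,
                   spec: PhantomSpec, protocol: DWIProtocol | None = None,
                   ground_truth: GroundTruth | None = None,
                   rng: np.random.Generator | None = None
                   ) -> tuple[DWIStack, DWIProtocol]:
    """Simulate the DWI stack from the fiber field.

    The per-voxel tensor has λ1 along the fiber, λ2 along fiber x radial
    (cross-fiber in-wall) and λ3 along the radial direction; lesion voxels
    scale all eigenvalues by the local MD multiplier weight.  The blood
    pool and background are isotropic with ``background_diffusivity`` and
    amplitude ``background_s0``.
    """
    if protocol is None:
        protocol = default_protocol()
    if protocol.n_directions < 6:
        raise ValueError("fewer than 6 unique directions: the tensor fit "
                         "will be underdetermined")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    myo = fibers.valid
    r_hat, _, _ = geometry.frame.basis(spec.shape)
    f = fibers.vectors[myo]
    e3 = r_hat[myo]
    e2 = np.cross(f, e3)
    l1, l2, l3 = spec.eigenvalues
    d = (l1 * f[..., :, None] * f[..., None, :]
         + l2 * e2[..., :, None] * e2[..., None, :]
         + l3 * e3[..., :, None] * e3[..., None, :])
    if spec.lesion is not None:
        if ground_truth is not None:
            scale = ground_truth.md[myo] / float(np.mean(spec.eigenvalues))
        else:
            w = spec.lesion.weight(geometry.azimuth_deg,
                                   geometry.td_percent / 100.0)[myo]
            scale = 1.0 + (spec.lesion.md_multiplier - 1.0) * w
        d = d * scale[..., None, None]

    n = protocol.n_volumes
    data = np.empty(spec.shape + (n,), dtype=float)
    b = protocol.bvals * _B_SCALE
    bg_att = np.exp(-b * spec.background_diffusivity)
    for j in range(n):
        g = protocol.bvecs[j]
        q = np.einsum("vab,a,b->v", d, g, g)
        vol = np.full(spec.shape, spec.background_s0 * bg_att[j])
        vol[myo] = spec.s0 * np.exp(-b[j] * q)
        data[..., j] = vol
    data = _add_noise(data, spec.noise, spec.sigma, rng)
    return DWIStack(data=data, spacing=np.asarray(spec.spacing, float)), protocol


@dataclass
class TextureParams:
    """Optical texture: fiber-aligned stripes plus laminar layers.

    ``wavelength_um`` sets the nominal stripe period perpendicular to the
    fibers (must be at least 3 voxels along every axis at the synthesis
    resolution; the local period varies as ``cos(HA) / axial_frequency``
    across the helical ramp).  Because the stripe direction follows the
    ramp, a single globally coherent grating cannot exist (the stripe
    normal field has curl); the phase ``C * (z - r tan(HA) Δφ)`` is
    therefore anchored in ``coherence_sectors`` azimuthal sectors blended
    with a smooth partition of unity.  This form has no axial phase
    drift, and its gradient lies exactly in the plane spanned by the
    stripe normal and the radial direction, so together with the
    concentric laminar layers the fiber direction remains the unique
    direction of least intensity variation.  Low-contrast blend seams at
    sector rims are meant to be flagged undefined by coherence filtering
    downstream.  ``layer_*`` add concentric laminar modulation emulating
    sheet-like radial intensity variation; shadow stripes emulate residual
    light-sheet illumination artifacts (constant along ``shadow_axis``).
    """

    base: float = 500.0
    contrast: float = 300.0
    wavelength_um: float = 250.0
    layer_contrast: float = 150.0
    layer_wavelength_um: float = 200.0
    coherence_sectors: int | None = None  # fixed count; None = radius-adaptive
    axial_frequency: float = 0.75  # C: axial wavenumber in units of 2π/wavelength
    shell_width_um: float = 125.0  # radial shells for adaptive anchoring
    max_drift: float = 1.5         # tolerated local wavenumber drift (x k0)
    shadow_axis: int | None = None
    shadow_amplitude: float = 0.0
    shadow_wavelength_um: float = 500.0
    noise_sigma: float = 0.0
    background: float = 0.0


def synthesize_optical(fibers: FiberField, geometry: PhantomGeometry,
                       spec: PhantomSpec, texture: TextureParams,
                       ground_truth: GroundTruth | None = None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Render the fiber field as a striped scalar volume.

    Within each azimuthal coherence sector the stripe phase is
    ``C * (z - r tan(HA) (phi - phi_sector))`` with ``C`` the axial
    frequency factor; surfaces of constant phase are helical sheets that
    contain the local fiber direction, so stripes run along fibers.  Helix
    angles are clipped to ±80° inside the tangent (nearly longitudinal
    fibers would need unbounded azimuthal frequency).
    """
    if texture.wavelength_um < 3.0 * max(spec.spacing):
        raise ValueError(
            f"stripe wavelength {texture.wavelength_um} µm is below 3 voxels "
            f"at spacing {tuple(spec.spacing)} µm (aliasing)")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    if ground_truth is None:
        _, ground_truth = make_fiber_field(geometry, spec)
    myo = fibers.valid
    nz = spec.shape[2]
    z = (np.arange(nz) * spec.spacing[2])[None, None, :]
    z = np.broadcast_to(z, spec.shape)

    vol = np.full(spec.shape, texture.background, dtype=float)
    vol[myo] = texture.base
    if texture.contrast != 0:
        ha = np.radians(ground_truth.ha_deg[myo])
        r = geometry.radius_um[myo]
        phi = np.radians(geometry.azimuth_deg[myo])  # [0, 2pi)
        zm = z[myo]
        k0 = 2.0 * np.pi / texture.wavelength_um
        c_ax = float(texture.axial_frequency)
        tan_ha = np.tan(np.clip(ha, np.radians(-80.0), np.radians(80.0)))
        acc = np.zeros(ha.shape)
        anchor_rng = np.random.default_rng(spec.seed + 2)

        # radial shells, each with its own azimuthal anchor count chosen so
        # (a) a sector window spans several azimuthal stripe periods
        # (envelope decorrelation) and (b) the intra-window phase drift
        # keeps the local wavenumber below max_drift x k0 (no aliasing)
        n_shell = max(1, int(np.ceil(np.ptp(r) / texture.shell_width_um))
                      ) if r.size else 1
        r_lo = r.min() if r.size else 0.0
        shell_of = np.minimum(((r - r_lo) / texture.shell_width_um).astype(int),
                              n_shell - 1)
        # base-ramp helix slope (rad/µm) for the drift estimate
        endo = float(np.mean(spec.endo_per_slice))
        epi = float(np.mean(spec.epi_per_slice))
        ha_slope = np.radians(spec.ha_epi_deg - spec.ha_endo_deg) / (epi - endo)
        for s in range(n_shell):
            sel = shell_of == s
            if not sel.any():
                continue
            r_s = (r_lo + (s + 0.5) * texture.shell_width_um)
            td_s = np.clip((r_s - endo) / (epi - endo), 0.0, 1.0)
            ha_s = np.radians(spec.ha_endo_deg
                              + (spec.ha_epi_deg - spec.ha_endo_deg) * td_s)
            tan_s = abs(np.tan(np.clip(ha_s, -1.4, 1.4)))
            if texture.coherence_sectors is not None:
                m = int(texture.coherence_sectors)
            else:
                lam_phi = texture.wavelength_um / max(c_ax * tan_s, 1e-6)
                m_env = max(np.pi * r_s / lam_phi, 1.0)
                drift = c_ax * abs(np.tan(ha_s)
                                   + r_s * ha_slope / np.cos(ha_s) ** 2)
                m_drift = max(2.0 * np.pi * drift / texture.max_drift, 1.0)
                if m_drift <= m_env:
                    m = int(round(0.5 * (m_drift + m_env)))
                else:  # conflicting demands: split the difference
                    m = int(round(np.sqrt(m_drift * m_env)))
                m = max(m, 1)
            sector = 2.0 * np.pi / m
            offset = anchor_rng.uniform(0.0, sector)
            phi_s, tan_v = phi[sel], tan_ha[sel]
            r_v, z_v = r[sel], zm[sel]
            out = np.zeros(phi_s.shape)
            for j in range(m):
                phi_j = offset + (j + 0.5) * sector
                dphi = (phi_s - phi_j + np.pi) % (2.0 * np.pi) - np.pi
                in_sec = np.abs(dphi) < sector
                if not in_sec.any():
                    continue
                # cos^2 windows spaced one half-support apart: partition
                w = np.cos(0.5 * np.pi * dphi[in_sec] / sector) ** 2
                psi = c_ax * (z_v[in_sec]
                              - tan_v[in_sec] * r_v[in_sec] * dphi[in_sec])
                out[in_sec] += w * np.cos(k0 * psi)
            acc[sel] = out
        vol[myo] += texture.contrast * acc
    if texture.layer_contrast != 0:
        vol[myo] += texture.layer_contrast * np.cos(
            2.0 * np.pi * geometry.radius_um[myo] / texture.layer_wavelength_um)
    if texture.shadow_axis is not None and texture.shadow_amplitude != 0:
        axis = int(texture.shadow_axis)
        perp = (axis + 1) % 3
        coord = np.arange(spec.shape[perp]) * spec.spacing[perp]
        shape = [1, 1, 1]
        shape[perp] = -1
        vol = vol + texture.shadow_amplitude * np.cos(
            2.0 * np.pi * coord / texture.shadow_wavelength_um).reshape(shape)
    if texture.noise_sigma > 0:
        vol = vol + rng.normal(0.0, texture.noise_sigma, vol.shape)
    # optical volumes can be large; single precision is ample for texture
    return vol.astype(np.float32)
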