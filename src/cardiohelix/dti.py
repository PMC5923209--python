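"""Diffusion-tensor estimation from diffusion-weighted MRI.

Per voxel the signal follows the monoexponential tensor model

    S(b, g) = S0 * exp(-b * g^T D g)

with ``D`` the symmetric 3x3 self-diffusion tensor.  Taking logs makes the
model linear in the six unique tensor components plus ``ln S0``, which are
estimated by ordinary (unweighted) least squares over all acquired volumes.
b-values are in s/mm^2 and diffusivities in µm^2/ms (1 µm^2/ms =
1e-3 mm^2/s, absorbed into the design matrix).

The eigenvector of the largest eigenvalue (e1) is taken as the local
cardiomyocyte orientation; mean diffusivity MD = trace(D)/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: component order used throughout: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

# b (s/mm^2) * D (µm^2/ms) -> dimensionless exponent
_B_SCALE = 1e-3


@dataclass
class DWIProtocol:
    """Acquisition protocol: one (b-value, gradient direction) per volume."""

    bvals: np.ndarray  # s/mm^2
    bvecs: np.ndarray  # (n, 3) unit vectors; zero rows for b=0

    def __post_init__(self) -> None:
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError(
                f"bvecs shape {self.bvecs.shape} does not match "
                f"{self.bvals.size} b-values"
            )
        norms = np.linalg.norm(self.bvecs, axis=1)
        dw = self.bvals > 0
        if dw.any() and np.abs(norms[dw] - 1.0).max() > 1e-6:
            bad = int(np.argmax(np.abs(norms - 1.0) * dw))
            raise ValueError(
                f"gradient direction {bad} has non-unit norm {norms[bad]:.6f}"
            )
        if not (~dw).any():
            raise ValueError("protocol needs at least one b=0 volume")

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def n_directions(self) -> int:
        """Number of unique diffusion-weighted directions (axial pairs merged)."""
        dirs = self.bvecs[self.bvals > 0]
        uniq: list[np.ndarray] = []
        for g in dirs:
            if not any(np.abs(np.abs(u @ g) - 1.0) < 1e-6 for u in uniq):
                uniq.append(g)
        return len(uniq)

    def design_matrix(self) -> np.ndarray:
        """(n, 7) matrix mapping (ln S0, Dxx..Dyz) to ln S."""
        b = self.bvals * _B_SCALE
        gx, gy, gz = self.bvecs.T
        return np.column_stack([
            np.ones_like(b),
            -b * gx * gx, -b * gy * gy, -b * gz * gz,
            -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz,
        ])


@dataclass
class DWIStack:
    """Diffusion-weighted volumes, shape (nx, ny, nz, n_volumes)."""

    data: np.ndarray
    spacing: np.ndarray  # µm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI stack must be 4-D (x, y, z, volume)")


@dataclass
class TensorField:
    """Per-voxel symmetric tensors (µm^2/ms) with a validity mask."""

    components: np.ndarray  # (..., 6) in TENSOR_COMPONENTS order
    valid: np.ndarray
    log_s0: np.ndarray | None = None

    def as_matrices(self) -> np.ndarray:
        c = self.components
        m = np.empty(c.shape[:-1] + (3, 3), dtype=float)
        m[..., 0, 0] = c[..., 0]
        m[..., 1, 1] = c[..., 1]
        m[..., 2, 2] = c[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 5]
        return m

    @staticmethod
    def from_matrices(m: np.ndarray, valid: np.ndarray | None = None) -> "TensorField":
        m = np.asarray(m, dtype=float)
        comp = np.stack([m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
                         m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]], axis=-1)
        if valid is None:
            valid = np.isfinite(comp).all(axis=-1)
        return TensorField(components=comp, valid=np.asarray(valid, bool))


@dataclass
class EigenSystem:
    """Sorted eigensystem of a tensor field: λ1 ≥ λ2 ≥ λ3."""

    eigenvalues: np.ndarray   # (..., 3) descending
    eigenvectors: np.ndarray  # (..., 3, 3); eigenvectors[..., :, i] pairs λ_i
    valid: np.ndarray
    degenerate: np.ndarray = field(default=None)  # λ1 ≈ λ3 (orientation meaningless)

    @property
    def e1(self) -> np.ndarray:
        return self.eigenvectors[..., :, 0]


def fit_tensor_loglinear(dwi, protocol: DWIProtocol,
                         mask: np.ndarray | None = None) -> TensorField:
    """Ordinary log-linear least-squares tensor fit.

    Solves ``ln S = ln S0 - b g^T D g`` per voxel for the 7 unknowns.
    Non-positive signals are clamped to a floor of ``1e-6 * max(S0)``;
    voxels where at least half the volumes are non-positive are masked out
    rather than fitted.

    Raises
    ------
    ValueError
        If fewer than 6 unique directions are provided or the design matrix
        is rank deficient (collinear direction set).
    """
    data = dwi.data if isinstance(dwi, DWIStack) else np.asarray(dwi, float)
    if protocol.n_directions < 6:
        raise ValueError(
            f"tensor fit needs >= 6 non-collinear directions, got "
            f"{protocol.n_directions}"
        )
    design = protocol.design_matrix()
    if np.linalg.matrix_rank(design) < 7:
        raise ValueError(
            "rank-deficient design matrix: direction set "
            f"{protocol.bvecs[protocol.bvals > 0].tolist()} does not span the "
            "6 tensor degrees of freedom"
        )
    shape = data.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, bool)

    signals = data[mask]  # (nvox, nvol)
    b0_max = data[..., protocol.bvals == 0].max() if signals.size else 1.0
    floor = 1e-6 * max(b0_max, np.finfo(float).tiny)
    nonpos = signals <= 0
    bad_voxel = nonpos.sum(axis=1) >= (signals.shape[1] + 1) // 2
    clamped = np.log(np.clip(signals, floor, None))

    # one pseudoinverse for all voxels (same design everywhere)
    coeffs = clamped @ np.linalg.pinv(design).T  # (nvox, 7)
    comp = np.full(shape + (6,), np.nan)
    log_s0 = np.full(shape, np.nan)
    fitted = np.zeros(shape, dtype=bool)
    idx = np.nonzero(mask)
    good = ~bad_voxel
    sel = tuple(a[good] for a in idx)
    comp[sel] = coeffs[good, 1:]
    log_s0[sel] = coeffs[good, 0]
    fitted[sel] = True
    fitted &= np.isfinite(comp).all(axis=-1)
    return TensorField(components=comp, valid=fitted, log_s0=log_s0)


def eigendecompose(tensors: TensorField,
                   reference: np.ndarray | None = None,
                   degeneracy_rtol: float = 1e-6) -> EigenSystem:
    """Sorted eigendecomposition with hemisphere-canonicalized e1.

    ``e1`` is flipped into the hemisphere of ``reference`` (for example the
    local circumferential direction) when given, else of +x.  Voxels with
    non-finite components are masked; isotropic voxels (λ1 ≈ λ3) are flagged
    degenerate since their orientation carries no information.
    """
    comp = tensors.components
    valid = tensors.valid & np.isfinite(comp).all(axis=-1)
    mats = TensorField(np.where(valid[..., None], comp, 0.0), valid).as_matrices()
    w, v = np.linalg.eigh(mats)          # ascending
    w = w[..., ::-1]
    v = v[..., ::-1]
    if reference is None:
        ref = np.zeros(comp.shape[:-1] + (3,))
        ref[..., 0] = 1.0
    else:
        ref = np.asarray(reference, dtype=float)
    for i in range(3):
        dot = np.einsum("...i,...i->...", v[..., :, i], ref)
        sign = np.where(dot < 0, -1.0, 1.0)
        v[..., :, i] *= sign[..., None]
    scale = np.maximum(np.abs(w[..., 0]), np.finfo(float).tiny)
    degenerate = valid & ((w[..., 0] - w[..., 2]) <= degeneracy_rtol * scale)
    return EigenSystem(eigenvalues=w, eigenvectors=v, valid=valid,
                       degenerate=degenerate)


def mean_diffusivity(eigs: EigenSystem) -> np.ndarray:
    """MD = (λ1 + λ2 + λ3) / 3, NaN where the fit was invalid."""
    md = eigs.eigenvalues.mean(axis=-1)
    return np.where(eigs.valid, md, np.nan)


def electrostatic_directions(n: int = 12, seed: int = 0,
                             iterations: int = 2000) -> np.ndarray:
    """Quasi-uniform unit directions by electrostatic repulsion of axial pairs.

    Deterministic for fixed ``seed``; used as the default 12-direction
    scheme (the reference acquisition does not publish its table).
    """
    rng = np.random.default_rng(seed)
    p = rng.standard_normal((n, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    lr = 0.05
    for _ in range(iterations):
        force = np.zeros_like(p)
        for s in (1.0, -1.0):  # antipodal charge pairs
            d = p[:, None, :] - s * p[None, :, :]
            dist2 = (d ** 2).sum(-1)
            np.fill_diagonal(dist2, np.inf)
            dist2 = np.maximum(dist2, 1e-12)
            force += (d / dist2[..., None] ** 1.5).sum(axis=1)
        p += lr * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p


def default_protocol(b: float = 1000.0, n_directions: int = 12,
                     seed: int = 0) -> DWIProtocol:
    """Reference protocol: one b=0 volume plus ``n_directions`` at b (s/mm^2)."""
    dirs = electrostatic_directions(n_directions, seed=seed)
    bvals = np.concatenate([[0.0], np.full(n_directions, b)])
    bvecs = np.vstack([np.zeros(3), dirs])
    return DWIProtocol(bvals=bvals, bvecs=bvecs)
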