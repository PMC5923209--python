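"""Cross-modality matching and agreement statistics.

The optical volume is block-average downsampled to the DTI grid, the
myocardium masks are aligned by mutual-information affine registration
(rigid initialisation from image moments), and agreement between the two
modalities' HA/HAT measurements is quantified with the standard toolkit:
Bland-Altman bias and 95 % limits of agreement, intraclass correlation
(two-way mixed, single measure; both absolute-agreement ICC(A,1) and
consistency ICC(C,1) are reported), Spearman correlation, linear-fit R²,
and group-difference tests (rank-sum for independent groups, signed-rank
or paired t for paired regions).

Bland-Altman differences are taken as ``x - y`` (DTI minus optical by
convention) and the order is recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

try:
    import SimpleITK as sitk
except ImportError:  # registration degrades gracefully if unavailable
    sitk = None


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n: int
    order: str = "x - y"


@dataclass
class AgreementStats:
    n: int
    bland_altman: BlandAltman
    icc_agreement: float
    icc_consistency: float
    spearman_rho: float
    spearman_p: float
    r_squared: float
    tests: dict = field(default_factory=dict)


def downsample_to(volume: np.ndarray, source_spacing, target_spacing,
                  mask: bool = False) -> np.ndarray:
    """Block-average resample onto a coarser grid.

    Every source voxel contributes to the target voxel containing its
    centre (physical-coordinate binning, so non-integer ratios are handled
    by partial-volume weighting of whole source voxels).  Masks are
    resampled by majority vote.  The grid mean is conserved, so total
    intensity is conserved up to edge partial volumes.
    """
    src = np.asarray(source_spacing, float)
    tgt = np.asarray(target_spacing, float)
    if (tgt < src - 1e-9).any():
        raise ValueError(f"target spacing {tgt} must be >= source {src}")
    vol = np.asarray(volume, float)
    shape = np.asarray(vol.shape)
    out_shape = np.maximum(np.ceil(shape * src / tgt).astype(int), 1)
    idx = [np.minimum((np.arange(n) * src[a] / tgt[a]).astype(int),
                      out_shape[a] - 1) for a, n in enumerate(shape)]
    flat_bin = (idx[0][:, None, None] * (out_shape[1] * out_shape[2])
                + idx[1][None, :, None] * out_shape[2]
                + idx[2][None, None, :])
    sums = np.bincount(flat_bin.ravel(), weights=vol.ravel(),
                       minlength=int(out_shape.prod()))
    counts = np.bincount(flat_bin.ravel(), minlength=int(out_shape.prod()))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    mean = mean.reshape(tuple(out_shape))
    if mask:
        return mean >= 0.5
    return mean


def register_masks(moving: np.ndarray, fixed: np.ndarray,
                   moving_spacing, fixed_spacing,
                   min_dice: float = 0.5):
    """Affine mutual-information registration of two binary masks.

    Returns ``(transform, dice)`` where ``transform`` is a SimpleITK
    affine transform mapping fixed physical points to moving physical
    points.  A final Dice below ``min_dice`` raises a hard warning in the
    returned report (via ``RuntimeWarning``).
    """
    if sitk is None:
        raise RuntimeError("SimpleITK is required for mask registration")
    if not (np.asarray(moving).any() and np.asarray(fixed).any()):
        raise ValueError("registration requires non-empty masks")

    def _img(arr, spacing):
        img = sitk.GetImageFromArray(np.asarray(arr, np.float32).T)
        img.SetSpacing(tuple(float(s) for s in np.asarray(spacing, float)))
        return img

    mov = _img(moving, moving_spacing)
    fix = _img(fixed, fixed_spacing)
    # binary masks give the metric almost no gradient; blur them into soft
    # edge images (standard practice for mask-driven registration)
    sigma = 2.0 * float(np.min(fixed_spacing))
    mov_s = sitk.SmoothingRecursiveGaussian(mov, sigma)
    fix_s = sitk.SmoothingRecursiveGaussian(fix, sigma)
    fixed_b = np.asarray(fixed, bool)

    def _dice(transform):
        resampled = sitk.Resample(mov, fix, transform, sitk.sitkLinear, 0.0)
        warped = sitk.GetArrayFromImage(resampled).T >= 0.5
        inter = np.logical_and(warped, fixed_b).sum()
        return 2.0 * inter / max(warped.sum() + fixed_b.sum(), 1)

    init = sitk.CenteredTransformInitializer(
        fix_s, mov_s, sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.MOMENTS)
    init_dice = _dice(init)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=0.5, minStep=1e-5, numberOfIterations=300,
        relaxationFactor=0.7)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
    reg.SetInitialTransform(init, inPlace=False)  # keep init as fallback
    transform = reg.Execute(fix_s, mov_s)
    # normalize to a plain affine for downstream introspection
    if isinstance(transform, sitk.CompositeTransform):
        transform = transform.GetNthTransform(0)
    transform = sitk.AffineTransform(transform.Downcast()
                                     if hasattr(transform, "Downcast")
                                     else transform)
    dice = _dice(transform)
    if dice < init_dice:  # optimizer made things worse; keep the init
        transform = sitk.AffineTransform(init.Downcast()
                                         if hasattr(init, "Downcast")
                                         else init)
        dice = init_dice
    if dice < min_dice:
        import warnings
        warnings.warn(f"mask registration Dice {dice:.3f} < {min_dice}",
                      RuntimeWarning, stacklevel=2)
    return transform, float(dice)


def apply_transform(volume: np.ndarray, transform, fixed_shape,
                    moving_spacing, fixed_spacing,
                    nearest: bool = False) -> np.ndarray:
    """Warp a volume (HA map: linear; labels: nearest) onto the fixed grid."""
    if sitk is None:
        raise RuntimeError("SimpleITK is required to apply transforms")
    img = sitk.GetImageFromArray(np.asarray(volume, np.float64).T)
    img.SetSpacing(tuple(float(s) for s in np.asarray(moving_spacing, float)))
    ref = sitk.Image([int(n) for n in fixed_shape], sitk.sitkFloat64)
    ref.SetSpacing(tuple(float(s) for s in np.asarray(fixed_spacing, float)))
    interp = sitk.sitkNearestNeighbor if nearest else sitk.sitkLinear
    out = sitk.Resample(img, ref, transform, interp, np.nan)
    return sitk.GetArrayFromImage(out).T


def bland_altman(x, y) -> BlandAltman:
    """Bias and 95 % limits of agreement of paired differences ``x - y``.

    LoA = bias ± 1.96 * SD (sample SD, n-1 denominator; 0 when n < 2
    variance is undefined — n < 2 is rejected).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("bland_altman needs equal-length 1-D samples")
    if x.size < 2:
        raise ValueError("bland_altman needs n >= 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd,
                       loa_high=bias + 1.96 * sd, sd=sd, n=x.size)


def icc(x, y) -> tuple[float, float]:
    """Single-measure two-way ICCs from the ANOVA mean squares.

    Returns ``(ICC(A,1), ICC(C,1))`` — absolute agreement and consistency —
    for two raters (methods) measuring the same n targets.  Undefined
    (NaN) when both raters have zero variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("icc needs paired 1-D samples with n >= 3")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom_a = msr + (k - 1) * mse + k * (msc - mse) / n
    denom_c = msr + (k - 1) * mse
    icc_a = (msr - mse) / denom_a if denom_a > 0 else float("nan")
    icc_c = (msr - mse) / denom_c if denom_c > 0 else float("nan")
    return float(icc_a), float(icc_c)


def agreement_suite(x, y, tests: tuple = ("spearman",),
                    paired: bool = True) -> AgreementStats:
    """Full agreement panel between two paired measurement series.

    ``tests`` may include "wilcoxon" (rank-sum on independent groups),
    "signed_rank" and "paired_t" (paired regions).  Spearman uses midranks
    for ties; all p-values are two-sided (α = 0.05 convention).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ba = bland_altman(x, y)
    icc_a, icc_c = icc(x, y) if x.size >= 3 else (float("nan"),) * 2
    rho, rho_p = stats.spearmanr(x, y)
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r ** 2)
    results: dict = {}
    for t in tests:
        if t == "spearman":
            continue
        if t == "wilcoxon":
            s, p = stats.ranksums(x, y)
        elif t == "signed_rank":
            if np.allclose(x, y):
                s, p = 0.0, 1.0
            else:
                s, p = stats.wilcoxon(x, y)
        elif t == "paired_t":
            s, p = stats.ttest_rel(x, y)
        else:
            raise ValueError(f"unknown test {t!r}")
        results[t] = {"statistic": float(s), "p": float(p)}
    return AgreementStats(n=x.size, bland_altman=ba, icc_agreement=icc_a,
                          icc_consistency=icc_c, spearman_rho=float(rho),
                          spearman_p=float(rho_p), r_squared=r2,
                          tests=results)
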