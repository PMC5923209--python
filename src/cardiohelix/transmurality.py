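"""Helix-angle transmurality (HAT): radial profiles, global and segmental.

Per short-axis slice, helix angle is sampled along equidistant radial
projections (default 20 rays) at equally spaced transmural-depth stations
(default 8, one per virtual transmural block).  An ordinary least-squares
line ``HA = a + s * TD`` is fitted per profile; the global HAT is the
unweighted mean of the fitted slopes (°/%TD), reported signed and in
magnitude.  Lower |HAT| means less helical winding.

Regional summaries follow the standard schemes: the AHA 16-segment model
(basal 6 / mid 6 / apical 4, by slice thirds and azimuth), and 100 radial
segments of 3.6° pooled across slices.  Infarct zoning thresholds the mean
diffusivity map: infarct MD > 1.12 µm²/ms (excluded from all HAT
statistics), peri-infarct 0.9 < MD <= 1.12, remote MD <= 0.9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import LVFrame, WallBoundary
from .phantom import (LABEL_BACKGROUND, LABEL_INFARCT, LABEL_PERI,
                      LABEL_REMOTE, MD_INFARCT, MD_REMOTE)

logger = logging.getLogger(__name__)


@dataclass
class RadialProfile:
    """HA-vs-TD samples along one radial projection of one slice."""

    slice_index: int
    azimuth_deg: float
    td: np.ndarray
    ha: np.ndarray
    labels: np.ndarray | None = None  # region label per sample, if known

    def __post_init__(self) -> None:
        self.td = np.asarray(self.td, float)
        self.ha = np.asarray(self.ha, float)
        if self.td.size and (np.diff(self.td) <= 0).any():
            raise ValueError("TD must be strictly increasing within a profile")

    @property
    def n_samples(self) -> int:
        return self.td.size

    @property
    def touches_infarct(self) -> bool:
        return self.labels is not None and bool(
            (self.labels == LABEL_INFARCT).any())


@dataclass
class HATResult:
    """Global and per-slice HAT summary."""

    slopes: np.ndarray          # accepted per-profile slopes, °/%TD
    intercepts: np.ndarray
    profiles: list              # accepted RadialProfile objects
    global_hat: float           # signed mean slope
    n_dropped: int = 0

    @property
    def abs_global_hat(self) -> float:
        return abs(self.global_hat)

    def per_slice_means(self) -> dict[int, float]:
        out: dict[int, list[float]] = {}
        for p, s in zip(self.profiles, self.slopes):
            out.setdefault(p.slice_index, []).append(s)
        return {k: float(np.mean(v)) for k, v in sorted(out.items())}


def extract_profiles(ha: np.ndarray, td: np.ndarray, frame: LVFrame,
                     boundary: WallBoundary, n_rays: int = 20,
                     n_stations: int = 8, reference_azimuth: float = 0.0,
                     labels: np.ndarray | None = None,
                     min_samples: int = 4) -> tuple[list[RadialProfile], int]:
    """Sample HA along equidistant radial projections.

    Stations sit at the centres of ``n_stations`` equal TD bins; HA is
    looked up at the nearest voxel and paired with that voxel's own TD
    value (duplicate voxels collapse to one sample).  Profiles with fewer
    than ``min_samples`` valid stations — rays through thinned or
    low-coherence sectors — are dropped and counted.

    Returns (profiles, n_dropped).
    """
    nx, ny, nz = ha.shape
    sx, sy = frame.spacing[:2]
    azimuths = (reference_azimuth + np.arange(n_rays) * 360.0 / n_rays) % 360.0
    stations = (np.arange(n_stations) + 0.5) / n_stations * 100.0
    profiles: list[RadialProfile] = []
    dropped = 0
    ok_slices = frame.valid_slices()
    for k in range(nz):
        if not ok_slices[k]:
            continue
        cx, cy = frame.centers[k]
        for az in azimuths:
            endo, epi = boundary.interp(k, np.array([az]))
            if not (np.isfinite(endo[0]) and np.isfinite(epi[0])):
                dropped += 1
                continue
            radii = endo[0] + stations / 100.0 * (epi[0] - endo[0])
            px = np.rint(cx + radii * np.cos(np.radians(az)) / sx).astype(int)
            py = np.rint(cy + radii * np.sin(np.radians(az)) / sy).astype(int)
            inb = (px >= 0) & (px < nx) & (py >= 0) & (py < ny)
            td_s = np.full(radii.shape, np.nan)
            ha_s = np.full(radii.shape, np.nan)
            lab_s = np.zeros(radii.shape, dtype=np.int8)
            td_s[inb] = td[px[inb], py[inb], k]
            ha_s[inb] = ha[px[inb], py[inb], k]
            if labels is not None:
                lab_s[inb] = labels[px[inb], py[inb], k]
            good = np.isfinite(td_s) & np.isfinite(ha_s)
            td_s, ha_s, lab_s = td_s[good], ha_s[good], lab_s[good]
            # collapse duplicate voxels (identical TD) keeping first
            if td_s.size:
                order = np.argsort(td_s, kind="stable")
                td_s, ha_s, lab_s = td_s[order], ha_s[order], lab_s[order]
                keep = np.concatenate([[True], np.diff(td_s) > 1e-9])
                td_s, ha_s, lab_s = td_s[keep], ha_s[keep], lab_s[keep]
            if td_s.size < min_samples:
                dropped += 1
                continue
            profiles.append(RadialProfile(
                slice_index=k, azimuth_deg=float(az), td=td_s, ha=ha_s,
                labels=lab_s if labels is not None else None))
    if dropped:
        logger.info("extract_profiles: dropped %d of %d rays",
                    dropped, dropped + len(profiles))
    return profiles, dropped


def fit_profile_slope(profile: RadialProfile,
                      min_td_range: float = 10.0) -> tuple[float, float]:
    """OLS line HA = intercept + slope * TD for one profile.

    Raises ``ValueError`` for degenerate TD spread (< ``min_td_range`` %TD)
    or fewer than 4 samples.
    """
    if profile.n_samples < 4:
        raise ValueError(f"profile needs >= 4 samples, has {profile.n_samples}")
    if np.ptp(profile.td) < min_td_range:
        raise ValueError(
            f"degenerate TD spread {np.ptp(profile.td):.1f} %TD "
            f"(< {min_td_range})")
    slope, intercept = np.polyfit(profile.td, profile.ha, 1)
    return float(slope), float(intercept)


def global_hat(profiles: list[RadialProfile],
               exclude_infarct: bool = True) -> HATResult:
    """Mean fitted slope over all accepted profiles.

    Profiles touching infarct-labelled voxels are excluded when region
    labels are available (the tensor model is unreliable in infarct).
    """
    slopes, intercepts, kept = [], [], []
    dropped = 0
    for p in profiles:
        if exclude_infarct and p.touches_infarct:
            dropped += 1
            continue
        try:
            s, a = fit_profile_slope(p)
        except ValueError:
            dropped += 1
            continue
        slopes.append(s)
        intercepts.append(a)
        kept.append(p)
    if not slopes:
        raise ValueError("no accepted profiles: cannot compute global HAT")
    slopes = np.asarray(slopes)
    return HATResult(slopes=slopes, intercepts=np.asarray(intercepts),
                     profiles=kept, global_hat=float(slopes.mean()),
                     n_dropped=dropped)


def _aha_segment(azimuth_deg: float, ring: str,
                 reference_azimuth: float = 0.0) -> int:
    """AHA segment number (1-16) for a profile azimuth within a ring."""
    az = (azimuth_deg - reference_azimuth) % 360.0
    if ring == "basal":
        return 1 + int(az // 60.0) % 6
    if ring == "mid":
        return 7 + int(az // 60.0) % 6
    if ring == "apical":
        return 13 + int(az // 90.0) % 4
    raise ValueError(f"unknown ring {ring!r}")


def aha16_bin(result: HATResult, n_slices: int,
              reference_azimuth: float = 0.0) -> np.ndarray:
    """Mean profile slope per AHA segment (16 values, NaN where empty).

    Slices are labelled basal/mid/apical by thirds of the analyzed
    long-axis extent (basal = low z).  Segments containing any
    infarct-touching profile are omitted (NaN), without affecting others.
    """
    thirds = np.clip((np.arange(n_slices) * 3) // max(n_slices, 1), 0, 2)
    ring_of_slice = np.array(["basal", "mid", "apical"])[thirds]
    sums = np.zeros(16)
    counts = np.zeros(16, dtype=int)
    poisoned = np.zeros(16, dtype=bool)
    for p, s in zip(result.profiles, result.slopes):
        seg = _aha_segment(p.azimuth_deg, ring_of_slice[p.slice_index],
                           reference_azimuth) - 1
        if p.touches_infarct:
            poisoned[seg] = True
            continue
        sums[seg] += s
        counts[seg] += 1
    out = np.full(16, np.nan)
    ok = (counts > 0) & ~poisoned
    out[ok] = sums[ok] / counts[ok]
    return out


def radial_segment_bin(result: HATResult, bin_width_deg: float = 3.6
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Mean slope per azimuthal bin pooled across slices.

    Default 3.6° width gives 100 segments spanning 360°.  Returns
    (values, counts); empty bins are NaN with count 0.  The count-weighted
    mean of the bin values equals the global HAT on complete data.
    """
    n_bins = int(round(360.0 / bin_width_deg))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for p, s in zip(result.profiles, result.slopes):
        b = int((p.azimuth_deg % 360.0) // bin_width_deg) % n_bins
        sums[b] += s
        counts[b] += 1
    values = np.full(n_bins, np.nan)
    values[counts > 0] = sums[counts > 0] / counts[counts > 0]
    return values, counts


def md_region_masks(md: np.ndarray, myocardium: np.ndarray,
                    infarct_threshold: float = MD_INFARCT,
                    remote_threshold: float = MD_REMOTE) -> np.ndarray:
    """Zone the myocardium by mean diffusivity.

    Infarct: MD > 1.12 µm²/ms; peri-infarct: 0.9 < MD <= 1.12; remote:
    MD <= 0.9.  Labels partition the myocardium mask (voxels with
    non-finite MD stay background).  Values far outside the plausible
    diffusivity range trigger a units warning.
    """
    md = np.asarray(md, float)
    finite = np.isfinite(md) & np.asarray(myocardium, bool)
    if finite.any() and ((md[finite] < 0).any() or (md[finite] > 4).any()):
        logger.warning("MD values outside [0, 4] µm²/ms; check units")
    labels = np.full(md.shape, LABEL_BACKGROUND, dtype=np.int8)
    labels[finite & (md > infarct_threshold)] = LABEL_INFARCT
    labels[finite & (md > remote_threshold)
           & (md <= infarct_threshold)] = LABEL_PERI
    labels[finite & (md <= remote_threshold)] = LABEL_REMOTE
    return labels


def region_hat(result: HATResult) -> dict[str, float]:
    """Mean slope of peri-infarct vs remote profiles (label-majority).

    A profile is peri-infarct when any of its samples is peri-labelled;
    infarct-touching profiles are already excluded upstream.
    """
    peri, remote = [], []
    for p, s in zip(result.profiles, result.slopes):
        if p.labels is None:
            continue
        if (p.labels == LABEL_PERI).any():
            peri.append(s)
        else:
            remote.append(s)
    return {
        "peri_infarct": float(np.mean(peri)) if peri else float("nan"),
        "remote": float(np.mean(remote)) if remote else float("nan"),
        "n_peri": len(peri),
        "n_remote": len(remote),
    }
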