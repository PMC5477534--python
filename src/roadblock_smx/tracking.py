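"""Subpixel 3D localization of bead diffraction patterns.

XY: radial-symmetry center finding.  Intensity gradients of a radially
symmetric pattern all point through its center, so the center is the
weighted least-squares point of minimum distance to the lines drawn
through the inter-pixel gradient midpoints along their gradient
directions.  Gradients are taken on the dual (half-pixel) grid from the
diagonal differences of 2x2 pixel blocks, smoothed with a 3x3 boxcar;
weights are gradient magnitude squared divided by the distance of each
midpoint from the gradient-magnitude centroid.  The solution is closed
form — no iteration, no initial guess.

Z: the radial intensity profile of the frame is matched against a
lookup table (LUT) of profiles recorded at known defocus heights by
minimizing the total squared difference; a parabola through the SSD
values at the best entry and its two neighbors gives the sub-step
height (the parabola vertex).  Profiles are normalized to zero mean and
unit variance before matching by default, which makes the estimate
invariant to uniform illumination changes; raw SSD matching is
available for strict fidelity to the recorded-intensity scheme.

Tether extension is the height of the tethered bead minus the height of
a surface-stuck reference bead, referred to the pre-run baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import ValidationError
from .traces import ExtensionTrace

__all__ = [
    "ImageFrame",
    "RadialProfile",
    "LookupTable",
    "TrackedPosition",
    "locate_xy",
    "radial_profile",
    "estimate_z",
    "build_lookup_table",
    "track",
    "tether_extension",
]


@dataclass
class ImageFrame:
    """One camera frame holding a single bead diffraction pattern."""

    pixels: np.ndarray
    pixel_size: float = 72.5  # nm/pixel
    timestamp: float = 0.0  # s

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 4:
            raise ValidationError("frame must be a 2-D image of at least 4x4 pixels")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")


@dataclass
class RadialProfile:
    """Mean intensity per 1-px annulus around a center."""

    radii: np.ndarray  # bin centers, pixel units (0, 1, 2, ...)
    intensity: np.ndarray
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.radii.shape != self.intensity.shape or self.radii.ndim != 1:
            raise ValidationError("radii and intensity must be matching 1-D arrays")
        if self.radii.size >= 2 and not np.all(np.diff(self.radii) > 0):
            raise ValidationError("radii must be strictly increasing")


@dataclass
class LookupTable:
    """Radial profiles at a uniform, ascending grid of defocus heights."""

    z_values: np.ndarray  # nm
    profiles: np.ndarray  # (n_z, n_bins)
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.z_values.size < 3:
            raise ValidationError("LUT needs at least 3 z planes")
        dz = np.diff(self.z_values)
        if not (np.all(dz > 0) and np.allclose(dz, dz[0])):
            raise ValidationError("LUT z grid must be strictly increasing and uniform")
        if self.profiles.shape[0] != self.z_values.size:
            raise ValidationError("one profile per z value is required")

    @property
    def z_step(self) -> float:
        return float(self.z_values[1] - self.z_values[0])


@dataclass
class TrackedPosition:
    t: float  # s
    x_nm: float
    y_nm: float
    z_nm: float
    matched_index: int
    ssd_curve: np.ndarray = field(repr=False, default=None)
    at_edge: bool = False
    ok: bool = True
    message: str = ""


def locate_xy(frame: ImageFrame | np.ndarray) -> tuple[float, float]:
    """Radial-symmetry subpixel center of the frame, in pixel coordinates.

    Returns (x, y) with pixel centers at integer coordinates, x along
    columns and y along rows.  Raises on a gradient-free (constant)
    image.
    """
    I = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame, dtype=float)
    ny, nx = I.shape
    # Dual-grid coordinates of the 2x2 block midpoints, relative to the
    # image center so the linear system stays well conditioned.
    xm = np.arange(nx - 1) - (nx - 2) / 2.0
    ym = np.arange(ny - 1) - (ny - 2) / 2.0
    xm, ym = np.meshgrid(xm, ym)

    # Diagonal derivatives (45-degree rotated frame), 3x3 boxcar smoothed.
    dIdu = I[:-1, 1:] - I[1:, :-1]
    dIdv = I[:-1, :-1] - I[1:, 1:]
    fdu = uniform_filter(dIdu, 3, mode="nearest")
    fdv = uniform_filter(dIdv, 3, mode="nearest")
    grad2 = fdu**2 + fdv**2
    total = grad2.sum()
    if total <= 0:
        raise ValidationError("constant image: radial-symmetry center undefined")

    # Slope of each gradient line back in the pixel frame.
    denom = fdu - fdv
    with np.errstate(divide="ignore", invalid="ignore"):
        m = -(fdv + fdu) / denom
    m = np.where(np.isnan(m), 0.0, m)
    m = np.clip(m, -1e9, 1e9)
    b = ym - m * xm

    # Weights: gradient power, de-emphasized far from the gradient centroid.
    xc0 = (grad2 * xm).sum() / total
    yc0 = (grad2 * ym).sum() / total
    dist = np.sqrt((xm - xc0) ** 2 + (ym - yc0) ** 2)
    w = grad2 / np.maximum(dist, 0.5)

    wm2p1 = w / (m * m + 1.0)
    sw = wm2p1.sum()
    smw = (m * wm2p1).sum()
    smmw = (m * m * wm2p1).sum()
    sbw = (b * wm2p1).sum()
    smbw = (m * b * wm2p1).sum()
    det = smw * smw - smmw * sw
    if det == 0:
        raise ValidationError("degenerate gradient geometry: center undefined")
    xc = (smbw * sw - smw * sbw) / det
    yc = (smbw * smw - smmw * sbw) / det
    return float(xc + (nx - 1) / 2.0), float(yc + (ny - 1) / 2.0)


def radial_profile(
    frame: ImageFrame | np.ndarray, center: tuple[float, float], bin_width: float = 1.0
) -> RadialProfile:
    """Annular mean intensities about ``center`` (pixel coordinates).

    Fractional radii are split linearly between the two neighboring
    1-px annuli; the profile extends to the largest annulus fully
    contained in the frame.  Deterministic.
    """
    I = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame, dtype=float)
    ny, nx = I.shape
    cx, cy = center
    if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
        raise ValidationError("profile center lies outside the frame")
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    n_bins = int(np.floor(min(cx, cy, nx - 1 - cx, ny - 1 - cy) / bin_width))
    if n_bins < 2:
        raise ValidationError("center too close to the frame edge for a radial profile")
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    r = np.hypot(xx - cx, yy - cy).ravel() / bin_width
    vals = I.ravel()
    lo = np.floor(r).astype(int)
    frac = r - lo
    # linear interpolation of fractional radii between adjacent annuli
    idx = np.concatenate([lo, lo + 1])
    wts = np.concatenate([1.0 - frac, frac])
    v = np.concatenate([vals, vals])
    keep = idx < n_bins
    num = np.bincount(idx[keep], weights=(wts * v)[keep], minlength=n_bins)
    den = np.bincount(idx[keep], weights=wts[keep], minlength=n_bins)
    if np.any(den <= 0):
        raise ValidationError("empty annulus in radial profile")
    return RadialProfile(
        radii=np.arange(n_bins, dtype=float) * bin_width,
        intensity=num / den,
        bin_width=bin_width,
    )


def _normalize(p: np.ndarray) -> np.ndarray:
    sd = p.std()
    if sd <= 0:
        raise ValidationError("flat radial profile cannot be matched against the LUT")
    return (p - p.mean()) / sd


def estimate_z(
    profile: RadialProfile, lut: LookupTable, normalize: bool = True
) -> tuple[float, int, np.ndarray, bool]:
    """LUT z estimate: SSD argmin plus parabolic sub-step refinement.

    Returns (z_nm, matched_index, ssd_curve, at_edge).  The parabola is
    fitted through the SSD values at the best-matching LUT entry and its
    two neighbors; its vertex abscissa is the height estimate.  At the
    first/last LUT entry the grid height is returned with ``at_edge``
    set (no extrapolation beyond the sampled range).
    """
    if not np.isclose(profile.bin_width, lut.bin_width):
        raise ValidationError(
            f"binning mismatch: profile {profile.bin_width} px vs LUT {lut.bin_width} px"
        )
    n = min(profile.intensity.size, lut.profiles.shape[1])
    if n < 3:
        raise ValidationError("too few shared radial bins for matching")
    p = profile.intensity[:n]
    table = lut.profiles[:, :n]
    if normalize:
        p = _normalize(p)
        table = np.array([_normalize(row) for row in table])
    ssd = np.sum((table - p[None, :]) ** 2, axis=1)
    k = int(np.argmin(ssd))
    if ssd[k] <= 1e-14 * (ssd.max() + 1e-300):
        # exact grid hit: no sub-step refinement needed
        return float(lut.z_values[k]), k, ssd, k in (0, ssd.size - 1)
    if k == 0 or k == ssd.size - 1:
        return float(lut.z_values[k]), k, ssd, True
    s0, s1, s2 = ssd[k - 1], ssd[k], ssd[k + 1]
    curv = s0 - 2.0 * s1 + s2
    if curv <= 0:  # flat or non-convex triplet: fall back to the grid point
        return float(lut.z_values[k]), k, ssd, False
    delta = 0.5 * (s0 - s2) / curv
    return float(lut.z_values[k] + delta * lut.z_step), k, ssd, False


def build_lookup_table(
    stack: list[tuple[float, np.ndarray]] | list[tuple[float, ImageFrame]],
    bin_width: float = 1.0,
) -> LookupTable:
    """Build a LUT from (z, calibration frame) pairs.

    Each frame is centered with :func:`locate_xy` before profiling, so
    the LUT and live profiles share the same binning exactly.
    """
    if len(stack) < 3:
        raise ValidationError("LUT needs at least 3 planes")
    z_values, profiles = [], []
    for z, img in stack:
        center = locate_xy(img)
        prof = radial_profile(img, center, bin_width)
        z_values.append(z)
        profiles.append(prof.intensity)
    n = min(p.size for p in profiles)
    return LookupTable(
        z_values=np.array(z_values),
        profiles=np.array([p[:n] for p in profiles]),
        bin_width=bin_width,
    )


def track(
    frames: list[ImageFrame],
    lut: LookupTable,
    normalize: bool = True,
) -> list[TrackedPosition]:
    """Per-frame 3D localization: locate_xy → radial_profile → estimate_z.

    The output series is complete: a frame that cannot be localized
    yields a flagged entry (``ok=False``) rather than being dropped.
    """
    out: list[TrackedPosition] = []
    for frame in frames:
        try:
            cx, cy = locate_xy(frame)
            prof = radial_profile(frame, (cx, cy), lut.bin_width)
            z, k, ssd, at_edge = estimate_z(prof, lut, normalize=normalize)
            out.append(
                TrackedPosition(
                    t=frame.timestamp,
                    x_nm=cx * frame.pixel_size,
                    y_nm=cy * frame.pixel_size,
                    z_nm=z,
                    matched_index=k,
                    ssd_curve=ssd,
                    at_edge=at_edge,
                )
            )
        except (ValidationError, FloatingPointError) as err:
            out.append(
                TrackedPosition(
                    t=frame.timestamp,
                    x_nm=np.nan,
                    y_nm=np.nan,
                    z_nm=np.nan,
                    matched_index=-1,
                    ssd_curve=None,
                    ok=False,
                    message=str(err),
                )
            )
    return out


def tether_extension(
    tether: list[TrackedPosition],
    reference: list[TrackedPosition],
    sample_rate: float,
    baseline_samples: int | None = None,
) -> ExtensionTrace:
    """Extension(t) = z_tether − z_reference, µm, re-zeroed to baseline.

    ``baseline_samples`` initial samples define the pre-run baseline
    mean (default: the whole series, appropriate for static checks).
    The two series must share the frame clock.
    """
    if len(tether) != len(reference):
        raise ValidationError("tether and reference series have different lengths")
    t = np.array([p.t for p in tether])
    t_ref = np.array([p.t for p in reference])
    if not np.allclose(t, t_ref):
        raise ValidationError("tether and reference series are not time-aligned")
    ext_nm = np.array([p.z_nm for p in tether]) - np.array([p.z_nm for p in reference])
    nb = len(ext_nm) if baseline_samples is None else max(1, int(baseline_samples))
    ext_nm = ext_nm - np.nanmean(ext_nm[:nb])
    return ExtensionTrace(
        time=t,
        extension=ext_nm / 1e3,
        sample_rate=sample_rate,
        bead_id="tether-extension",
        history=["tether_extension"],
    )
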