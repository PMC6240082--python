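"""Resolution and contrast metrics for reconstructed images.

Three yardsticks:

* Fourier Ring Correlation (FRC) — the correlation between the spectra of
  two independent half-reconstructions as a function of spatial frequency;
  resolution is the inverse frequency at which the curve falls to the fixed
  1/7 threshold.
* Feature-of-interest (FOI) effective PSF — Gaussian fits to intensity
  cross-sections of fibres of known physical width, histogrammed over many
  backbone positions; the modal FWHM minus the fibre width minus the
  fluorophore size is the effective point-spread-function width.
* Contrast C = (I - I_b) / I_b between a feature and its background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .inference import RegionMask, photon_density
from .render import SRImage, render_sr
from .scene import Fibre, _rng

__all__ = [
    "FRCResult",
    "FOIResult",
    "ContrastResult",
    "frc",
    "frc_from_images",
    "foi",
    "contrast",
    "improvement_factor",
]

FRC_THRESHOLD = 1.0 / 7.0
GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass
class FRCResult:
    frequencies: np.ndarray  # 1/nm
    correlation: np.ndarray  # smoothed ring correlation
    resolution_nm: float  # nan when the curve never crosses the threshold
    threshold: float = FRC_THRESHOLD
    resolved: bool = True

    def __post_init__(self) -> None:
        if self.resolved and not self.resolution_nm > 0:
            raise ValueError("resolution must be positive when resolved")


@dataclass
class FOIResult:
    fwhm_values_nm: np.ndarray
    bin_edges_nm: np.ndarray
    histogram: np.ndarray
    modal_fwhm_nm: float
    effective_psf_nm: float
    fibre_width_nm: float = 11.0
    fluorophore_nm: float = 1.0
    n_failed_fits: int = 0
    failure_reasons: dict = field(default_factory=dict)

    @property
    def negative_psf(self) -> bool:
        """Flagged when the subtraction overshoots the modal width."""
        return self.effective_psf_nm < 0


@dataclass(frozen=True)
class ContrastResult:
    i_feature: float
    i_background: float

    def __post_init__(self) -> None:
        if self.i_background <= 0:
            raise ZeroDivisionError("background intensity must be positive for contrast")

    @property
    def c(self) -> float:
        return (self.i_feature - self.i_background) / self.i_background


# ---------------------------------------------------------------------------
# Fourier Ring Correlation


def _ring_correlation(img1: np.ndarray, img2: np.ndarray, pixel_nm: float):
    """Raw ring correlation of two equally shaped square images."""
    f1 = np.fft.fftshift(np.fft.fft2(img1))
    f2 = np.fft.fftshift(np.fft.fft2(img2))
    n = img1.shape[0]
    ky, kx = np.indices(img1.shape)
    r = np.rint(np.hypot(ky - n // 2, kx - n // 2)).astype(int)
    nr = n // 2
    num = np.bincount(r.ravel(), weights=np.real(f1 * np.conj(f2)).ravel(), minlength=nr)
    d1 = np.bincount(r.ravel(), weights=np.abs(f1).ravel() ** 2, minlength=nr)
    d2 = np.bincount(r.ravel(), weights=np.abs(f2).ravel() ** 2, minlength=nr)
    num, d1, d2 = num[:nr], d1[:nr], d2[:nr]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / np.sqrt(d1 * d2)
    corr = np.nan_to_num(corr, nan=0.0)
    freqs = np.arange(nr) / (n * pixel_nm)
    return freqs, corr


def _threshold_crossing(freqs, corr, threshold):
    """First crossing below threshold, linearly interpolated; nan if none."""
    for i in range(1, len(corr)):
        if corr[i] < threshold:
            f0, f1 = freqs[i - 1], freqs[i]
            c0, c1 = corr[i - 1], corr[i]
            if c0 <= threshold:  # starts below: report this ring
                return f1 if f1 > 0 else np.nan
            fc = f0 + (c0 - threshold) / (c0 - c1) * (f1 - f0)
            return fc
    return np.nan


def frc_from_images(
    half1: SRImage | np.ndarray,
    half2: SRImage | np.ndarray,
    pixel_nm: float | None = None,
    smooth_rings: int = 3,
) -> FRCResult:
    """FRC between two pre-rendered half-images (padded square to match)."""
    if isinstance(half1, SRImage):
        pixel_nm = half1.pixel_nm
        img1, img2 = half1.pixels, half2.pixels
    else:
        img1, img2 = np.asarray(half1, float), np.asarray(half2, float)
    if pixel_nm is None or pixel_nm <= 0:
        raise ValueError("pixel size required")
    n = max(max(img1.shape), max(img2.shape))
    n += n % 2  # even square grid

    def pad(img):
        out = np.zeros((n, n))
        out[: img.shape[0], : img.shape[1]] = img
        return out

    freqs, corr = _ring_correlation(pad(img1), pad(img2), pixel_nm)
    if smooth_rings > 1:
        kernel = np.ones(smooth_rings)
        norm = np.convolve(np.ones_like(corr), kernel, mode="same")
        smoothed = np.convolve(corr, kernel, mode="same") / norm
        smoothed[0] = corr[0]  # keep the DC ring untouched
    else:
        smoothed = corr
    fc = _threshold_crossing(freqs, smoothed, FRC_THRESHOLD)
    resolved = np.isfinite(fc) and fc > 0
    return FRCResult(
        frequencies=freqs,
        correlation=smoothed,
        resolution_nm=1.0 / fc if resolved else float("nan"),
        resolved=bool(resolved),
    )


def frc(
    table: pd.DataFrame,
    pixel_nm: float = 5.0,
    seed: int = 0,
    field_size: tuple[float, float] | None = None,
) -> FRCResult:
    """FRC resolution of a localization data set.

    Localizations are split at random (seeded, bit-stable) into two half
    sets, each rendered as a histogram image on a common square grid; the
    ring correlation is smoothed with a 3-ring moving average before the
    1/7 threshold is applied.  A curve that never crosses the threshold
    within Nyquist yields ``resolved=False`` (unresolved at this pixel
    size), not an exception.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 localizations to split")
    rng = _rng(seed, "frc_split")
    perm = rng.permutation(len(table))
    half = len(table) // 2
    t1 = table.iloc[perm[:half]]
    t2 = table.iloc[perm[half:]]
    if field_size is None:
        w = float(table["x_nm"].max()) + pixel_nm
        h = float(table["y_nm"].max()) + pixel_nm
        field_size = (max(w, h), max(w, h))
    img1 = render_sr(t1, pixel_nm, "histogram", field_size=field_size)
    img2 = render_sr(t2, pixel_nm, "histogram", field_size=field_size)
    return frc_from_images(img1, img2, pixel_nm)


# ---------------------------------------------------------------------------
# feature-of-interest effective PSF


def _gauss_offset(t, amp, mu, sigma, offset):
    return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2) + offset


def _resample_backbone(points: np.ndarray, step_nm: float):
    """Equally spaced positions and unit normals along a polyline."""
    seg = np.diff(points, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    keep = seg_len > 0
    seg, seg_len = seg[keep], seg_len[keep]
    pts = np.concatenate([points[:1], points[1:][keep]])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.arange(0.0, cum[-1], step_nm)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    t = (s - cum[idx]) / seg_len[idx]
    pos = pts[idx] + t[:, None] * seg[idx]
    tang = seg[idx] / seg_len[idx][:, None]
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    return pos, normal


def foi(
    source: SRImage | pd.DataFrame,
    backbones: list,
    step_nm: float = 10.0,
    profile_halfwidth_nm: float | None = None,
    fibre_width_nm: float = 11.0,
    fluorophore_nm: float = 1.0,
    bin_nm: float = 4.0,
    min_fits: int = 10,
    render_pixel_nm: float = 2.0,
    expected_psf_fwhm_nm: float = 40.0,
) -> FOIResult:
    """Effective-PSF width from fibre cross-sections.

    At positions every ``step_nm`` along each backbone, the image intensity
    is sampled along the local normal (bilinear interpolation) and fitted
    with a 1-D Gaussian plus constant offset.  The FWHMs are histogrammed in
    ``bin_nm`` bins; the modal bin centre minus the fibre width minus the
    fluorophore size is the effective PSF.  A localization table input is
    first rendered in gaussian mode at ``render_pixel_nm`` pixels.

    ``profile_halfwidth_nm`` defaults to 5x the expected PSF FWHM.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    if not backbones:
        raise ValueError("at least one backbone polyline required")
    if profile_halfwidth_nm is None:
        profile_halfwidth_nm = 5.0 * expected_psf_fwhm_nm
    if isinstance(source, pd.DataFrame):
        image = render_sr(source, render_pixel_nm, "gaussian")
    else:
        image = source

    sample_step = max(image.pixel_nm / 2.0, 1.0)
    t = np.arange(-profile_halfwidth_nm, profile_halfwidth_nm + sample_step, sample_step)
    fwhms = []
    failures: dict[str, int] = {}

    def _fail(reason):
        failures[reason] = failures.get(reason, 0) + 1

    for bb in backbones:
        points = np.asarray(bb.points if isinstance(bb, Fibre) else bb, dtype=float)
        pos, normal = _resample_backbone(points, step_nm)
        for p, nvec in zip(pos, normal):
            prof = image.sample(p[0] + t * nvec[0], p[1] + t * nvec[1])
            lo, hi = prof.min(), prof.max()
            if hi - lo <= 0:
                _fail("flat profile")
                continue
            w = np.clip(prof - lo, 0, None)
            mu0 = float(np.sum(t * w) / np.sum(w))
            var0 = float(np.sum((t - mu0) ** 2 * w) / np.sum(w))
            sigma0 = np.sqrt(max(var0, sample_step**2)) / 1.5
            try:
                popt, _ = optimize.curve_fit(
                    _gauss_offset,
                    t,
                    prof,
                    p0=[hi - lo, mu0, sigma0, lo],
                    maxfev=2000,
                )
            except RuntimeError:
                _fail("fit divergence")
                continue
            amp, mu, sigma, _off = popt
            sigma = abs(sigma)
            if amp <= 0:
                _fail("non-positive amplitude")
                continue
            if abs(mu) > profile_halfwidth_nm / 2:
                _fail("peak off backbone")
                continue
            if not (sample_step / 2 < sigma < profile_halfwidth_nm):
                _fail("width out of range")
                continue
            fwhms.append(GAUSS_FWHM * sigma)

    if len(fwhms) < min_fits:
        raise RuntimeError(
            f"only {len(fwhms)} successful profile fits (< {min_fits}); "
            f"failures: {failures}"
        )
    fwhms = np.asarray(fwhms)
    edges = np.arange(0.0, fwhms.max() + 2 * bin_nm, bin_nm)
    hist, edges = np.histogram(fwhms, bins=edges)
    modal = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    return FOIResult(
        fwhm_values_nm=fwhms,
        bin_edges_nm=edges,
        histogram=hist,
        modal_fwhm_nm=float(modal),
        effective_psf_nm=float(modal - fibre_width_nm - fluorophore_nm),
        fibre_width_nm=fibre_width_nm,
        fluorophore_nm=fluorophore_nm,
        n_failed_fits=sum(failures.values()),
        failure_reasons=failures,
    )


# ---------------------------------------------------------------------------
# contrast


def contrast(
    source: SRImage | pd.DataFrame,
    feature_mask: RegionMask,
    background_mask: RegionMask,
) -> ContrastResult:
    """Contrast C = (I - I_b) / I_b between a feature and its background.

    On an image, I and I_b are mean pixel intensities over the masks; on a
    localization table they are photon densities.  The two masks must be
    disjoint.
    """
    if isinstance(source, pd.DataFrame):
        i_f = photon_density(source, feature_mask)
        i_b = photon_density(source, background_mask)
    else:
        ny, nx = source.pixels.shape
        ox, oy = source.origin_nm
        xs = ox + (np.arange(nx) + 0.5) * source.pixel_nm
        ys = oy + (np.arange(ny) + 0.5) * source.pixel_nm
        xx, yy = np.meshgrid(xs, ys)
        in_f = feature_mask.contains(xx.ravel(), yy.ravel())
        in_b = background_mask.contains(xx.ravel(), yy.ravel())
        if (in_f & in_b).any():
            raise ValueError("feature and background masks overlap")
        if not in_f.any() or not in_b.any():
            raise ValueError("mask covers no pixels at this resolution")
        flat = source.pixels.ravel()
        i_f = float(flat[in_f].mean())
        i_b = float(flat[in_b].mean())
    return ContrastResult(i_feature=i_f, i_background=i_b)


def improvement_factor(with_go: float, without_go: float, kind: str) -> float:
    """Improvement of a metric due to the GO coating.

    * ``contrast_ratio``      C_with / C_without (composes multiplicatively)
    * ``resolution_percent``  100 (res_without - res_with) / res_with
    * ``psf_ratio``           psf_without / psf_with
    """
    if kind == "contrast_ratio":
        if without_go == 0:
            raise ZeroDivisionError("contrast without GO is zero")
        return with_go / without_go
    if kind == "resolution_percent":
        if with_go == 0:
            raise ZeroDivisionError("resolution with GO is zero")
        return 100.0 * (without_go - with_go) / with_go
    if kind == "psf_ratio":
        if with_go == 0:
            raise ZeroDivisionError("effective PSF with GO is zero")
        return without_go / with_go
    raise ValueError(f"unknown improvement kind {kind!r}")
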