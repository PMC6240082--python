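"""Photophysics: RET quenching, stochastic blinking and localization.

The core physics is the resonance energy-transfer efficiency of a point
dipole a distance ``z`` above a graphene-like sheet,

    epsilon(z) = 1 - [1 + A (lambda / z)^4]^(-1),

with a single dimensionless coupling/orientation coefficient ``A`` and
emission wavelength ``lambda``.  Quenching is applied as an attenuation of
the emitted photon rate by (1 - epsilon); blinking is a memoryless per-frame
Bernoulli process; localization precision scales as PSF width / sqrt(N).

Two routes from placements to a localization table are provided and agree
statistically:

* :func:`simulate_acquisition` — direct: photon counts are Poisson draws and
  localization error is Gaussian with the predicted precision;
* :func:`render_frames` + :func:`localize_frames` — end-to-end: camera
  frames are rendered (integrated pixel Gaussians + Poisson noise) and
  localizations recovered by local-maximum detection and least-squares
  2-D Gaussian fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import erf

from .scene import FluorophorePlacement, placements_to_arrays, _rng

__all__ = [
    "QuenchModel",
    "AcquisitionParams",
    "quench_efficiency",
    "invert_quench",
    "simulate_emission_events",
    "simulate_acquisition",
    "render_frames",
    "localize_frames",
    "LOCALIZATION_COLUMNS",
]

#: canonical localization-table columns (nm / photon units)
LOCALIZATION_COLUMNS = ["frame", "x_nm", "y_nm", "sigma_nm", "photons", "uncertainty_nm"]

#: coupling coefficient fitted to the monolayer-GO quenching data
DEFAULT_A = 2.6e-8


@dataclass(frozen=True)
class QuenchModel:
    """Quenching law parameters: coupling coefficient ``a`` (dimensionless)
    and emission wavelength in nm."""

    a: float = DEFAULT_A
    wavelength_nm: float = 570.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("coupling coefficient A must be >= 0")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera/acquisition parameters for a blinking movie."""

    n_frames: int = 1000
    frame_rate_hz: float = 100.0  # informational only
    p_on: float = 0.005
    psf_sigma_nm: float = 150.0
    camera_pixel_nm: float = 100.0
    detection_threshold_photons: float = 50.0
    background_photons_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0 < self.p_on <= 1:
            raise ValueError("p_on must be in (0, 1]")
        if self.psf_sigma_nm <= 0 or self.camera_pixel_nm <= 0:
            raise ValueError("psf sigma and camera pixel must be positive")
        if self.detection_threshold_photons < 0 or self.background_photons_per_pixel < 0:
            raise ValueError("threshold and background must be >= 0")


def quench_efficiency(z_gap, model: QuenchModel):
    """RET quenching efficiency at gap distance ``z_gap`` (nm).

    Strictly decreasing in z; -> 0 as z -> infinity; -> 1 as z -> 0+ for
    A > 0.  Accepts scalars or arrays.
    """
    z = np.asarray(z_gap, dtype=float)
    if np.any(z <= 0):
        raise ValueError("z_gap must be positive")
    eps = 1.0 - 1.0 / (1.0 + model.a * (model.wavelength_nm / z) ** 4)
    return float(eps) if np.isscalar(z_gap) else eps


def invert_quench(efficiency, model: QuenchModel):
    """Gap distance from a quenching efficiency: z = lambda [A (1-e)/e]^(1/4).

    Closed-form inverse of the quenching law, the basis of RET height
    measurement.  Requires 0 < efficiency < 1 and A > 0.
    """
    e = np.asarray(efficiency, dtype=float)
    if np.any(e <= 0) or np.any(e >= 1):
        raise ValueError("efficiency must lie strictly in (0, 1)")
    if model.a == 0:
        raise ValueError("cannot invert with A = 0 (no coupling)")
    z = model.wavelength_nm * (model.a * (1.0 - e) / e) ** 0.25
    return float(z) if np.isscalar(efficiency) else z


# ---------------------------------------------------------------------------
# blinking simulation


def _effective_quench(arrays, model, go_membership):
    try:
        over_go = np.asarray(go_membership(arrays["x"], arrays["y"]), dtype=bool)
    except Exception as exc:  # contract: membership must work for every placement
        raise ValueError(f"GO membership function failed: {exc}") from exc
    eps = np.zeros(len(arrays["x"]))
    if over_go.any():
        eps[over_go] = quench_efficiency(arrays["z_gap"][over_go], model)
    return eps


def simulate_emission_events(
    placements: list[FluorophorePlacement],
    model: QuenchModel,
    params: AcquisitionParams,
    go_membership,
    seed: int = 0,
) -> pd.DataFrame:
    """Ground-truth emission events (frame, true position, emitted photons).

    Each fluorophore is on in each frame independently with probability
    ``p_on``; photons per on-event are Poisson with mean
    photon_budget_mean x (1 - epsilon_eff), where epsilon_eff is the
    quenching efficiency at the fluorophore's z_gap if it sits over a GO
    region and 0 otherwise.  Events below the detection threshold are kept
    here (they are emission, not detection); thresholding happens at the
    localization stage.
    """
    if not placements:
        raise ValueError("placements must be non-empty")
    arrays = placements_to_arrays(placements)
    eps = _effective_quench(arrays, model, go_membership)
    mean_photons = arrays["photon_budget_mean"] * (1.0 - eps)

    rng = _rng(seed, "simulate_acquisition")
    n = len(placements)
    frames_out = []
    ids_out = []
    # chunked Bernoulli on-matrix keeps the exact per-frame process tractable
    chunk = max(1, int(5e6 // max(params.n_frames, 1)))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        on = rng.random((hi - lo, params.n_frames)) < params.p_on
        idx, frm = np.nonzero(on)
        frames_out.append(frm + 1)
        ids_out.append(idx + lo)
    frame = np.concatenate(frames_out) if frames_out else np.empty(0, int)
    tid = np.concatenate(ids_out) if ids_out else np.empty(0, int)
    photons = rng.poisson(mean_photons[tid])
    keep = photons > 0
    return pd.DataFrame(
        {
            "frame": frame[keep].astype(int),
            "x_nm": arrays["x"][tid[keep]],
            "y_nm": arrays["y"][tid[keep]],
            "photons": photons[keep].astype(float),
            "truth_id": tid[keep],
        }
    ).sort_values(["frame"], kind="stable").reset_index(drop=True)


def simulate_acquisition(
    placements: list[FluorophorePlacement],
    model: QuenchModel,
    params: AcquisitionParams,
    go_membership,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct-route localization table.

    Emission events are sampled by :func:`simulate_emission_events`; events
    with fewer photons than ``detection_threshold_photons`` are dropped; each
    detection's coordinates are the truth plus independent Gaussian noise of
    standard deviation psf_sigma_nm / sqrt(photons) per axis, which is also
    the reported ``uncertainty_nm``.
    """
    events = simulate_emission_events(placements, model, params, go_membership, seed)
    events = events[events["photons"] >= max(params.detection_threshold_photons, 1)]
    events = events.reset_index(drop=True)
    rng = _rng(seed, "localization_noise")
    unc = params.psf_sigma_nm / np.sqrt(events["photons"].to_numpy())
    x = events["x_nm"].to_numpy() + rng.normal(0, unc)
    y = events["y_nm"].to_numpy() + rng.normal(0, unc)
    return pd.DataFrame(
        {
            "frame": events["frame"],
            "x_nm": x,
            "y_nm": y,
            "sigma_nm": params.psf_sigma_nm,
            "photons": events["photons"],
            "uncertainty_nm": unc,
            "truth_id": events["truth_id"],
        }
    )


# ---------------------------------------------------------------------------
# camera-frame rendering and localization

MAX_RENDER_PIXELS = 512 * 512 * 2000  # guard against oversize frame stacks


def _integrated_gaussian_patch(x0, y0, photons, sigma_px, xlo, ylo, nx, ny):
    """Expected counts of an integrated 2-D Gaussian on a pixel patch."""
    xs = np.arange(xlo, xlo + nx)
    ys = np.arange(ylo, ylo + ny)
    sq2 = np.sqrt(2.0) * sigma_px
    fx = 0.5 * (erf((xs + 1 - x0) / sq2) - erf((xs - x0) / sq2))
    fy = 0.5 * (erf((ys + 1 - y0) / sq2) - erf((ys - y0) / sq2))
    return photons * np.outer(fy, fx)


def render_frames(
    events: pd.DataFrame,
    params: AcquisitionParams,
    field_size: tuple[float, float],
    seed: int = 0,
    poisson_noise: bool = True,
) -> np.ndarray:
    """Render emission events into a camera-frame stack (float photons).

    Each event renders as a 2-D Gaussian integrated over pixels (truncated at
    4 sigma) plus Poisson camera background, so the expected total count of a
    frame equals the emitted photons plus background.  Frames are indexed
    1..n_frames; pixels are ``camera_pixel_nm`` wide with half-open binning.
    """
    w, h = field_size
    px = params.camera_pixel_nm
    nx = int(np.ceil(w / px))
    ny = int(np.ceil(h / px))
    if nx * ny * params.n_frames > MAX_RENDER_PIXELS:
        raise ValueError(
            f"frame stack {params.n_frames}x{ny}x{nx} exceeds the render guard "
            f"({MAX_RENDER_PIXELS} pixels)"
        )
    stack = np.zeros((params.n_frames, ny, nx), dtype=float)
    sigma_px = params.psf_sigma_nm / px
    halfwin = int(np.ceil(4 * sigma_px))
    for frame, x_nm, y_nm, photons in zip(
        events["frame"].to_numpy(int),
        events["x_nm"].to_numpy(),
        events["y_nm"].to_numpy(),
        events["photons"].to_numpy(),
    ):
        x0, y0 = x_nm / px, y_nm / px
        xlo = max(int(np.floor(x0)) - halfwin, 0)
        ylo = max(int(np.floor(y0)) - halfwin, 0)
        xhi = min(int(np.floor(x0)) + halfwin + 1, nx)
        yhi = min(int(np.floor(y0)) + halfwin + 1, ny)
        if xhi <= xlo or yhi <= ylo:
            continue
        stack[frame - 1, ylo:yhi, xlo:xhi] += _integrated_gaussian_patch(
            x0, y0, photons, sigma_px, xlo, ylo, xhi - xlo, yhi - ylo
        )
    if poisson_noise:
        rng = _rng(seed, "camera_noise")
        stack = rng.poisson(stack + params.background_photons_per_pixel).astype(float)
    else:
        stack = stack + params.background_photons_per_pixel
    return stack


def _fit_spot(patch, x0_px, y0_px, sigma_px, background, mask=None):
    """Weighted least-squares integrated-Gaussian fit on a patch.

    Minimizes the Poisson deviance (via signed square-root deviance
    residuals, so Levenberg-Marquardt performs the maximum-likelihood fit
    appropriate for counting noise); an unweighted Gaussian-noise fit would
    inflate the position variance 30-50 % above the sqrt(N) limit.
    Returns (x, y, photons, sigma) in patch pixels, or None on divergence.
    """
    ny, nx = patch.shape
    data = patch.ravel()
    keep = np.ones(data.size, dtype=bool) if mask is None else mask.ravel()

    def model(p):
        x0, y0, logN, logs, b = p
        mu = (
            _integrated_gaussian_patch(x0, y0, np.exp(logN), np.exp(logs), 0, 0, nx, ny)
            + b
        )
        return np.maximum(mu.ravel(), 1e-9)

    amp0 = max(patch.max() - background, 1.0)
    n0 = amp0 * 2 * np.pi * sigma_px**2
    p0 = np.array([x0_px, y0_px, np.log(n0), np.log(sigma_px), max(background, 1e-3)])

    def resid(p):
        mu = model(p)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(data > 0, data * np.log(data / mu), 0.0)
        dev = 2.0 * (mu - data + term)
        return (np.sign(data - mu) * np.sqrt(np.maximum(dev, 0.0))) * keep

    try:
        sol = optimize.least_squares(resid, p0, method="lm", max_nfev=200)
    except Exception:
        return None
    if not sol.success and sol.status <= 0:
        return None
    x0, y0, logN, logs, _ = sol.x
    if not (0 <= x0 <= nx and 0 <= y0 <= ny):
        return None
    return x0, y0, float(np.exp(logN)), float(np.exp(logs))


def localize_frames(stack: np.ndarray, params: AcquisitionParams) -> pd.DataFrame:
    """Localize emitters in a rendered frame stack.

    Per frame: candidate pixels are local maxima (3x3) whose value exceeds
    the expected background plus half the peak amplitude a
    threshold-level emitter would produce; each candidate is fitted with an
    integrated 2-D Gaussian (free position, photon number, width and offset)
    on a +-4 sigma window.  Fits that diverge or land below the photon
    threshold are dropped.  Uncertainty is sigma / sqrt(N).
    """
    if stack.size == 0 or len(stack) == 0:
        return pd.DataFrame(columns=LOCALIZATION_COLUMNS)
    px = params.camera_pixel_nm
    sigma_px = params.psf_sigma_nm / px
    halfwin = max(int(np.ceil(3 * sigma_px)), 2)
    bg = params.background_photons_per_pixel
    # peak amplitude (counts in the central pixel) of a threshold-level emitter
    thresh_amp = max(params.detection_threshold_photons, 1.0) / (
        2 * np.pi * sigma_px**2
    )
    min_peak = bg + 0.5 * thresh_amp + 3.0 * np.sqrt(bg)
    rows = []
    n_failed = 0
    for iframe, frame in enumerate(stack, start=1):
        smoothed = ndimage.gaussian_filter(frame.astype(float), sigma=max(sigma_px / 2, 0.8))
        maxima = (
            ndimage.maximum_filter(smoothed, size=3) == smoothed
        ) & (smoothed > min_peak)
        ys, xs = np.nonzero(maxima)
        # row-major scan order already; drop maxima too close to a brighter one
        order = np.argsort(-smoothed[ys, xs], kind="stable")
        kept: list[tuple[int, int]] = []
        for i in order:
            if all((ys[i] - y) ** 2 + (xs[i] - x) ** 2 > (2 * sigma_px) ** 2 for y, x in kept):
                kept.append((ys[i], xs[i]))
        for cy, cx in kept:
            ylo, yhi = max(cy - halfwin, 0), min(cy + halfwin + 1, frame.shape[0])
            xlo, xhi = max(cx - halfwin, 0), min(cx + halfwin + 1, frame.shape[1])
            patch = frame[ylo:yhi, xlo:xhi].astype(float)
            # exclude pixels closer to another detected emitter than to this
            # one, so neighbouring spots do not pull the fit
            mask = None
            others = [(oy, ox) for oy, ox in kept if (oy, ox) != (cy, cx)]
            if others:
                yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
                d_self = (yy - cy) ** 2 + (xx - cx) ** 2
                mask = np.ones_like(patch, dtype=bool)
                for oy, ox in others:
                    mask &= d_self <= (yy - oy) ** 2 + (xx - ox) ** 2
            fit = _fit_spot(patch, cx - xlo + 0.5, cy - ylo + 0.5, sigma_px, bg, mask)
            if fit is None:
                n_failed += 1
                continue
            fx, fy, photons, fsig = fit
            if photons < max(params.detection_threshold_photons, 1.0):
                continue
            rows.append(
                {
                    "frame": iframe,
                    "x_nm": (xlo + fx) * px,
                    "y_nm": (ylo + fy) * px,
                    "sigma_nm": fsig * px,
                    "photons": photons,
                    "uncertainty_nm": fsig * px / np.sqrt(photons),
                }
            )
    table = pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)
    table.attrs["n_failed_fits"] = n_failed
    return table
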