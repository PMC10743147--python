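"""Retrieval of the inter-nanoparticle vector from a scattering image.

The mock experimental image is fit with the idealized two-sphere model
``S_theo(d) = P * Omega * r_e^2 * Phi * 2 f_NP^2 (1 + cos(q . d))`` by
minimizing the per-pixel error-weighted sum of squared residuals

    chi^2(d) = sum_pix (S_exp - S_theo(d))^2 / sigma_pix^2,
    sigma_pix^2 = max(S_exp, pixel_error_floor),

a Poisson-style measured-variance weighting.  The interference pattern
determines ``d`` only up to a global sign (``cos`` is even), so results are
canonicalized to a fixed hemisphere before use.

Initialization is a chirp-matched fringe search: after subtracting the
smooth single-particle envelope, the image oscillates as
``env * cos(q . d)``, a transverse fringe chirped by the Ewald-curvature
phase ``q_z(q) d_z``.  Demodulating by ``exp(-i q_z z)`` on a fine z grid
and Fourier transforming each slice refocuses the fringe into a sharp
transverse peak exactly when z matches; the best (x, y, z) combinations
are then refined with a bounded least-squares optimizer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .optics import DetectorModel
from .scattering import ScatterImage, aunp_f, intensity_prefactor, two_aunp_image

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "RetrievalResult",
    "canonicalize",
    "chi2",
    "initialize",
    "fit_distance",
]


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the distance-retrieval optimizer.

    Attributes
    ----------
    r_max:
        Search bound on each component of ``d`` (A).
    r_min:
        Known lower bound on |d| (A), used to mask the fringe-candidate
        search; with AuNP labels placed under the 2.4R separation rule
        this is 2.4R, and it excludes the short-separation region of the
        spectrum where intramolecular pair correlations dominate.
    z_grid_points:
        Minimum number of z values scanned between ``-r_max`` and
        ``r_max``; the actual scan is finer when the Ewald-curvature
        bandwidth pi/q_z,max demands it.
    refine_tolerance:
        Relative ftol/xtol passed to the local least-squares refinement.
    multistart:
        How many ranked initialization candidates are refined.
    pixel_error_floor:
        Lower bound on the per-pixel variance (counts); keeps empty pixels
        from dominating the weighted residual.
    """

    r_max: float = 120.0
    r_min: float = 0.0
    z_grid_points: int = 15
    refine_tolerance: float = 1e-12
    multistart: int = 6
    pixel_error_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.z_grid_points < 3:
            raise ValueError("z_grid_points must be >= 3")
        if self.refine_tolerance <= 0:
            raise ValueError("refine_tolerance must be positive")


@dataclass
class RetrievalResult:
    """Fitted inter-particle vector, canonicalized, with fit diagnostics."""

    d_fit: np.ndarray
    chi2: float
    n_evaluations: int
    converged: bool
    r_fit: float = field(init=False)

    def __post_init__(self) -> None:
        self.d_fit = np.asarray(self.d_fit, dtype=float)
        self.r_fit = float(np.linalg.norm(self.d_fit)) if self.converged else math.nan


def canonicalize(d: np.ndarray) -> np.ndarray:
    """Resolve the d <-> -d degeneracy of the two-particle pattern.

    Flips the overall sign so that z > 0; on the z = 0 plane requires
    x > 0; on the z = x = 0 axis requires y >= 0.
    """
    d = np.asarray(d, dtype=float)
    z, x, y = d[2], d[0], d[1]
    if abs(z) >= 1e-9:
        return d if z > 0 else -d
    if abs(x) >= 1e-9:
        return d if x > 0 else -d
    return d if y >= 0 else -d


def _sigma2(counts: np.ndarray, floor: float) -> np.ndarray:
    return np.maximum(counts, floor)


class _TwoSphereModel:
    """Cached two-sphere forward model on one detector at one radius.

    Precomputes the per-pixel envelope ``P * Omega * r_e^2 * Phi * 2 f_NP^2``
    so each evaluation costs one 3-vector phase projection and a cosine;
    also supplies the analytic Jacobian of the counts with respect to d.
    """

    def __init__(self, radius: float, det_model: DetectorModel) -> None:
        self.q = det_model.q_flat  # (m, 3)
        env = (
            intensity_prefactor(det_model)
            * 2.0
            * aunp_f(det_model.q_mag, radius) ** 2
        )
        self.envelope = env.ravel()
        self.shape = det_model.shape

    def counts(self, d: np.ndarray) -> np.ndarray:
        phase = self.q @ d
        return self.envelope * (1.0 + np.cos(phase))

    def counts_and_jac(self, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        phase = self.q @ d
        counts = self.envelope * (1.0 + np.cos(phase))
        dcounts = -(self.envelope * np.sin(phase))[:, None] * self.q
        return counts, dcounts


def chi2(
    image: ScatterImage,
    d: np.ndarray,
    radius: float,
    det_model: DetectorModel,
    cfg: FitConfig = FitConfig(),
) -> float:
    """Error-weighted squared misfit of the two-sphere model at vector d."""
    if image.shape != det_model.shape:
        raise ValueError(
            f"image shape {image.shape} does not match detector {det_model.shape}"
        )
    model = _TwoSphereModel(radius, det_model)
    resid2 = (image.counts.ravel() - model.counts(np.asarray(d, dtype=float))) ** 2
    return float((resid2 / _sigma2(image.counts.ravel(), cfg.pixel_error_floor)).sum())


def _z_scan_grid(det_model: DetectorModel, cfg: FitConfig) -> np.ndarray:
    """z values sampled at least twice per Ewald-curvature basin.

    For near-axial vectors the rings oscillate as ``cos(q_z z)``, so the
    chi2 basin along z is only ``~pi / q_z,max`` wide; a coarser scan
    silently converges to false minima several Angstrom off.
    """
    qz_max = float(np.abs(det_model.q_map[..., 2]).max())
    z_step = max(0.5 * math.pi / max(qz_max, 1e-9), 0.25)
    z_step = min(z_step, 2.0 * cfg.r_max / (cfg.z_grid_points - 1))
    return np.arange(-cfg.r_max, cfg.r_max + 0.5 * z_step, z_step)


def _matched_filter_candidates(
    image: ScatterImage,
    radius: float,
    det_model: DetectorModel,
    cfg: FitConfig,
    n_candidates: int = 8,
) -> tuple[list[tuple[float, float, float, float]], float, float]:
    """(score, x, y, z) candidates from a chirp-matched fringe search.

    The envelope-subtracted fringe ``S_exp - env ~ env * cos(q . d)`` is,
    for nonzero z, a *chirped* transverse oscillation: the Ewald-curvature
    phase ``q_z(q) z`` is quadratic in the pixel radius and smears the
    plain 2D Fourier peak (badly enough that molecular speckle can win).
    Demodulating with ``exp(-i q_z z)`` on a z grid and Fourier
    transforming each slice concentrates the fringe back into a sharp
    peak exactly when z matches; the per-slice peak positions (parabolic
    sub-bin interpolation, mapped through the small-angle dispersion
    ``q_xy ~ k p / l`` per pixel) then rank (x, y, z) candidates.

    Returns (candidates sorted by descending score, top peak-to-mean
    power ratio, transverse bin width in A).
    """
    n = det_model.shape[0]
    envelope = intensity_prefactor(det_model) * 2.0 * aunp_f(det_model.q_mag, radius) ** 2
    # the residual keeps the envelope as an implicit SNR weight: the
    # fringe term is envelope * cos(q . d) while the shot noise per pixel
    # scales as sqrt(envelope), so dividing the envelope out would let
    # noise-dominated high-q pixels swamp the spectrum
    fringe = image.counts - envelope
    qz = det_model.q_map[..., 2]

    k = det_model.beam.k_A_inv
    p = det_model.det.pixel_size_A
    l = det_model.det.distance_A
    per_pixel = k * p / l
    bin_width = 2.0 * math.pi / (n * per_pixel)

    def signed_freq(idx: float) -> float:
        f = idx / n
        return f - 1.0 if f > 0.5 else f

    # transverse separation (A) encoded by each spectrum bin
    freqs = np.fft.fftfreq(n)
    xy_bins = 2.0 * math.pi * freqs / per_pixel
    rho2 = xy_bins[:, None] ** 2 + xy_bins[None, :] ** 2

    candidates: list[tuple[float, float, float, float]] = []
    top_ratio = 0.0
    for z in _z_scan_grid(det_model, cfg):
        # bins whose total separation violates the physical bounds on |d|
        # carry intramolecular pair correlations, not the label fringe
        sep2 = rho2 + z * z
        mask = (sep2 >= cfg.r_min**2) & (sep2 <= cfg.r_max**2)
        mask[0, 0] = False  # DC carries envelope mismatch, not fringe
        if not mask.any():
            continue
        spectrum = np.fft.fft2(fringe * np.exp(-1j * qz * z))
        power = np.abs(spectrum) ** 2
        mean_power = float(power.sum() / max(power.size - 1, 1))
        power = np.where(mask, power, 0.0)
        peak = np.unravel_index(int(np.argmax(power)), power.shape)
        if mean_power <= 0.0 or power[peak] <= 0.0:
            continue
        top_ratio = max(top_ratio, float(power[peak] / mean_power))

        def refine(axis_idx: int) -> float:
            before = list(peak)
            after = list(peak)
            before[axis_idx] = (peak[axis_idx] - 1) % n
            after[axis_idx] = (peak[axis_idx] + 1) % n
            pm, p0, pp = power[tuple(before)], power[tuple(peak)], power[tuple(after)]
            denom = pm - 2.0 * p0 + pp
            delta = 0.5 * (pm - pp) / denom if denom != 0 else 0.0
            return peak[axis_idx] + float(np.clip(delta, -0.5, 0.5))

        x = 2.0 * math.pi * signed_freq(refine(0)) / per_pixel
        y = 2.0 * math.pi * signed_freq(refine(1)) / per_pixel
        candidates.append((float(power[peak]), x, y, float(z)))

    candidates.sort(reverse=True)
    return candidates[:n_candidates], top_ratio, bin_width


def initialize(
    image: ScatterImage,
    radius: float,
    det_model: DetectorModel,
    cfg: FitConfig = FitConfig(),
    min_peak_ratio: float = 25.0,
) -> list[np.ndarray]:
    """Ranked starting vectors for the fit.

    Candidates come from the chirp-matched fringe search: for each z on a
    fine grid the whitened fringe is demodulated by the Ewald-curvature
    phase and Fourier transformed, and the per-slice peaks yield
    (x, y, z) combinations, polished by sub-bin transverse offsets and
    ranked by chi2.  Returns up to ``cfg.multistart`` candidates, or an
    empty list (with a warning) when no fringe peak rises above the noise
    floor.
    """
    # an image from this model has mean counts ~ the single-particle
    # envelope (the fringe term averages out); an image far dimmer than
    # that carries no usable fringe signal
    envelope_total = float(
        (intensity_prefactor(det_model) * 2.0 * aunp_f(det_model.q_mag, radius) ** 2).sum()
    )
    if float(image.counts.sum()) < 0.05 * envelope_total:
        logger.warning(
            "image total counts far below the two-sphere envelope; "
            "no fringe signal to initialize from"
        )
        return []

    mf_candidates, ratio, bin_width = _matched_filter_candidates(
        image, radius, det_model, cfg
    )
    if not mf_candidates or ratio < min_peak_ratio:
        logger.warning(
            "no fringe peak above noise floor (peak/mean power %.1f < %.1f)",
            ratio,
            min_peak_ratio,
        )
        return []

    model = _TwoSphereModel(radius, det_model)
    s_exp = image.counts.ravel()
    sigma2 = _sigma2(s_exp, cfg.pixel_error_floor)

    def score(d: np.ndarray) -> float:
        return float(((s_exp - model.counts(d)) ** 2 / sigma2).sum())

    # sub-bin transverse offsets around the strongest matched-filter
    # (x, y, z) combinations, ranked by chi2
    offsets = bin_width * np.array([-0.75, -0.375, 0.0, 0.375, 0.75])
    candidates = []
    for _, x0, y0, z in mf_candidates:
        if abs(x0) > cfg.r_max or abs(y0) > cfg.r_max:
            continue
        for dx in offsets:
            for dy in offsets:
                d = np.array([x0 + dx, y0 + dy, z])
                if np.all(np.abs(d) <= cfg.r_max):
                    candidates.append(d)
    if not candidates:
        return []
    scores = [score(d) for d in candidates]
    order = np.argsort(scores)
    return [candidates[i] for i in order[: cfg.multistart]]


def fit_distance(
    image: ScatterImage,
    radius: float,
    det_model: DetectorModel,
    cfg: FitConfig = FitConfig(),
) -> RetrievalResult:
    """Fit the two-sphere interference model and return the canonical vector.

    Each initialization candidate is refined with a bounded trust-region
    least-squares minimization of the error-weighted residuals; the lowest
    chi2 wins.  Fully deterministic for a given image and configuration.
    """
    if image.shape != det_model.shape:
        raise ValueError(
            f"image shape {image.shape} does not match detector {det_model.shape}"
        )
    starts = initialize(image, radius, det_model, cfg)
    if not starts:
        return RetrievalResult(
            d_fit=np.full(3, np.nan), chi2=math.inf, n_evaluations=0, converged=False
        )

    s_exp = image.counts.ravel()
    sigma = np.sqrt(_sigma2(s_exp, cfg.pixel_error_floor))
    model = _TwoSphereModel(radius, det_model)
    n_eval = 0

    def residuals(d: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        return (model.counts(d) - s_exp) / sigma

    def jacobian(d: np.ndarray) -> np.ndarray:
        _, dcounts = model.counts_and_jac(d)
        return dcounts / sigma[:, None]

    best_d, best_chi2, any_success = None, math.inf, False
    bounds = (-cfg.r_max * np.ones(3), cfg.r_max * np.ones(3))
    for start in starts:
        res = optimize.least_squares(
            residuals,
            np.clip(start, bounds[0] + 1e-9, bounds[1] - 1e-9),
            jac=jacobian,
            bounds=bounds,
            method="trf",
            ftol=cfg.refine_tolerance,
            xtol=cfg.refine_tolerance,
            gtol=cfg.refine_tolerance,
        )
        c = 2.0 * res.cost  # least_squares cost = 0.5 * sum(residuals^2)
        if c < best_chi2:
            best_chi2, best_d = c, res.x
        any_success = any_success or res.status > 0

    return RetrievalResult(
        d_fit=canonicalize(best_d),
        chi2=best_chi2,
        n_evaluations=n_eval,
        converged=any_success,
    )
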