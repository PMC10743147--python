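"""Ensemble runs, accuracy distributions, and parameter sweeps.

For every (conformer, label pair) sample this module simulates the noisy
scattering image, retrieves the inter-particle vector, and records the
discrepancies ``dr = r_fit - r_AuNP`` and the canonicalized component
errors ``dx, dy, dz``.  Samples from all label pairs are pooled before the
Gaussian fit of each discrepancy distribution (per-pair counts alone are
too small for stable widths); the Gaussian-fit standard deviation is the
headline accuracy figure, with plain sample statistics reported alongside.

Parameter sweeps vary one experimental setting at a time — AuNP radius,
X-ray energy, detector pixel count, photon count, focal size, or detector
distance — holding the rest at the baseline, with common random numbers
across grid points so that trend comparisons are not swamped by resampling
noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .optics import BeamParams, DetectorModel, DetectorParams, build_detector
from .retrieval import FitConfig, canonicalize, fit_distance
from .scattering import (
    NoiseParams,
    ScatterImage,
    add_noise,
    atomic_f,
    simulate_image,
    structure_amplitude,
)
from .structures import (
    Ensemble,
    LabelPair,
    LabeledStructure,
    NoFeasibleLabelingError,
    rebuild_label_pairs,
    select_label_pairs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EmptyStatsError",
    "DeltaStats",
    "SweepResult",
    "RunSettings",
    "SWEEP_PARAMETERS",
    "component_delta",
    "gaussian_fit",
    "probability_histogram",
    "run_ensemble",
    "run_sweep",
]

DELTA_KEYS = ("dr", "dx", "dy", "dz")

#: Supported sweep parameter names and the RunSettings field they map to.
SWEEP_PARAMETERS = {
    "R": "radius",
    "energy": "energy_keV",
    "n_pixels": "n_pixels",
    "photons": "photons",
    "focal_size": "focal_size_nm",
    "distance": "distance_mm",
}


class EmptyStatsError(RuntimeError):
    """Raised when every fit in an ensemble run failed."""


@dataclass(frozen=True)
class RunSettings:
    """One experimental configuration (baseline defaults).

    The defaults are the practical conditions of the reference study:
    R = 9 A AuNPs, 12 keV X-rays, 1e14 photons per pulse focused to
    100 nm, a 250 x 250 detector of 234 um pitch 40 mm downstream.
    Sweeps may scale ``n_pixels`` down (e.g. 128 or 96): the pixel pitch
    is fixed, so the single-pixel dq — the quantity that governs
    retrieval accuracy — is unchanged.
    """

    radius: float = 9.0  # AuNP radius R, A
    energy_keV: float = 12.0
    photons: float = 1e14
    focal_size_nm: float = 100.0
    n_pixels: int = 250
    pixel_size_um: float = 234.0
    distance_mm: float = 40.0
    poisson: bool = True
    uniform_max: float = 1.0  # counts/pixel
    include_molecule: bool = True
    fit: FitConfig = field(default_factory=FitConfig)
    clash_margin: float = 0.5
    min_spread: float = 10.0
    n_pairs_min: int = 2
    n_pairs_max: int = 6

    def beam(self) -> BeamParams:
        return BeamParams(self.energy_keV, self.photons, self.focal_size_nm)

    def detector(self) -> DetectorParams:
        return DetectorParams(self.n_pixels, self.pixel_size_um, self.distance_mm)

    def detector_model(self) -> DetectorModel:
        return build_detector(self.beam(), self.detector())


@dataclass
class DeltaStats:
    """Pooled discrepancy statistics for one configuration.

    ``gauss_center``/``gauss_std`` come from least-squares Gaussian fits to
    the histogrammed distributions; ``sample_mean``/``sample_std`` are the
    plain moments of the same samples.
    """

    deltas: pd.DataFrame  # one row per converged sample
    gauss_center: dict[str, float]
    gauss_std: dict[str, float]
    sample_mean: dict[str, float]
    sample_std: dict[str, float]
    n_samples: int
    n_failed: int = 0


@dataclass
class SweepResult:
    """Per-grid-point statistics for a one-parameter sweep."""

    parameter: str
    values: np.ndarray
    stats: list[DeltaStats | None]  # None where labeling was infeasible
    table: pd.DataFrame

    def sigma_dr(self) -> np.ndarray:
        return np.array(
            [s.gauss_std["dr"] if s is not None else np.nan for s in self.stats]
        )


def component_delta(
    d_fit: np.ndarray, d_true: np.ndarray
) -> tuple[float, float, float, float]:
    """Componentwise errors and the scalar distance error.

    Both vectors must already be canonicalized.  Note ``dr`` is the
    difference of lengths, ``|d_fit| - |d_true|``, not ``|d_fit - d_true|``.
    """
    d_fit = np.asarray(d_fit, dtype=float)
    d_true = np.asarray(d_true, dtype=float)
    diff = d_fit - d_true
    dr = float(np.linalg.norm(d_fit) - np.linalg.norm(d_true))
    return float(diff[0]), float(diff[1]), float(diff[2]), dr


def _gauss(x: np.ndarray, amp: float, center: float, std: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - center) / std) ** 2)


def gaussian_fit(samples: np.ndarray) -> tuple[float, float]:
    """Gaussian center and width of a sample distribution.

    Histograms the samples with Freedman-Diaconis bins and least-squares
    fits ``amp * exp(-(x - c)^2 / 2 s^2)``; falls back to the sample
    moments if the fit does not converge.  Degenerate all-equal samples
    return ``(value, 0)`` with a warning.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 10:
        raise ValueError(f"need >= 10 samples for a Gaussian fit, got {samples.size}")
    if np.ptp(samples) == 0.0:
        warnings.warn("degenerate all-equal samples; returning zero width")
        return float(samples[0]), 0.0

    edges = np.histogram_bin_edges(samples, bins="fd")
    if edges.size < 6:  # FD can collapse on heavy-tailed small samples
        edges = np.histogram_bin_edges(samples, bins=10)
    hist, edges = np.histogram(samples, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    mean, std = float(samples.mean()), float(samples.std())
    try:
        popt, _ = curve_fit(
            _gauss, centers, hist, p0=[float(hist.max()), mean, std], maxfev=20000
        )
        return float(popt[1]), abs(float(popt[2]))
    except RuntimeError:
        warnings.warn("Gaussian fit did not converge; using sample moments")
        return mean, std


def probability_histogram(
    samples: np.ndarray, bins: str | int = "fd"
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram normalized so that it integrates to 1 (density)."""
    hist, edges = np.histogram(np.asarray(samples, dtype=float), bins=bins, density=True)
    return hist, edges


def _delta_stats_from_table(table: pd.DataFrame, n_failed: int) -> DeltaStats:
    ok = table[table["converged"]]
    if ok.empty:
        raise EmptyStatsError("all fits failed; no statistics available")
    gauss_center, gauss_std, sample_mean, sample_std = {}, {}, {}, {}
    for key in DELTA_KEYS:
        vals = ok[key].to_numpy()
        sample_mean[key] = float(vals.mean())
        sample_std[key] = float(vals.std())
        if vals.size >= 10:
            gauss_center[key], gauss_std[key] = gaussian_fit(vals)
        else:
            gauss_center[key], gauss_std[key] = sample_mean[key], sample_std[key]
    return DeltaStats(
        deltas=ok.reset_index(drop=True),
        gauss_center=gauss_center,
        gauss_std=gauss_std,
        sample_mean=sample_mean,
        sample_std=sample_std,
        n_samples=len(ok),
        n_failed=n_failed,
    )


def _substituted_amplitude(
    conformer, pair: LabelPair, det_model: DetectorModel, full_amplitude: np.ndarray
) -> np.ndarray:
    """Molecular amplitude with the two labeled oxygens removed.

    Subtracts the two single-atom contributions from the precomputed
    full-molecule amplitude — exact, and far cheaper than resumming all
    atoms for every label pair sharing one conformer.
    """
    ia = conformer.atom_index(*pair.site_a)
    ib = conformer.atom_index(*pair.site_b)
    qf = det_model.q_flat
    qmag = det_model.q_mag.ravel()
    corr = np.zeros(qf.shape[0], dtype=complex)
    for idx in (ia, ib):
        f = atomic_f(str(conformer.elements[idx]), qmag)
        corr += f * np.exp(1j * (qf @ conformer.positions[idx]))
    return full_amplitude - corr.reshape(det_model.shape)


def run_ensemble(
    ensemble: Ensemble,
    label_pairs: list[LabelPair],
    settings: RunSettings | None = None,
    seed: int = 0,
    det_model: DetectorModel | None = None,
    amplitude_cache: dict | None = None,
) -> tuple[DeltaStats, pd.DataFrame]:
    """Simulate, noise, and fit every (conformer, label pair) sample.

    Returns the pooled :class:`DeltaStats` and the full per-sample table
    (one row per sample, including failed fits).  Per-sample noise seeds
    derive deterministically from ``seed``.  ``amplitude_cache`` (keyed by
    conformer and geometry) lets sweeps reuse the expensive molecular
    amplitude where beam/detector geometry is unchanged.
    """
    if len(ensemble) < 1 or not label_pairs:
        raise ValueError("need at least one conformer and one label pair")
    settings = settings or RunSettings()
    if det_model is None:
        det_model = settings.detector_model()

    n_samples = len(ensemble) * len(label_pairs)
    noise_seeds = np.random.SeedSequence(seed).generate_state(n_samples) % (2**31)

    geom_key = (
        round(settings.energy_keV, 9),
        settings.n_pixels,
        round(settings.pixel_size_um, 9),
        round(settings.distance_mm, 9),
    )

    rows = []
    sample = 0
    for ci, conf in enumerate(ensemble):
        a_full = None
        if settings.include_molecule:
            cache_key = (id(conf), geom_key)
            if amplitude_cache is not None and cache_key in amplitude_cache:
                a_full = amplitude_cache[cache_key]
            else:
                a_full = structure_amplitude(conf, det_model)
                if amplitude_cache is not None:
                    amplitude_cache[cache_key] = a_full

        for pi, pair in enumerate(label_pairs):
            labeled = LabeledStructure(
                conformer=conf,
                center_a=pair.centers[ci, 0],
                center_b=pair.centers[ci, 1],
                radius=pair.radius,
                substituted_indices=(
                    conf.atom_index(*pair.site_a),
                    conf.atom_index(*pair.site_b),
                ),
            )
            if settings.include_molecule:
                a_mol = _substituted_amplitude(conf, pair, det_model, a_full)
            else:
                a_mol = None
            image = simulate_image(
                labeled,
                det_model,
                include_molecule=settings.include_molecule,
                molecule_amplitude=a_mol,
            )
            if settings.poisson or settings.uniform_max > 0:
                image = add_noise(
                    image,
                    NoiseParams(
                        poisson=settings.poisson,
                        uniform_max=settings.uniform_max,
                        seed=int(noise_seeds[sample]),
                    ),
                )
            fit_cfg = settings.fit
            if fit_cfg.r_min == 0.0:
                # labels were placed under the 2.4R separation rule, so the
                # fringe search may exclude shorter separations
                fit_cfg = replace(fit_cfg, r_min=2.4 * pair.radius)
            result = fit_distance(image, pair.radius, det_model, fit_cfg)
            d_true = canonicalize(labeled.d_true)
            if result.converged:
                dx, dy, dz, dr = component_delta(result.d_fit, d_true)
            else:
                dx = dy = dz = dr = np.nan
            rows.append(
                {
                    "snapshot_id": conf.snapshot_id,
                    "pair_index": pi,
                    "r_aunp": labeled.r_aunp,
                    "r_fit": result.r_fit,
                    "dx": dx,
                    "dy": dy,
                    "dz": dz,
                    "dr": dr,
                    "chi2": result.chi2,
                    "converged": result.converged,
                }
            )
            sample += 1

    table = pd.DataFrame(rows)
    n_failed = int((~table["converged"]).sum())
    if n_failed:
        logger.info("%d of %d fits failed", n_failed, len(table))
    stats = _delta_stats_from_table(table, n_failed)
    return stats, table


def run_sweep(
    parameter: str,
    grid,
    base: RunSettings,
    ensemble: Ensemble,
    seed: int = 0,
) -> SweepResult:
    """Vary one experimental parameter over a grid, rerunning the pipeline.

    Label pairs are reselected at each AuNP radius (the 2.4R separation
    constraint depends on R) and kept fixed otherwise; the same seed is
    used at every grid point (common random numbers) so that the trend of
    the accuracy across the grid reflects the parameter, not resampling.
    Grid points where labeling is infeasible are flagged (stats ``None``),
    not fatal.
    """
    if parameter not in SWEEP_PARAMETERS:
        raise ValueError(
            f"unknown sweep parameter {parameter!r}; "
            f"choose from {sorted(SWEEP_PARAMETERS)}"
        )
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("sweep grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sweep grid values must be strictly increasing")

    field_name = SWEEP_PARAMETERS[parameter]
    # labeling sites stay fixed across the grid; for a radius sweep they are
    # chosen at the largest (most constrained) radius and the particle
    # centers are rebuilt per grid value
    selection_radius = float(grid[-1]) if parameter == "R" else base.radius
    base_pairs = select_label_pairs(
        ensemble,
        radius=selection_radius,
        n_pairs_min=base.n_pairs_min,
        n_pairs_max=base.n_pairs_max,
        min_spread=base.min_spread,
        seed=seed,
        clash_margin=base.clash_margin,
    )

    amplitude_cache: dict = {}
    stats_list: list[DeltaStats | None] = []
    rows = []
    for value in grid:
        cast = int(value) if field_name == "n_pixels" else float(value)
        settings = replace(base, **{field_name: cast})
        try:
            if parameter == "R":
                pairs = rebuild_label_pairs(
                    ensemble, base_pairs, settings.radius, settings.clash_margin
                )
                if len(pairs) < settings.n_pairs_min:
                    raise NoFeasibleLabelingError(
                        f"only {len(pairs)} of {len(base_pairs)} site pairs "
                        f"remain feasible at R = {settings.radius} A"
                    )
            else:
                pairs = base_pairs
            stats, _ = run_ensemble(
                ensemble, pairs, settings, seed=seed, amplitude_cache=amplitude_cache
            )
        except NoFeasibleLabelingError as exc:
            logger.warning("grid point %s=%g infeasible: %s", parameter, value, exc)
            stats_list.append(None)
            rows.append({"parameter": parameter, "value": value, "feasible": False})
            continue
        stats_list.append(stats)
        row = {
            "parameter": parameter,
            "value": value,
            "feasible": True,
            "n_samples": stats.n_samples,
        }
        for key in DELTA_KEYS:
            row[f"sigma_{key}"] = stats.gauss_std[key]
            row[f"center_{key}"] = stats.gauss_center[key]
            row[f"sample_std_{key}"] = stats.sample_std[key]
        rows.append(row)

    return SweepResult(
        parameter=parameter, values=grid, stats=stats_list, table=pd.DataFrame(rows)
    )
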