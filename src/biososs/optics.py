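"""Beam and detector geometry for single-object scattering on a flat area detector.

The detector is a square grid of ``n x n`` pixels of pitch ``p`` placed
perpendicular to the beam at distance ``l`` downstream of the sample, with
the beam axis through the detector center.  Each pixel center is mapped onto
the Ewald sphere: with incident wavevector ``k = 2*pi/lambda`` along +z and
unit vector ``s_hat`` from the sample to the pixel center, the momentum
transfer is ``q = k * (s_hat - z_hat)``, so ``|q| = 4*pi*sin(theta)/lambda``
and ``q_z = k*(cos(2*theta) - 1) <= 0`` everywhere off the axis.  The
curvature of the Ewald sphere is what makes ``q_z`` second order in the
scattering angle — the physical origin of the poor z-resolution of
fringe-based distance retrieval.

Per-pixel solid angle and the unpolarized Thomson polarization factor
``0.5*(1 + cos^2(2*theta))`` are tabulated here so that the scattering
module can turn squared amplitudes into expected photon counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HC_KEV_ANGSTROM",
    "CLASSICAL_ELECTRON_RADIUS_A",
    "BeamParams",
    "DetectorParams",
    "DetectorModel",
    "build_detector",
    "r_lim",
    "dq_center",
    "fluence",
]

#: h*c in keV * Angstrom: E[keV] = HC / lambda[A]
HC_KEV_ANGSTROM = 12.39842

#: Classical electron radius in Angstrom.
CLASSICAL_ELECTRON_RADIUS_A = 2.8179403e-5


@dataclass(frozen=True)
class BeamParams:
    """X-ray pulse parameters.

    Parameters
    ----------
    energy_keV:
        Photon energy in keV.  The wavelength follows from
        ``lambda[A] = 12.39842 / E[keV]``.
    photons:
        Total photons per pulse (the direct-beam intensity ``I``).
    focal_size_nm:
        Focal spot diameter ``f`` in nm.  The spot is modeled as a uniform
        circular top-hat; the molecule is assumed fully inside it.
    """

    energy_keV: float
    photons: float = 1e14
    focal_size_nm: float = 100.0

    def __post_init__(self) -> None:
        if self.energy_keV <= 0:
            raise ValueError(f"energy_keV must be positive, got {self.energy_keV}")
        if self.photons < 0:
            raise ValueError(f"photons must be non-negative, got {self.photons}")
        if self.focal_size_nm <= 0:
            raise ValueError(f"focal_size_nm must be positive, got {self.focal_size_nm}")

    @property
    def wavelength_A(self) -> float:
        return HC_KEV_ANGSTROM / self.energy_keV

    @property
    def k_A_inv(self) -> float:
        """Wavenumber 2*pi/lambda in 1/A."""
        return 2.0 * math.pi / self.wavelength_A

    @classmethod
    def from_wavelength(
        cls, wavelength_A: float, photons: float = 1e14, focal_size_nm: float = 100.0
    ) -> "BeamParams":
        if wavelength_A <= 0:
            raise ValueError(f"wavelength_A must be positive, got {wavelength_A}")
        return cls(HC_KEV_ANGSTROM / wavelength_A, photons, focal_size_nm)


@dataclass(frozen=True)
class DetectorParams:
    """Flat square pixel-array detector.

    Parameters
    ----------
    n_pixels:
        Pixels per side (``n``); the detector is ``n x n``.
    pixel_size_um:
        Pixel pitch ``p`` in micrometers.
    distance_mm:
        Sample-to-detector distance ``l`` in millimeters.
    """

    n_pixels: int
    pixel_size_um: float
    distance_mm: float

    def __post_init__(self) -> None:
        if self.n_pixels < 2:
            raise ValueError(f"n_pixels must be >= 2, got {self.n_pixels}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if self.distance_mm <= 0:
            raise ValueError(f"distance_mm must be positive, got {self.distance_mm}")

    @property
    def pixel_size_A(self) -> float:
        return self.pixel_size_um * 1e4  # um -> A

    @property
    def distance_A(self) -> float:
        return self.distance_mm * 1e7  # mm -> A


@dataclass
class DetectorModel:
    """Per-pixel geometry tables, all shaped ``(n, n)`` (or ``(n, n, 3)``).

    Attributes
    ----------
    q_map:
        Momentum transfer vectors ``(q_x, q_y, q_z)`` in 1/A.
    q_mag:
        ``|q|`` in 1/A.
    solid_angle:
        Pixel solid angle in steradian, ``p^2 * cos^3(2*theta) / l^2``.
    polarization:
        Unpolarized Thomson factor ``0.5*(1 + cos^2(2*theta))``.
    two_theta:
        Scattering angle ``2*theta`` in radians.
    """

    beam: BeamParams
    det: DetectorParams
    q_map: np.ndarray
    q_mag: np.ndarray
    solid_angle: np.ndarray
    polarization: np.ndarray
    two_theta: np.ndarray
    _q_flat: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._q_flat = np.ascontiguousarray(self.q_map.reshape(-1, 3))

    @property
    def shape(self) -> tuple[int, int]:
        return self.q_mag.shape

    @property
    def q_flat(self) -> np.ndarray:
        """``(n*n, 3)`` view of q_map for vectorized phase sums."""
        return self._q_flat


def build_detector(beam: BeamParams, det: DetectorParams) -> DetectorModel:
    """Tabulate q vectors, solid angles and polarization for every pixel.

    Pixel ``(i, j)`` has its center at lab position
    ``((i - (n-1)/2)*p, (j - (n-1)/2)*p, l)``; index ``i`` runs along x
    (first array axis), ``j`` along y.  Intensity is evaluated at pixel
    centers only.
    """
    n = det.n_pixels
    p = det.pixel_size_A
    l = det.distance_A
    k = beam.k_A_inv

    idx = np.arange(n, dtype=float) - (n - 1) / 2.0
    x = idx[:, None] * p * np.ones((1, n))
    y = np.ones((n, 1)) * idx[None, :] * p
    r = np.sqrt(x * x + y * y + l * l)

    cos_2t = l / r
    # arctan2 keeps full precision at small scattering angles, where
    # arccos(l/r) would lose half the significant digits
    two_theta = np.arctan2(np.sqrt(x * x + y * y), l)

    # q = k (s_hat - z_hat); q_z = k (cos 2theta - 1) <= 0
    q = np.empty((n, n, 3))
    q[..., 0] = k * x / r
    q[..., 1] = k * y / r
    q[..., 2] = k * (cos_2t - 1.0)
    q_mag = np.sqrt(np.sum(q * q, axis=-1))

    solid_angle = (p * p) * cos_2t**3 / (l * l)
    polarization = 0.5 * (1.0 + cos_2t * cos_2t)

    return DetectorModel(
        beam=beam,
        det=det,
        q_map=q,
        q_mag=q_mag,
        solid_angle=solid_angle,
        polarization=polarization,
        two_theta=two_theta,
    )


def _q_at_angle(beam: BeamParams, two_theta: float) -> float:
    return 4.0 * math.pi * math.sin(two_theta / 2.0) / beam.wavelength_A


def r_lim(beam: BeamParams, det: DetectorParams) -> float:
    """Nominal real-space resolution ``2*pi/q_max`` in Angstrom.

    ``q_max`` is evaluated at the midpoint of the detector edge
    (half-width ``n*p/2``), i.e. ``2*theta_max = atan(n*p/2 / l)``.
    """
    half_width = det.n_pixels * det.pixel_size_A / 2.0
    two_theta_max = math.atan2(half_width, det.distance_A)
    return 2.0 * math.pi / _q_at_angle(beam, two_theta_max)


def dq_center(beam: BeamParams, det: DetectorParams) -> float:
    """Momentum-transfer increment across one pixel at the detector center, 1/A.

    The ``|q|`` of a pixel offset by one pitch ``p`` from the beam axis:
    ``2*theta = atan(p/l)``.  This sets how finely the interference fringes
    are sampled near the beam axis.
    """
    two_theta = math.atan2(det.pixel_size_A, det.distance_A)
    return _q_at_angle(beam, two_theta)


def fluence(beam: BeamParams) -> float:
    """Incident photons per Angstrom^2 for a uniform circular top-hat spot.

    ``Phi = I / (pi * (f/2)^2)`` with the focal diameter ``f`` converted
    from nm to Angstrom.
    """
    radius_A = beam.focal_size_nm * 10.0 / 2.0
    return beam.photons / (math.pi * radius_A * radius_A)
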