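"""Detector/beam geometry, q-space conversions and azimuthal integration.

Conventions
-----------
* Momentum transfer ``q = 4 pi sin(theta) / lambda`` with ``2 theta`` the full
  scattering angle and ``lambda`` the X-ray wavelength in Angstrom, so q is in
  inverse Angstrom.
* Pixel indices are 0-based, (row, column) order; a pixel's q is evaluated at
  its center (no area-weighted splitting across bins).
* q-bins are half-open intervals ``[lo, hi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: hc in eV * Angstrom; reproduces 1.55 A at 8,000 eV to printed precision.
HC_EV_ANGSTROM = 12_398.42

__all__ = [
    "HC_EV_ANGSTROM",
    "BeamlineGeometry",
    "QGrid",
    "RadialProfile",
    "wavelength_from_energy",
    "q_from_scattering_angle",
    "scattering_angle_from_q",
    "resolution_from_q",
    "pulse_time_grid",
    "azimuthal_integrate",
]


def wavelength_from_energy(photon_energy_ev: float) -> float:
    """X-ray wavelength in Angstrom for a photon energy in eV (lambda = hc/E)."""
    if not np.isfinite(photon_energy_ev) or photon_energy_ev <= 0:
        raise ValueError(f"photon energy must be positive, got {photon_energy_ev!r}")
    return HC_EV_ANGSTROM / photon_energy_ev


def q_from_scattering_angle(theta: float | np.ndarray, wavelength: float):
    """Momentum transfer q = 4 pi sin(theta)/lambda.

    Parameters
    ----------
    theta
        Half the scattering angle (i.e. theta where the full angle is 2 theta),
        in radians, in [0, pi/2).
    wavelength
        X-ray wavelength in Angstrom.
    """
    theta = np.asarray(theta, dtype=float)
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if np.any(theta < 0) or np.any(theta >= np.pi / 2):
        raise ValueError("theta must lie in [0, pi/2)")
    q = 4.0 * np.pi * np.sin(theta) / wavelength
    return q if q.ndim else float(q)


def scattering_angle_from_q(q: float | np.ndarray, wavelength: float):
    """Inverse of :func:`q_from_scattering_angle`: theta = asin(q lambda / 4 pi)."""
    q = np.asarray(q, dtype=float)
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    x = q * wavelength / (4.0 * np.pi)
    if np.any(x < 0) or np.any(x >= 1):
        raise ValueError("q outside the reachable range for this wavelength")
    theta = np.arcsin(x)
    return theta if theta.ndim else float(theta)


def resolution_from_q(q: float | np.ndarray):
    """Real-space resolution d = 2 pi / q in Angstrom for q in 1/Angstrom."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    d = 2.0 * np.pi / q
    return d if d.ndim else float(d)


def pulse_time_grid(n_pulses: int, intra_train_rate_hz: float) -> np.ndarray:
    """Delay times (microseconds) of the pulses in one train.

    Pulse ``j`` arrives at ``j / rate``; the spacing is the inverse of the
    intra-train repetition rate (1.77 us at 564 kHz).
    """
    if n_pulses < 1:
        raise ValueError("need at least one pulse")
    if intra_train_rate_hz <= 0:
        raise ValueError("repetition rate must be positive")
    return np.arange(n_pulses, dtype=float) / intra_train_rate_hz * 1e6


@dataclass(frozen=True)
class QGrid:
    """Strictly increasing q values (1/Angstrom) with half-open bin edges."""

    values: np.ndarray
    edges: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "edges", edges)
        if values.ndim != 1 or len(values) < 1:
            raise ValueError("q values must be a non-empty 1-D array")
        if len(edges) != len(values) + 1:
            raise ValueError("need len(values)+1 bin edges")
        if np.any(values <= 0):
            raise ValueError("q values must be positive")
        if np.any(np.diff(values) <= 0) or np.any(np.diff(edges) <= 0):
            raise ValueError("q values and edges must be strictly increasing")
        if np.any(values < edges[:-1]) or np.any(values >= edges[1:]):
            raise ValueError("each q value must lie inside its [lo, hi) bin")

    @classmethod
    def linear(cls, lo: float = 0.08, hi: float = 1.5, n: int = 170) -> "QGrid":
        """Linear grid of ``n`` points spanning [lo, hi] (values at bin centers)."""
        values = np.linspace(lo, hi, n)
        half = 0.5 * (hi - lo) / max(n - 1, 1)
        edges = np.concatenate([[values[0] - half], values[:-1] + np.diff(values) / 2, [values[-1] + half]])
        return cls(values=values, edges=edges)

    def __len__(self) -> int:
        return len(self.values)

    def window(self, q_lo: float, q_hi: float) -> np.ndarray:
        """Boolean mask of values inside the closed window [q_lo, q_hi]."""
        return (self.values >= q_lo) & (self.values <= q_hi)


@dataclass
class RadialProfile:
    """A 1-D scattering curve S(q) on a :class:`QGrid`.

    ``counts_per_bin`` tallies the unmasked pixels that contributed to each bin
    (integration output); ``empty`` flags bins with no usable pixels.
    """

    q: QGrid
    intensity: np.ndarray
    counts_per_bin: np.ndarray | None = None
    empty: np.ndarray | None = None

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.q),):
            raise ValueError("intensity length must match the q grid")
        populated = np.ones(len(self.q), bool) if self.empty is None else ~np.asarray(self.empty)
        if not np.all(np.isfinite(self.intensity[populated])):
            raise ValueError("intensity must be finite in populated bins")
        if self.counts_per_bin is not None:
            self.counts_per_bin = np.asarray(self.counts_per_bin)
            if np.any(self.counts_per_bin < 0):
                raise ValueError("counts_per_bin must be non-negative")


@dataclass
class BeamlineGeometry:
    """Flat-detector geometry mapping pixels to momentum transfer.

    A single rectangular detector with a user mask stands in for the real
    multi-panel layout; per-panel calibration is out of scope.
    """

    photon_energy: float = 8_000.0          # eV
    detector_distance: float = 0.281        # m
    pixel_pitch: float = 200e-6             # m
    beam_center: tuple[float, float] = (0.0, 0.0)  # (row, col), 0-based pixels
    mask: np.ndarray | None = None          # True = usable
    wavelength: float | None = None         # Angstrom; derived from energy if None

    def __post_init__(self):
        if self.detector_distance <= 0:
            raise ValueError("detector distance must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")
        derived = wavelength_from_energy(self.photon_energy)
        if self.wavelength is None:
            self.wavelength = derived
        elif self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        elif abs(self.wavelength - derived) / derived > 0.005:
            raise ValueError(
                f"wavelength {self.wavelength:.4f} A inconsistent with photon energy "
                f"{self.photon_energy:.1f} eV (hc/E = {derived:.4f} A)"
            )

    def pixel_q(self, shape: tuple[int, int]) -> np.ndarray:
        """q (1/A) at each pixel center of an image with the given shape."""
        rows, cols = np.indices(shape)
        cy, cx = self.beam_center
        r = np.hypot((rows - cy) * self.pixel_pitch, (cols - cx) * self.pixel_pitch)
        theta = 0.5 * np.arctan2(r, self.detector_distance)
        return 4.0 * np.pi * np.sin(theta) / self.wavelength


def azimuthal_integrate(image: np.ndarray, geometry: BeamlineGeometry, grid: QGrid) -> RadialProfile:
    """Ring-average a detector image onto a q grid.

    Each bin is the mean of the unmasked pixel values whose pixel-center q
    falls inside the half-open bin; bins without usable pixels are flagged
    empty (intensity NaN) rather than silently zeroed.
    """
    image = np.asarray(image, dtype=float)
    mask = geometry.mask if geometry.mask is not None else np.ones(image.shape, bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match the image")
    if not mask.any():
        raise ValueError("mask leaves no usable pixels")
    qpix = geometry.pixel_q(image.shape)
    idx = np.searchsorted(grid.edges, qpix[mask], side="right") - 1
    inside = (idx >= 0) & (idx < len(grid))
    counts = np.bincount(idx[inside], minlength=len(grid))
    sums = np.bincount(idx[inside], weights=image[mask][inside], minlength=len(grid))
    empty = counts == 0
    intensity = np.full(len(grid), np.nan)
    np.divide(sums, counts, out=intensity, where=~empty)
    return RadialProfile(q=grid, intensity=intensity, counts_per_bin=counts, empty=empty)
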