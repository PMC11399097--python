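"""Theoretical solution scattering from atomic models via the Debye formula.

The orientation-averaged intensity of an atomic model is

    I(q) = sum_i sum_j f_i f_j sin(q r_ij) / (q r_ij)

with constant effective electron counts per element as form factors.  This
vacuum Debye calculation deliberately omits the solvation shell and excluded
volume: the quantities consumed downstream are *difference* profiles and their
low-q (radius-of-gyration) behaviour, for which the relative algebra matters,
not solvent-accurate absolute curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import QGrid

#: Effective electrons per element used as constant form factors.
EFFECTIVE_ELECTRONS = {"H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0, "P": 15.0, "S": 16.0}

__all__ = [
    "EFFECTIVE_ELECTRONS",
    "AtomicModel",
    "TheoreticalProfile",
    "debye_profile",
    "radius_of_gyration",
    "model_difference",
    "guinier_rg",
]


@dataclass
class AtomicModel:
    """Labeled atomic coordinates (Angstrom) with per-atom scattering weights."""

    coords: np.ndarray              # (n_atoms, 3), Angstrom
    elements: np.ndarray            # element symbols
    weights: np.ndarray | None = None  # effective electrons; from elements if None
    id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) < 1:
            raise ValueError("coords must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self.elements = np.asarray(self.elements, dtype=object)
        if self.elements.shape != (len(self.coords),):
            raise ValueError("one element label per atom required")
        if self.weights is None:
            try:
                self.weights = np.array(
                    [EFFECTIVE_ELECTRONS[str(e).capitalize()] for e in self.elements]
                )
            except KeyError as exc:
                raise ValueError(f"no effective electron count for element {exc}") from exc
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.coords),) or np.any(self.weights <= 0):
            raise ValueError("weights must be positive, one per atom")

    def __len__(self) -> int:
        return len(self.coords)

    def transformed(self, rotation: np.ndarray | None = None, translation=0.0) -> "AtomicModel":
        coords = self.coords @ rotation.T if rotation is not None else self.coords.copy()
        return AtomicModel(coords + translation, self.elements, self.weights, self.id)


@dataclass
class TheoreticalProfile:
    """Computed scattering curve I(q) in arbitrary absolute units."""

    q: QGrid
    intensity: np.ndarray
    source_model: str = ""

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.q),):
            raise ValueError("intensity length must match the q grid")


def _pair_terms(model: AtomicModel):
    d = np.linalg.norm(model.coords[:, None, :] - model.coords[None, :, :], axis=-1)
    w = np.outer(model.weights, model.weights)
    return d, w


def debye_profile(
    model: AtomicModel, q: QGrid, method: str = "auto", histogram_dr: float = 1e-5
) -> TheoreticalProfile:
    """Debye-formula intensity of a model on a q grid.

    ``method='direct'`` evaluates the exact O(N^2) double sum; ``'histogram'``
    bins the pair distances on a fine grid (width ``histogram_dr`` Angstrom)
    before summing, which is much faster for large models and agrees with the
    direct path to better than 1e-6 relative at WAXS q.  ``'auto'`` switches to
    the histogram above 400 atoms.
    """
    qv = q.values
    if method == "auto":
        method = "histogram" if len(model) > 400 else "direct"
    d, w = _pair_terms(model)
    if method == "direct":
        # sinc(x/pi) = sin(x)/x with the correct x=0 limit
        intensity = np.array([np.sum(w * np.sinc(qi * d / np.pi)) for qi in qv])
    elif method == "histogram":
        self_term = np.sum(model.weights**2)
        iu = np.triu_indices(len(model), k=1)
        dist, ww = d[iu], w[iu]
        n_bins = int(np.ceil(dist.max() / histogram_dr)) + 1 if len(dist) else 1
        idx = np.minimum((dist / histogram_dr).astype(int), n_bins - 1)
        hist = np.bincount(idx, weights=ww, minlength=n_bins)
        occupied = np.flatnonzero(hist)  # keep memory bounded at fine bin widths
        centers = (occupied + 0.5) * histogram_dr
        intensity = self_term + 2.0 * (np.sinc(np.outer(qv, centers) / np.pi) @ hist[occupied])
    else:
        raise ValueError(f"unknown method {method!r}")
    return TheoreticalProfile(q=q, intensity=intensity, source_model=model.id)


def radius_of_gyration(model: AtomicModel) -> float:
    """Weight-averaged RMS distance of the atoms from their weighted centroid."""
    w = model.weights
    center = np.average(model.coords, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((model.coords - center) ** 2, axis=1), weights=w)))


def model_difference(candidate: AtomicModel, native: AtomicModel, q: QGrid) -> np.ndarray:
    """Difference scattering of a structural pair: I_candidate(q) - I_native(q)."""
    return debye_profile(candidate, q).intensity - debye_profile(native, q).intensity


def guinier_rg(q: np.ndarray, intensity: np.ndarray, q_rg_max: float = 1.0) -> float:
    """Radius of gyration from the Guinier slope of a scattering curve.

    Fits ln I = ln I0 - (Rg^2/3) q^2 over the self-consistent window
    q * Rg < ``q_rg_max``, iterating the window until stable.
    """
    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        raise ValueError("Guinier fit needs positive intensities")
    rg = 2.0 / q.max()  # generous initial window
    for _ in range(50):
        sel = q * rg < q_rg_max
        if sel.sum() < 3:
            raise ValueError("too few points in the Guinier window")
        slope = np.polyfit(q[sel] ** 2, np.log(intensity[sel]), 1)[0]
        if slope >= 0:
            raise ValueError("non-negative Guinier slope; curve is not decaying at low q")
        new_rg = float(np.sqrt(-3.0 * slope))
        if abs(new_rg - rg) < 1e-10:
            return new_rg
        rg = new_rg
    return rg
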