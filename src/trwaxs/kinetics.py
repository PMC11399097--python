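"""Global kinetic decomposition of difference scattering by variable projection.

The measured transient difference intensity is modeled as a linear combination
of time-independent basis spectra weighted by the concentrations of the states
of an irreversible sequential scheme (A -> B or A -> B -> C):

    dS(q, t) = sum_i BS_i(q) C_i(t)

The concentrations are closed-form exponentials in the rate constants; for
fixed rates the basis spectra are the exact linear least-squares solution, so
the nonlinear search (Nelder-Mead over log-rates) only sees the rates
("variable projection").  The target is the sum of squared per-(q,t)
residuals; the three-state model is accepted over the two-state one only when
it lowers that residual by more than a configurable relative margin.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

__all__ = [
    "SequentialModel",
    "KineticFit",
    "concentration_profiles",
    "solve_basis_spectra",
    "KineticsDecomposition",
    "fit_global",
    "compare_models",
]


@dataclass(frozen=True)
class SequentialModel:
    """Irreversible sequential first-order scheme with 2 or 3 states.

    Rates are in inverse microseconds; ``degenerate_tol`` is the relative rate
    gap below which the analytic equal-rate limit replaces the generic formula.
    """

    n_states: int
    rates: tuple[float, ...]
    degenerate_tol: float = 1e-7

    def __post_init__(self):
        if self.n_states not in (2, 3):
            raise ValueError("n_states must be 2 or 3")
        if len(self.rates) != self.n_states - 1:
            raise ValueError(f"a {self.n_states}-state chain needs {self.n_states - 1} rates")
        if any(k <= 0 or not np.isfinite(k) for k in self.rates):
            raise ValueError("rates must be positive and finite")


def concentration_profiles(model: SequentialModel, t_us: np.ndarray) -> np.ndarray:
    """Concentrations C_i(t) of the sequential scheme, shape (n_t, n_states).

    Two-state:  C_A = exp(-k_A t),  C_B = 1 - C_A.
    Three-state: C_A = exp(-k_A t);
                 C_B = k_A/(k_B - k_A) [exp(-k_A t) - exp(-k_B t)];
                 C_C = 1 - C_A - C_B.
    Near-degenerate rates (|k_B - k_A|/k_A below tolerance) use the analytic
    limit C_B = k_A t exp(-k_A t).  Rows sum to one exactly.
    """
    t = np.asarray(t_us, dtype=float)
    if np.any(t < 0):
        raise ValueError("delay times must be non-negative")
    k_a = model.rates[0]
    c_a = np.exp(-k_a * t)
    if model.n_states == 2:
        return np.column_stack([c_a, 1.0 - c_a])
    k_b = model.rates[1]
    if abs(k_b - k_a) / k_a < model.degenerate_tol:
        c_b = k_a * t * np.exp(-k_a * t)
    else:
        c_b = k_a / (k_b - k_a) * (np.exp(-k_a * t) - np.exp(-k_b * t))
    return np.column_stack([c_a, c_b, 1.0 - c_a - c_b])


def solve_basis_spectra(delta_s: np.ndarray, concentrations: np.ndarray) -> np.ndarray:
    """Exact least-squares basis spectra for fixed concentrations.

    Parameters
    ----------
    delta_s
        Difference matrix, shape (n_q, n_t).
    concentrations
        C matrix, shape (n_t, n_states); must have full column rank.

    Returns
    -------
    Basis spectra, shape (n_states, n_q).
    """
    delta_s = np.asarray(delta_s, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if c.shape[0] != delta_s.shape[1]:
        raise ValueError("concentration rows must match the number of time points")
    sv = np.linalg.svd(c, compute_uv=False)
    if sv[-1] < 1e-12 * sv[0]:
        corr = np.corrcoef(c.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"concentration matrix is rank deficient: states {i} and {j} are collinear "
            f"(|corr| = {abs(corr[i, j]):.6f}) on this time grid"
        )
    bs, *_ = np.linalg.lstsq(c, delta_s.T, rcond=None)
    return bs


def _residual(delta_s: np.ndarray, c: np.ndarray, bs: np.ndarray) -> float:
    return float(np.sum((delta_s - (c @ bs).T) ** 2))


def _data_hash(delta_s: np.ndarray, t_us: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(delta_s).tobytes())
    h.update(np.ascontiguousarray(t_us).tobytes())
    return h.hexdigest()


@dataclass
class KineticFit:
    """Result of a global sequential-model fit."""

    model: SequentialModel
    basis_spectra: np.ndarray     # (n_states, n_q)
    concentrations: np.ndarray    # (n_t, n_states)
    residual_r: float
    n_iterations: int
    converged: bool
    data_hash: str = ""

    def reconstruct(self) -> np.ndarray:
        """Model difference matrix, shape (n_q, n_t)."""
        return (self.concentrations @ self.basis_spectra).T


class KineticsDecomposition(BaseEstimator):
    """Sequential-model decomposition of a difference matrix, sklearn-style.

    Parameters
    ----------
    n_states : 2 or 3
    init_rates : initial rate constants in 1/us; defaults reflect microsecond
        photoreceptor kinetics (fast first step ~ 1/(2 us), slow second step
        ~ 1/(100 us)).
    multistart_factors : multiplicative grid around the initial rates; the best
        of all starts is kept.
    q_weights : optional per-q weights applied to the rows of the data.
    xatol, fatol, max_iter : Nelder-Mead termination controls (log-rate space).

    Attributes (after ``fit``)
    --------------------------
    rates_, basis_spectra_, concentrations_, residual_, n_iter_, converged_,
    fit_ (the full :class:`KineticFit`).
    """

    def __init__(
        self,
        n_states: int = 3,
        init_rates: tuple[float, ...] | None = None,
        multistart_factors: tuple[float, ...] = (0.1, 1.0, 10.0),
        q_weights: np.ndarray | None = None,
        xatol: float = 1e-8,
        fatol_rel: float = 1e-12,
        max_iter: int = 4000,
    ):
        self.n_states = n_states
        self.init_rates = init_rates
        self.multistart_factors = multistart_factors
        self.q_weights = q_weights
        self.xatol = xatol
        self.fatol_rel = fatol_rel
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y: np.ndarray | None = None, *, t_us: np.ndarray | None = None):
        """Fit the decomposition.

        ``X`` is the difference matrix with shape (n_q, n_t); ``t_us`` the
        matching delay grid in microseconds (required).
        """
        if t_us is None:
            raise ValueError("t_us (delay grid in microseconds) is required")
        if self.n_states not in (2, 3):
            raise ValueError("n_states must be 2 or 3")
        delta_s = np.asarray(X, dtype=float)
        t = np.asarray(t_us, dtype=float)
        if delta_s.shape[1] != len(t):
            raise ValueError("delta_s columns must match the time grid")
        data = delta_s if self.q_weights is None else delta_s * np.asarray(self.q_weights)[:, None]

        init = self.init_rates if self.init_rates is not None else (0.5, 0.01)[: self.n_states - 1]
        n_rates = self.n_states - 1

        def objective(log_k: np.ndarray) -> float:
            model = SequentialModel(self.n_states, tuple(np.exp(log_k)))
            c = concentration_profiles(model, t)
            try:
                bs = solve_basis_spectra(data, c)
            except ValueError:
                return np.inf
            return _residual(data, c, bs)

        starts = [np.log(init)]
        grids = np.meshgrid(*([np.log(self.multistart_factors)] * n_rates), indexing="ij")
        offsets = np.stack([g.ravel() for g in grids], axis=-1)
        starts = [np.log(init) + off for off in offsets]

        best = None
        total_iter = 0
        for x0 in starts:
            f0 = objective(x0)
            res = minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={
                    "xatol": self.xatol,
                    # scale the function tolerance to the data (the residual is
                    # in squared-intensity units, so an absolute ftol is moot)
                    "fatol": self.fatol_rel * (1.0 + abs(f0)),
                    "maxiter": self.max_iter,
                    "maxfev": self.max_iter,
                },
            )
            total_iter += res.nit
            if best is None or res.fun < best.fun:
                best = res

        rates = tuple(np.exp(best.x))
        model = SequentialModel(self.n_states, rates)
        c = concentration_profiles(model, t)
        bs = solve_basis_spectra(data, c)
        if self.q_weights is not None:
            bs = bs / np.asarray(self.q_weights)[None, :]
            c_plain = c
            r = _residual(data, c_plain, solve_basis_spectra(data, c_plain))
        else:
            r = _residual(data, c, bs)
        self.fit_ = KineticFit(
            model=model,
            basis_spectra=bs,
            concentrations=c,
            residual_r=r,
            n_iterations=total_iter,
            converged=bool(best.success),
            data_hash=_data_hash(delta_s, t),
        )
        self.rates_ = np.array(rates)
        self.basis_spectra_ = bs
        self.concentrations_ = c
        self.residual_ = r
        self.n_iter_ = total_iter
        self.converged_ = bool(best.success)
        return self

    def predict(self, t_us: np.ndarray) -> np.ndarray:
        """Reconstructed difference matrix (n_q, n_t) on an arbitrary delay grid."""
        c = concentration_profiles(self.fit_.model, np.asarray(t_us, dtype=float))
        return (c @ self.basis_spectra_).T


def fit_global(
    delta_s: np.ndarray,
    t_us: np.ndarray,
    n_states: int = 3,
    init_rates: tuple[float, ...] | None = None,
    **optimizer_settings,
) -> KineticFit:
    """Functional wrapper over :class:`KineticsDecomposition`."""
    est = KineticsDecomposition(n_states=n_states, init_rates=init_rates, **optimizer_settings)
    est.fit(delta_s, t_us=t_us)
    return est.fit_


def compare_models(fit2: KineticFit, fit3: KineticFit, improvement_threshold: float = 0.05) -> dict:
    """Model selection between nested sequential fits on the same data.

    The larger model is selected only when its residual improves on the smaller
    one by more than ``improvement_threshold`` (relative).
    """
    if fit2.data_hash != fit3.data_hash:
        raise ValueError("fits were computed on different data (hash mismatch)")
    r2, r3 = fit2.residual_r, fit3.residual_r
    improvement = (r2 - r3) / r2 if r2 > 0 else 0.0
    selected = fit3 if improvement > improvement_threshold else fit2
    return {
        "r_two_state": r2,
        "r_three_state": r3,
        "relative_improvement": improvement,
        "threshold": improvement_threshold,
        "selected_n_states": selected.model.n_states,
        "selected": selected,
    }
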