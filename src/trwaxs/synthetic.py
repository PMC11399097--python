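"""Synthetic MHz pulse-train scattering and toy structural ensembles.

The generator reproduces the statistical structure the downstream analysis
relies on, at a size a desk machine can iterate on:

* alternating light/dark 10 Hz trains of 175 pulses at 564 kHz;
* per-train multiplicative common-mode jitter (jet thickness / beam intensity
  fluctuations, shared by all pulses of a train);
* Poisson photon noise on per-bin integrated counts;
* a light-train difference signal composed as yield x sum_i BS_i(q) C_i(t)
  with sequential-model concentrations, i.e. the kinetic forward model run in
  reverse;
* an adjustable fraction of "unstable-jet" trains whose scattering shape is
  smoothly distorted, which is what the correlation filter must catch.

Toy folded/unfolded structure pairs (a compact helical bundle whose terminal
span is resampled as an increasingly extended coil) stand in for the candidate
ensembles; their Debye difference profiles provide physically shaped basis
spectra tied to known radius-of-gyration changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import QGrid, RadialProfile, pulse_time_grid
from .kinetics import SequentialModel, concentration_profiles
from .scattering import AtomicModel, debye_profile, model_difference, radius_of_gyration

__all__ = [
    "GeneratorConfig",
    "TrainSeries",
    "make_toy_structures",
    "default_ground_truth",
    "simulate_train_series",
    "inject_instability",
]


@dataclass
class TrainSeries:
    """Per-train, per-pulse scattering profiles with light/dark flags.

    ``profiles`` has shape (n_trains, n_pulses, n_q); ``truth`` carries the
    synthetic ground-truth record (rates, yield, basis spectra, corrupted ids)
    and is absent for real data.
    """

    profiles: np.ndarray
    light_flag: np.ndarray
    time_us: np.ndarray
    q: QGrid
    truth: dict | None = None

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        self.light_flag = np.asarray(self.light_flag, dtype=bool)
        if self.profiles.ndim != 3:
            raise ValueError("profiles must have shape (n_trains, n_pulses, n_q)")
        n_trains, n_pulses, n_q = self.profiles.shape
        if self.light_flag.shape != (n_trains,):
            raise ValueError("one light/dark flag per train required")
        if len(self.time_us) != n_pulses or len(self.q) != n_q:
            raise ValueError("time and q grids must match the profile block")

    @property
    def n_trains(self) -> int:
        return self.profiles.shape[0]

    def train_means(self) -> np.ndarray:
        """Pulse-averaged profile of each train, shape (n_trains, n_q)."""
        return self.profiles.mean(axis=1)


@dataclass
class GeneratorConfig:
    """Study conditions for the pulse-train generator.

    Defaults: 60 light/dark train pairs of 175 pulses at 564 kHz; a yield of
    0.15; sequential rates (0.1, 0.01) 1/us — a ~10 us intermediate step well
    inside the pulse grid and a final state developing over the ~300 us train;
    1e10 expected photons per pulse across the q-window, which puts the
    averaged difference-signal noise floor at the 1e-5 relative scale (the
    larger per-pulse budget compensates the much smaller train count relative
    to a real beamtime, so the averaged noise floor is comparable);
    1e-3 train-level common-mode jitter; basis spectra rescaled to a peak
    amplitude of 1e-3 of the background peak (``relative_signal=None`` keeps
    the Debye absolute relation between background and basis spectra instead,
    which the absolute-scale structural screen requires).
    """

    n_train_pairs: int = 60
    pulses_per_train: int = 175
    intra_train_rate: float = 564e3
    photons_per_pulse_scale: float = 1e10
    yield_c: float = 0.15
    rates: tuple[float, ...] = (0.1, 0.01)
    jitter_sd: float = 1e-3
    jitter_corr: float = 0.9
    corrupt_fraction: float = 0.0
    corrupt_strength: float = 0.05
    relative_signal: float | None = 1e-3
    n_states: int = 3
    poisson: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.yield_c <= 1.0:
            raise ValueError("yield_c must be in [0, 1]")
        if any(k <= 0 for k in self.rates):
            raise ValueError("rates must be positive")
        if not 0.0 <= self.corrupt_fraction < 1.0:
            raise ValueError("corrupt_fraction must be in [0, 1)")
        if self.n_train_pairs < 1 or self.pulses_per_train < 1:
            raise ValueError("need at least one train pair and one pulse")
        if self.jitter_sd < 0 or self.photons_per_pulse_scale <= 0:
            raise ValueError("jitter_sd must be >= 0 and photon scale > 0")
        if not 0.0 <= self.jitter_corr < 1.0:
            raise ValueError("jitter_corr must be in [0, 1)")
        if self.n_states not in (2, 3) or len(self.rates) != self.n_states - 1:
            raise ValueError("n_states must be 2 or 3 with matching rate count")


def _helix(n: int, start: np.ndarray, axis_z: float = 1.0) -> np.ndarray:
    """Ideal alpha-helical C-alpha trace: 2.3 A radius, 1.5 A rise, 100 deg/res."""
    j = np.arange(n)
    ang = np.deg2rad(100.0) * j
    xyz = np.column_stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), axis_z * 1.5 * j])
    return xyz - xyz[0] + start


def make_toy_structures(
    n_residues: int = 64,
    unfold_span: int = 20,
    n_candidates: int = 12,
    seed: int = 0,
) -> tuple[AtomicModel, list[AtomicModel]]:
    """Compact helical-bundle native plus partially unfolded candidates.

    The native model is a four-helix C-alpha bundle.  Each candidate keeps the
    first ``n_residues - unfold_span`` atoms and resamples the terminal span as
    a persistent random walk (3.8 A steps) whose directional persistence grows
    across the list, so the candidates sweep an increasing radius-of-gyration
    change (all ``delta Rg >= 0``).  Fully deterministic for a fixed seed.
    """
    if not 0 < unfold_span < n_residues:
        raise ValueError("unfold_span must be positive and smaller than n_residues")
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    per = n_residues // 4
    rest = n_residues - 3 * per
    sep = 5.2
    anchors = [(-sep, -sep), (sep, -sep), (sep, sep), (-sep, sep)]
    pieces, z_dir = [], 1.0
    for h, nres in enumerate([per, per, per, rest]):
        x0, y0 = anchors[h]
        start = np.array([x0, y0, 0.0 if z_dir > 0 else 1.5 * (nres - 1)])
        pieces.append(_helix(nres, start, axis_z=z_dir))
        z_dir *= -1.0
    coords = np.vstack(pieces)
    elements = np.full(n_residues, "C", dtype=object)
    native = AtomicModel(coords, elements, id="native")

    rng = np.random.default_rng(seed)
    keep = n_residues - unfold_span
    attach = coords[keep - 1]
    direction = attach - coords[keep - 2]
    direction = direction / np.linalg.norm(direction)
    j = np.arange(1, unfold_span + 1)[:, None]
    # two tail extremes sharing the attachment point: a native-like compact
    # continuation (helical, delta Rg ~ 0) and a fully extended 3.8 A/step coil
    compact_tail = _helix(unfold_span + 1, attach, axis_z=1.0)[1:]
    extended_tail = attach + 3.8 * j * direction
    candidates = []
    extensions = np.linspace(0.06, 1.0, n_candidates)
    for k, ext in enumerate(extensions):
        wobble = 0.6 * rng.standard_normal((unfold_span, 3))
        tail = (1.0 - ext) * compact_tail + ext * extended_tail + wobble
        cand = AtomicModel(np.vstack([coords[:keep], tail]), elements, id=f"cand_{k:02d}")
        candidates.append(cand)
    return native, candidates


def default_ground_truth(config: GeneratorConfig, q: QGrid | None = None) -> dict:
    """Build the default simulation truth from toy structures.

    Returns a dict with the dark (background) profile, per-state basis
    spectra, the toy models, the index/delta-Rg of the "true" final-state
    candidate (the one nearest a 6 A radius-of-gyration increase) and the
    saturated full-conversion reference curve.
    """
    q = q if q is not None else QGrid.linear()
    native, candidates = make_toy_structures(seed=config.seed + 1)
    rg_native = radius_of_gyration(native)
    delta_rg = np.array([radius_of_gyration(c) - rg_native for c in candidates])
    true_idx = int(np.argmin(np.abs(delta_rg - 6.0)))

    i_native = debye_profile(native, q).intensity
    scale = config.photons_per_pulse_scale / i_native.sum()
    dark = i_native * scale

    diffs = [model_difference(c, native, q) * scale for c in candidates]
    final_bs = diffs[true_idx]
    if config.n_states == 3:
        # A: small prompt rearrangement; B: intermediate partial change; C: final state
        basis = np.vstack([0.10 * diffs[max(true_idx - 2, 0)],
                           0.45 * diffs[max(true_idx - 1, 0)],
                           final_bs])
    else:
        basis = np.vstack([0.10 * diffs[max(true_idx - 2, 0)], final_bs])
    if config.relative_signal is not None:
        basis = basis * (config.relative_signal * dark.max() / np.abs(basis).max())

    return {
        "q": q,
        "native": native,
        "candidates": candidates,
        "delta_rg": delta_rg,
        "true_candidate": true_idx,
        "dark_profile": dark,
        "basis_spectra": basis,
        "saturated_reference": basis[-1].copy(),
    }


def _shape_distortion(
    rng: np.random.Generator,
    q_values: np.ndarray,
    reference: np.ndarray,
    strength: float,
    threshold: float = 0.99995,
) -> np.ndarray:
    """Relative shape distortion (unit peak amplitude) for jet instability.

    A smooth random cubic in normalized q, decorrelated from the reference
    curve's own shape so a multiplicative distortion of amplitude ``strength``
    genuinely changes the profile shape; candidate polynomials are drawn until
    the distorted reference falls clearly below the correlation ``threshold``
    (the generator's contract is that corrupted trains are detectable).
    """
    x = (q_values - q_values[0]) / (q_values[-1] - q_values[0])
    margin = 1.0 - 2.0 * (1.0 - threshold)
    best, best_r = None, np.inf
    for _ in range(32):
        coeff = rng.standard_normal(4)
        poly = coeff[0] + coeff[1] * x + coeff[2] * x**2 + coeff[3] * x**3
        # component of reference*poly orthogonal to (constant, reference):
        # a multiplicative distortion along it changes the shape, not the scale
        w = reference * poly
        basis = np.column_stack([np.ones_like(reference), reference])
        w_perp = w - basis @ np.linalg.lstsq(basis, w, rcond=None)[0]
        sd_perp = w_perp.std()
        if sd_perp == 0:
            continue
        # scale so a distortion of amplitude `strength` moves the profile by
        # strength * sd(reference) orthogonally, i.e. 1 - r ~ strength^2 / 2
        rel = w_perp * (reference.std() / sd_perp) / np.where(reference > 0, reference, 1.0)
        factor = np.clip(1.0 + strength * rel, 0.05, None)
        r = np.corrcoef(reference * factor, reference)[0, 1]
        if r < best_r:
            best, best_r = rel, r
        if r < margin:
            return rel
    return best


def simulate_train_series(
    config: GeneratorConfig,
    dark_profile: np.ndarray | RadialProfile | None = None,
    basis_spectra: np.ndarray | None = None,
    q: QGrid | None = None,
) -> TrainSeries:
    """Generate an alternating light/dark pulse-train series.

    Dark-train pulse expectations are ``g_train * S_dark(q)``; light-train
    pulses add the kinetic signal ``yield * sum_i BS_i(q) C_i(t_j)`` before the
    shared train gain.  Counts are Poisson around the expectation unless
    ``config.poisson`` is off.  Trains selected for corruption get a smooth
    q-dependent shape distortion of relative amplitude ``corrupt_strength``.
    """
    rng = np.random.default_rng(config.seed)
    truth_extra: dict = {}
    if dark_profile is None or basis_spectra is None:
        gt = default_ground_truth(config, q=q)
        q = gt["q"]
        dark = gt["dark_profile"]
        basis = gt["basis_spectra"]
        truth_extra = {
            "delta_rg_true": gt["delta_rg"][gt["true_candidate"]],
            "true_candidate": gt["true_candidate"],
            "saturated_reference": gt["saturated_reference"],
        }
    else:
        if q is None:
            if isinstance(dark_profile, RadialProfile):
                q = dark_profile.q
            else:
                raise ValueError("q grid required with array inputs")
        dark = dark_profile.intensity if isinstance(dark_profile, RadialProfile) else np.asarray(dark_profile, float)
        basis = np.atleast_2d(np.asarray(basis_spectra, dtype=float))
        truth_extra = {"saturated_reference": basis[-1].copy()}
    if basis.shape[1] != len(q) or len(dark) != len(q):
        raise ValueError("dark profile and basis spectra must live on the q grid")
    if basis.shape[0] != config.n_states:
        raise ValueError(
            f"{config.n_states}-state kinetics needs {config.n_states} basis spectra, "
            f"got {basis.shape[0]}"
        )

    t_us = pulse_time_grid(config.pulses_per_train, config.intra_train_rate)
    model = SequentialModel(config.n_states, config.rates)
    conc = concentration_profiles(model, t_us)               # (n_pulses, n_states)
    signal = config.yield_c * conc @ basis                   # (n_pulses, n_q)

    n_trains = 2 * config.n_train_pairs
    light_flag = np.arange(n_trains) % 2 == 0
    light_expect = dark[None, :] + signal
    if np.any(light_expect < 0):
        raise ValueError("negative light-train expectation: basis spectra too large for background")

    n_corrupt = int(round(config.corrupt_fraction * n_trains))
    corrupted_ids = np.sort(rng.choice(n_trains, size=n_corrupt, replace=False)) if n_corrupt else np.array([], int)

    profiles = np.empty((n_trains, config.pulses_per_train, len(q)))
    # train-level common-mode gain: AR(1) across trains (jet thickness and
    # beam intensity drift slowly, which is what makes adjacent-train
    # subtraction better than arbitrary pairing), constant within a train
    z = rng.standard_normal(n_trains)
    rho = config.jitter_corr
    for i in range(1, n_trains):
        z[i] = rho * z[i - 1] + np.sqrt(1.0 - rho**2) * z[i]
    gains = 1.0 + config.jitter_sd * z
    for i in range(n_trains):
        expect = (light_expect if light_flag[i] else dark[None, :]) * gains[i]
        if i in corrupted_ids:
            rel = _shape_distortion(rng, q.values, dark, config.corrupt_strength)
            expect = expect * np.clip(1.0 + config.corrupt_strength * rel, 0.05, None)
        profiles[i] = rng.poisson(expect) if config.poisson else expect

    truth = {
        "rates": np.asarray(config.rates),
        "yield_c": config.yield_c,
        "basis_spectra": basis,
        "dark_profile": dark,
        "corrupted_ids": corrupted_ids,
        **truth_extra,
    }
    return TrainSeries(profiles=profiles, light_flag=light_flag, time_us=t_us, q=q, truth=truth)


def inject_instability(
    series: TrainSeries, ids, strength: float = 0.05, seed: int = 0
) -> TrainSeries:
    """Return a copy with the listed trains' shapes smoothly distorted.

    At the default strength the distorted trains fall below the 0.99995
    profile-correlation threshold of the train filter; untouched trains are
    bit-identical.  The injected ids are recorded in the truth block.
    """
    ids = np.asarray(ids, dtype=int)
    if np.any(ids < 0) or np.any(ids >= series.n_trains):
        raise ValueError("train ids out of range")
    rng = np.random.default_rng(seed)
    profiles = series.profiles.copy()
    for i in ids:
        if strength > 0:
            ref = series.profiles[i].mean(axis=0)
            rel = _shape_distortion(rng, series.q.values, ref, strength)
            profiles[i] = profiles[i] * np.clip(1.0 + strength * rel, 0.05, None)
    truth = dict(series.truth) if series.truth is not None else {}
    prev = np.asarray(truth.get("corrupted_ids", np.array([], int)), dtype=int)
    truth["corrupted_ids"] = np.union1d(prev, ids)
    return TrainSeries(
        profiles=profiles,
        light_flag=series.light_flag.copy(),
        time_us=series.time_us.copy(),
        q=series.q,
        truth=truth,
    )
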