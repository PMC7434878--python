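"""Population kinetics of the haem photocycle and IRF-convolved fit models.

The photocycle is modelled as a sequential first-order cascade: the
photoexcited porphyrin Q-state decays (``tau_Q``, ~100 fs) to an
intermediate triplet (S=1) haem, which decays (``tau_T``) to the high-spin
(S=2) domed deoxy form.  Ligand rebinding then drives the reverse
spin cross-over: the high-spin pool recombines through parallel first-order
channels (fast/slow geminate rebinding plus a nanosecond non-geminate
channel for ligands that escaped to the solvent) into a ligated high-spin
domed species, which relaxes back to the low-spin planar ground state.

All populations of linear first-order chains have closed forms (Bateman
solutions); the full recombination chain is propagated through the
eigendecomposition of its rate matrix, which is exact for distinct rates.

Every model observable is convolved with a Gaussian instrument response
analytically: an exponential convolved with a normalized Gaussian is the
exponentially-modified Gaussian, evaluated here in an overflow-safe
``erfcx`` formulation.

Times are femtoseconds throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eig
from scipy.special import erfc, erfcx

from .errors import ParameterError

__all__ = [
    "FWHM_TO_SIGMA",
    "KineticTrace",
    "ThreeLevelParams",
    "RecombinationParams",
    "RiseBiexpParams",
    "PopulationTrajectory",
    "bateman_sequential",
    "extend_with_recombination",
    "population_trajectory",
    "gaussian_irf_convolve_exp",
    "gaussian_irf_convolve_step",
    "rise_biexp_model",
    "rise_biexp_signal",
    "three_level_amplitude_model",
]

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Default IRF: the ~150 fs pump/probe cross-correlation read as a FWHM.
DEFAULT_IRF_SIGMA_FS = 150.0 * FWHM_TO_SIGMA

#: Relative rate difference below which the equal-rate limit form is used.
_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class ThreeLevelParams:
    """Sequential Q -> triplet -> high-spin cascade parameters (fs)."""

    tau_Q: float = 100.0
    tau_T: float = 500.0
    initial_Q: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_Q > 0 and self.tau_T > 0):
            raise ParameterError("lifetimes must be positive")
        if not (0 < self.initial_Q <= 1):
            raise ParameterError("initial_Q must lie in (0, 1]")


@dataclass(frozen=True)
class RecombinationParams:
    """Parallel recombination channels feeding the domed ligated state.

    ``branch_fast``/``branch_slow`` are the geminate rebinding fractions
    (distal pocket / Xe4 pocket); ``branch_escape`` is the fraction whose
    ligand escapes to the solvent and returns on the nanosecond
    non-geminate timescale.  The ligated high-spin domed species relaxes to
    the planar low-spin ground state with ``tau_domed_to_planar``.
    """

    tau_gem_fast: float = 10_000.0       # 10 ps
    tau_gem_slow: float = 200_000.0      # 200 ps
    tau_nongem: float = 1_500_000.0      # 1.5 ns
    tau_domed_to_planar: float = 30_000.0  # 30 ps
    branch_fast: float = 0.4
    branch_slow: float = 0.3
    branch_escape: float = 0.3

    def __post_init__(self) -> None:
        taus = (self.tau_gem_fast, self.tau_gem_slow, self.tau_nongem,
                self.tau_domed_to_planar)
        if any(t <= 0 for t in taus):
            raise ParameterError("all recombination lifetimes must be positive")
        branches = (self.branch_fast, self.branch_slow, self.branch_escape)
        if any(b < 0 for b in branches):
            raise ParameterError("branch fractions must be non-negative")
        if abs(sum(branches) - 1.0) > 1e-9:
            raise ParameterError(
                f"branch fractions must sum to 1, got {sum(branches)!r}")


@dataclass(frozen=True)
class RiseBiexpParams:
    """Phenomenological rise + biexponential decay observable (fs).

    The observable is the IRF-convolved
    ``theta(x) * (1 - exp(-x/tau_rise)) * (A1 exp(-x/tau1) + A2 exp(-x/tau2))``
    with ``x = t - t0`` (product form; a sum form is available through
    :func:`rise_biexp_model`).
    """

    t0: float = 0.0
    sigma_irf: float = DEFAULT_IRF_SIGMA_FS
    tau_rise: float = 800.0
    tau1: float = 30_000.0       # 30 ps
    tau2: float = 1_500_000.0    # 1.5 ns
    A1: float = 0.6
    A2: float = 0.4
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau_rise > 0 and self.tau1 > 0 and self.tau2 > 0):
            raise ParameterError("time constants must be positive")
        if not (self.tau_rise < self.tau1 < self.tau2):
            raise ParameterError(
                "time constants must be ordered tau_rise < tau1 < tau2")
        if self.A1 < 0 or self.A2 < 0:
            raise ParameterError("amplitudes must be non-negative")
        if self.sigma_irf <= 0:
            raise ParameterError("sigma_irf must be positive")


@dataclass
class KineticTrace:
    """Delay-binned marker values with 1-sigma uncertainties.

    ``marker_label`` names the observable: ``kbeta13_centroid_shift`` (eV),
    ``kalpha1_sigma`` (eV), or ``transient_amplitude_7053eV`` (normalized
    transient units).
    """

    delays: np.ndarray
    values: np.ndarray
    errors: np.ndarray
    marker_label: str = "kbeta13_centroid_shift"

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if not (self.delays.shape == self.values.shape == self.errors.shape):
            raise ParameterError("delays, values and errors must align")
        if np.any(np.diff(self.delays) <= 0):
            raise ParameterError("delays must be strictly increasing")
        if np.any(self.errors <= 0):
            raise ParameterError("errors must be positive")

    def restrict(self, max_delay_fs: float) -> "KineticTrace":
        """Trace restricted to delays <= ``max_delay_fs``."""
        m = self.delays <= max_delay_fs
        return KineticTrace(self.delays[m], self.values[m], self.errors[m],
                            self.marker_label)


@dataclass
class PopulationTrajectory:
    """Per-state populations on a time grid (fractions of the whole sample).

    ``populations`` maps state labels (``Q``, ``T``, ``HS``, ``domed``,
    ``ground``) to arrays on ``times``; ``unexcited`` is the constant
    fraction never promoted out of the ground state.
    """

    times: np.ndarray
    populations: dict[str, np.ndarray]
    unexcited: float

    def total(self) -> np.ndarray:
        """Sum of all tracked populations plus the unexcited fraction."""
        return sum(self.populations.values()) + self.unexcited


# ---------------------------------------------------------------------------
# Closed-form cascade populations
# ---------------------------------------------------------------------------

def bateman_sequential(t, params: ThreeLevelParams):
    """Populations (P_Q, P_T, P_HS) of the sequential three-level cascade.

    Closed-form first-order kinetics with rates ``k = 1/tau``::

        P_Q  = N exp(-k_Q t)
        P_T  = N k_Q/(k_T - k_Q) (exp(-k_Q t) - exp(-k_T t))
        P_HS = N - P_Q - P_T

    Negative times return zero excited population.  The degenerate case
    ``tau_Q == tau_T`` uses the exact limit ``P_T = N k t exp(-k t)``.
    """
    t = np.asarray(t, dtype=float)
    kQ, kT = 1.0 / params.tau_Q, 1.0 / params.tau_T
    N = params.initial_Q
    tp = np.where(t >= 0, t, 0.0)

    P_Q = N * np.exp(-kQ * tp)
    if abs(kT - kQ) <= _DEGENERATE_RTOL * kQ:
        P_T = N * kQ * tp * np.exp(-kQ * tp)
    else:
        P_T = N * kQ / (kT - kQ) * (np.exp(-kQ * tp) - np.exp(-kT * tp))
    P_HS = N - P_Q - P_T

    neg = t < 0
    P_Q = np.where(neg, 0.0, P_Q)
    P_T = np.where(neg, 0.0, P_T)
    P_HS = np.where(neg, 0.0, np.clip(P_HS, 0.0, None))
    return P_Q, P_T, P_HS


def _chain_rate_matrix(three: ThreeLevelParams, rec: RecombinationParams):
    """Rate matrix of the 7-state chain.

    State order: Q, T, HS_fast, HS_slow, HS_escaped, domed, ground.
    Columns sum to zero, so the total population is conserved exactly.
    """
    kQ, kT = 1.0 / three.tau_Q, 1.0 / three.tau_T
    kf = 1.0 / rec.tau_gem_fast
    ks = 1.0 / rec.tau_gem_slow
    ke = 1.0 / rec.tau_nongem
    kd = 1.0 / rec.tau_domed_to_planar

    K = np.zeros((7, 7))
    K[0, 0] = -kQ
    K[1, 0] = kQ
    K[1, 1] = -kT
    K[2, 1] = rec.branch_fast * kT
    K[3, 1] = rec.branch_slow * kT
    K[4, 1] = rec.branch_escape * kT
    K[2, 2] = -kf
    K[3, 3] = -ks
    K[4, 4] = -ke
    K[5, 2] = kf
    K[5, 3] = ks
    K[5, 4] = ke
    K[5, 5] = -kd
    K[6, 5] = kd
    return K


def population_trajectory(times, three: ThreeLevelParams,
                          rec: RecombinationParams | None = None,
                          excited_fraction: float = 1.0) -> PopulationTrajectory:
    """Exact populations of the full photocycle on a time grid.

    The linear chain is propagated through the eigendecomposition of its
    rate matrix; coincident rates are split by a 1e-9 relative nudge so the
    decomposition stays well conditioned (documented limit handling).
    ``excited_fraction`` scales the initially promoted population; the
    remainder is reported as ``unexcited``.
    """
    if not (0.0 <= excited_fraction <= 1.0):
        raise ParameterError("excited_fraction must lie in [0, 1]")
    times = np.asarray(times, dtype=float)
    if rec is None:
        rec = RecombinationParams()

    K = _chain_rate_matrix(three, rec)
    # split coincident decay rates so K is diagonalizable
    diag = np.diag(K).copy()
    for i in range(len(diag)):
        while any(abs(diag[i] - diag[j]) <= _DEGENERATE_RTOL * max(abs(diag[i]), 1e-30)
                  for j in range(i)):
            diag[i] *= 1.0 + 1e-7
    if not np.allclose(diag, np.diag(K)):
        scale = diag / np.where(np.diag(K) == 0, 1.0, np.diag(K))
        K = K * scale[np.newaxis, :]
        np.fill_diagonal(K, diag)

    w, V = eig(K)
    w, V = w.real, V.real
    p0 = np.zeros(7)
    p0[0] = excited_fraction * three.initial_Q
    c = np.linalg.solve(V, p0)

    tp = np.where(times >= 0, times, 0.0)
    P = (V @ (c[:, None] * np.exp(w[:, None] * tp[None, :])))  # (7, nt)
    P = np.where(times[None, :] < 0, 0.0, P)
    P = np.clip(P, 0.0, None)
    # before excitation the whole sample sits in the LS ground state
    P[6] = np.where(times < 0, excited_fraction * three.initial_Q, P[6])

    pops = {
        "Q": P[0],
        "T": P[1],
        "HS": P[2] + P[3] + P[4],
        "domed": P[5],
        "ground": P[6],
    }
    unexcited = 1.0 - excited_fraction * three.initial_Q
    return PopulationTrajectory(times=times, populations=pops,
                                unexcited=unexcited)


def extend_with_recombination(traj: PopulationTrajectory,
                              three: ThreeLevelParams,
                              rec: RecombinationParams) -> PopulationTrajectory:
    """Recompute a cascade-only trajectory with recombination branches.

    Convenience wrapper: takes the time grid and excited fraction of an
    existing trajectory and returns the full-photocycle populations on it.
    """
    excited = 1.0 - traj.unexcited
    return population_trajectory(traj.times, three, rec,
                                 excited_fraction=excited / three.initial_Q)


# ---------------------------------------------------------------------------
# Analytic Gaussian-IRF convolution
# ---------------------------------------------------------------------------

def gaussian_irf_convolve_exp(t, tau, t0, sigma):
    """Exponential decay convolved with a normalized Gaussian IRF.

    Closed form (exponentially-modified Gaussian)::

        0.5 * exp(sigma^2/(2 tau^2) - x/tau) * erfc(sigma/(sqrt2 tau) - x/(sqrt2 sigma))

    with ``x = t - t0``.  Where the exponential prefactor would overflow the
    scaled complement ``erfcx`` identity is used, giving finite output for
    all ``|x| <= 10 ns`` and ``sigma >= 1 fs``.
    """
    if tau <= 0 or sigma <= 0:
        raise ParameterError("tau and sigma must be positive")
    x = np.asarray(t, dtype=float) - t0
    a = sigma / (np.sqrt(2.0) * tau) - x / (np.sqrt(2.0) * sigma)
    out = np.empty_like(x)
    pos = a >= 0
    # erfc(a) = erfcx(a) exp(-a^2); the combined exponent is -x^2/(2 sigma^2)
    out[pos] = 0.5 * erfcx(a[pos]) * np.exp(-(x[pos] ** 2) / (2.0 * sigma ** 2))
    xn = x[~pos]
    out[~pos] = 0.5 * np.exp(sigma ** 2 / (2.0 * tau ** 2) - xn / tau) \
        * erfc(a[~pos])
    return out if out.ndim else float(out)


def gaussian_irf_convolve_step(t, t0, sigma):
    """Heaviside step convolved with a normalized Gaussian IRF."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    x = np.asarray(t, dtype=float) - t0
    out = 0.5 * erfc(-x / (np.sqrt(2.0) * sigma))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Fit model functions
# ---------------------------------------------------------------------------

def rise_biexp_signal(t, t0: float, sigma_irf: float, tau_rise: float,
                      tau1: float, tau2: float, A1: float, A2: float,
                      offset: float = 0.0, form: str = "product"):
    """Rise x biexponential observable without parameter-ordering checks.

    Used directly by fitting code, whose intermediate iterates may violate
    the ordering that :class:`RiseBiexpParams` enforces.
    """
    t = np.asarray(t, dtype=float)

    def E(tau):
        return gaussian_irf_convolve_exp(t, tau, t0, sigma_irf)

    if form == "product":
        tau_a = 1.0 / (1.0 / tau_rise + 1.0 / tau1)
        tau_b = 1.0 / (1.0 / tau_rise + 1.0 / tau2)
        sig = A1 * E(tau1) + A2 * E(tau2) - A1 * E(tau_a) - A2 * E(tau_b)
    elif form == "sum":
        sig = A1 * E(tau1) + A2 * E(tau2) - (A1 + A2) * E(tau_rise)
    else:
        raise ParameterError(f"unknown rise model form {form!r}")
    return sig + offset


def rise_biexp_model(t, params: RiseBiexpParams, form: str = "product"):
    """IRF-convolved rising component times (or plus) a biexponential decay.

    ``form="product"`` (default) is
    ``(1 - exp(-x/tau_rise)) * (A1 exp(-x/tau1) + A2 exp(-x/tau2))``,
    which expands exactly into four pure exponentials; each is convolved
    analytically.  ``form="sum"`` uses
    ``A1 exp(-x/tau1) + A2 exp(-x/tau2) - (A1+A2) exp(-x/tau_rise)``,
    which also starts from zero and rises with ``tau_rise``.
    """
    p = params
    return rise_biexp_signal(t, p.t0, p.sigma_irf, p.tau_rise, p.tau1,
                             p.tau2, p.A1, p.A2, p.offset, form)


def three_level_amplitude_model(t, params: ThreeLevelParams, c_T: float,
                                c_HS: float, t0: float, sigma: float):
    """Signal ``c_T * P_T(t) + c_HS * P_HS(t)`` with analytic IRF convolution.

    The Bateman populations are expanded into exponentials plus a step and
    each term is convolved with the Gaussian IRF in closed form.  The
    degenerate ``tau_Q == tau_T`` case is handled by a 1e-7 relative rate
    split (the convolved limit form is not needed at that accuracy).
    """
    t = np.asarray(t, dtype=float)
    kQ, kT = 1.0 / params.tau_Q, 1.0 / params.tau_T
    if abs(kT - kQ) <= _DEGENERATE_RTOL * kQ:
        kT = kQ * (1.0 + 1e-7)
    N = params.initial_Q

    EQ = gaussian_irf_convolve_exp(t, 1.0 / kQ, t0, sigma)
    ET = gaussian_irf_convolve_exp(t, 1.0 / kT, t0, sigma)
    step = gaussian_irf_convolve_step(t, t0, sigma)

    P_T = N * kQ / (kT - kQ) * (EQ - ET)
    P_HS = N * (step - kT / (kT - kQ) * EQ + kQ / (kT - kQ) * ET)
    return c_T * P_T + c_HS * P_HS
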