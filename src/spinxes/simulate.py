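"""Synthetic shot-level XFEL experiments with the statistics of the analysis.

Emulates a femtosecond pump-probe XES measurement at an FEL: per-shot
arrival-time jitter (Gaussian, sigma ~150 fs), a timing-tool estimate of the
jitter with its own measurement noise, 1:1 laser-on/laser-off interleaving,
a photoexcitation fraction times photolysis quantum yield setting the
observable amplitude, and Poisson photon-counting noise on every spectrum.
Everything is deterministic given the configured seed.

Shot reduction follows the standard FEL recipe: each shot's delay is
corrected by its timing-tool estimate, shots are sorted into delay bins,
and per-bin averaged laser-on/laser-off spectra yield the transients.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DataError, GridError, ParameterError
from .kinetics import (KineticTrace, RecombinationParams, RiseBiexpParams,
                       ThreeLevelParams, population_trajectory,
                       rise_biexp_model, three_level_amplitude_model)
from .spectral import (DifferenceSpectrum, EmissionSpectrum, SpectralFixture,
                       default_fixture, mix_spectra, synth_state_spectrum)

__all__ = [
    "ShotRecord",
    "ExperimentConfig",
    "DelayBin",
    "BinnedExperiment",
    "default_delay_schedule",
    "generate_experiment",
    "timing_sort_and_bin",
    "compute_transient",
    "generate_rise_biexp_trace",
    "generate_three_level_trace",
]


@dataclass
class ShotRecord:
    """One simulated detector readout.

    ``timing_tool_estimate`` = ``true_jitter`` + timing-tool measurement
    noise, by construction.  Laser-off shots carry delay-independent
    spectra.
    """

    shot_id: int
    nominal_delay: float
    true_jitter: float
    timing_tool_estimate: float
    laser_on: bool
    spectrum: EmissionSpectrum


def default_delay_schedule() -> np.ndarray:
    """Delay grid mirroring the measurement: dense 50 fs steps from
    -0.5 to +2 ps, then 25 log-spaced points out to 750 ps."""
    dense = np.arange(-500.0, 2000.0 + 1, 50.0)
    sparse = np.geomspace(2500.0, 750_000.0, 25)
    return np.concatenate([dense, sparse])


@dataclass
class ExperimentConfig:
    """Ground truth and statistical settings of a synthetic experiment."""

    delays: np.ndarray = field(default_factory=default_delay_schedule)
    shots_per_delay: int = 100
    jitter_sigma: float = 150.0
    timing_tool_noise_sigma: float = 10.0
    photon_budget: float = 50_000.0
    rng_seed: int = 0
    line_family: str = "Kbeta"
    three_level: ThreeLevelParams = field(default_factory=ThreeLevelParams)
    recombination: RecombinationParams = field(
        default_factory=RecombinationParams)
    fixture: SpectralFixture | None = None

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        if self.delays.size == 0:
            raise ConfigError("delay grid must not be empty")
        if self.shots_per_delay < 2:
            raise ConfigError("need at least 2 shots per delay (on/off pair)")
        if self.photon_budget <= 0:
            raise ConfigError("photon_budget must be positive")
        if self.jitter_sigma < 0 or self.timing_tool_noise_sigma < 0:
            raise ConfigError("jitter sigmas must be non-negative")
        if self.fixture is None:
            self.fixture = default_fixture()

    @property
    def excitation_fraction(self) -> float:
        return self.fixture.excitation_fraction

    @property
    def photolysis_qy(self) -> float:
        return self.fixture.photolysis_qy

    @property
    def excited_fraction(self) -> float:
        """Fraction of haems that photodissociate (excitation x QY)."""
        return self.fixture.excited_fraction

    def provenance(self) -> dict:
        """Seed and a stable hash of the configuration."""
        payload = {
            "delays": self.delays.tolist(),
            "shots_per_delay": self.shots_per_delay,
            "jitter_sigma": self.jitter_sigma,
            "timing_tool_noise_sigma": self.timing_tool_noise_sigma,
            "photon_budget": self.photon_budget,
            "line_family": self.line_family,
            "excitation_fraction": self.excitation_fraction,
            "photolysis_qy": self.photolysis_qy,
            "tau_Q": self.three_level.tau_Q,
            "tau_T": self.three_level.tau_T,
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
        return {"rng_seed": self.rng_seed, "config_hash": digest}


def _state_weights(config: ExperimentConfig, times: np.ndarray) -> np.ndarray:
    """(n_times, 3) spectral weights (LS, triplet, HS) of laser-on shots.

    The porphyrin Q-state and the recovered/unexcited ground state are
    spectrally low spin; the ligated domed species is spectrally high spin
    (K emission does not distinguish it from deoxy high spin).
    """
    traj = population_trajectory(times, config.three_level,
                                 config.recombination,
                                 excited_fraction=config.excited_fraction)
    p = traj.populations
    w_t = p["T"]
    w_hs = p["HS"] + p["domed"]
    w_ls = 1.0 - w_t - w_hs
    return np.column_stack([w_ls, w_t, w_hs])


def generate_experiment(config: ExperimentConfig) -> list[ShotRecord]:
    """Simulate the full interleaved laser-on/laser-off shot stream.

    For each nominal delay, ``shots_per_delay`` shots alternate laser-on
    and laser-off.  Laser-on spectra mix the per-state lineshapes at the
    populations of the effective (nominal + jitter) delay; expected counts
    are scaled to ``photon_budget`` per spectrum and drawn Poisson.
    """
    rng = np.random.default_rng(config.rng_seed)
    fixture = config.fixture
    family = config.line_family
    grid = fixture.grid(family)
    state_spectra = np.stack([
        s.intensity for s in fixture.state_spectra(family)])  # (3, nE)

    n_delays = config.delays.size
    n_shots = n_delays * config.shots_per_delay
    nominal = np.repeat(config.delays, config.shots_per_delay)
    jitter = rng.normal(0.0, config.jitter_sigma, n_shots)
    tt_noise = rng.normal(0.0, config.timing_tool_noise_sigma, n_shots)
    laser_on = (np.arange(n_shots) % 2) == 0

    weights = np.empty((n_shots, 3))
    weights[~laser_on] = [1.0, 0.0, 0.0]
    weights[laser_on] = _state_weights(config,
                                       nominal[laser_on] + jitter[laser_on])

    expected = weights @ state_spectra                       # (n_shots, nE)
    expected *= config.photon_budget / expected.sum(axis=1, keepdims=True)
    counts = rng.poisson(expected).astype(float)

    shots = []
    for i in range(n_shots):
        shots.append(ShotRecord(
            shot_id=i,
            nominal_delay=float(nominal[i]),
            true_jitter=float(jitter[i]),
            timing_tool_estimate=float(jitter[i] + tt_noise[i]),
            laser_on=bool(laser_on[i]),
            spectrum=EmissionSpectrum(grid, counts[i], family, "raw"),
        ))
    return shots


@dataclass
class DelayBin:
    """Averaged laser-on/laser-off spectra of one corrected-delay bin."""

    lo: float
    hi: float
    on: EmissionSpectrum | None
    off: EmissionSpectrum | None
    n_on: int
    n_off: int

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def usable(self) -> bool:
        """Transient computation needs both laser-on and laser-off shots."""
        return self.n_on > 0 and self.n_off > 0


@dataclass
class BinnedExperiment:
    bins: list[DelayBin]
    line_family: str

    def usable_bins(self) -> list[DelayBin]:
        return [b for b in self.bins if b.usable]


def _mean_spectrum(counts: np.ndarray, grid: np.ndarray, family: str,
                   delay: float) -> EmissionSpectrum:
    n = counts.shape[0]
    total = counts.sum(axis=0)
    # Poisson: var of the summed counts is the summed counts
    unc = np.sqrt(np.clip(total, 1.0, None)) / n
    return EmissionSpectrum(grid, total / n, family, "raw",
                            uncertainty=unc, delay_fs=delay)


def timing_sort_and_bin(shots: list[ShotRecord], bin_edges: np.ndarray,
                        use_timing_tool: bool = True) -> BinnedExperiment:
    """Sort shots by timing-tool-corrected delay and average per bin.

    Corrected delay = nominal + timing-tool estimate; bins are half-open
    ``[lo, hi)``.  Empty or laser-off-free bins are kept and flagged, never
    silently dropped.  ``use_timing_tool=False`` bins by nominal delay
    (for quantifying the jitter bias of unsorted analysis).
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise DataError("bin edges must be strictly increasing")
    if not shots:
        raise DataError("empty shot stream")
    grid = shots[0].spectrum.energy
    family = shots[0].spectrum.line_family

    corrected = np.array([
        s.nominal_delay + (s.timing_tool_estimate if use_timing_tool else 0.0)
        for s in shots])
    counts = np.stack([s.spectrum.intensity for s in shots])
    on_flags = np.array([s.laser_on for s in shots])
    idx = np.digitize(corrected, bin_edges) - 1

    bins = []
    for b in range(len(bin_edges) - 1):
        in_bin = idx == b
        on_sel = in_bin & on_flags
        off_sel = in_bin & ~on_flags
        center = 0.5 * (bin_edges[b] + bin_edges[b + 1])
        on = (_mean_spectrum(counts[on_sel], grid, family, center)
              if on_sel.any() else None)
        off = (_mean_spectrum(counts[off_sel], grid, family, center)
               if off_sel.any() else None)
        bins.append(DelayBin(lo=float(bin_edges[b]),
                             hi=float(bin_edges[b + 1]),
                             on=on, off=off,
                             n_on=int(on_sel.sum()),
                             n_off=int(off_sel.sum())))
    return BinnedExperiment(bins=bins, line_family=family)


def compute_transient(on: EmissionSpectrum,
                      off: EmissionSpectrum) -> DifferenceSpectrum:
    """Area-normalized laser-on minus laser-off difference spectrum.

    Both spectra are normalized to unit area over the full recorded window
    before subtraction, so the transient is invariant to overall count
    scale.  Per-point uncertainties are propagated from both inputs
    (normalization treated as a constant, the count-noise-dominant limit).
    """
    if on.energy.shape != off.energy.shape or \
            np.max(np.abs(on.energy - off.energy)) > 1e-9:
        raise GridError("laser-on and laser-off spectra must share a grid")
    on_n = on.area_normalized()
    off_n = off.area_normalized()
    unc = None
    if on_n.uncertainty is not None and off_n.uncertainty is not None:
        unc = np.hypot(on_n.uncertainty, off_n.uncertainty)
    return DifferenceSpectrum(on.energy,
                              on_n.intensity - off_n.intensity,
                              on.line_family, "area_normalized",
                              uncertainty=unc, delay_fs=on.delay_fs)


# ---------------------------------------------------------------------------
# Trace-level generators (ground truth directly in the fit-model family)
# ---------------------------------------------------------------------------

def generate_rise_biexp_trace(delays, params: RiseBiexpParams,
                              noise_fraction: float = 0.05,
                              rng: np.random.Generator | int | None = None,
                              marker_label: str = "kbeta13_centroid_shift",
                              ) -> KineticTrace:
    """Marker trace drawn from the rise x biexponential ground truth.

    Gaussian per-point noise at ``noise_fraction`` of the plateau
    amplitude ``A1 + A2``; the per-point 1-sigma errors are set to the
    true noise level.
    """
    rng = np.random.default_rng(rng)
    delays = np.asarray(delays, dtype=float)
    truth = rise_biexp_model(delays, params)
    sigma = noise_fraction * (params.A1 + params.A2)
    if sigma <= 0:
        raise ParameterError("noise_fraction and plateau must be positive")
    values = truth + rng.normal(0.0, sigma, delays.shape)
    return KineticTrace(delays, values, np.full(delays.shape, sigma),
                        marker_label)


def generate_three_level_trace(delays, three: ThreeLevelParams,
                               c_T: float, c_HS: float,
                               t0: float, sigma_irf: float,
                               noise_fraction: float = 0.10,
                               rng: np.random.Generator | int | None = None,
                               ) -> KineticTrace:
    """7053 eV transient-amplitude trace from the sequential cascade.

    Gaussian per-point noise at ``noise_fraction`` of the maximum absolute
    noiseless amplitude.
    """
    rng = np.random.default_rng(rng)
    delays = np.asarray(delays, dtype=float)
    truth = three_level_amplitude_model(delays, three, c_T, c_HS,
                                        t0, sigma_irf)
    sigma = noise_fraction * float(np.max(np.abs(truth)))
    if sigma <= 0:
        raise ParameterError("trace has zero amplitude")
    values = truth + rng.normal(0.0, sigma, delays.shape)
    return KineticTrace(delays, values, np.full(delays.shape, sigma),
                        "transient_amplitude_7053eV")
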