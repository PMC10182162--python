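"""Correlated pink-noise current stimuli for current-clamp simulations.

The stimulus emulates an idealized somatic current-clamp experiment: every
trial injects the same 3 s "frozen" broadband signal riding on a DC offset,
plus trial-unique noise that induces realistic trial-to-trial spike-time
variability.  Both the shared (parent) component and the per-trial noise are
built by convolving Gaussian white noise with an alpha kernel

    alpha(t) = (t / tau) * exp(-t / tau),    tau = 3 ms by default,

which low-passes the white noise into pink-ish broadband current.  A trial's
fluctuating part is the variance-preserving mixture

    sqrt(c) * parent + sqrt(1 - c) * unique_noise,

so the expected inter-trial Pearson correlation of the fluctuating component
equals ``trial_correlation = c`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from ._exceptions import InvalidParameterError

__all__ = [
    "AlphaKernel",
    "StimulusEnsemble",
    "make_alpha_kernel",
    "generate_stimulus_ensemble",
]


@dataclass(frozen=True)
class AlphaKernel:
    """Discretely sampled alpha function, peak-normalized to 1 at t = tau.

    Attributes
    ----------
    tau : float
        Time constant in ms; the kernel peaks at ``t = tau``.
    dt : float
        Sample interval in ms.
    values : ndarray
        Kernel samples at t = 0, dt, 2*dt, ...; nonnegative, unimodal,
        decaying toward zero at the end of the support.
    """

    tau: float
    dt: float
    values: np.ndarray = field(repr=False)

    @property
    def support_ms(self) -> float:
        return (len(self.values) - 1) * self.dt


def make_alpha_kernel(tau: float = 3.0, dt: float = 0.025, support: float | None = None) -> AlphaKernel:
    """Sample the alpha function on a finite support.

    Parameters
    ----------
    tau : float
        Time constant in ms (> 0).  The raw function (t/tau)exp(-t/tau)
        attains its maximum e^-1 at t = tau; the returned kernel is divided
        by that maximum so its peak is 1 (normalization convention: unit
        peak, not unit area).
    dt : float
        Sampling step in ms (> 0).
    support : float, optional
        Kernel length in ms.  Defaults to ``10 * tau``; must be at least
        ``5 * tau`` so the truncated tail is negligible
        (alpha(5 tau)/alpha(tau) = 5 e^-4 < 1%).
    """
    if tau <= 0 or dt <= 0:
        raise InvalidParameterError(f"tau and dt must be positive, got tau={tau}, dt={dt}")
    if support is None:
        support = 10.0 * tau
    if support < 5.0 * tau:
        raise InvalidParameterError(f"support must be >= 5*tau ({5 * tau} ms), got {support}")
    t = np.arange(0.0, support + 0.5 * dt, dt)
    raw = (t / tau) * np.exp(-t / tau)
    return AlphaKernel(tau=tau, dt=dt, values=raw / np.exp(-1.0))


@dataclass
class StimulusEnsemble:
    """A set of injected-current waveforms sharing a frozen parent signal.

    ``waveforms`` is an ``n_trials x n_samples`` matrix in current units
    (uA/cm^2 for the bundled point-neuron model); rows are trials.
    """

    dt: float
    duration: float
    n_trials: int
    dc_offset: float
    noise_sd: float
    trial_correlation: float
    parent_seed: int
    noise_seed: int
    tau: float
    waveforms: np.ndarray = field(repr=False)

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def bin_average(self, bin_width: float = 1.0) -> np.ndarray:
        """Average each trial within consecutive ``bin_width``-ms bins.

        Used to downsample the integration-rate stimulus (e.g. 40 kHz) to
        the GLM bin rate (1 kHz) before building design matrices.
        """
        per_bin = int(round(bin_width / self.dt))
        n_bins = self.n_samples // per_bin
        w = self.waveforms[:, : n_bins * per_bin]
        return w.reshape(self.n_trials, n_bins, per_bin).mean(axis=2)


def _filtered_unit_noise(rng: np.random.Generator, shape: tuple[int, ...], kernel: AlphaKernel,
                         n_samples: int) -> np.ndarray:
    """White noise convolved causally with the kernel, scaled to unit SD.

    Convolution is 'full' mode truncated to ``n_samples``: the first few
    samples contain the kernel ramp-in, matching a causal filter switched
    on at t = 0.
    """
    white = rng.standard_normal(shape)
    out = fftconvolve(white, kernel.values[None, :] if white.ndim == 2 else kernel.values,
                      mode="full", axes=-1)[..., :n_samples]
    sd = out.std()
    if sd > 0:
        out = out / sd
    return out


def generate_stimulus_ensemble(
    tau: float = 3.0,
    dt: float = 0.025,
    duration: float = 3000.0,
    n_trials: int = 100,
    dc_offset: float = 3.5,
    noise_sd: float = 2.0,
    trial_correlation: float = 0.8,
    parent_seed: int = 0,
    noise_seed: int = 1,
) -> StimulusEnsemble:
    """Generate the correlated pink-noise stimulus ensemble.

    Each trial equals ``dc_offset + noise_sd * (sqrt(c)*parent +
    sqrt(1-c)*unique)`` where parent and unique components are unit-SD
    alpha-filtered Gaussian noise.  ``c = 1`` makes all trials identical
    (pure frozen noise); ``c = 0`` makes them independent.

    The DC offset and noise SD defaults are calibrated so the bundled
    point-neuron model fires at a moderate rate (roughly 20 Hz at control
    conductance, a few Hz at the strongest A-type scaling); they are free
    parameters, not physical constants.

    Reproducible bit-for-bit given ``(parent_seed, noise_seed)``.
    """
    if not 0.0 <= trial_correlation <= 1.0:
        raise InvalidParameterError(f"trial_correlation must be in [0, 1], got {trial_correlation}")
    if n_trials < 1:
        raise InvalidParameterError(f"n_trials must be >= 1, got {n_trials}")
    kernel = make_alpha_kernel(tau=tau, dt=dt)
    n_samples = int(round(duration / dt))

    parent_rng = np.random.Generator(np.random.PCG64(parent_seed))
    noise_rng = np.random.Generator(np.random.PCG64(noise_seed))

    parent = _filtered_unit_noise(parent_rng, (n_samples + len(kernel.values),), kernel, n_samples)
    unique = _filtered_unit_noise(noise_rng, (n_trials, n_samples + len(kernel.values)), kernel, n_samples)

    c = trial_correlation
    fluct = np.sqrt(c) * parent[None, :] + np.sqrt(1.0 - c) * unique
    waveforms = dc_offset + noise_sd * fluct
    if noise_sd == 0.0:
        waveforms = np.full((n_trials, n_samples), float(dc_offset))

    return StimulusEnsemble(
        dt=dt, duration=duration, n_trials=n_trials, dc_offset=dc_offset,
        noise_sd=noise_sd, trial_correlation=trial_correlation,
        parent_seed=parent_seed, noise_seed=noise_seed, tau=tau,
        waveforms=waveforms,
    )
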