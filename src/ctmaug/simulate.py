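"""Artificial source-signal generation from a fitted corticothalamic model.

Two interchangeable generators are provided: direct time-domain integration of
the linearized model driven by white sensory noise, and frequency-domain
synthesis drawing random Fourier coefficients against the analytic spectrum.
The two act as mutual cross-checks — their long-run spectra must agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import signal as sps

from . import _kernels
from .core import CTMGains, PowerSpectrum, SpectrumGrid, analytic_spectrum, canonical_factorization
from .errors import ConfigError, DegenerateSignal, Instability, TooShort

__all__ = [
    "SimConfig",
    "SourceSignal",
    "impulse_response",
    "simulate_source",
    "welch_spectrum",
    "calibrate_amplitude",
    "segment_epochs",
]

#: spatial modes lighter than this (relative to the k=0 weight) are dropped
_MODE_WEIGHT_FLOOR = 1e-10


@dataclass
class SimConfig:
    """Integration / synthesis settings.

    ``grid_n`` counts spatial grid nodes per sheet side; 1 selects the
    spatially uniform mode only, larger (odd) values include wave modes up to
    ``m_max = (grid_n - 1) // 2`` per axis, matching an analytic-spectrum grid
    of the same order.
    """

    dt: float = 1e-4          # integration step, s (adjusted down to divide t0/2)
    duration: float = 60.0    # total simulated time incl. burn-in, s
    fs_out: float = 250.0     # output sampling rate, Hz
    burn_in: float = 2.0      # discarded initial transient, s
    grid_n: int = 1
    seed: int = 0
    method: Literal["time_domain", "spectral_synthesis"] = "time_domain"
    noise_scale: float = 1.0  # multiplier on the sensory-drive standard deviation
    sheet: SpectrumGrid = field(default_factory=SpectrumGrid)

    def __post_init__(self) -> None:
        if self.duration <= self.burn_in:
            raise ConfigError("duration must exceed burn_in")
        if self.fs_out > 1.0 / self.dt:
            raise ConfigError("fs_out cannot exceed the integration rate 1/dt")
        if self.grid_n < 1:
            raise ConfigError("grid_n must be >= 1")

    @property
    def m_max(self) -> int:
        return (self.grid_n - 1) // 2

    def resolve_step(self, t0: float, max_rate: float) -> tuple[float, int]:
        """Snap dt downward so the half-loop delay is an integer step count."""
        if self.dt > 0.5 / max_rate:
            raise ConfigError(
                f"dt={self.dt} too coarse for rates up to {max_rate:.0f} s^-1")
        half = t0 / 2.0
        n_delay = int(np.ceil(half / self.dt - 1e-12))
        return half / n_delay, n_delay


@dataclass
class SourceSignal:
    """A simulated continuous source signal with provenance."""

    samples: np.ndarray
    fs: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def scaled(self, factor: float) -> "SourceSignal":
        return SourceSignal(self.samples * factor, self.fs,
                            {**self.provenance, "scale": factor})


def impulse_response(t, alpha: float, beta: float):
    """Dendritic impulse kernel: the time-domain pair of the dendritic filter.

    Uses the confluent branch ``alpha**2 * t * exp(-alpha t)`` when the two
    rates are within 1e-8 relative.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be strictly positive")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    if abs(beta - alpha) / alpha < 1e-8:
        out[pos] = alpha ** 2 * t[pos] * np.exp(-alpha * t[pos])
    else:
        c = alpha * beta / (beta - alpha)
        out[pos] = c * (np.exp(-alpha * t[pos]) - np.exp(-beta * t[pos]))
    return out if out.ndim else float(out)


def _sim_modes(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Unique k^2 values and sqrt-weights for the requested mode order."""
    sheet = replace(cfg.sheet, m_max=cfg.m_max)
    k2, w = sheet.mode_weights()
    keep = w >= _MODE_WEIGHT_FLOOR * w.max()
    return k2[keep], np.sqrt(w[keep])


def simulate_source(g: CTMGains, cfg: SimConfig) -> SourceSignal:
    """Generate a source signal from gains ``g`` under ``cfg``.

    The time-domain method integrates, per retained spatial mode, the
    second-order dendritic equations with half-loop delay buffers and the
    damped-wave operator for the excitatory field, driven by white noise at
    the thalamic relay.  The spectral method inverse-transforms random Fourier
    coefficients with expected power matching the analytic spectrum.  Both are
    bit-reproducible for a fixed seed and configuration.
    """
    if cfg.method == "spectral_synthesis":
        return _synthesize_spectral(g, cfg)

    fac = canonical_factorization(g)
    # The drive enters at the relay and reaches the cortex through G_es; its
    # strength is chosen so the product along that path equals `amplitude`.
    # For a degenerate G_ese = 0 the coupling is carried entirely by the drive.
    G_es_sim = fac["G_es"] if fac["G_es"] > 0 else 1.0
    G_se_sim = g.G_ese / G_es_sim
    # 1/sqrt(2): the white drive's variance is split across positive and
    # negative frequencies, while the analytic spectrum is one-sided.
    drive = cfg.noise_scale * g.amplitude / (G_es_sim * np.sqrt(2.0))
    max_rate = max(g.alpha, g.beta, g.gamma_e)
    dt, n_delay = cfg.resolve_step(g.t0, max_rate)
    n_steps = int(round(cfg.duration / dt))
    burn_steps = int(round(cfg.burn_in / dt))
    k2, sqrt_w = _sim_modes(cfg)
    raw, ok = _kernels.integrate_modes(
        n_steps, burn_steps, dt, n_delay,
        g.G_ee, g.G_ei, G_es_sim, G_se_sim, fac["G_sr"],
        fac["G_re"], fac["G_rs"],
        g.alpha, g.beta, g.gamma_e, k2 * g.r_e ** 2, sqrt_w, drive,
        np.uint32(cfg.seed))
    if not ok:
        raise Instability(
            f"time-domain state diverged for gains {g.as_array().round(3)}")

    fs_sim = 1.0 / dt
    n_out = int(round((cfg.duration - cfg.burn_in) * cfg.fs_out))
    if cfg.fs_out < fs_sim:
        sos = sps.butter(8, 0.45 * cfg.fs_out / (fs_sim / 2.0), output="sos")
        raw = sps.sosfiltfilt(sos, raw)
    t_out = np.arange(n_out) / cfg.fs_out
    samples = np.interp(t_out, np.arange(raw.size) * dt, raw)
    return SourceSignal(samples, cfg.fs_out, provenance={
        "gains": g, "seed": cfg.seed, "method": "time_domain",
        "dt": dt, "duration": cfg.duration, "grid_n": cfg.grid_n,
        "noise_scale": cfg.noise_scale,
    })


def _synthesize_spectral(g: CTMGains, cfg: SimConfig) -> SourceSignal:
    n_out = int(round((cfg.duration - cfg.burn_in) * cfg.fs_out))
    freqs = np.fft.rfftfreq(n_out, 1.0 / cfg.fs_out)
    sheet = replace(cfg.sheet, m_max=cfg.m_max)
    P = np.zeros_like(freqs)
    P[1:] = analytic_spectrum(g, sheet, freqs[1:]).power
    P *= cfg.noise_scale ** 2
    rng = np.random.default_rng(cfg.seed)
    re_, im_ = rng.standard_normal(freqs.size), rng.standard_normal(freqs.size)
    coef = np.sqrt(cfg.fs_out * n_out * P / 2.0) * (re_ + 1j * im_) / np.sqrt(2.0)
    coef[0] = 0.0
    if n_out % 2 == 0:
        coef[-1] = np.sqrt(cfg.fs_out * n_out * P[-1]) * re_[-1]
    samples = np.fft.irfft(coef, n=n_out)
    return SourceSignal(samples, cfg.fs_out, provenance={
        "gains": g, "seed": cfg.seed, "method": "spectral_synthesis",
        "duration": cfg.duration, "grid_n": cfg.grid_n,
        "noise_scale": cfg.noise_scale,
    })


def welch_spectrum(s: SourceSignal, seg_seconds: float = 4.0) -> PowerSpectrum:
    """Welch periodogram (one-sided density) of a source signal."""
    nper = min(s.samples.size, int(round(seg_seconds * s.fs)))
    f, p = sps.welch(s.samples, fs=s.fs, nperseg=nper)
    return PowerSpectrum(f[1:], p[1:], units="signal^2/Hz")


def band_power_of(s: SourceSignal, band: tuple[float, float]) -> float:
    """Integrated Welch power of ``s`` over ``band`` (Hz)."""
    ps = welch_spectrum(s)
    return ps.band_power(band)


def calibrate_amplitude(s: SourceSignal, target: PowerSpectrum,
                        band: tuple[float, float] = (8.0, 30.0)) -> SourceSignal:
    """Rescale ``s`` by one positive scalar to match the target's band power."""
    if band[0] < target.freqs[0] or band[1] > target.freqs[-1]:
        raise ValueError("band outside the target spectrum's frequency range")
    own = band_power_of(s, band)
    if own <= 0 or not np.isfinite(own):
        raise DegenerateSignal("cannot calibrate a zero-power signal")
    factor = float(np.sqrt(target.band_power(band) / own))
    return s.scaled(factor)


def segment_epochs(s: SourceSignal, epoch_len: float) -> np.ndarray:
    """Cut a continuous signal into contiguous non-overlapping epochs.

    Returns an ``(n_epochs, n_samples)`` array; a trailing remainder shorter
    than one epoch is dropped.
    """
    n_samp = int(round(epoch_len * s.fs))
    n_ep = s.samples.size // n_samp
    if n_ep < 1:
        raise TooShort(
            f"signal of {s.samples.size} samples is shorter than one epoch "
            f"({n_samp} samples)")
    return s.samples[: n_ep * n_samp].reshape(n_ep, n_samp).copy()
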