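"""Fitting corticothalamic gains to an experimental power spectrum by MCMC.

The sampler is a single-parameter-at-a-time random-walk Metropolis chain on
the eight identifiable parameters (two cortical gains, three loop gains, the
synaptic rates and the loop delay) inside a literature-typical prior box.  The
overall spectral amplitude is profiled out of the objective in closed form, so
the fit is invariant to the absolute calibration of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import periodogram

from . import _kernels
from .core import CTMGains, PowerSpectrum, SpectrumGrid, analytic_spectrum
from .errors import Instability, LengthMismatch, NoStableInit

__all__ = [
    "FitConfig",
    "FitResult",
    "epoch_average_spectrum",
    "spectrum_objective",
    "stability_check",
    "fit_ctm_mcmc",
]

# prior box: (low, high) per fitted parameter, order matching CTMGains.as_array()
_DEFAULT_BOUNDS = {
    "G_ee": (0.0, 25.0),
    "G_ei": (-25.0, 0.0),
    "G_ese": (0.0, 40.0),
    "G_esre": (-40.0, 0.0),
    "G_srs": (-10.0, 0.0),
    "alpha": (20.0, 200.0),
    "beta": (20.0, 800.0),   # additionally constrained to beta >= alpha
    "t0": (0.06, 0.14),
}
_PARAM_ORDER = tuple(_DEFAULT_BOUNDS)


@dataclass
class FitConfig:
    band: tuple[float, float] = (8.0, 30.0)
    n_chains: int = 2
    n_steps: int = 20_000
    burn_in_steps: int = 2_000      # adaptation phase, discarded from diagnostics
    proposal_frac: float = 0.05     # initial proposal sd as fraction of box width
    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    seed: int = 0
    gamma_e: float = 116.0          # held fixed (not identifiable from band shape)
    r_e: float = 0.086
    grid: SpectrumGrid = field(default_factory=SpectrumGrid)
    ratio_ceiling: float = 1e4      # stability screen: peak/median power ceiling
    max_init_draws: int = 2000
    init_pool: int = 256            # stable prior draws screened for chain starts
    log_noise_sd: float = 0.05      # assumed per-bin sd of log10 power residuals
    polish: bool = True             # simplex refinement of the best sample

    def __post_init__(self) -> None:
        if self.band[0] >= self.band[1]:
            raise ValueError("band must satisfy f_lo < f_hi")
        if self.n_steps <= self.burn_in_steps:
            raise ValueError("n_steps must exceed burn_in_steps")
        for name, (lo, hi) in self.bounds.items():
            d_lo, d_hi = _DEFAULT_BOUNDS[name]
            if lo > hi or (d_lo >= 0 and lo < 0) or (d_hi <= 0 and hi > 0):
                raise ValueError(f"bounds for {name} violate its sign invariant")

    def box_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[k][0] for k in _PARAM_ORDER])
        hi = np.array([self.bounds[k][1] for k in _PARAM_ORDER])
        return lo, hi


@dataclass
class FitResult:
    map_gains: CTMGains
    chain: np.ndarray              # (n_chains, n_steps, 8) post-warmup samples
    objectives: np.ndarray         # (n_chains, n_steps)
    acceptance_rate: float
    converged: bool
    r_hat: dict
    shape_error: float             # band mean relative error, fitted vs target

    @property
    def best_objective(self) -> float:
        return float(self.objectives.min())


def epoch_average_spectrum(source_epochs: Sequence[np.ndarray] | np.ndarray,
                           fs: float) -> PowerSpectrum:
    """Per-epoch periodogram averaged across epochs.

    Uses the one-sided density normalization under which summing power times
    the bin width recovers the epoch's mean squared amplitude (Parseval).
    """
    epochs = np.asarray(source_epochs, dtype=float)
    if epochs.ndim == 1:
        epochs = epochs[None, :]
    if epochs.ndim != 2 or epochs.shape[0] < 1:
        raise LengthMismatch("need a 2-D stack of equal-length epochs")
    f, p = periodogram(epochs, fs=fs, window="boxcar", detrend=False, axis=-1)
    return PowerSpectrum(f, p.mean(axis=0), units="signal^2/Hz")


def _band_target(target: PowerSpectrum, band: tuple[float, float]):
    sel = (target.freqs >= band[0]) & (target.freqs <= band[1])
    if sel.sum() < 4:
        raise ValueError("target spectrum has too few bins inside the fit band")
    if np.any(target.power[sel] <= 0):
        raise ValueError("target power must be strictly positive on the band")
    return target.freqs[sel], np.log10(target.power[sel])


def spectrum_objective(g: CTMGains, target: PowerSpectrum,
                       cfg: FitConfig | None = None) -> float:
    """Band log-power misfit with the multiplicative scale profiled out.

    Zero iff the model's band shape matches the target's exactly on the grid;
    infinite for unstable parameter sets.
    """
    cfg = cfg if cfg is not None else FitConfig()
    freqs, log_t = _band_target(target, cfg.band)
    try:
        model = analytic_spectrum(g, cfg.grid, freqs)
    except Instability:
        return np.inf
    r = np.log10(model.power) - log_t
    r -= r.mean()
    return float((r ** 2).sum())


def stability_check(g: CTMGains, cfg: FitConfig | None = None) -> bool:
    """Screen for near-bifurcation parameter sets.

    True iff the analytic spectrum is finite and positive on a dense
    0.5-45 Hz grid and the peak-to-median power ratio stays below the
    configured ceiling (a proxy for a pole approaching the real axis).
    """
    cfg = cfg if cfg is not None else FitConfig()
    freqs = np.arange(0.5, 45.0 + 1e-9, 0.25)
    try:
        ps = analytic_spectrum(g, cfg.grid, freqs)
    except Instability:
        return False
    return bool(ps.power.max() <= cfg.ratio_ceiling * np.median(ps.power))


def _gains_from_vector(x: np.ndarray, cfg: FitConfig,
                       amplitude: float = 1.0) -> CTMGains:
    d = dict(zip(_PARAM_ORDER, (float(v) for v in x)))
    return CTMGains(amplitude=amplitude, gamma_e=cfg.gamma_e, r_e=cfg.r_e, **d)


def fit_ctm_mcmc(target: PowerSpectrum, cfg: FitConfig | None = None) -> FitResult:
    """Fit gains to a measured spectrum's band shape by random-walk Metropolis.

    Chains start from uniform stable draws inside the prior box; proposal
    scales adapt during the warm-up phase.  The best-objective sample over all
    chains becomes ``map_gains``, with its amplitude set so the fitted band
    power matches the target's.  Deterministic for a fixed config seed.
    """
    cfg = cfg if cfg is not None else FitConfig()
    freqs, log_t = _band_target(target, cfg.band)
    omega = 2.0 * np.pi * freqs
    omega_dense = 2.0 * np.pi * np.arange(0.5, 45.0 + 1e-9, 0.25)
    k2, kw = cfg.grid.mode_weights()
    keep = kw >= 1e-10 * kw.max()   # drop modes killed by volume conduction
    k2, kw = k2[keep], kw[keep]
    lo, hi = cfg.box_arrays()
    prop = cfg.proposal_frac * (hi - lo)

    rng = np.random.default_rng(cfg.seed)
    # Draw a pool of stable prior points and start the chains from the ones
    # with the lowest misfit: the objective surface is multimodal and a chain
    # rarely escapes a poor basin within its step budget.
    pool, pool_f = [], []
    for _ in range(cfg.max_init_draws):
        cand = rng.uniform(lo, hi)
        if cand[6] < cand[5]:
            cand[5], cand[6] = cand[6], cand[5]  # enforce beta >= alpha
        if _kernels.spectrum_is_stable(cand, cfg.gamma_e, cfg.r_e,
                                       omega_dense, k2, kw, cfg.ratio_ceiling):
            pool.append(cand)
            pool_f.append(_kernels.shape_objective(
                cand, cfg.gamma_e, cfg.r_e, omega, k2, kw, log_t))
        if len(pool) >= cfg.init_pool:
            break
    if not pool:
        raise NoStableInit(
            f"no stable initialization in {cfg.max_init_draws} prior draws")
    order = np.argsort(pool_f)

    chains, objs, rates = [], [], []
    best_x, best_f = None, np.inf
    for c in range(cfg.n_chains):
        x0 = pool[order[min(c, len(pool) - 1)]]
        chain_seed = int(rng.integers(0, 2**31 - 1))
        inv_temp = 1.0 / (2.0 * cfg.log_noise_sd ** 2)
        chain, obj, best, fbest, rate = _kernels.metropolis_chain(
            x0, lo, hi, prop.copy(), cfg.n_steps, cfg.burn_in_steps,
            cfg.gamma_e, cfg.r_e, omega, k2, kw, log_t,
            omega_dense, cfg.ratio_ceiling, inv_temp, np.uint32(chain_seed))
        chains.append(chain[cfg.burn_in_steps:])
        objs.append(obj[cfg.burn_in_steps:])
        rates.append(rate)
        if cfg.polish:
            best, fbest = _polish(best, fbest, lo, hi, cfg, omega, k2, kw,
                                  log_t, omega_dense)
        if fbest < best_f:
            best_f, best_x = fbest, best

    if cfg.polish:
        # Deterministic multistart guard: refine the two best screened prior
        # points as well, in case every chain settled in a poor basin.
        for j in order[:2]:
            cand, fcand = _polish(pool[j], pool_f[j], lo, hi, cfg, omega,
                                  k2, kw, log_t, omega_dense)
            if fcand < best_f:
                best_f, best_x = fcand, cand

    chains_arr = np.stack(chains)
    objs_arr = np.stack(objs)
    r_hat = {name: _split_rhat(chains_arr[:, :, i])
             for i, name in zip((7, 5), ("t0", "alpha"))}
    converged = all(v < 1.1 for v in r_hat.values())

    # profile the amplitude back in: match band log-power levels exactly
    model = analytic_spectrum(_gains_from_vector(best_x, cfg), cfg.grid, freqs)
    log_scale = float(np.mean(log_t - np.log10(model.power)))
    amplitude = 10.0 ** (log_scale / 2.0)
    map_gains = _gains_from_vector(best_x, cfg, amplitude=amplitude)

    fitted = model.power * 10.0 ** log_scale
    target_band = 10.0 ** log_t
    shape_error = float(np.mean(np.abs(fitted - target_band) / target_band))
    return FitResult(
        map_gains=map_gains,
        chain=chains_arr,
        objectives=objs_arr,
        acceptance_rate=float(np.mean(rates)),
        converged=bool(converged),
        r_hat=r_hat,
        shape_error=shape_error,
    )


def _polish(x, fx, lo, hi, cfg, omega, k2, kw, log_t, omega_dense):
    """Deterministic simplex refinement of the best MCMC sample.

    Stays inside the prior box and the stability screen; returns the input
    unchanged if no improvement is found.
    """
    from scipy.optimize import minimize

    def fun(v):
        if np.any(v < lo) or np.any(v > hi) or v[6] < v[5]:
            return 1e6
        if not _kernels.spectrum_is_stable(v, cfg.gamma_e, cfg.r_e,
                                           omega_dense, k2, kw,
                                           cfg.ratio_ceiling):
            return 1e6
        return _kernels.shape_objective(v, cfg.gamma_e, cfg.r_e, omega,
                                        k2, kw, log_t)

    res = minimize(fun, x, method="Nelder-Mead",
                   options={"maxfev": 2000, "xatol": 1e-8, "fatol": 1e-12})
    if res.fun < fx:
        return res.x, float(res.fun)
    return x, fx


def _split_rhat(samples: np.ndarray) -> float:
    """Split-chain potential scale reduction factor on one scalar parameter."""
    half = samples.shape[1] // 2
    seqs = np.concatenate([samples[:, :half], samples[:, half:2 * half]], axis=0)
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    w = seqs.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))
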