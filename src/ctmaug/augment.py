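"""Training-data augmentation: model-based source generation and a noise baseline.

The model-based route fits the corticothalamic model to each condition's
average CSP-source spectrum, optionally jitters the physiological parameters
(synaptic decay rate, cortical damping, loop delay), simulates new source
time series, and cuts them into artificial epochs.  The baseline draws new
feature vectors from a variance-inflated Gaussian fitted per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import CTMGains, PowerSpectrum, analytic_spectrum
from .errors import CountMismatch, Instability, SingularCovariance, TooManyUnstableDraws
from .fit import FitConfig, epoch_average_spectrum, fit_ctm_mcmc, stability_check
from .pipeline import CSPModel, EpochSet, FeatureMatrix, apply_csp, bandpass, extract_features
from .simulate import SimConfig, SourceSignal, segment_epochs, simulate_source, welch_spectrum

__all__ = [
    "JitterSpec",
    "AugmentedSources",
    "jitter_draws",
    "nft_augment",
    "assemble_training_features",
    "noise_augment",
    "NFTStrategy",
    "NoiseStrategy",
]

#: literature-typical parameter spreads used to scale the jitter
SIGMA_TYPICAL = {"alpha": 14.0, "gamma_e": 25.0, "t0": 0.003}


@dataclass
class JitterSpec:
    """Which parameters to jitter and how widely.

    Each target parameter receives independent zero-mean Gaussian
    perturbations with standard deviation ``scale * sigma_typical``; loop
    gains are never jittered (perturbing them risks crossing a bifurcation
    and producing a qualitatively different spectrum).
    """

    targets: tuple[str, ...] = ("t0",)
    sigma_typical: Mapping[str, float] = field(
        default_factory=lambda: dict(SIGMA_TYPICAL))
    scale: float = 1.5
    draws_per_factor: int = 10

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("scale must be nonnegative")
        bad = set(self.targets) - set(self.sigma_typical)
        if bad:
            raise ValueError(f"jitter targets without a typical spread: {bad}")


@dataclass
class AugmentedSources:
    """Generated source epochs per condition per CSP, with provenance."""

    epochs: dict      # condition -> {csp index -> (n_epochs, n_samples) array}
    fs: float
    provenance: dict = field(default_factory=dict)

    def n_epochs(self, condition) -> int:
        per_csp = self.epochs[condition]
        counts = {arr.shape[0] for arr in per_csp.values()}
        if len(counts) != 1:
            raise CountMismatch(f"unequal epoch counts across CSPs: {counts}")
        return counts.pop()


def jitter_draws(g: CTMGains, spec: JitterSpec, factor: float,
                 seed: int = 0, max_retries: int = 100,
                 fit_cfg: FitConfig | None = None) -> list[CTMGains]:
    """Draw ``round(draws_per_factor * factor)`` jittered parameter sets.

    Draws failing the stability screen (or basic parameter validity) are
    redrawn up to ``max_retries`` times each.
    """
    n = int(round(spec.draws_per_factor * factor))
    rng = np.random.default_rng(seed)
    out = []
    n_redrawn = 0
    for _ in range(n):
        for attempt in range(max_retries + 1):
            kw = {}
            for name in spec.targets:
                sd = spec.scale * spec.sigma_typical[name]
                kw[name] = getattr(g, name) + rng.normal(0.0, sd)
            try:
                cand = g.replace(**kw)
            except ValueError:
                n_redrawn += 1
                continue
            if spec.scale == 0 or stability_check(cand, fit_cfg):
                out.append(cand)
                break
            n_redrawn += 1
        else:
            raise TooManyUnstableDraws(
                f"exceeded {max_retries} redraws for a jitter sample")
    jitter_draws.last_redraws = n_redrawn  # audit hook for tests/logging
    return out


def _generate_epochs(g_fit: CTMGains, draws: list[CTMGains],
                     target: PowerSpectrum, n_needed: int, epoch_len: float,
                     fs: float, band: tuple[float, float],
                     sim_cfg: SimConfig, seeds: list[int]) -> np.ndarray:
    """Simulate per draw (round-robin), calibrate band power, cut epochs.

    Every draw's signal is band-passed with the pipeline filter and scaled so
    its band power equals the experimental target's, times the analytic
    band-power ratio between the jittered and the fitted parameter set (so
    jitter-induced power changes survive the calibration).
    """
    base_bp = target.band_power(band)
    fine = np.arange(0.5, 45.0 + 1e-9, 0.25)
    fit_bp = analytic_spectrum(g_fit, freqs=fine).band_power(band)

    counts = np.full(len(draws), n_needed // len(draws), dtype=int)
    counts[: n_needed % len(draws)] += 1
    chunks = []
    for d, (g_d, cnt) in enumerate(zip(draws, counts)):
        if cnt == 0:
            continue
        dur = cnt * epoch_len + sim_cfg.burn_in
        cfg = SimConfig(dt=sim_cfg.dt, duration=dur, fs_out=fs,
                        burn_in=sim_cfg.burn_in, grid_n=sim_cfg.grid_n,
                        seed=seeds[d], method=sim_cfg.method,
                        sheet=sim_cfg.sheet)
        try:
            sig = simulate_source(g_d, cfg)
        except Instability:
            # The spectral screen tests the real frequency axis only; a fit
            # can still carry a growing mode.  The linearized model driven by
            # Gaussian noise is a stationary Gaussian process determined by
            # its spectrum, so synthesizing against the analytic spectrum is
            # a distributionally equivalent generator that cannot diverge.
            cfg = SimConfig(dt=sim_cfg.dt, duration=dur, fs_out=fs,
                            burn_in=sim_cfg.burn_in, grid_n=sim_cfg.grid_n,
                            seed=seeds[d], method="spectral_synthesis",
                            sheet=sim_cfg.sheet)
            sig = simulate_source(g_d, cfg)
        carrier = EpochSet(sig.samples[None, None, :], fs,
                           np.array(["x"]))
        filtered = bandpass(carrier, band[0], band[1]).data[0, 0]
        sig_f = SourceSignal(filtered, fs, sig.provenance)
        own_bp = welch_spectrum(sig_f).band_power(band)
        ratio = (analytic_spectrum(g_d, freqs=fine).band_power(band) / fit_bp
                 if g_d is not g_fit else 1.0)
        scale = np.sqrt(base_bp * ratio / own_bp)
        chunks.append(segment_epochs(sig_f.scaled(scale), epoch_len)[:cnt])
    return np.vstack(chunks)


def nft_augment(train: EpochSet, csp: CSPModel, factor: float,
                spec: JitterSpec | None = None,
                fit_cfg: FitConfig | None = None,
                sim_cfg: SimConfig | None = None,
                seed: int = 0) -> AugmentedSources:
    """Model-based augmentation at the CSP-source level.

    For each condition and each CSP source: average the training epochs'
    spectra, fit the corticothalamic model to the average, optionally jitter
    the fitted parameters, simulate continuous source signals (cycling the
    draws round-robin over the required epochs), calibrate their band power
    and segment into epochs of the training epoch length.

    ``train`` must contain only training-fold epochs and ``csp`` must have
    been fitted on them alone — augmentation must never see validation data.
    """
    fit_cfg = fit_cfg if fit_cfg is not None else FitConfig()
    sim_cfg = sim_cfg if sim_cfg is not None else SimConfig()
    sources = apply_csp(csp, train)
    epoch_len = train.data.shape[2] / train.fs
    band = fit_cfg.band
    ss = np.random.SeedSequence([int(seed), 0xA46])
    out: dict = {}
    prov: dict = {"factor": factor, "seed": seed, "fits": {}}
    for cond in sources.conditions:
        eps_c = sources.data[sources.labels == cond]
        n_train = eps_c.shape[0]
        n_needed = int(round(factor * n_train))
        out[cond] = {}
        for j in range(csp.n_csp):
            child = ss.spawn(1)[0]
            ints = child.generate_state(2 + 10 * max(1, int(np.ceil(factor))) + 64)
            target = epoch_average_spectrum(eps_c[:, j, :], train.fs)
            f_cfg = FitConfig(**{**fit_cfg.__dict__, "seed": int(ints[0] % (2**31 - 1))})
            fit = fit_ctm_mcmc(target, f_cfg)
            if spec is not None:
                draws = jitter_draws(fit.map_gains, spec, factor,
                                     seed=int(ints[1] % (2**31 - 1)),
                                     fit_cfg=fit_cfg)
            else:
                draws = [fit.map_gains]
            sim_seeds = [int(v % (2**31 - 1)) for v in ints[2:2 + len(draws)]]
            out[cond][j] = _generate_epochs(
                fit.map_gains, draws, target, n_needed, epoch_len,
                train.fs, band, sim_cfg, sim_seeds)
            prov["fits"][(str(cond), j)] = {
                "map_gains": fit.map_gains, "shape_error": fit.shape_error,
                "n_draws": len(draws),
            }
    return AugmentedSources(epochs=out, fs=train.fs, provenance=prov)


def assemble_training_features(real_sources: EpochSet, aug: AugmentedSources | None,
                               feature: str = "TP",
                               hfd_n_max: int = 10) -> FeatureMatrix:
    """Real feature rows followed by artificial rows aligned across CSPs.

    The i-th artificial row of a condition combines the i-th generated epoch
    of every CSP source (the simulations are independent across sources, so
    any alignment is statistically equivalent; index alignment keeps it
    reproducible).
    """
    real = extract_features(real_sources, feature, hfd_n_max)
    if aug is None:
        return real
    rows, labels = [], []
    for cond, per_csp in aug.epochs.items():
        n_art = aug.n_epochs(cond)
        csp_ids = sorted(per_csp)
        for i in range(n_art):
            row = []
            for j in csp_ids:
                x = per_csp[j][i]
                if feature.upper() == "TP":
                    row.append(np.mean(x ** 2))
                else:
                    from .pipeline import higuchi_fd
                    row.append(higuchi_fd(x, hfd_n_max))
            rows.append(row)
            labels.append(cond)
    if not rows:
        return real
    art = FeatureMatrix(np.asarray(rows), np.asarray(labels),
                        list(real.feature_names))
    return real.concat(art)


def noise_augment(f: FeatureMatrix, factor: float, scale: float = 1.5,
                  seed: int = 0) -> FeatureMatrix:
    """Feature-space Gaussian baseline.

    Per condition, draws ``factor`` times the condition's row count from a
    Gaussian with the condition's sample mean and ``scale`` times its sample
    covariance, and appends the draws to the input features.
    """
    rng = np.random.default_rng(seed)
    conds = np.unique(f.labels)
    n_feat = f.values.shape[1]
    rows, labels = [], []
    for c in conds:
        block = f.values[f.labels == c]
        if block.shape[0] < n_feat + 1:
            raise SingularCovariance(
                f"condition {c}: need >= {n_feat + 1} rows for a covariance")
        mu = block.mean(axis=0)
        cov = np.cov(block, rowvar=False)
        n_new = int(round(factor * block.shape[0]))
        if n_new:
            draws = rng.multivariate_normal(mu, scale * np.atleast_2d(cov),
                                            size=n_new, method="svd")
            rows.append(draws)
            labels.extend([c] * n_new)
    if not rows:
        return f
    art = FeatureMatrix(np.vstack(rows), np.asarray(labels),
                        list(f.feature_names))
    return f.concat(art)


# ---------------------------------------------------------------------------
# strategy objects for the evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class NFTStrategy:
    """Model-based augmentation strategy usable in the evaluation protocol."""

    factor: float = 2.0
    jitter: JitterSpec | None = None
    fit_cfg: FitConfig = field(default_factory=FitConfig)
    sim_cfg: SimConfig = field(default_factory=SimConfig)

    @property
    def name(self) -> str:
        jit = f" jitter[{','.join(self.jitter.targets)}]" if self.jitter else ""
        return f"NFT x{self.factor:g}{jit}"

    def training_features(self, train_bp: EpochSet, csp: CSPModel,
                          sources: EpochSet, feats_real: FeatureMatrix,
                          feature: str, hfd_n_max: int, seed: int) -> FeatureMatrix:
        if self.factor == 0:
            return feats_real
        aug = nft_augment(train_bp, csp, self.factor, self.jitter,
                          self.fit_cfg, self.sim_cfg, seed=seed)
        return assemble_training_features(sources, aug, feature, hfd_n_max)


@dataclass
class NoiseStrategy:
    """Feature-space Gaussian-noise augmentation strategy."""

    factor: float = 2.0
    scale: float = 1.5

    @property
    def name(self) -> str:
        return f"noise x{self.factor:g}"

    def training_features(self, train_bp: EpochSet, csp: CSPModel,
                          sources: EpochSet, feats_real: FeatureMatrix,
                          feature: str, hfd_n_max: int, seed: int) -> FeatureMatrix:
        if self.factor == 0:
            return feats_real
        return noise_augment(feats_real, self.factor, self.scale, seed=seed)
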