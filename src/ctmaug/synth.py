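"""Synthetic motor-imagery cohorts with a planted, model-generated class effect.

Each subject's epochs are built from corticothalamic sources: two
"discriminative" sources whose parameters swap between conditions (mimicking
contralateral sensorimotor power asymmetry) plus one condition-independent
background source, mixed into EEG channels through fixed smooth topographies,
with white sensor noise on top.  Because the class contrast is planted through
model parameters, the augmentation fit is well-specified on these fixtures:
the model family contains the ground truth.

An alternative surrogate mode replaces the model sources with AR(2)
oscillators so pipeline robustness can be probed under model mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import CTMGains, default_gains
from .io import read_epochs, write_epochs
from .pipeline import EpochSet
from .simulate import SimConfig, segment_epochs, simulate_source

__all__ = [
    "CohortSpec",
    "default_class_params",
    "make_subject",
    "make_cohort",
    "read_epochs",
    "write_epochs",
]


def default_class_params() -> tuple[CTMGains, CTMGains]:
    """Condition-specific source parameters: a delay and band-power contrast.

    The two conditions differ in loop delay (10 ms apart, shifting the alpha
    and beta resonances) and in drive amplitude (a ~2x band-power asymmetry,
    the scale of sensorimotor desynchronization).
    """
    hi = default_gains(t0=0.080, amplitude=1.60)
    lo = default_gains(t0=0.090, amplitude=0.80)
    return hi, lo


def _default_mixing(n_sources: int, n_channels: int) -> np.ndarray:
    """Smooth unimodal topographies (Gaussian bumps over the channel axis)."""
    centers = np.linspace(0.25, 0.75, n_sources) * (n_channels - 1)
    width = max(n_channels / 9.0, 1.0)
    ch = np.arange(n_channels)
    pats = np.stack([np.exp(-0.5 * ((ch - c) / width) ** 2) for c in centers])
    return pats / np.linalg.norm(pats, axis=1, keepdims=True)


@dataclass
class CohortSpec:
    """Geometry and physics of a synthetic two-condition cohort."""

    n_subjects: int = 12
    n_epochs_per_condition: int = 72
    fs: float = 250.0
    n_channels: int = 22
    epoch_len: float = 2.5
    class_params: tuple[CTMGains, CTMGains] = field(
        default_factory=default_class_params)
    background: CTMGains = field(default_factory=lambda: default_gains(amplitude=0.7))
    mixing_patterns: np.ndarray | None = None   # (n_sources=3, n_channels)
    sensor_noise_sd: float = 1.0
    subject_noise_range: tuple[float, float] = (1.0, 25.0)  # per-subject multiplier
    subject_jitter_t0: float = 0.0015   # s, subject-specific offset sd
    subject_jitter_amp: float = 0.08    # relative amplitude offset sd
    epoch_power_jitter: float = 0.30    # lognormal sd of per-epoch source amplitude
    conditions: tuple[str, str] = ("left", "right")
    mode: str = "ctm"                   # "ctm" | "ar2" (model-mismatch surrogate)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_epochs_per_condition < 1:
            raise ValueError("counts must be positive")
        if self.mixing_patterns is None:
            self.mixing_patterns = _default_mixing(3, self.n_channels)
        self.mixing_patterns = np.asarray(self.mixing_patterns, dtype=float)
        if self.mixing_patterns.shape != (3, self.n_channels):
            raise ValueError("mixing_patterns must be (3, n_channels)")
        if np.linalg.matrix_rank(self.mixing_patterns) < 3:
            raise ValueError("mixing patterns must have full row rank")


def _ar2_source(peak_hz: float, fs: float, n: int, amp: float,
                rng: np.random.Generator) -> np.ndarray:
    """AR(2) oscillator surrogate with a resonance at ``peak_hz``."""
    r = 0.97
    theta = 2 * np.pi * peak_hz / fs
    a = [1.0, -2 * r * np.cos(theta), r ** 2]
    x = sps.lfilter([1.0], a, rng.standard_normal(n + 500))[500:]
    return amp * x / x.std()


def _simulate_sources(spec: CohortSpec, cond_idx: int,
                      subj_gains: list[CTMGains], seeds: list[int],
                      rng: np.random.Generator) -> np.ndarray:
    """(3, n_epochs, n_samples): contralateral pair + background."""
    n_ep = spec.n_epochs_per_condition
    dur = n_ep * spec.epoch_len + 2.0
    # source 0 expresses this condition's parameters, source 1 the other's
    order = [cond_idx, 1 - cond_idx]
    gains = [subj_gains[order[0]], subj_gains[order[1]], subj_gains[2]]
    out = np.empty((3, n_ep, int(round(spec.epoch_len * spec.fs))))
    for s, g in enumerate(gains):
        if spec.mode == "ar2":
            peak = 1.0 / g.t0 * 0.85
            sig = _ar2_source(peak, spec.fs, int(round(dur * spec.fs)),
                              g.amplitude, rng)
            eps = sig[: n_ep * out.shape[2]].reshape(n_ep, -1)
        else:
            cfg = SimConfig(duration=dur, fs_out=spec.fs, burn_in=2.0,
                            seed=seeds[s])
            eps = segment_epochs(simulate_source(g, cfg), spec.epoch_len)[:n_ep]
        if spec.epoch_power_jitter > 0:
            # slow inter-epoch power fluctuation (ERD/ERS-like nonstationarity)
            eps = eps * np.exp(rng.normal(0.0, spec.epoch_power_jitter,
                                          size=(n_ep, 1)))
        out[s] = eps
    return out


def make_subject(spec: CohortSpec, subject_index: int) -> EpochSet:
    """Generate one subject's labeled epochs, deterministic in (seed, index)."""
    ss = np.random.SeedSequence([spec.seed, subject_index, 0x5EED])
    rng = np.random.default_rng(ss)
    sim_seeds = [int(v % (2**31 - 1)) for v in ss.generate_state(8)]

    # subject-specific physiology offsets, shared across conditions
    def offset(g: CTMGains) -> CTMGains:
        return g.replace(
            t0=float(np.clip(g.t0 + rng.normal(0, spec.subject_jitter_t0),
                             0.065, 0.135)),
            amplitude=float(g.amplitude
                            * np.exp(rng.normal(0, spec.subject_jitter_amp))),
        )

    subj_gains = [offset(spec.class_params[0]), offset(spec.class_params[1]),
                  offset(spec.background)]
    lo_m, hi_m = spec.subject_noise_range
    frac = 0.5 if spec.n_subjects == 1 else subject_index / (spec.n_subjects - 1)
    noise_sd = spec.sensor_noise_sd * lo_m * (hi_m / lo_m) ** frac

    n_ep = spec.n_epochs_per_condition
    n_samp = int(round(spec.epoch_len * spec.fs))
    data = np.empty((2 * n_ep, spec.n_channels, n_samp))
    labels = np.empty(2 * n_ep, dtype=object)
    for c, cond in enumerate(spec.conditions):
        srcs = _simulate_sources(spec, c, subj_gains,
                                 sim_seeds[4 * c:4 * c + 4], rng)
        mixed = np.einsum("sen,sc->ecn", srcs, spec.mixing_patterns)
        mixed += noise_sd * rng.standard_normal(mixed.shape)
        data[c * n_ep:(c + 1) * n_ep] = mixed
        labels[c * n_ep:(c + 1) * n_ep] = cond
    perm = rng.permutation(2 * n_ep)
    return EpochSet(data[perm], spec.fs, np.array(labels[perm], dtype=str),
                    subject_id=f"synth{subject_index:02d}")


def make_cohort(spec: CohortSpec, n: int | None = None) -> list[EpochSet]:
    """Independent subjects spanning a range of sensor-noise levels.

    The per-subject noise multiplier sweeps ``subject_noise_range``
    geometrically across the cohort, producing heterogeneous baseline
    accuracies (strong performers at the quiet end, near-chance at the noisy
    end) so that subject filtering and proficiency thresholds have something
    to act on.
    """
    n = n if n is not None else spec.n_subjects
    spec = replace(spec, n_subjects=n)
    return [make_subject(spec, i) for i in range(n)]
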