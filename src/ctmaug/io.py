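"""Persistence: HDF5 epoch containers, spectrum CSV, parameter text files,
and an optional GDF reader for the BCI Competition IV '2a' recordings."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .core import CTMGains, PowerSpectrum
from .errors import FormatError
from .pipeline import EpochSet

__all__ = [
    "write_epochs",
    "read_epochs",
    "write_source_signal",
    "read_source_signal",
    "write_fit_result",
    "read_fit_result",
    "spectrum_to_csv",
    "spectrum_from_csv",
    "gains_to_text",
    "gains_from_text",
    "load_bci2a_session",
]

_GAIN_FIELDS = ("G_ee", "G_ei", "G_ese", "G_esre", "G_srs", "amplitude",
                "alpha", "beta", "t0", "gamma_e", "r_e")


def _gains_to_attrs(g: CTMGains, group) -> None:
    for name in _GAIN_FIELDS:
        group.attrs[name] = float(getattr(g, name))


def _gains_from_attrs(group) -> CTMGains:
    return CTMGains(**{name: float(group.attrs[name]) for name in _GAIN_FIELDS})


def write_epochs(e: EpochSet, path) -> None:
    """Persist an epoch set losslessly (data, labels, rate, channel names)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=e.data)
        f.create_dataset("labels", data=np.asarray(e.labels, dtype="S"))
        f.attrs["fs"] = float(e.fs)
        f.attrs["subject_id"] = e.subject_id
        f.attrs["channel_names"] = [str(c) for c in e.channel_names]


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        for name in ("data", "labels"):
            if name not in f:
                raise FormatError(f"missing dataset '{name}' in {path}")
        for attr in ("fs",):
            if attr not in f.attrs:
                raise FormatError(f"missing attribute '{attr}' in {path}")
        return EpochSet(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            labels=np.array([v.decode() for v in f["labels"][()]]),
            subject_id=str(f.attrs.get("subject_id", "")),
            channel_names=[str(c) for c in f.attrs.get("channel_names", [])],
        )


def write_source_signal(s, path) -> None:
    """Persist a simulated source signal with its generation provenance."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=s.samples)
        f.attrs["fs"] = float(s.fs)
        prov = f.create_group("provenance")
        for key, val in s.provenance.items():
            if isinstance(val, CTMGains):
                _gains_to_attrs(val, prov.create_group("gains"))
            elif isinstance(val, (int, float, str)):
                prov.attrs[key] = val


def read_source_signal(path):
    from .simulate import SourceSignal

    with h5py.File(path, "r") as f:
        if "samples" not in f:
            raise FormatError(f"missing dataset 'samples' in {path}")
        prov = {}
        if "provenance" in f:
            prov.update({k: (v.item() if hasattr(v, "item") else v)
                         for k, v in f["provenance"].attrs.items()})
            if "gains" in f["provenance"]:
                prov["gains"] = _gains_from_attrs(f["provenance"]["gains"])
        return SourceSignal(f["samples"][()], float(f.attrs["fs"]), prov)


def write_fit_result(res, path) -> None:
    """Persist an MCMC fit: chains, objectives and the selected parameter set."""
    with h5py.File(path, "w") as f:
        f.create_dataset("chain", data=res.chain)
        f.create_dataset("objectives", data=res.objectives)
        _gains_to_attrs(res.map_gains, f.create_group("map_gains"))
        f.attrs["acceptance_rate"] = res.acceptance_rate
        f.attrs["converged"] = bool(res.converged)
        f.attrs["shape_error"] = res.shape_error
        for key, val in res.r_hat.items():
            f.attrs[f"r_hat_{key}"] = float(val)


def read_fit_result(path):
    from .fit import FitResult

    with h5py.File(path, "r") as f:
        for name in ("chain", "objectives"):
            if name not in f:
                raise FormatError(f"missing dataset '{name}' in {path}")
        r_hat = {k[len("r_hat_"):]: float(v) for k, v in f.attrs.items()
                 if k.startswith("r_hat_")}
        return FitResult(
            map_gains=_gains_from_attrs(f["map_gains"]),
            chain=f["chain"][()],
            objectives=f["objectives"][()],
            acceptance_rate=float(f.attrs["acceptance_rate"]),
            converged=bool(f.attrs["converged"]),
            r_hat=r_hat,
            shape_error=float(f.attrs["shape_error"]),
        )


def spectrum_to_csv(ps: PowerSpectrum, path) -> None:
    arr = np.column_stack([ps.freqs, ps.power])
    np.savetxt(path, arr, delimiter=",", header="frequency_hz,power", comments="")


def spectrum_from_csv(path) -> PowerSpectrum:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns frequency_hz,power")
    return PowerSpectrum(arr[:, 0], arr[:, 1])


# Units are spelled out in the key names so a parameter file is unambiguous
# on its own.
_GAIN_KEYS = {
    "G_ee": "G_ee", "G_ei": "G_ei", "G_ese": "G_ese", "G_esre": "G_esre",
    "G_srs": "G_srs", "amplitude_au": "amplitude", "alpha_per_s": "alpha",
    "beta_per_s": "beta", "t0_s": "t0", "gamma_e_per_s": "gamma_e",
    "r_e_m": "r_e",
}


def gains_to_text(g: CTMGains, path) -> None:
    lines = [f"{key} = {getattr(g, attr)!r}" for key, attr in _GAIN_KEYS.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def gains_from_text(path) -> CTMGains:
    kw = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}: malformed line {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in _GAIN_KEYS:
            raise FormatError(f"{path}: unknown parameter key {key!r}")
        kw[_GAIN_KEYS[key]] = float(val)
    missing = set(_GAIN_KEYS.values()) - set(kw)
    if missing:
        raise FormatError(f"{path}: missing parameters {sorted(missing)}")
    return CTMGains(**kw)


def load_bci2a_session(path, mi_window: tuple[float, float] = (2.5, 5.0),
                       drop_bad: bool = True) -> EpochSet:
    """Read one BCI Competition IV '2a' GDF session as a two-class epoch set.

    Extracts the left-hand/right-hand cue trials (event codes 769/770), cuts
    the motor-imagery window relative to trial onset (code 768), keeps the 22
    EEG channels, and drops trials flagged as artifactual (code 1023) when
    ``drop_bad`` is set.  Requires :mod:`mne`.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading GDF files requires the optional 'mne' "
                          "dependency (pip install ctmaug[gdf])") from exc
    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    eeg_picks = [i for i, name in enumerate(raw.ch_names)
                 if not name.upper().startswith("EOG")][:22]
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    code = {str(k).strip(): v for k, v in event_id.items()}
    fs = float(raw.info["sfreq"])
    want = {"769": "left", "770": "right"}
    bad_onsets = set(events[events[:, 2] == code.get("1023", -1), 0].tolist())
    data, labels = [], []
    lo = int(round(mi_window[0] * fs))
    hi = int(round(mi_window[1] * fs))
    trial_starts = events[events[:, 2] == code.get("768", -2), 0]
    sig = raw.get_data(picks=eeg_picks)
    for sample, _, ev in events:
        key = next((k for k, v in code.items() if v == ev and k in want), None)
        if key is None:
            continue
        starts = trial_starts[trial_starts <= sample]
        start = int(starts[-1]) if starts.size else int(sample - round(2.0 * fs))
        if drop_bad and any(abs(int(b) - start) < round(2.0 * fs)
                            for b in bad_onsets):
            continue
        seg = sig[:, start + lo:start + hi]
        if seg.shape[1] == hi - lo:
            data.append(seg)
            labels.append(want[key])
    if not data:
        raise FormatError(f"{path}: no usable left/right-hand trials found")
    return EpochSet(np.stack(data), fs, np.array(labels),
                    subject_id=Path(path).stem,
                    channel_names=[raw.ch_names[i] for i in eeg_picks])
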