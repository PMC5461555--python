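"""Plain-text and HDF5 serialisation of the package's data objects.

Formats
-------
* Continuous synthetic EEG: HDF5 with ``/data`` (``sequences x channels x
  samples`` or ``channels x samples``), ``/fs`` and ``/channel_names``.
* Stimulus sequences: CSV with columns ``sequence_id, frame_index,
  luminance`` (0-1 normalised).
* Event tables: TSV with columns ``sequence_id, frame_index, outcome``
  (hit/miss) and a ``catch`` flag.
* IRFs: HDF5 with ``/kernel``, ``/fs``, ``/lags_ms``.
* Phase tensors: HDF5 with ``/coeffs_real``, ``/coeffs_imag``, ``/freqs``,
  ``/cycles``, ``/times``, ``/valid_mask`` and ``/fs``.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .containers import Irf, TrialTensor
from .errors import InvalidInputError
from .spectral import PhaseTensor, WaveletPlan

__all__ = [
    "save_continuous_h5", "load_continuous_h5",
    "save_sequences_csv", "load_sequences_csv",
    "save_events_tsv", "load_events_tsv",
    "save_irf_h5", "load_irf_h5",
    "save_phase_tensor_h5", "load_phase_tensor_h5",
]


def save_continuous_h5(path, tensor: TrialTensor,
                       channel_names: list[str] | None = None) -> None:
    names = channel_names or [f"ch{i}" for i in range(tensor.n_channels)]
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=tensor.data)
        fh.create_dataset("fs", data=tensor.fs)
        fh.create_dataset("t0_ms", data=tensor.t0_ms)
        fh.create_dataset("channel_names",
                          data=np.array(names, dtype=h5py.string_dtype()))


def load_continuous_h5(path) -> tuple[TrialTensor, list[str]]:
    with h5py.File(path, "r") as fh:
        data = fh["data"][()]
        fs = float(fh["fs"][()])
        t0 = float(fh["t0_ms"][()]) if "t0_ms" in fh else 0.0
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in fh["channel_names"][()]]
    if data.ndim == 2:       # channels x samples -> one continuous "trial"
        data = data[None, :, :]
    return TrialTensor(data, fs=fs, t0_ms=t0), names


def save_sequences_csv(path, sequences: np.ndarray) -> None:
    sequences = np.atleast_2d(sequences)
    n_seq, n_frames = sequences.shape
    frame = np.tile(np.arange(n_frames), n_seq)
    seq = np.repeat(np.arange(n_seq), n_frames)
    pd.DataFrame(
        {"sequence_id": seq, "frame_index": frame,
         "luminance": sequences.reshape(-1)}
    ).to_csv(path, index=False)


def load_sequences_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("sequence_id", "frame_index", "luminance"):
        if col not in df.columns:
            raise InvalidInputError(f"sequence CSV is missing column {col!r}")
    wide = df.pivot(index="sequence_id", columns="frame_index",
                    values="luminance").sort_index()
    return wide.to_numpy()


def save_events_tsv(path, events: pd.DataFrame) -> None:
    cols = ["sequence_id", "frame_index", "outcome", "catch"]
    out = events.copy()
    if "catch" not in out.columns:
        out["catch"] = False
    out[cols].to_csv(path, sep="\t", index=False)


def load_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sequence_id", "frame_index", "outcome"):
        if col not in df.columns:
            raise InvalidInputError(f"event TSV is missing column {col!r}")
    if "catch" not in df.columns:
        df["catch"] = False
    df["catch"] = df["catch"].astype(bool)
    return df


def save_irf_h5(path, irf: Irf) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("kernel", data=irf.kernel)
        fh.create_dataset("fs", data=irf.fs)
        fh.create_dataset("lags_ms", data=irf.lags_ms)


def load_irf_h5(path) -> Irf:
    with h5py.File(path, "r") as fh:
        kernel = fh["kernel"][()]
        fs = float(fh["fs"][()])
        lags = fh["lags_ms"][()]
    return Irf(kernel=kernel, fs=fs, lag0_ms=float(lags[0]))


def save_phase_tensor_h5(path, pt: PhaseTensor) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("coeffs_real", data=pt.coeffs.real)
        fh.create_dataset("coeffs_imag", data=pt.coeffs.imag)
        fh.create_dataset("freqs", data=pt.plan.freqs)
        fh.create_dataset("cycles", data=pt.plan.cycles)
        fh.create_dataset("times", data=pt.times_ms)
        fh.create_dataset("valid_mask", data=pt.valid)
        fh.create_dataset("fs", data=pt.plan.fs)
        for name in ("fmin", "fmax", "cmin", "cmax"):
            fh.create_dataset(name, data=getattr(pt.plan, name))


def load_phase_tensor_h5(path) -> PhaseTensor:
    with h5py.File(path, "r") as fh:
        coeffs = fh["coeffs_real"][()] + 1j * fh["coeffs_imag"][()]
        plan = WaveletPlan(
            freqs=fh["freqs"][()], cycles=fh["cycles"][()],
            fs=float(fh["fs"][()]), fmin=float(fh["fmin"][()]),
            fmax=float(fh["fmax"][()]), cmin=float(fh["cmin"][()]),
            cmax=float(fh["cmax"][()]),
        )
        times = fh["times"][()]
        valid = fh["valid_mask"][()].astype(bool)
    return PhaseTensor(coeffs=coeffs, plan=plan, times_ms=times, valid=valid)
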