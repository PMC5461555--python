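"""The white-noise (WN) reconstruction paradigm.

The impulse-response function (IRF) of the visual system is estimated by
cross-correlating white-noise luminance sequences with the concurrently
recorded signal; convolving the IRF with new sequences *reconstructs* the
stimulus-driven part of the signal.  Because targets embedded in the
sequences carry exactly the mean-gray luminance, they are invisible to the
convolution: the reconstructed signal contains no target-evoked response,
so phase effects measured on it are free of the ERP-induced latency
distortion quantified in :mod:`wnphase.latency_simulation`.

The module covers IRF estimation, reconstruction, epoching/ERP extraction,
cross-validated reconstruction-vs-recording correlation (raw and
band-filtered, IRF- or ERP-based models), classification images, and the
grand-average phase-opposition analysis of reconstructed epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.signal import fftconvolve

from .containers import Irf, TrialTensor
from .errors import AlignmentError, InvalidConfigError, InvalidInputError
from .phase_opposition import (
    correct_multiple,
    grand_average_pos,
    surrogate_pos_samples,
    PosResult,
)
from .spectral import WaveletPlan, bandpass_fft, wavelet_transform

__all__ = [
    "EpochSet",
    "CvCorrResult",
    "WnPosResult",
    "estimate_irf",
    "reconstruct_eeg",
    "epoch_and_erp",
    "fisher_z",
    "inverse_fisher_z",
    "crossval_model_correlation",
    "cohort_correlation_test",
    "classification_image",
    "classification_image_cohort",
    "phase_opposition_on_reconstruction",
]

BAND_LIMITS_HZ = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (7.0, 14.0),
    "beta": (14.0, 28.0),
    "gamma": (30.0, 60.0),
}


# ---------------------------------------------------------------------------
# IRF estimation and reconstruction
# ---------------------------------------------------------------------------

def estimate_irf(
    eeg: TrialTensor,
    sequences: np.ndarray,
    lag_window_ms: tuple[float, float] = (0.0, 750.0),
) -> Irf:
    """Estimate the per-channel IRF by stimulus-signal cross-correlation.

    ``eeg.data`` is ``(n_sequences, n_channels, n_samples)`` and must share
    its sampling grid with the luminance ``sequences``
    (``n_sequences x n_samples``).  The stimulus is mean-centred and the
    kernel normalised by the total stimulus energy, giving
    regression-coefficient units (exact least squares for white stimuli).
    """
    sequences = np.asarray(sequences, dtype=np.float64)
    if sequences.ndim != 2 or sequences.shape != (eeg.n_trials, eeg.n_samples):
        raise AlignmentError(
            f"sequences shape {sequences.shape} does not match signal "
            f"({eeg.n_trials}, {eeg.n_samples})"
        )
    l0 = int(round(lag_window_ms[0] * eeg.fs / 1000.0))
    l1 = int(round(lag_window_ms[1] * eeg.fs / 1000.0))
    if l0 < 0 or l1 <= l0:
        raise InvalidConfigError("lag window must satisfy 0 <= lag0 < lag1")
    n_lags = l1 - l0 + 1
    centred = sequences - sequences.mean()
    energy = np.sum(centred ** 2)
    if energy == 0:
        return Irf(np.zeros((eeg.n_channels, n_lags)), fs=eeg.fs,
                   lag0_ms=lag_window_ms[0])
    n = eeg.n_samples
    # full cross-correlation via convolution with the time-reversed stimulus
    cross = fftconvolve(eeg.data, centred[:, None, ::-1], axes=-1)
    acc = cross[:, :, n - 1 + l0: n - 1 + l1 + 1].sum(axis=0)
    return Irf(acc / energy, fs=eeg.fs, lag0_ms=lag_window_ms[0])


def reconstruct_eeg(
    irf: Irf,
    sequences: np.ndarray,
    mean_gray: float | None = None,
) -> TrialTensor:
    """Causal convolution of the IRF with luminance sequences.

    The output is aligned so lag 0 of the kernel multiplies the current
    frame.  The stimulus is centred on ``mean_gray`` (its own mean when not
    given) before convolution; target frames that carry the mean-gray value
    therefore contribute exactly zero.
    """
    sequences = np.atleast_2d(np.asarray(sequences, dtype=np.float64))
    n = sequences.shape[-1]
    centre = sequences.mean() if mean_gray is None else mean_gray
    centred = sequences - centre
    out = fftconvolve(centred[:, None, :], irf.kernel[None, :, :],
                      axes=-1)[:, :, :n]
    if irf.lag0_ms:
        shift = int(round(irf.lag0_ms * irf.fs / 1000.0))
        out = np.concatenate(
            [np.zeros(out.shape[:-1] + (shift,)), out[..., :n - shift]], axis=-1
        )
    return TrialTensor(out, fs=irf.fs)


# ---------------------------------------------------------------------------
# Epoching and ERPs
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Target-locked epochs with outcomes and baseline bookkeeping."""

    epochs: np.ndarray            # (n_events, n_channels, n_samples)
    times_ms: np.ndarray
    window_ms: tuple[float, float]
    baseline_ms: tuple[float, float]
    outcomes: np.ndarray          # bool, True = hit
    fs: float
    n_dropped: int = 0

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def epoch_and_erp(
    signal: TrialTensor,
    events: pd.DataFrame,
    window_ms: tuple[float, float] = (-800.0, 794.0),
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
) -> tuple[EpochSet, dict[str, np.ndarray]]:
    """Cut target-locked epochs, remove per-epoch baselines, average ERPs.

    ``events`` needs ``sequence_id``, ``frame_index`` and ``outcome``
    columns; events whose window exceeds the sequence bounds are dropped
    (counted in ``n_dropped``).  Returns the epochs plus mean ERPs for
    ``"hit"``, ``"miss"`` and ``"all"``.
    """
    i0 = int(round(window_ms[0] * signal.fs / 1000.0))
    i1 = int(round(window_ms[1] * signal.fs / 1000.0))
    if not i0 <= 0 <= i1:
        raise InvalidConfigError("epoch window must cover time 0")
    times = np.arange(i0, i1 + 1) * 1000.0 / signal.fs
    b_mask = (times >= baseline_ms[0]) & (times <= baseline_ms[1])
    cut, outcomes, dropped = [], [], 0
    for _, ev in events.iterrows():
        s, pos = int(ev["sequence_id"]), int(ev["frame_index"])
        if pos + i0 < 0 or pos + i1 >= signal.n_samples:
            dropped += 1
            continue
        cut.append(signal.data[s, :, pos + i0: pos + i1 + 1])
        outcomes.append(ev["outcome"] == "hit")
    if not cut:
        raise InvalidInputError("no event fits inside the signal bounds")
    epochs = np.asarray(cut)
    if b_mask.any():
        epochs = epochs - epochs[:, :, b_mask].mean(axis=-1, keepdims=True)
    outcomes = np.asarray(outcomes, dtype=bool)
    eset = EpochSet(epochs=epochs, times_ms=times, window_ms=tuple(window_ms),
                    baseline_ms=tuple(baseline_ms), outcomes=outcomes,
                    fs=signal.fs, n_dropped=dropped)
    erps = {"all": epochs.mean(axis=0)}
    erps["hit"] = epochs[outcomes].mean(axis=0) if outcomes.any() else None
    erps["miss"] = epochs[~outcomes].mean(axis=0) if (~outcomes).any() else None
    return eset, erps


# ---------------------------------------------------------------------------
# Cross-validated model correlation
# ---------------------------------------------------------------------------

def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilising transform ``0.5 * ln((1 + r) / (1 - r))``."""
    return np.arctanh(np.asarray(r, dtype=float))


def inverse_fisher_z(z: np.ndarray) -> np.ndarray:
    return np.tanh(np.asarray(z, dtype=float))


@dataclass
class CvCorrResult:
    """Per-channel cross-validated correlation for one subject."""

    mean_z: np.ndarray            # (n_channels,) mean Fisher-z across folds
    mean_r: np.ndarray            # inverse-transformed mean
    fold_z: np.ndarray            # (k, n_channels)
    model: str
    band: str | None


def _erp_prediction(erp: np.ndarray, times_ms: np.ndarray,
                    events: pd.DataFrame, seq_ids: np.ndarray,
                    shape: tuple, fs: float) -> np.ndarray:
    """Convolve a target-onset train with an ERP template per channel."""
    pred = np.zeros(shape)
    offsets = np.round(times_ms * fs / 1000.0).astype(int)
    pos_by_seq = events.groupby("sequence_id")["frame_index"].apply(list)
    for row, s in enumerate(seq_ids):
        for pos in pos_by_seq.get(s, []):
            idx = pos + offsets
            ok = (idx >= 0) & (idx < shape[-1])
            pred[row, :, idx[ok]] += erp[:, ok].T
    return pred


def crossval_model_correlation(
    recorded: TrialTensor,
    sequences: np.ndarray,
    events: pd.DataFrame | None = None,
    model: str = "irf",
    k: int = 10,
    band: str | None = None,
    lag_window_ms: tuple[float, float] = (0.0, 750.0),
    erp_window_ms: tuple[float, float] = (-200.0, 794.0),
    n_keep: int | None = None,
    seed: int = 0,
    circular: bool = False,
) -> CvCorrResult:
    """K-fold cross-validated correlation between recorded and modelled signal.

    For the ``irf`` model the IRF is estimated on the training folds and
    used to reconstruct the held-out sequences; for the ``erp`` model the
    target-locked ERP is extracted on the training folds and convolved with
    the held-out target-onset trains (``events`` required).  Pearson r is
    computed per channel over the concatenated held-out samples, Fisher-z
    transformed per fold and averaged.  ``band`` selects one of the
    zero-phase band-filtered variants (delta/theta/alpha/beta/gamma); both
    signals are filtered before correlating.  ``n_keep`` subsamples the
    sequences first (to equate counts across subjects); ``circular=True``
    trains and tests on the same folds, quantifying the leakage a proper
    cross-validation avoids.
    """
    if k < 2:
        raise InvalidConfigError("need k >= 2 folds")
    if band is not None:
        if band not in BAND_LIMITS_HZ:
            raise InvalidConfigError(f"unknown band {band!r}")
        lo, hi = BAND_LIMITS_HZ[band]
        if hi >= recorded.fs / 2:
            raise InvalidConfigError(
                f"band {band} exceeds Nyquist at fs={recorded.fs}"
            )
    sequences = np.asarray(sequences, dtype=np.float64)
    n_seq = recorded.n_trials
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_seq)
    if n_keep is not None:
        order = order[:n_keep]
    folds = np.array_split(order, k)
    fold_z = np.zeros((k, recorded.n_channels))
    for i, test_idx in enumerate(folds):
        train_idx = test_idx if circular else \
            np.concatenate([f for j, f in enumerate(folds) if j != i])
        if model == "irf":
            irf = estimate_irf(
                TrialTensor(recorded.data[train_idx], recorded.fs),
                sequences[train_idx], lag_window_ms,
            )
            pred = reconstruct_eeg(irf, sequences[test_idx],
                                   mean_gray=sequences.mean()).data
        elif model == "erp":
            if events is None:
                raise InvalidInputError("the erp model requires an event table")
            train_ev = events[events["sequence_id"].isin(train_idx)]
            remap = {s: j for j, s in enumerate(train_idx)}
            ev = train_ev.assign(
                sequence_id=train_ev["sequence_id"].map(remap))
            eset, erps = epoch_and_erp(
                TrialTensor(recorded.data[train_idx], recorded.fs), ev,
                window_ms=erp_window_ms, baseline_ms=(erp_window_ms[0], 0.0))
            pred = _erp_prediction(
                erps["all"], eset.times_ms,
                events[events["sequence_id"].isin(test_idx)], test_idx,
                (len(test_idx), recorded.n_channels, recorded.n_samples),
                recorded.fs)
        else:
            raise InvalidConfigError(f"unknown model {model!r}")
        rec = recorded.data[test_idx]
        if band is not None:
            rec = bandpass_fft(rec, recorded.fs, lo, hi)
            pred = bandpass_fft(pred, recorded.fs, lo, hi)
        for c in range(recorded.n_channels):
            a = rec[:, c, :].ravel()
            b = pred[:, c, :].ravel()
            if a.std() == 0 or b.std() == 0:
                fold_z[i, c] = 0.0
            else:
                fold_z[i, c] = fisher_z(np.corrcoef(a, b)[0, 1])
    mean_z = fold_z.mean(axis=0)
    return CvCorrResult(mean_z=mean_z, mean_r=inverse_fisher_z(mean_z),
                        fold_z=fold_z, model=model, band=band)


def cohort_correlation_test(
    per_subject: list[CvCorrResult], alpha: float = 0.05
) -> dict[str, np.ndarray]:
    """One-sample t-test of subject-level mean Fisher-z against zero.

    Returns per-channel ``t``, ``p`` (t distribution, df = subjects - 1),
    FDR mask at ``alpha`` across channels, and the cohort mean r.
    """
    z = np.stack([r.mean_z for r in per_subject])   # (subjects, channels)
    if z.shape[0] < 2:
        raise InvalidInputError("need at least 2 subjects for a t-test")
    t, p = stats.ttest_1samp(z, 0.0, axis=0)
    sig = correct_multiple(np.clip(p, np.finfo(float).tiny, 1.0), "fdr_bh", alpha)
    return {"t": t, "p": p, "sig": sig,
            "mean_r": inverse_fisher_z(z.mean(axis=0))}


# ---------------------------------------------------------------------------
# Classification image
# ---------------------------------------------------------------------------

def classification_image(
    sequences: np.ndarray,
    events: pd.DataFrame,
    fs: float,
    window_ms: tuple[float, float] = (-400.0, 400.0),
) -> dict[str, np.ndarray]:
    """Per-time-point luminance t-test between hit and miss trials.

    Returns the time axis, t statistics, p-values and an exclusion mask for
    time points with zero luminance variance (e.g. inside the suppression
    window, where every trial carries the same mean-gray value).  FDR
    correction is left to the caller (it runs across time and subjects for
    a cohort).
    """
    sequences = np.asarray(sequences, dtype=np.float64)
    i0 = int(round(window_ms[0] * fs / 1000.0))
    i1 = int(round(window_ms[1] * fs / 1000.0))
    times = np.arange(i0, i1 + 1) * 1000.0 / fs
    ev = events[~events.get("catch", pd.Series(False, index=events.index))]
    lum, hit = [], []
    for _, row in ev.iterrows():
        pos = int(row["frame_index"])
        if pos + i0 < 0 or pos + i1 >= sequences.shape[1]:
            continue
        lum.append(sequences[int(row["sequence_id"]), pos + i0: pos + i1 + 1])
        hit.append(row["outcome"] == "hit")
    lum = np.asarray(lum)
    hit = np.asarray(hit, dtype=bool)
    if hit.all() or not hit.any():
        raise InvalidInputError("both hit and miss trials are required")
    a, b = lum[hit], lum[~hit]
    excluded = (lum.std(axis=0) == 0)
    t = np.full(times.shape, np.nan)
    p = np.full(times.shape, np.nan)
    ok = ~excluded
    t[ok], p[ok] = stats.ttest_ind(a[:, ok], b[:, ok], axis=0)
    return {"times_ms": times, "t": t, "p": p, "excluded": excluded,
            "n_hit": int(hit.sum()), "n_miss": int((~hit).sum())}


def classification_image_cohort(
    per_subject: list[dict[str, np.ndarray]], alpha: float = 0.05
) -> np.ndarray:
    """BH-FDR significance masks across time points and subjects jointly."""
    ps = np.stack([r["p"] for r in per_subject])
    ok = np.isfinite(ps)
    sig = np.zeros(ps.shape, dtype=bool)
    if ok.any():
        sig[ok] = correct_multiple(ps[ok], "fdr_bh", alpha)
    return sig


# ---------------------------------------------------------------------------
# Grand-average phase opposition on reconstructed epochs
# ---------------------------------------------------------------------------

@dataclass
class WnPosResult:
    """Grand-average POS over reconstructed epochs, with cluster and topography."""

    freqs: np.ndarray
    times_ms: np.ndarray
    z: np.ndarray                 # (n_freqs, n_times)
    p: np.ndarray
    sig: np.ndarray
    cluster_mask: np.ndarray      # largest significant cluster (freq x time)
    peak_freq: float
    peak_time_ms: float
    peak_z: float
    centroid_freq: float          # z-weighted centre of mass of the cluster
    centroid_time_ms: float       # (log-frequency axis; stabler than argmax)
    topography_z: np.ndarray | None   # (n_channels,)


def phase_opposition_on_reconstruction(
    epoch_sets: list[EpochSet],
    plan: WaveletPlan | None = None,
    n_perm: int = 1000,
    n_resample: int = 100_000,
    n_resample_topo: int = 10_000,
    fmax: float = 80.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> WnPosResult:
    """Grand-average POS across subjects and channels on reconstructed epochs.

    Per subject, wavelet phases are computed on the plan's grid (capped at
    ``fmax``), the POS is summed over channels, and ``n_perm`` label-shuffle
    surrogates are stored; subjects are then aggregated by resampled
    surrogate sums (:func:`wnphase.phase_opposition.grand_average_pos`),
    FDR-corrected over time and frequency.  The topography of the largest
    significant cluster is obtained by summing per-channel POS over the
    cluster's cells and re-aggregating across subjects with
    ``n_resample_topo`` resamples.
    """
    if not epoch_sets:
        raise InvalidInputError("need at least one subject")
    fs = epoch_sets[0].fs
    if plan is None:
        # canonical 3-100 Hz / 50-step grid with the 2->8 cycle schedule;
        # grid points at or above this signal's Nyquist are dropped below
        freqs = np.geomspace(3.0, 100.0, 50)
        alpha = np.log(8.0 / 2.0) / np.log(100.0 / 3.0)
        plan = WaveletPlan(freqs=freqs, cycles=2.0 * (freqs / 3.0) ** alpha,
                           fs=fs, fmin=3.0, fmax=100.0, cmin=2.0, cmax=8.0)
    keep = plan.freqs <= min(fmax, 0.999 * fs / 2)
    freqs = plan.freqs[keep]
    rng = np.random.default_rng(seed)

    per_subj_obs, per_subj_surr = [], []
    per_subj_phases, per_subj_labels = [], []
    time_mask = None
    times = None
    for eset in epoch_sets:
        if eset.fs != fs:
            raise AlignmentError("all subjects must share the sampling rate")
        pt = wavelet_transform(
            TrialTensor(eset.epochs, fs, t0_ms=eset.times_ms[0]), plan)
        valid = pt.valid[keep]
        if time_mask is None:
            time_mask = valid.all(axis=0)
            times = eset.times_ms[time_mask]
            if not time_mask.any():
                raise InvalidInputError(
                    "no time point is valid at every analysed frequency"
                )
        phases = np.angle(pt.coeffs[:, :, keep][:, :, :, time_mask])
        n_tr, n_ch, n_f, n_t = phases.shape
        obs, surr = surrogate_pos_samples(
            phases.reshape(n_tr, -1), eset.outcomes, n_perm=n_perm,
            seed=int(rng.integers(2 ** 31)), chunk=max(1, 10 ** 7 // (n_ch * n_f * n_t)),
        )
        obs = obs.reshape(n_ch, n_f, n_t)
        surr = surr.reshape(n_perm, n_ch, n_f, n_t)
        per_subj_obs.append(obs.sum(axis=0))
        per_subj_surr.append(surr.sum(axis=1))
        per_subj_phases.append(phases.astype(np.float32))
        per_subj_labels.append(eset.outcomes)

    grand = grand_average_pos(per_subj_obs, per_subj_surr,
                              n_resample=n_resample,
                              seed=int(rng.integers(2 ** 31)))
    sig = correct_multiple(grand.p, "fdr_bh", alpha)

    cluster_mask = np.zeros_like(sig)
    topo_z = None
    peak_f = peak_t = peak_z = float("nan")
    cen_f = cen_t = float("nan")
    if sig.any():
        labeled, n_clusters = ndimage.label(sig)
        sizes = ndimage.sum_labels(sig, labeled, index=np.arange(1, n_clusters + 1))
        cluster_mask = labeled == (1 + int(np.argmax(sizes)))
        z_in = np.where(cluster_mask, grand.z, -np.inf)
        fi, ti = np.unravel_index(np.argmax(z_in), z_in.shape)
        peak_f, peak_t = float(freqs[fi]), float(times[ti])
        peak_z = float(grand.z[fi, ti])
        w = np.where(cluster_mask, np.maximum(grand.z, 0.0), 0.0)
        fw = w.sum(axis=1)
        tw = w.sum(axis=0)
        cen_f = float(np.exp((fw @ np.log(freqs)) / fw.sum()))
        cen_t = float((tw @ times) / tw.sum())

        cells = np.flatnonzero(cluster_mask.reshape(-1))
        topo_obs, topo_surr = [], []
        for phases, labels in zip(per_subj_phases, per_subj_labels):
            n_tr, n_ch = phases.shape[:2]
            flat = phases.reshape(n_tr, n_ch, -1)[:, :, cells]
            obs, surr = surrogate_pos_samples(
                flat.reshape(n_tr, -1).astype(np.float64), labels,
                n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
            topo_obs.append(obs.reshape(n_ch, -1).sum(axis=1))
            topo_surr.append(surr.reshape(n_perm, n_ch, -1).sum(axis=2))
        topo = grand_average_pos(topo_obs, topo_surr,
                                 n_resample=n_resample_topo,
                                 seed=int(rng.integers(2 ** 31)))
        topo_z = np.asarray(topo.z)

    return WnPosResult(
        freqs=freqs, times_ms=times, z=np.asarray(grand.z),
        p=np.asarray(grand.p), sig=sig, cluster_mask=cluster_mask,
        peak_freq=peak_f, peak_time_ms=peak_t, peak_z=peak_z,
        centroid_freq=cen_f, centroid_time_ms=cen_t,
        topography_z=topo_z,
    )
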