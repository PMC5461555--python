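"""Phase-opposition statistics.

The intertrial phase clustering (ITPC) of ``n`` phases is the norm of the
mean unit phase vector; the phase opposition sum (POS) of two trial groups
A and B is::

    POS = ITPC_A + ITPC_B - 2 * ITPC_all

POS is large when the two groups cluster at opposing angles and near zero
when phases are either uniform or locked to a common angle.  Because its
null distribution depends on the (possibly biased) phase sampling of the
data at hand, observed values are referenced to a surrogate distribution
obtained by shuffling the group labels while preserving group sizes.  The
observed POS is z-scored against the surrogates (the reported effect size),
and converted to an upper-tail p-value through a distribution matched to
the surrogates' first three moments: the permutation null of the POS is
right-skewed, so a plain normal tail is anticonservative (empirically an
8% false-positive rate at a nominal 5%, worse deeper into the tail, where
the Bonferroni and FDR cutoffs of the downstream analyses live).  A shifted
gamma with the surrogates' mean, SD and skewness restores calibration at
all tested levels (verified by simulation in the test suite); when the
measured skew is negligible the normal tail is used unchanged.

Also here: grand-average aggregation of POS across channels and subjects,
multiple-comparison corrections (Bonferroni, Benjamini-Hochberg), cluster
latency extraction, the quartile-based confidence interval of a median, and
phase-binned performance with a cosine fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateNullError, InvalidInputError

__all__ = [
    "PosResult",
    "LatencyDistribution",
    "PhaseBinCurve",
    "itpc",
    "pos",
    "surrogate_pos",
    "grand_average_pos",
    "correct_multiple",
    "largest_cluster_latency",
    "median_latency_ci",
    "phase_binned_performance",
]

_P_FLOOR = np.finfo(np.float64).tiny
_SKEW_EPS = 0.05  # below this measured skewness the normal tail is used


def _skewed_tail_p(obs: np.ndarray, mean: np.ndarray, sd: np.ndarray,
                   skew: np.ndarray) -> np.ndarray:
    """Upper-tail probability of ``obs`` under a null matched to the
    surrogate moments: a shifted gamma (shape ``4/skew^2``) when the null is
    right-skewed, a normal otherwise."""
    obs, mean, sd, skew = np.broadcast_arrays(obs, mean, sd, skew)
    g = np.maximum(skew, 1e-9)
    shape = 4.0 / g ** 2
    scale = sd * g / 2.0
    loc = mean - 2.0 * sd / g
    p_gamma = stats.gamma.sf(obs, shape, loc=loc, scale=scale)
    p_norm = stats.norm.sf((obs - mean) / sd)
    return np.clip(np.where(skew > _SKEW_EPS, p_gamma, p_norm), _P_FLOOR, 1.0)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def itpc(phases: np.ndarray, axis: int = 0) -> np.ndarray:
    """Intertrial phase clustering: ``|mean(exp(i*phi))|`` along ``axis``."""
    phases = np.asarray(phases, dtype=float)
    if phases.shape[axis] == 0:
        raise InvalidInputError("ITPC of an empty phase set is undefined")
    return np.abs(np.exp(1j * phases).mean(axis=axis))


def _check_labels(phases: np.ndarray, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if labels.ndim != 1 or labels.shape[0] != phases.shape[0]:
        raise InvalidInputError("labels must be 1-D and aligned with trials")
    if labels.all() or not labels.any():
        raise InvalidInputError("both outcome classes must be present")
    return labels


def pos(phases: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Phase opposition sum along the first (trial) axis."""
    phases = np.asarray(phases, dtype=float)
    labels = _check_labels(phases, labels)
    return (
        itpc(phases[labels]) + itpc(phases[~labels]) - 2.0 * itpc(phases)
    )


# ---------------------------------------------------------------------------
# Surrogate testing
# ---------------------------------------------------------------------------

@dataclass
class PosResult:
    """Observed POS with its surrogate-referenced z-score and p-value."""

    pos: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_perm: int
    surrogate_mean: np.ndarray
    surrogate_sd: np.ndarray


def _permuted_memberships(rng: np.random.Generator, n: int, n_a: int,
                          n_perm: int) -> np.ndarray:
    """Boolean (n_perm, n) matrix; each row marks a random subset of size n_a."""
    order = rng.random((n_perm, n)).argsort(axis=1)
    memb = np.zeros((n_perm, n), dtype=bool)
    memb[np.arange(n_perm)[:, None], order[:, :n_a]] = True
    return memb


def _surrogate_sums(memb: np.ndarray, unit: np.ndarray) -> np.ndarray:
    """Complex (n_perm, m) sums of unit vectors over each permuted group A."""
    memb_f = memb.astype(np.float64)
    return memb_f @ unit.real + 1j * (memb_f @ unit.imag)


def surrogate_pos(
    phases: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    tail: str = "calibrated",
) -> PosResult:
    """Label-shuffle surrogate test of the POS.

    ``phases`` has trials on the first axis; any further axes (time,
    frequency, channels) are carried through element-wise, with the *same*
    label permutations applied to every cell.  ``z`` is the observed POS
    standardised by the surrogate mean and SD.  With ``tail="calibrated"``
    (default) ``p`` is the upper-tail probability under a skew-matched null
    (see the module docstring); ``tail="normal"`` uses the plain normal
    upper tail of ``z`` -- the convention of the original phase-opposition
    literature, kept for protocol replication despite its anticonservative
    deep tail.
    """
    phases = np.asarray(phases, dtype=float)
    labels = _check_labels(phases, labels)
    if n_perm < 100:
        raise InvalidInputError("n_perm must be at least 100")
    n = phases.shape[0]
    n_a = int(labels.sum())
    n_b = n - n_a
    extra_shape = phases.shape[1:]
    unit = np.exp(1j * phases.reshape(n, -1))
    sum_all = unit.sum(axis=0)
    itpc_all = np.abs(sum_all) / n

    obs = (np.abs(unit[labels].sum(axis=0)) / n_a
           + np.abs(unit[~labels].sum(axis=0)) / n_b
           - 2.0 * itpc_all)

    rng = np.random.default_rng(seed)
    memb = _permuted_memberships(rng, n, n_a, n_perm)
    sum_a = _surrogate_sums(memb, unit)
    surr = (np.abs(sum_a) / n_a
            + np.abs(sum_all[None, :] - sum_a) / n_b
            - 2.0 * itpc_all[None, :])

    mean = surr.mean(axis=0)
    sd = surr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateNullError("surrogate POS distribution has zero spread")
    z = (obs - mean) / sd
    if tail == "normal":
        p = np.clip(stats.norm.sf(z), _P_FLOOR, 1.0)
    elif tail == "calibrated":
        p = _skewed_tail_p(obs, mean, sd, stats.skew(surr, axis=0, bias=False))
    else:
        raise InvalidInputError(f"unknown tail convention {tail!r}")

    def _shape(a: np.ndarray):
        return a.reshape(extra_shape) if extra_shape else float(a[0])

    return PosResult(pos=_shape(obs), z=_shape(z), p=_shape(p), n_perm=n_perm,
                     surrogate_mean=_shape(mean), surrogate_sd=_shape(sd))


def surrogate_pos_samples(
    phases: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    chunk: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed POS and the full surrogate sample (``(n_perm,) + cell shape``).

    Used by aggregation steps that need the individual surrogate values
    rather than just their first two moments (e.g. grand averaging across
    subjects).  Permutations are generated in chunks to bound memory.
    """
    phases = np.asarray(phases, dtype=float)
    labels = _check_labels(phases, labels)
    n = phases.shape[0]
    n_a = int(labels.sum())
    n_b = n - n_a
    extra_shape = phases.shape[1:]
    unit = np.exp(1j * phases.reshape(n, -1))
    sum_all = unit.sum(axis=0)
    itpc_all = np.abs(sum_all) / n
    obs = (np.abs(unit[labels].sum(axis=0)) / n_a
           + np.abs(unit[~labels].sum(axis=0)) / n_b
           - 2.0 * itpc_all)
    rng = np.random.default_rng(seed)
    out = np.empty((n_perm, unit.shape[1]))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        memb = _permuted_memberships(rng, n, n_a, m)
        sum_a = _surrogate_sums(memb, unit)
        out[done:done + m] = (np.abs(sum_a) / n_a
                              + np.abs(sum_all[None, :] - sum_a) / n_b
                              - 2.0 * itpc_all[None, :])
        done += m
    return obs.reshape(extra_shape), out.reshape((n_perm,) + extra_shape)


def grand_average_pos(
    per_subject_obs: list[np.ndarray],
    per_subject_surrogates: list[np.ndarray],
    n_resample: int = 100_000,
    seed: int | None = None,
    tail: str = "calibrated",
) -> PosResult:
    """Grand-average POS across subjects with resampled surrogate sums.

    The observed grand POS is the plain sum of per-subject observed values
    (each typically already summed over channels).  The surrogate
    distribution of that sum is built by repeatedly drawing one stored
    surrogate per subject and summing across subjects; each resample draws
    independently, so surrogates recur across resamples once ``n_resample``
    exceeds the per-subject surrogate count.
    """
    if not per_subject_obs:
        raise InvalidInputError("need at least one subject")
    if len(per_subject_obs) != len(per_subject_surrogates):
        raise InvalidInputError("observed and surrogate lists must align")
    obs = np.sum([np.asarray(o, dtype=float) for o in per_subject_obs], axis=0)
    cell_shape = np.asarray(per_subject_obs[0]).shape
    m = int(np.prod(cell_shape)) if cell_shape else 1

    rng = np.random.default_rng(seed)
    surr = [np.asarray(s, dtype=float).reshape(s.shape[0], -1)
            for s in per_subject_surrogates]
    total = np.zeros(m)
    total_sq = np.zeros(m)
    total_cube = np.zeros(m)
    chunk = max(1, int(2e7 // max(m, 1)))
    done = 0
    while done < n_resample:
        k = min(chunk, n_resample - done)
        acc = np.zeros((k, m))
        for s in surr:
            idx = rng.integers(0, s.shape[0], size=k)
            acc += s[idx]
        total += acc.sum(axis=0)
        total_sq += (acc ** 2).sum(axis=0)
        total_cube += (acc ** 3).sum(axis=0)
        done += k
    mean = total / n_resample
    var = (total_sq - n_resample * mean ** 2) / (n_resample - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    if np.any(sd == 0):
        raise DegenerateNullError("resampled surrogate sums have zero spread")
    m3 = total_cube / n_resample - 3 * mean * var * (n_resample - 1) / n_resample \
        - mean ** 3
    skew = m3 / sd ** 3
    z = (obs.reshape(m) - mean) / sd
    if tail == "normal":
        p = np.clip(stats.norm.sf(z), _P_FLOOR, 1.0)
    elif tail == "calibrated":
        p = _skewed_tail_p(obs.reshape(m), mean, sd, skew)
    else:
        raise InvalidInputError(f"unknown tail convention {tail!r}")

    def _shape(a: np.ndarray):
        return a.reshape(cell_shape) if cell_shape else float(a[0])

    return PosResult(pos=obs, z=_shape(z), p=_shape(p), n_perm=n_resample,
                     surrogate_mean=_shape(mean), surrogate_sd=_shape(sd))


# ---------------------------------------------------------------------------
# Multiple comparisons and clusters
# ---------------------------------------------------------------------------

def correct_multiple(p: np.ndarray, method: str = "fdr_bh",
                     alpha: float = 0.05) -> np.ndarray:
    """Significance mask after multiple-comparison correction.

    ``bonferroni`` thresholds at ``alpha / m`` over the ``m`` tests;
    ``fdr_bh`` applies the Benjamini-Hochberg step-up procedure.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidInputError("p-values must lie in (0, 1]")
    if method == "bonferroni":
        return p <= alpha / p.size
    if method == "fdr_bh":
        adjusted = stats.false_discovery_control(p.reshape(-1), method="bh")
        return (adjusted <= alpha).reshape(p.shape)
    raise InvalidInputError(f"unknown correction method {method!r}")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True as (start, stop) index pairs (stop exclusive)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts, stops))


def largest_cluster_latency(sig_mask: np.ndarray,
                            times_ms: np.ndarray) -> float:
    """Mean time of the longest contiguous run of significant samples.

    Ties in run length go to the earliest run.  An empty mask returns NaN
    (the dataset is counted as non-significant upstream).
    """
    sig_mask = np.asarray(sig_mask, dtype=bool)
    times_ms = np.asarray(times_ms, dtype=float)
    if sig_mask.shape != times_ms.shape:
        raise InvalidInputError("mask and time axis must have the same shape")
    runs = _runs(sig_mask)
    if not runs:
        return float("nan")
    lengths = [stop - start for start, stop in runs]
    best = int(np.argmax(lengths))  # argmax takes the first maximum: earliest run
    start, stop = runs[best]
    return float(times_ms[start:stop].mean())


# ---------------------------------------------------------------------------
# Latency distributions
# ---------------------------------------------------------------------------

@dataclass
class LatencyDistribution:
    """Median latency with a quartile-based 95% confidence interval.

    The CI is ``q2 +/- 1.7 * 1.25 * (q3 - q1) / (1.35 * sqrt(N))`` with
    quartiles computed by linear interpolation of order statistics (the
    conventional "type 7" rule).
    """

    latencies: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    q1: float
    q3: float
    n: int


def median_latency_ci(latencies: np.ndarray) -> LatencyDistribution:
    lat = np.asarray(latencies, dtype=float)
    lat = lat[np.isfinite(lat)]
    if lat.size < 2:
        raise InvalidInputError("need at least 2 finite latencies")
    q1, q2, q3 = np.percentile(lat, [25.0, 50.0, 75.0])
    half = 1.7 * 1.25 * (q3 - q1) / (1.35 * np.sqrt(lat.size))
    return LatencyDistribution(
        latencies=lat, median=float(q2), ci_low=float(q2 - half),
        ci_high=float(q2 + half), q1=float(q1), q3=float(q3), n=int(lat.size),
    )


# ---------------------------------------------------------------------------
# Phase-binned performance
# ---------------------------------------------------------------------------

@dataclass
class PhaseBinCurve:
    """Normalized hit ratio per phase bin with a cosine fit.

    ``cosine_amp_percent`` is the fitted cosine amplitude expressed as a
    percentage of mean performance (the normalized ratio averages ~1).
    Bin centres are fixed (no realignment across subjects).
    """

    bin_centers: np.ndarray
    normalized_hit_ratio: np.ndarray
    n_per_bin: np.ndarray
    cosine_amp_percent: float
    cosine_phase0: float
    excluded_bins: np.ndarray


def phase_binned_performance(phases: np.ndarray, hits: np.ndarray,
                             n_bins: int = 11) -> PhaseBinCurve:
    """Bin trials by phase, normalize hit rates, and fit ``a + b cos(th - th0)``.

    The fit is a linear regression on ``cos`` and ``sin`` predictors of the
    per-bin normalized ratios; its amplitude ``b = sqrt(bc^2 + bs^2)`` is
    reported in percent.  Empty bins are flagged and excluded from the fit.
    """
    phases = np.asarray(phases, dtype=float)
    hits = np.asarray(hits, dtype=bool)
    if phases.shape != hits.shape or phases.ndim != 1:
        raise InvalidInputError("phases and hits must be aligned 1-D arrays")
    overall = hits.mean()
    if overall == 0:
        raise InvalidInputError("cannot normalize: no hits at all")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    wrapped = np.angle(np.exp(1j * phases))
    which = np.clip(np.digitize(wrapped, edges) - 1, 0, n_bins - 1)
    ratio = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        counts[b] = sel.sum()
        if counts[b]:
            ratio[b] = hits[sel].mean() / overall
    ok = counts > 0
    design = np.column_stack([np.ones(ok.sum()), np.cos(centers[ok]),
                              np.sin(centers[ok])])
    beta, *_ = np.linalg.lstsq(design, ratio[ok], rcond=None)
    amp = float(np.hypot(beta[1], beta[2]))
    phase0 = float(np.arctan2(beta[2], beta[1]))
    return PhaseBinCurve(
        bin_centers=centers, normalized_hit_ratio=ratio, n_per_bin=counts,
        cosine_amp_percent=100.0 * amp, cosine_phase0=phase0,
        excluded_bins=~ok,
    )
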