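"""Kinetic and distribution fitting.

Covers the four summary fits used downstream of event calling:

* cumulative fraction-bound curve, ``F(t) = A * (1 - exp(-k t))``, giving the
  observed binding rate ``k_obs`` and the plateau ``A`` (percent bound when
  multiplied by 100);
* exponential dwell decays, with a left-truncated maximum-likelihood
  estimator (``tau = mean - cutoff``), an optional frame-quantization
  correction for durations recorded as whole frames, and a binned
  least-squares mode mirroring histogram fitting;
* Gaussian fit of the FRET-change magnitudes (``mu``, ``sigma``);
* the conversion of ``mu`` to nucleotides incorporated at 0.1 efficiency
  decrease per nucleotide.

Standard errors come from a seeded nonparametric bootstrap.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import optimize

from .events import FirstBinding

__all__ = [
    "FitResult",
    "fit_binding_cdf",
    "fit_fraction_bound_curve",
    "fit_dwell_exponential",
    "fit_delta_e_gaussian",
    "nucleotides_from_delta_e",
]

MIN_OBSERVATIONS = {"binding-cdf": 20, "dwell-exp": 20, "gaussian": 20,
                    "isotherm": 8}


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Fitted parameters with uncertainties and basic diagnostics."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float]
    n_observations: int
    goodness: float
    censored_count: int = 0
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, value in self.params.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite estimate for {name}")

    def param(self, name: str) -> float:
        return self.params[name]


def _note_if_small(n: int, model: str, notes: list[str]) -> None:
    minimum = MIN_OBSERVATIONS.get(model, 0)
    if n < minimum:
        notes.append(f"only {n} observations (recommended minimum {minimum})")


def fit_fraction_bound_curve(
    t: np.ndarray, fraction: np.ndarray, *, k_max: float = 50.0
) -> tuple[float, float, float, list[str]]:
    """Least-squares fit of ``A * (1 - exp(-k t))`` to fraction-bound points.

    Returns ``(k, A, residual_ss, notes)``.
    """
    t = np.asarray(t, dtype=float)
    fraction = np.asarray(fraction, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two curve points")

    def model(tt, k, a):
        return a * (1.0 - np.exp(-k * tt))

    a0 = min(max(float(fraction[-1]), 1e-3), 1.0)
    positive = t[t > 0]
    k0 = 1.0 / float(np.median(positive)) if positive.size else 1.0
    k0 = min(max(k0, 1e-5), k_max)
    popt, _ = optimize.curve_fit(
        model, t, fraction, p0=(k0, a0),
        bounds=((1e-8, 1e-6), (k_max, 1.0)), maxfev=20000)
    k, a = float(popt[0]), float(popt[1])
    resid = fraction - model(t, k, a)
    notes: list[str] = []
    if k > 0.8 * k_max:
        notes.append("rate at optimizer bound: binding saturates within the "
                     "first frames")
    return k, a, float(np.sum(resid ** 2)), notes


def fit_binding_cdf(
    first_times: Sequence[FirstBinding],
    *,
    n_boot: int = 200,
    seed: int | None = None,
    k_max: float = 50.0,
) -> FitResult:
    """Fit the cumulative fraction-bound curve of first binding times.

    Censored molecules contribute to the denominator only. Returns ``k``
    (s^-1) and the plateau ``A`` (fraction of molecules that ever bind).
    """
    n_total = len(first_times)
    if n_total == 0:
        raise ValueError("no molecules supplied")
    binder_times = np.sort([fb.time_s for fb in first_times if not fb.censored])
    censored = n_total - binder_times.size
    if binder_times.size == 0:
        raise ValueError("no events to fit")

    grid = np.unique(binder_times)
    ecdf = np.searchsorted(binder_times, grid, side="right") / n_total
    if grid.size >= 2:
        k, a, rss, notes = fit_fraction_bound_curve(grid, ecdf, k_max=k_max)
    else:
        # every binder arrived in the same frame: binding saturates faster
        # than the time resolution
        k, a, rss = k_max, float(ecdf[-1]), 0.0
        notes = ["rate at optimizer bound: binding saturates within the "
                 "first frames"]
    _note_if_small(n_total, "binding-cdf", notes)

    stderr = {"k": math.nan, "A": math.nan}
    if n_boot > 0 and binder_times.size >= 3:
        rng = np.random.default_rng(seed)
        times_all = np.array([fb.time_s for fb in first_times])
        cens_all = np.array([fb.censored for fb in first_times])
        ks, aas = [], []
        for _ in range(n_boot):
            idx = rng.integers(0, n_total, n_total)
            bt = np.sort(times_all[idx][~cens_all[idx]])
            if bt.size < 3:
                continue
            g = np.unique(bt)
            f = np.searchsorted(bt, g, side="right") / n_total
            try:
                kb, ab, _, _ = fit_fraction_bound_curve(g, f, k_max=k_max)
            except (RuntimeError, ValueError):
                continue
            ks.append(kb)
            aas.append(ab)
        if len(ks) >= 10:
            stderr = {"k": float(np.std(ks, ddof=1)),
                      "A": float(np.std(aas, ddof=1))}

    return FitResult(
        model="binding-cdf",
        params={"k": k, "A": a},
        stderr=stderr,
        n_observations=n_total,
        goodness=rss,
        censored_count=censored,
        notes=tuple(notes),
    )


def _tau_mle(durations: np.ndarray, cutoff: float,
             frame_interval: float | None) -> float:
    m = float(np.mean(durations)) - cutoff
    if frame_interval is None:
        return max(m, 1e-12)
    # durations recorded as whole frames follow a geometric law whose excess
    # over the cutoff has mean dt * q / (1 - q) with q = exp(-dt / tau)
    dt = frame_interval
    if m <= 0:
        return 1e-12
    q = m / (m + dt)
    return float(-dt / np.log(q))


def _tau_histogram(durations: np.ndarray) -> float | None:
    n = durations.size
    iqr = np.subtract(*np.percentile(durations, [75, 25]))
    if iqr <= 0:
        return None
    width = 2.0 * iqr / n ** (1.0 / 3.0)  # Freedman-Diaconis
    nbins = max(int(np.ceil(np.ptp(durations) / width)), 3)
    counts, edges = np.histogram(durations, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        return None
    try:
        popt, _ = optimize.curve_fit(
            lambda t, amp, tau: amp * np.exp(-t / tau),
            centers[keep], counts[keep],
            p0=(float(counts.max()), float(np.mean(durations))),
            bounds=((1e-9, 1e-9), (np.inf, np.inf)), maxfev=20000)
    except RuntimeError:
        return None
    return float(popt[1])


def fit_dwell_exponential(
    durations: Sequence[float],
    cutoff: float = 0.0,
    *,
    frame_interval: float | None = None,
    mode: str = "mle",
    n_boot: int = 200,
    seed: int | None = None,
) -> FitResult:
    """Fit an exponential dwell-time decay.

    ``cutoff`` is the minimum observable duration imposed by event calling;
    the left-truncated MLE is ``mean(durations) - cutoff``. Pass
    ``frame_interval`` when durations are whole-frame counts to correct the
    quantization bias. ``mode="histogram"`` selects the binned least-squares
    estimate as the primary value; the MLE is always reported as ``tau_mle``.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("no durations supplied")
    if np.any(d < cutoff - 1e-9):
        raise ValueError("durations below the stated cutoff")
    if mode not in ("mle", "histogram"):
        raise ValueError("mode must be 'mle' or 'histogram'")

    notes: list[str] = []
    _note_if_small(d.size, "dwell-exp", notes)
    tau_mle = _tau_mle(d, cutoff, frame_interval)
    tau_hist = _tau_histogram(d) if d.size >= 10 else None
    if mode == "histogram":
        if tau_hist is None:
            raise ValueError("histogram fit not possible for these durations")
        tau = tau_hist
    else:
        tau = tau_mle

    params = {"tau": tau, "tau_mle": tau_mle}
    stderr = {"tau": math.nan}
    if tau_hist is not None:
        params["tau_hist"] = tau_hist
    if n_boot > 0 and d.size >= 3:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            sample = rng.choice(d, size=d.size, replace=True)
            if mode == "histogram":
                tb = _tau_histogram(sample)
                if tb is None:
                    continue
            else:
                tb = _tau_mle(sample, cutoff, frame_interval)
            boots.append(tb)
        if len(boots) >= 10:
            stderr["tau"] = float(np.std(boots, ddof=1))

    loglik = float(-d.size * (np.log(tau_mle) + 1.0))
    return FitResult(
        model="dwell-exp",
        params=params,
        stderr=stderr,
        n_observations=int(d.size),
        goodness=loglik,
        notes=tuple(notes),
    )


def _gaussian_histogram_fit(v: np.ndarray) -> tuple[float, float] | None:
    """Binned least-squares Gaussian fit; None when not enough structure."""
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    if iqr <= 0 or v.size < 10:
        return None
    width = 2.0 * iqr / v.size ** (1.0 / 3.0)
    # at least 10 bins so the peak is resolved even for skewed histograms
    nbins = max(int(np.ceil(np.ptp(v) / width)), 10)
    counts, edges = np.histogram(v, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = optimize.curve_fit(
            lambda x, amp, mu, sig: amp * np.exp(-0.5 * ((x - mu) / sig) ** 2),
            centers, counts,
            p0=(float(counts.max()), float(centers[np.argmax(counts)]),
                float(np.std(v, ddof=1))),
            bounds=((1e-9, float(v.min()), 1e-6),
                    (np.inf, float(v.max()), np.ptp(v))),
            maxfev=20000)
    except RuntimeError:
        return None
    return float(popt[1]), float(abs(popt[2]))


def fit_delta_e_gaussian(
    values: Sequence[float],
    *,
    mode: str = "mle",
    n_boot: int = 200,
    seed: int | None = None,
) -> FitResult:
    """Gaussian fit of FRET-change magnitudes.

    ``mode="mle"`` reports the sample mean and SD. ``mode="histogram"``
    fits the binned magnitude histogram to a Gaussian by least squares,
    which tracks the modal magnitude and is robust to the left tail of
    sampling-censored events; the sample mean is always reported as
    ``mu_mean``.
    """
    if mode not in ("mle", "histogram"):
        raise ValueError("mode must be 'mle' or 'histogram'")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values supplied")
    notes: list[str] = []
    _note_if_small(v.size, "gaussian", notes)
    mu = float(np.mean(v))
    mu_mean = mu
    if np.unique(v).size < 2:
        notes.append("fewer than 2 distinct values: sigma undefined")
        sigma = 0.0
        sigma_se = math.nan
    else:
        sigma = float(np.std(v, ddof=1))
        sigma_se = sigma / math.sqrt(2.0 * (v.size - 1))
    hist_fit = _gaussian_histogram_fit(v) if np.unique(v).size >= 2 else None
    if mode == "histogram":
        if hist_fit is None:
            raise ValueError("histogram fit not possible for these values")
        mu, sigma = hist_fit
    stderr = {"mu": sigma / math.sqrt(v.size) if v.size else math.nan,
              "sigma": sigma_se}
    if n_boot > 0 and v.size >= 3 and np.unique(v).size >= 2:
        rng = np.random.default_rng(seed)
        mus = []
        for _ in range(n_boot):
            sample = rng.choice(v, v.size, replace=True)
            if mode == "histogram":
                fit = _gaussian_histogram_fit(sample)
                if fit is None:
                    continue
                mus.append(fit[0])
            else:
                mus.append(float(np.mean(sample)))
        if len(mus) >= 10:
            stderr["mu"] = float(np.std(mus, ddof=1))
    if sigma > 0:
        loglik = float(-0.5 * v.size * (1.0 + np.log(2 * np.pi * sigma ** 2)))
    else:
        loglik = math.inf
    params = {"mu": mu, "sigma": sigma, "mu_mean": mu_mean}
    if hist_fit is not None:
        params["mu_hist"] = hist_fit[0]
    return FitResult(
        model="gaussian",
        params=params,
        stderr=stderr,
        n_observations=int(v.size),
        goodness=loglik,
        notes=tuple(notes),
    )


def nucleotides_from_delta_e(mu: float, step: float = 0.1) -> float:
    """Convert a mean FRET-change magnitude to nucleotides incorporated."""
    if step <= 0:
        raise ValueError("step must be > 0")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    return mu / step
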