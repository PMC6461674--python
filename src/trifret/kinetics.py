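"""Lag-time distribution fits, ATP dependence, and FRET population histograms.

Lag times between entry- and exit-side DNA movement onsets are modelled as
a single-exponential waiting time (one rate-limiting event).  The primary
estimator is the closed-form maximum-likelihood mean (the sample mean);
a right-censored variant accounts for molecules whose observation ended
(photobleach or trace end) before the exit onset, and a binned
least-squares mode reproduces the conventional histogram fit.  Uncertainty
comes from a seeded nonparametric bootstrap, and a Kolmogorov-Smirnov
statistic reports goodness of the exponential description.

The ATP dependence of the lag rate is fit with the hyperbolic
(Michaelis-Menten) form 1/tau = k_max * S / (K_app + S) by weighted
nonlinear least squares with multi-start initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from trifret.correction import FretTraceSet
from trifret.detection import EventTable

MIN_EVENTS = 5


@dataclass
class ExpFit:
    """Single-exponential fit of a lag-time sample."""

    mean_lag: float
    sem: float
    n_events: int
    n_censored: int
    ks_statistic: float
    ks_p: float
    method: str

    @property
    def rate(self) -> float:
        return 1.0 / self.mean_lag


@dataclass
class HyperbolicFit:
    """Michaelis-Menten fit of lag rate vs ATP concentration."""

    k_max: float
    K_app: float
    k_max_ci: tuple
    K_app_ci: tuple
    residuals: pd.DataFrame = field(repr=False)

    def rate(self, atp_uM) -> np.ndarray:
        s = np.asarray(atp_uM, dtype=float)
        return self.k_max * s / (self.K_app + s)


def _binned_ls_mean(lags: np.ndarray) -> float:
    """Least-squares fit of histogram counts to an exponential density,
    Freedman-Diaconis bin width."""
    q75, q25 = np.percentile(lags, [75, 25])
    width = 2.0 * (q75 - q25) / len(lags) ** (1.0 / 3.0)
    if width <= 0:
        width = np.ptp(lags) / max(int(np.sqrt(len(lags))), 1) or 1.0
    nbins = max(int(np.ceil(np.ptp(lags) / width)), 3)
    counts, edges = np.histogram(lags, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(t, amp, tau):
        return amp * np.exp(-t / tau)

    p0 = (counts.max() if counts.max() > 0 else 1.0, float(np.mean(lags)))
    popt, _ = optimize.curve_fit(model, centers, counts, p0=p0, maxfev=10000)
    return abs(float(popt[1]))


def fit_exponential(lags, censored=(), method: str = "mle",
                    n_bootstrap: int = 1000, seed: int = 0) -> ExpFit:
    """Fit a single-exponential distribution to lag times.

    ``method``: 'mle' (sample mean; ignores censored), 'mle_censored'
    (mean = (sum of lags + sum of censoring times) / n_uncensored) or
    'binned_ls' (histogram least squares).  SEM is a seeded bootstrap over
    events; the KS statistic compares the uncensored lags with the fitted
    exponential.
    """
    lags = np.asarray(lags, dtype=float)
    censored = np.asarray(censored, dtype=float)
    n = len(lags)
    if n < MIN_EVENTS:
        raise ValueError(f"need at least {MIN_EVENTS} uncensored events, got {n}")
    if np.any(lags < 0) or np.any(censored < 0):
        raise ValueError("lag and censoring times must be non-negative")

    def estimate(lg: np.ndarray, cs: np.ndarray) -> float:
        if method == "mle":
            return float(np.mean(lg))
        if method == "mle_censored":
            return float((np.sum(lg) + np.sum(cs)) / len(lg))
        if method == "binned_ls":
            return _binned_ls_mean(lg)
        raise ValueError(f"unknown method {method!r}")

    mean = estimate(lags, censored)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        lg = rng.choice(lags, size=n, replace=True)
        cs = (rng.choice(censored, size=len(censored), replace=True)
              if len(censored) else censored)
        try:
            boots[b] = estimate(lg, cs)
        except RuntimeError:   # binned fit may fail on a degenerate resample
            boots[b] = np.nan
    sem = float(np.nanstd(boots, ddof=1))
    ks = stats.kstest(lags, "expon", args=(0.0, mean))
    return ExpFit(mean_lag=mean, sem=sem, n_events=n, n_censored=len(censored),
                  ks_statistic=float(ks.statistic), ks_p=float(ks.pvalue),
                  method=method)


def fit_atp_dependence(points) -> HyperbolicFit:
    """Weighted NLS fit of 1/mean_lag vs [ATP] to k_max*S/(K_app+S).

    ``points`` is a list of (atp_uM, ExpFit).  Rates are 1/mean_lag with
    SEM-propagated weights; initialisation is a multi-start grid over
    decades of both parameters.  Raises on non-convergence of every start,
    attaching the best parameters found.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 distinct ATP concentrations")
    s = np.array([p[0] for p in points], dtype=float)
    if len(np.unique(s)) < 3:
        raise ValueError("need at least 3 distinct ATP concentrations")
    mean = np.array([p[1].mean_lag for p in points])
    sem = np.array([p[1].sem for p in points])
    v = 1.0 / mean
    # delta method: sd(1/tau) = sem(tau) / tau^2
    sd_v = np.where(sem > 0, sem / mean**2, np.max(sem / mean**2, initial=1e-6))
    sd_v = np.where(sd_v > 0, sd_v, 1e-6)

    def resid(theta):
        k_max, K = np.exp(theta)
        return (k_max * s / (K + s) - v) / sd_v

    best = None
    for k0 in np.max(v) * np.array([0.5, 1.0, 2.0, 10.0]):
        for K0 in [1.0, 10.0, 100.0, 1000.0]:
            sol = optimize.least_squares(resid, x0=np.log([k0, K0]), method="lm",
                                         max_nfev=5000)
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success:
        k_max, K = np.exp(best.x) if best is not None else (np.nan, np.nan)
        raise RuntimeError(f"hyperbolic fit did not converge; best found "
                           f"k_max={k_max:.4g}, K_app={K:.4g}")
    k_max, K = np.exp(best.x)
    # covariance in log-parameters -> relative CIs
    J = best.jac
    dof = max(len(s) - 2, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    ci = lambda val, logse: (val * np.exp(-1.96 * logse), val * np.exp(1.96 * logse))
    res = pd.DataFrame({
        "atp_uM": s, "rate": v, "rate_sd": sd_v,
        "fitted": k_max * s / (K + s),
    })
    res["residual"] = res["rate"] - res["fitted"]
    return HyperbolicFit(k_max=float(k_max), K_app=float(K),
                         k_max_ci=ci(k_max, se[0]), K_app_ci=ci(K, se[1]),
                         residuals=res)


@dataclass
class FretHistogram:
    """Population histogram of per-molecule mean FRET in a time window."""

    edges: np.ndarray
    counts_entry: np.ndarray
    counts_exit: np.ndarray
    n_molecules: int
    n_skipped: int
    mean_entry: float
    sd_entry: float
    mean_exit: float
    sd_exit: float


HIST_EDGES = np.arange(-0.1, 1.1 + 1e-12, 0.02)


def build_fret_histograms(fret: FretTraceSet, window: str,
                          events: EventTable) -> FretHistogram:
    """Entry-/exit-side FRET histograms before or after remodelling.

    ``window`` is 'before_event' (times before the entry onset) or
    'after_event' (times at or after the exit onset).  Each molecule
    contributes its mean valid FRET in the window; molecules with an empty
    window are skipped and counted.
    """
    if window not in ("before_event", "after_event"):
        raise ValueError("window must be 'before_event' or 'after_event'")
    ev = events.rows.set_index("molecule_id")
    entry_vals, exit_vals = [], []
    n_skipped = 0
    for mol, g in fret.frames.groupby("molecule_id", sort=False):
        if mol not in ev.index:
            n_skipped += 1
            continue
        row = ev.loc[mol]
        t = g["time_s"].to_numpy()
        if window == "before_event":
            bound = row["t_entry_s"]
            mask = t < bound if np.isfinite(bound) else np.ones(len(t), bool)
        else:
            bound = row["t_exit_s"]
            if not np.isfinite(bound):
                n_skipped += 1
                continue
            mask = t >= bound
        ge = g[mask & g["entry_valid"].to_numpy()]["E_entry"]
        gx = g[mask & g["exit_valid"].to_numpy()]["E_exit"]
        if len(ge) == 0 and len(gx) == 0:
            n_skipped += 1
            continue
        if len(ge):
            entry_vals.append(float(ge.mean()))
        if len(gx):
            exit_vals.append(float(gx.mean()))
    entry_vals = np.array(entry_vals)
    exit_vals = np.array(exit_vals)
    return FretHistogram(
        edges=HIST_EDGES.copy(),
        counts_entry=np.histogram(entry_vals, bins=HIST_EDGES)[0],
        counts_exit=np.histogram(exit_vals, bins=HIST_EDGES)[0],
        n_molecules=max(len(entry_vals), len(exit_vals)),
        n_skipped=n_skipped,
        mean_entry=float(np.mean(entry_vals)) if len(entry_vals) else np.nan,
        sd_entry=float(np.std(entry_vals, ddof=1)) if len(entry_vals) > 1 else np.nan,
        mean_exit=float(np.mean(exit_vals)) if len(exit_vals) else np.nan,
        sd_exit=float(np.std(exit_vals, ddof=1)) if len(exit_vals) > 1 else np.nan,
    )
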