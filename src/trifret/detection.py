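"""Photobleach-step and FRET-onset detection on per-molecule time series.

The onset of a FRET change is defined by a two-phase least-squares model: a
constant baseline followed by a linear ramp, continuous at the breakpoint.
The breakpoint minimising the residual sum of squares over an exhaustive
scan is the onset; an event is called only when the fitted post-onset
change exceeds a threshold in the required direction.  This replaces
by-eye assignment of onsets with a deterministic, training-free criterion.

Photobleaching appears as a single abrupt downward step in the emission of
the bleached dye.  Steps are found by recursive two-segment mean-shift
fits with a robust noise estimate, and a sharpness test distinguishes
genuine single-frame steps from gradual FRET ramps.  Dye presence is read
from FRET-insensitive channel combinations: Cy3 from its 532 nm channel,
Cy5 from the summed 638 nm emission (Cy5 + A750 channels), and A750 from
its 638 nm channel (bleed-corrected when correction parameters are given).
Molecules with more than one step per dye indicate double labelling and
are flagged for exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trifret.correction import CorrectionParams, FretTraceSet
from trifret.trace_io import TraceSet


@dataclass
class DetectionParams:
    """Tuning constants of onset and bleach-step detection."""

    penalty: float = 6.0          # bleach-step acceptance, in robust-noise SDs
    min_segment: int = 2          # frames on each side of a breakpoint
    onset_threshold: float = 0.1  # minimum absolute FRET change to call an event
    baseline_window: int = 10     # ALEX cycles; smoothing for window trimming

    def __post_init__(self) -> None:
        if self.min_segment < 2:
            raise ValueError("min_segment must be >= 2")
        if self.onset_threshold <= 0:
            raise ValueError("onset_threshold must be > 0")


@dataclass
class Onset:
    """A detected change onset: breakpoint time, fit quality and magnitude."""

    time: float
    confidence: float   # RSS reduction vs a single constant fit
    change: float       # fitted change from onset to series end
    slope: float
    index: int


@dataclass
class BleachResult:
    """Per-dye bleach times (inf if none) and the single-step-per-dye flag."""

    bleach_cy3: float = math.inf
    bleach_cy5: float = math.inf
    bleach_a750: float = math.inf
    single_step: bool = True
    n_steps: dict = field(default_factory=dict)


@dataclass
class EventTable:
    """Per-molecule onset, lag, censoring and bleach times with quality flags.

    One row per molecule.  ``flag`` is a '+'-joined subset of
    {complete, entry_only, censored_by_bleach, no_event, multi_step_bleach};
    t_lag_s is present iff both onsets are.  ``diagnostics`` records the
    fraction of molecules whose unconstrained exit onset would precede the
    entry onset.
    """

    rows: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    @property
    def lags(self) -> np.ndarray:
        """Completed (uncensored) lag times, seconds."""
        return self.rows.loc[self.rows["t_lag_s"].notna(), "t_lag_s"].to_numpy()

    @property
    def censored(self) -> np.ndarray:
        """Censoring times (observed entry, no exit) for censored-MLE fits."""
        m = self.rows["flag"].str.contains("entry_only") & self.rows["t_censor_s"].notna()
        return self.rows.loc[m, "t_censor_s"].to_numpy()


def _two_phase_scan(t: np.ndarray, y: np.ndarray, min_segment: int):
    """RSS of the baseline+ramp model for every breakpoint; returns
    (k_candidates, rss, mu, slope)."""
    n = len(y)
    ks = np.arange(min_segment - 1, n - min_segment)
    if len(ks) == 0:
        return None
    # suffix sums over i > k
    def sfx(a):
        c = np.concatenate([np.cumsum(a[::-1])[::-1], [0.0]])
        return c[ks + 1]

    St, Stt, Sy2_t, Sty = sfx(t), sfx(t * t), sfx(y), sfx(t * y)
    tk = t[ks]
    n2 = n - 1 - ks
    Sx = St - n2 * tk
    Sxx = Stt - 2 * tk * St + n2 * tk * tk
    Sxy = Sty - tk * Sy2_t
    Sy = np.sum(y)
    Syy = np.sum(y * y)
    det = n * Sxx - Sx * Sx
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = (Sxx * Sy - Sx * Sxy) / det
        s = (n * Sxy - Sx * Sy) / det
        rss = Syy - mu * Sy - s * Sxy
    bad = ~np.isfinite(rss) | (det <= 0)
    rss = np.where(bad, np.inf, rss)
    return ks, rss, mu, s


def _rss_at(t: np.ndarray, y: np.ndarray, t0: float):
    """Profile RSS of the baseline+ramp model for a continuous breakpoint t0."""
    x = np.maximum(t - t0, 0.0)
    n = len(y)
    Sx, Sxx = x.sum(), (x * x).sum()
    Sy, Sxy, Syy = y.sum(), (x * y).sum(), (y * y).sum()
    det = n * Sxx - Sx * Sx
    if det <= 0:
        return np.inf, 0.0, 0.0
    mu = (Sxx * Sy - Sx * Sxy) / det
    s = (n * Sxy - Sx * Sy) / det
    return Syy - mu * Sy - s * Sxy, mu, s


def detect_onset(times: np.ndarray, values: np.ndarray, params: DetectionParams,
                 direction: str = "any") -> Onset | None:
    """Onset of a FRET change in one series via the two-phase breakpoint scan.

    The discrete scan is refined to a continuous breakpoint by minimising
    the profile RSS over the two sampling intervals adjacent to the best
    sample, so the onset is not quantised to the ALEX cycle.  ``direction``
    is 'increase', 'decrease' or 'any'.  Returns None when the series is
    too short, all-invalid, or the fitted change does not exceed
    ``params.onset_threshold`` in the required direction.
    """
    from scipy.optimize import minimize_scalar

    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    t, y = t[ok], y[ok]
    if len(y) < 2 * params.min_segment:
        return None
    scan = _two_phase_scan(t, y, params.min_segment)
    if scan is None:
        return None
    ks, rss, mu, s = scan
    i = int(np.argmin(rss))
    if not np.isfinite(rss[i]):
        return None
    k = int(ks[i])
    # sub-sample refinement around the winning breakpoint
    t_best, rss_best, slope = float(t[k]), float(rss[i]), float(s[i])
    lo = t[max(k - 1, 0)]
    hi = t[min(k + 1, len(t) - 1)]
    for a, b in ((lo, t[k]), (t[k], hi)):
        if b <= a:
            continue
        sol = minimize_scalar(lambda t0: _rss_at(t, y, t0)[0], bounds=(a, b),
                              method="bounded",
                              options={"xatol": 1e-9 * max(abs(b), 1.0)})
        r, _, sl = _rss_at(t, y, float(sol.x))
        if r < rss_best:
            t_best, rss_best, slope = float(sol.x), float(r), float(sl)
    change = slope * (t[-1] - t_best)
    if direction == "increase" and change < params.onset_threshold:
        return None
    if direction == "decrease" and change > -params.onset_threshold:
        return None
    if direction == "any" and abs(change) < params.onset_threshold:
        return None
    rss0 = float(np.sum(y * y) - np.sum(y) ** 2 / len(y))
    return Onset(time=t_best, confidence=rss0 - rss_best,
                 change=float(change), slope=slope, index=k)


def find_down_steps(times: np.ndarray, values: np.ndarray, min_segment: int = 3,
                    penalty: float = 6.0, sharpness: float = 0.7,
                    sharp_window: int = 3) -> list[tuple[int, float]]:
    """Abrupt downward mean-shift steps in one series.

    Returns (index of first post-step sample, drop size) pairs in time
    order.  A candidate split must reduce RSS beyond ``penalty`` robust
    noise SDs and must complete at least ``sharpness`` of its drop within
    ``sharp_window`` samples of the breakpoint, which rejects gradual FRET
    ramps while keeping single-frame photobleach steps.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 2 * min_segment:
        return []
    d = np.diff(y)
    sigma = 1.4826 * np.median(np.abs(d)) / math.sqrt(2.0)
    sigma = max(sigma, 1e-9 * max(np.max(np.abs(y)), 1.0), 1e-12)
    steps: list[tuple[int, float]] = []

    def scan(lo: int, hi: int) -> None:
        m = hi - lo
        if m < 2 * min_segment:
            return
        seg = y[lo:hi]
        c = np.cumsum(seg)
        tot = c[-1]
        n1 = np.arange(min_segment, m - min_segment + 1)
        s1 = c[n1 - 1]
        n2 = m - n1
        m1 = s1 / n1
        m2 = (tot - s1) / n2
        gain = n1 * m1**2 + n2 * m2**2 - tot**2 / m  # RSS reduction
        drop = m1 - m2
        se = sigma * np.sqrt(1.0 / n1 + 1.0 / n2)
        valid = (drop > 0) & (drop > penalty * se) & (gain > 0)
        if not valid.any():
            return
        j = int(np.argmax(np.where(valid, gain, -np.inf)))
        k = lo + int(n1[j])  # first post-step index
        dk = float(drop[j])
        # sharp if the drop within a narrow window matches the drop within a
        # 3x wider one; a gradual ramp keeps accumulating with window size
        w = sharp_window
        d_local = (y[max(0, k - w):k].mean() - y[k:min(n, k + w)].mean())
        d_wide = (y[max(0, k - 3 * w):k].mean() - y[k:min(n, k + 3 * w)].mean())
        if d_local > 0 and d_local >= sharpness * d_wide:
            steps.append((k, dk))
        scan(lo, k)
        scan(k, hi)

    scan(0, n)
    return sorted(steps)


def detect_bleach_steps(molecule_frames: pd.DataFrame,
                        params: DetectionParams | None = None,
                        corrections: CorrectionParams | None = None,
                        min_frames: int = 20,
                        min_drop_frac: float = 0.2) -> BleachResult:
    """Per-dye photobleach times for one molecule's raw frames.

    Requires at least ``min_frames`` frames (else returns an untrusted
    all-inf result with single_step=False).  Steps smaller than
    ``min_drop_frac`` of the channel's initial level are ignored (they are
    crosstalk echoes of another dye's bleach, not a bleach of this dye).
    """
    if params is None:
        params = DetectionParams()
    g = molecule_frames
    if len(g) < min_frames:
        return BleachResult(single_step=False, n_steps={"too_short": 1})
    is532 = g["excitation"].to_numpy() == 532
    t = g["time_s"].to_numpy()
    cy3_t, cy3_y = t[is532], g["I_cy3"].to_numpy()[is532]
    c638_cy5 = g["I_cy5"].to_numpy()[~is532]
    c638_a750 = g["I_a750"].to_numpy()[~is532]
    cy5_t = t[~is532]
    cy5_y = c638_cy5 + c638_a750
    b57 = corrections.b_cy5_to_a750 if corrections is not None else 0.0
    a750_y = c638_a750 - b57 * c638_cy5

    def channel_steps(tt, yy):
        raw = find_down_steps(tt, yy, min_segment=max(3, params.min_segment),
                              penalty=params.penalty)
        level = np.mean(yy[:max(3, params.min_segment)])
        return [(k, d) for k, d in raw if d >= min_drop_frac * max(level, 1e-12)]

    s5 = channel_steps(cy5_t, cy5_y)
    s7 = channel_steps(cy5_t, a750_y)
    s3 = channel_steps(cy3_t, cy3_y)
    # a Cy5 bleach also drops the A750 channel; drop coincident echoes
    cy5_times = [cy5_t[k] for k, _ in s5]
    s7 = [(k, d) for k, d in s7
          if not any(abs(cy5_t[k] - ct) < 3 * np.median(np.diff(t)) * 2 for ct in cy5_times)]
    res = BleachResult(
        bleach_cy3=cy3_t[s3[0][0]] if s3 else math.inf,
        bleach_cy5=cy5_t[s5[0][0]] if s5 else math.inf,
        bleach_a750=cy5_t[s7[0][0]] if s7 else math.inf,
        single_step=(len(s3) <= 1 and len(s5) <= 1 and len(s7) <= 1),
        n_steps={"cy3": len(s3), "cy5": len(s5), "a750": len(s7)},
    )
    return res


def detect_all_bleach(traces: TraceSet, params: DetectionParams | None = None,
                      corrections: CorrectionParams | None = None) -> pd.DataFrame:
    """Bleach table (molecule_id, bleach_*_s, single_step) for a whole TraceSet."""
    rows = []
    for mol, g in traces.frames.groupby("molecule_id", sort=False):
        r = detect_bleach_steps(g, params=params, corrections=corrections)
        rows.append((mol, r.bleach_cy3, r.bleach_cy5, r.bleach_a750, r.single_step))
    return pd.DataFrame(rows, columns=["molecule_id", "bleach_cy3_s", "bleach_cy5_s",
                                       "bleach_a750_s", "single_step"])


def _moving_average(y: np.ndarray, w: int) -> np.ndarray:
    if w <= 1 or len(y) < 2:
        return y.copy()
    c = np.cumsum(np.concatenate([[0.0], y]))
    h = w // 2
    lo = np.clip(np.arange(len(y)) - h, 0, len(y))
    hi = np.clip(np.arange(len(y)) + h + 1, 0, len(y))
    return (c[hi] - c[lo]) / (hi - lo)


def _trim_window(y_s: np.ndarray, mode: str, frac: float = 0.2) -> int:
    """Index (inclusive) where the smoothed series first completes
    (1 - frac) of its total excursion; keeps the breakpoint model
    well-specified by cutting plateaus and reversals."""
    lo, hi = float(np.min(y_s)), float(np.max(y_s))
    if hi <= lo:
        return len(y_s) - 1
    if mode == "increase":
        thr = hi - frac * (hi - lo)
        idx = np.nonzero(y_s >= thr)[0]
    else:
        thr = lo + frac * (hi - lo)
        idx = np.nonzero(y_s <= thr)[0]
    return int(idx[0]) if len(idx) else len(y_s) - 1


def _onset_on_window(t, y, params, direction):
    sm = _moving_average(y, params.baseline_window)
    end = _trim_window(sm, direction)
    end = max(end, 2 * params.min_segment - 1)
    return detect_onset(t[:end + 1], y[:end + 1], params, direction)


def extract_events(fret: FretTraceSet, params: DetectionParams | None = None,
                   bleach_table: pd.DataFrame | None = None) -> EventTable:
    """Per-molecule entry/exit onsets, lag times and quality flags.

    Entry onsets are sought as increases of the entry-side series, exit
    onsets as decreases of the exit-side series restricted to times at or
    after the entry onset (the unconstrained exit onset is also computed as
    a diagnostic).  Molecules whose Cy5 bleaches before an exit onset are
    censored; multi-step-bleach molecules are excluded from analysis.
    """
    if params is None:
        params = DetectionParams()
    bt = None
    if bleach_table is not None:
        bt = bleach_table.set_index("molecule_id")
    rows = []
    n_exit_first = 0
    n_with_both = 0
    for mol, g in fret.frames.groupby("molecule_id", sort=False):
        b3 = b5 = b7 = math.inf
        single = True
        if bt is not None and mol in bt.index:
            r = bt.loc[mol]
            b3 = float(r.get("bleach_cy3_s", math.inf))
            b5 = float(r.get("bleach_cy5_s", math.inf))
            b7 = float(r.get("bleach_a750_s", math.inf))
            single = bool(r.get("single_step", True))
        t_end = float(g["time_s"].iloc[-1])
        if not single:
            rows.append((mol, np.nan, np.nan, np.nan, np.nan, b3, b5, b7,
                         "multi_step_bleach"))
            continue
        t_ent_col = "time_638_s" if "time_638_s" in g.columns else "time_s"
        t_exi_col = "time_532_s" if "time_532_s" in g.columns else "time_s"
        ent = g[g["entry_valid"]]
        entry = _onset_on_window(ent[t_ent_col].to_numpy(), ent["E_entry"].to_numpy(),
                                 params, "increase") if len(ent) else None
        exl = g[g["exit_valid"]]
        exit_on = None
        if entry is not None and len(exl):
            after = exl[exl[t_exi_col] >= entry.time]
            exit_on = _onset_on_window(after[t_exi_col].to_numpy(),
                                       after["E_exit"].to_numpy(), params, "decrease")
            # diagnostic: where would the exit onset fall unconstrained?
            un = _onset_on_window(exl[t_exi_col].to_numpy(), exl["E_exit"].to_numpy(),
                                  params, "decrease")
            if un is not None:
                n_with_both += 1
                if un.time < entry.time:
                    n_exit_first += 1
        flags = []
        t_entry = t_exit = t_lag = t_cens = np.nan
        if entry is not None and exit_on is not None:
            flags.append("complete")
            t_entry, t_exit = entry.time, exit_on.time
            t_lag = t_exit - t_entry
        elif entry is not None:
            flags.append("entry_only")
            t_entry = entry.time
            cens_end = min(b5, t_end)
            t_cens = max(cens_end - t_entry, 0.0)
            if b5 < t_end:
                flags.append("censored_by_bleach")
        else:
            flags.append("no_event")
        rows.append((mol, t_entry, t_exit, t_lag, t_cens, b3, b5, b7, "+".join(flags)))
    df = pd.DataFrame(rows, columns=["molecule_id", "t_entry_s", "t_exit_s", "t_lag_s",
                                     "t_censor_s", "bleach_cy3_s", "bleach_cy5_s",
                                     "bleach_a750_s", "flag"])
    diag = {
        "n_molecules": len(df),
        "n_unconstrained_exit_before_entry": n_exit_first,
        "frac_unconstrained_exit_before_entry": (n_exit_first / n_with_both
                                                 if n_with_both else 0.0),
    }
    return EventTable(df, diagnostics=diag)
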