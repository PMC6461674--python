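"""Spectral corrections and entry-/exit-side FRET computation for ALEX traces.

Raw channel intensities mix three linear artefacts: direct excitation of
Cy5 by the 532 nm laser and of Alexa750 by the 638 nm laser, emission
bleedthrough (Cy3 into the Cy5 channel, Cy5 into the Alexa750 channel), and
per-dye differences in quantum yield and detection efficiency.  Direct
excitation of Alexa750 by 532 nm is negligible and Cy3 -> Alexa750 FRET is
taken to be zero throughout (the dyes are too far apart and too poorly
matched), so no three-way de-mixing is attempted.

``apply_corrections`` inverts the mixing exactly, in the order bleedthrough
-> direct excitation -> scaling.  Bleedthrough is removed first because the
Cy5 emission that bleeds into the Alexa750 channel includes the
direct-excited Cy5 contribution; removing direct excitation first would
leave a residual.  The direct-excitation step also removes the portion of
direct-excited Cy5 emission that was re-transferred to Alexa750.  On
noiseless data with exact parameters the round trip through the renderer
and this module reproduces the ground-truth efficiencies to 1e-9.

``compute_fret`` then forms the two observables:

    E_exit  = 1 - I532_cy3 / (I532_cy3 + I532_cy5 + I532_a750)
    E_entry = I638_a750 / (I638_cy5 + I638_a750)

E_exit is all FRET originating from Cy3 (the cascade makes Alexa750 photons
under 532 nm count as Cy3-originated transfer); E_entry is the
Cy5 -> Alexa750 efficiency probed by 638 nm excitation alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from trifret.trace_io import AlexSeries, TraceSet

#: FRET values outside this range on valid records indicate broken corrections
FRET_HARD_RANGE = (-0.2, 1.2)


@dataclass
class CorrectionParams:
    """Direct-excitation, bleedthrough and channel-scaling coefficients.

    Scale factors map Cy3 and Alexa750 channel counts into Cy5-equivalent
    units (s = 1/g for detection factor g).  There is no d_a750_532 term:
    direct excitation of Alexa750 at 532 nm is negligible.
    """

    d_cy5_532: float = 0.0
    d_a750_638: float = 0.0
    b_cy3_to_cy5: float = 0.0
    b_cy5_to_a750: float = 0.0
    s_cy3: float = 1.0
    s_a750: float = 1.0

    def __post_init__(self) -> None:
        for name in ("d_cy5_532", "d_a750_638", "b_cy3_to_cy5", "b_cy5_to_a750"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.s_cy3 <= 0 or self.s_a750 <= 0:
            raise ValueError("scale factors must be > 0")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in asdict(self).items():
                fh.write(f"{key}\t{float(val)!r}\n")

    @classmethod
    def read(cls, path) -> "CorrectionParams":
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("\t")
                kv[key.strip()] = float(val)
        return cls(**kv)


@dataclass
class FretTraceSet:
    """Per-molecule, per-ALEX-cycle FRET observables with validity flags.

    Columns: molecule_id, time_s, E_exit, E_entry, exit_valid, entry_valid
    plus the corrected intensities they were computed from.  Validity is
    false where the relevant denominator falls below the floor or after the
    relevant dye has photobleached.
    """

    frames: pd.DataFrame
    denom_floor: float
    n_out_of_range: int = 0

    def molecule(self, molecule_id: int) -> pd.DataFrame:
        return self.frames[self.frames["molecule_id"] == molecule_id]


def apply_corrections(aligned: AlexSeries, params: CorrectionParams,
                      background: dict | None = None) -> AlexSeries:
    """Remove crosstalk from aligned ALEX records; order: bleedthrough,
    direct excitation, scaling.

    ``background`` optionally holds per-channel offsets {"cy3", "cy5",
    "a750"} subtracted from every record first.  Negative corrected
    intensities are permitted.
    """
    df = aligned.frames.copy()
    if background:
        df["I532_cy3"] -= background.get("cy3", 0.0)
        df["I532_cy5"] -= background.get("cy5", 0.0)
        df["I532_a750"] -= background.get("a750", 0.0)
        df["I638_cy5"] -= background.get("cy5", 0.0)
        df["I638_a750"] -= background.get("a750", 0.0)
    b35, b57 = params.b_cy3_to_cy5, params.b_cy5_to_a750
    d5, d7 = params.d_cy5_532, params.d_a750_638
    g7 = 1.0 / params.s_a750
    # bleedthrough (uses the direct-excitation-included Cy5 signal)
    c5_532 = df["I532_cy5"] - b35 * df["I532_cy3"]
    a7_532 = df["I532_a750"] - b57 * c5_532
    a7_638 = df["I638_a750"] - b57 * df["I638_cy5"]
    # direct excitation: A750 at 638 nm via the per-record Cy5-equivalent
    # total, Cy5 at 532 nm via the 638 nm Cy5 reference, and the
    # direct-excited-Cy5 -> A750 re-transfer at 532 nm
    total_638 = df["I638_cy5"] + a7_638 / g7
    a7_638 = a7_638 - g7 * d7 * total_638 / (1.0 + d7)
    c5_532 = c5_532 - d5 * df["I638_cy5"]
    a7_532 = a7_532 - d5 * a7_638
    # scaling to Cy5-equivalent units
    out = pd.DataFrame({
        "molecule_id": df["molecule_id"],
        "time_s": df["time_s"],
        "time_532_s": df.get("time_532_s", df["time_s"]),
        "time_638_s": df.get("time_638_s", df["time_s"]),
        "I532_cy3": params.s_cy3 * df["I532_cy3"],
        "I532_cy5": c5_532,
        "I532_a750": params.s_a750 * a7_532,
        "I638_cy5": df["I638_cy5"],
        "I638_a750": params.s_a750 * a7_638,
    })
    return AlexSeries(out, n_dropped=dict(aligned.n_dropped), skipped=list(aligned.skipped))


def default_denom_floor(read_noise_sd: float = 5.0) -> float:
    """Denominator floor below which FRET is undefined: 3 x read-noise SD x sqrt(3)."""
    return 3.0 * read_noise_sd * math.sqrt(3.0)


def compute_fret(corrected: AlexSeries, denom_floor: float | None = None,
                 bleach_table: pd.DataFrame | None = None) -> FretTraceSet:
    """Entry- and exit-side FRET per aligned record.

    Records whose denominator is below ``denom_floor`` are marked invalid,
    never dropped.  ``bleach_table`` (columns molecule_id, bleach_cy3_s,
    bleach_cy5_s, bleach_a750_s) additionally invalidates E_exit after a
    Cy3 or Cy5 bleach and E_entry after a Cy5 or A750 bleach.  Valid values
    outside [-0.2, 1.2] raise ValueError (they indicate broken corrections,
    not noise).
    """
    if denom_floor is None:
        denom_floor = default_denom_floor()
    df = corrected.frames
    denom_exit = df["I532_cy3"] + df["I532_cy5"] + df["I532_a750"]
    denom_entry = df["I638_cy5"] + df["I638_a750"]
    exit_valid = (denom_exit > denom_floor).to_numpy()
    entry_valid = (denom_entry > denom_floor).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        e_exit = np.where(exit_valid, 1.0 - df["I532_cy3"] / denom_exit, np.nan)
        e_entry = np.where(entry_valid, df["I638_a750"] / denom_entry, np.nan)
    if bleach_table is not None:
        bt = bleach_table.set_index("molecule_id")
        # each observable is judged at its own excitation frame's time
        t_exit = df.get("time_532_s", df["time_s"]).to_numpy()
        t_entry = df.get("time_638_s", df["time_s"]).to_numpy()
        mol = df["molecule_id"].to_numpy()

        def _limit(*cols):
            lim = np.full(len(df), np.inf)
            for c in cols:
                if c in bt.columns:
                    vals = bt[c].reindex(mol).to_numpy(dtype=float)
                    vals = np.where(np.isnan(vals), np.inf, vals)
                    lim = np.minimum(lim, vals)
            return lim

        exit_valid &= t_exit < _limit("bleach_cy3_s", "bleach_cy5_s")
        entry_valid &= t_entry < _limit("bleach_cy5_s", "bleach_a750_s")
    lo, hi = FRET_HARD_RANGE
    bad = (exit_valid & ((e_exit < lo) | (e_exit > hi))) | (
        entry_valid & ((e_entry < lo) | (e_entry > hi)))
    n_bad = int(np.sum(bad))
    if n_bad:
        raise ValueError(
            f"{n_bad} valid FRET value(s) outside hard range {FRET_HARD_RANGE}; "
            "check correction parameters"
        )
    out = df.copy()
    out["E_exit"] = e_exit
    out["E_entry"] = e_entry
    out["exit_valid"] = exit_valid
    out["entry_valid"] = entry_valid
    return FretTraceSet(out, denom_floor=denom_floor, n_out_of_range=n_bad)


@dataclass
class EstimationResult:
    """Correction parameters estimated from post-bleach trace segments."""

    params: CorrectionParams
    segment_counts: dict = field(default_factory=dict)
    defaulted: set = field(default_factory=set)
    backgrounds: dict = field(default_factory=dict)


def _segment_means(traces: TraceSet, annotations: pd.DataFrame, guard_s: float,
                   window_s: float):
    """Per-molecule channel means in dye-alive/dead segments and bleach-step windows."""
    ann = annotations.set_index("molecule_id")
    recs = []
    for mol, g in traces.frames.groupby("molecule_id", sort=False):
        if mol not in ann.index:
            continue
        row = ann.loc[mol]
        b3 = float(row.get("bleach_cy3_s", np.inf))
        b5 = float(row.get("bleach_cy5_s", np.inf))
        b7 = float(row.get("bleach_a750_s", np.inf))
        b3, b5, b7 = (np.inf if np.isnan(b) else b for b in (b3, b5, b7))
        t = g["time_s"].to_numpy()
        is532 = g["excitation"].to_numpy() == 532
        recs.append(dict(mol=mol, g=g, t=t, is532=is532, b3=b3, b5=b5, b7=b7))
    return recs


def estimate_corrections(traces: TraceSet, bleach_annotations: pd.DataFrame,
                         guard_s: float = 0.3, window_s: float = 10.0,
                         defaults: CorrectionParams | None = None) -> EstimationResult:
    """Estimate correction parameters from segments where a subset of dyes
    has photobleached.

    Bleedthrough fractions come from acceptor-dark segments, direct
    excitation of Cy5 from donor-dark segments, and the scale factors and
    d_a750_638 from intensity changes across bleach steps (the latter two
    are coupled and solved by fixed-point iteration).  Channel backgrounds
    are estimated from dye-dark segments first and subtracted.  Parameters
    without qualifying segments keep their default and are flagged.
    """
    if defaults is None:
        defaults = CorrectionParams()
    recs = _segment_means(traces, bleach_annotations, guard_s, window_s)
    counts: dict[str, int] = {}
    est = {}

    def dead(r, b, t):  # noqa: E741 - segment masks
        return t >= b + guard_s

    def alive(r, b, t):
        return t < b - guard_s

    # --- backgrounds ---------------------------------------------------
    bg = {"cy3": 0.0, "cy5": 0.0, "a750": 0.0}
    cy3_638 = [r["g"]["I_cy3"].to_numpy()[~r["is532"]] for r in recs]
    if cy3_638:
        bg["cy3"] = float(np.mean(np.concatenate(cy3_638)))
    cy5_dark, a750_dark = [], []
    for r in recs:
        m5 = dead(r, r["b5"], r["t"])
        m5_638 = m5 & ~r["is532"]   # 638 nm: nothing bleeds into the Cy5 channel
        if m5_638.any():
            cy5_dark.append(r["g"]["I_cy5"].to_numpy()[m5_638])
        m7 = m5 & dead(r, r["b7"], r["t"]) & ~r["is532"]
        if m7.any():
            a750_dark.append(r["g"]["I_a750"].to_numpy()[m7])
    if cy5_dark:
        bg["cy5"] = float(np.mean(np.concatenate(cy5_dark)))
    if a750_dark:
        bg["a750"] = float(np.mean(np.concatenate(a750_dark)))

    def ch(r, name):
        key = {"I_cy3": "cy3", "I_cy5": "cy5", "I_a750": "a750"}[name]
        return r["g"][name].to_numpy() - bg[key]

    # --- bleedthrough and Cy5 direct excitation ------------------------
    num = den = 0.0
    n = 0
    for r in recs:
        m = alive(r, r["b3"], r["t"]) & dead(r, r["b5"], r["t"]) & r["is532"]
        if m.sum() >= 3:
            num += ch(r, "I_cy5")[m].sum()
            den += ch(r, "I_cy3")[m].sum()
            n += 1
    counts["b_cy3_to_cy5"] = n
    if n and den > 0:
        est["b_cy3_to_cy5"] = num / den

    num = den = 0.0
    n = 0
    for r in recs:
        m = alive(r, r["b5"], r["t"]) & dead(r, r["b7"], r["t"]) & ~r["is532"]
        if m.sum() >= 3:
            num += ch(r, "I_a750")[m].sum()
            den += ch(r, "I_cy5")[m].sum()
            n += 1
    counts["b_cy5_to_a750"] = n
    if n and den > 0:
        est["b_cy5_to_a750"] = num / den

    num = den = 0.0
    n = 0
    for r in recs:
        base = dead(r, r["b3"], r["t"]) & alive(r, r["b5"], r["t"])
        m532, m638 = base & r["is532"], base & ~r["is532"]
        if m532.sum() >= 3 and m638.sum() >= 3:
            num += ch(r, "I_cy5")[m532].mean()
            den += ch(r, "I_cy5")[m638].mean()
            n += 1
    counts["d_cy5_532"] = n
    if n and den > 0:
        est["d_cy5_532"] = num / den

    b57 = est.get("b_cy5_to_a750", defaults.b_cy5_to_a750)

    # --- A750-bleach steps: g_a750; Cy5-bleach steps: g_cy3; then d_a750_638
    a750_steps = []
    for r in recs:
        if not math.isfinite(r["b7"]) or r["b5"] <= r["b7"] + guard_s:
            continue
        t, m638 = r["t"], ~r["is532"]
        pre = m638 & (t >= r["b7"] - window_s) & (t < r["b7"] - guard_s)
        post = m638 & (t >= r["b7"] + guard_s) & (t < min(r["b7"] + window_s, r["b5"] - guard_s))
        if pre.sum() >= 3 and post.sum() >= 3:
            c_pre, c_post = ch(r, "I_cy5")[pre].mean(), ch(r, "I_cy5")[post].mean()
            a_pre = ch(r, "I_a750")[pre].mean() - b57 * c_pre
            if c_post > 0 and c_post > c_pre:
                a750_steps.append((a_pre / c_post, 1.0 - c_pre / c_post))
    counts["s_a750"] = len(a750_steps)

    b35 = est.get("b_cy3_to_cy5", defaults.b_cy3_to_cy5)
    d5 = est.get("d_cy5_532", defaults.d_cy5_532)
    cy5_steps = []  # raw window means around each Cy5-bleach step
    for r in recs:
        if not math.isfinite(r["b5"]) or r["b3"] <= r["b5"] + guard_s:
            continue
        t, m532 = r["t"], r["is532"]
        m638 = ~r["is532"]
        pre = (t >= r["b5"] - window_s) & (t < r["b5"] - guard_s)
        post = (t >= r["b5"] + guard_s) & (t < min(r["b5"] + window_s, r["b3"] - guard_s, r["b7"] - guard_s))
        if (pre & m532).sum() >= 3 and (post & m532).sum() >= 3 and (pre & m638).sum() >= 3:
            d_cy3 = ch(r, "I_cy3")[post & m532].mean() - ch(r, "I_cy3")[pre & m532].mean()
            if d_cy3 > 0:
                cy5_steps.append({
                    "d_cy3": d_cy3,
                    "c3_532": ch(r, "I_cy3")[pre & m532].mean(),
                    "c5_532": ch(r, "I_cy5")[pre & m532].mean(),
                    "a7_532": ch(r, "I_a750")[pre & m532].mean(),
                    "c5_638": ch(r, "I_cy5")[pre & m638].mean(),
                    "a7_638": ch(r, "I_a750")[pre & m638].mean(),
                })
    counts["s_cy3"] = len(cy5_steps)

    d7_segs = []
    for r in recs:
        base = dead(r, r["b5"], r["t"]) & alive(r, r["b7"], r["t"]) & alive(r, r["b3"], r["t"])
        m532, m638 = base & r["is532"], base & ~r["is532"]
        if m532.sum() >= 3 and m638.sum() >= 3:
            d7_segs.append((ch(r, "I_a750")[m638].mean(), ch(r, "I_cy3")[m532].mean()))
    counts["d_a750_638"] = len(d7_segs)

    # coupled g_a750 / g_cy3 / d_a750_638 fixed point; each equation is exact
    # given the others, and the couplings are weak, so iteration converges
    d7 = defaults.d_a750_638 if not d7_segs else 0.0
    g7 = 1.0 / defaults.s_a750
    g3 = 1.0 / defaults.s_cy3
    for _ in range(200):
        prev = (g7, g3, d7)
        if a750_steps:
            g7 = float(np.mean([ratio / (e2 + d7) for ratio, e2 in a750_steps if e2 + d7 > 0.01]))
        if cy5_steps:
            vals = []
            for w in cy5_steps:
                # same correction chain as apply_corrections, on window means
                c5b = w["c5_532"] - b35 * w["c3_532"]
                a7b = w["a7_532"] - b57 * c5b
                a7_638b = w["a7_638"] - b57 * w["c5_638"]
                a7_638c = a7_638b - g7 * d7 * (w["c5_638"] + a7_638b / g7) / (1.0 + d7)
                c5c = c5b - d5 * w["c5_638"]
                a7c = a7b - d5 * a7_638c
                denom = c5c + a7c / g7   # Cy5-equivalents originating from Cy3
                if denom > 0:
                    vals.append(w["d_cy3"] / denom)
            if vals:
                g3 = float(np.mean(vals))
        if d7_segs:
            d7 = float(np.mean([a / (g7 * (c3 / g3)) for a, c3 in d7_segs if c3 > 0]))
        if max(abs(g7 - prev[0]), abs(g3 - prev[1]), abs(d7 - prev[2])) < 1e-13:
            break
    if a750_steps:
        est["s_a750"] = 1.0 / g7
    if cy5_steps:
        est["s_cy3"] = 1.0 / g3
    if d7_segs:
        est["d_a750_638"] = d7

    fields = ("d_cy5_532", "d_a750_638", "b_cy3_to_cy5", "b_cy5_to_a750", "s_cy3", "s_a750")
    values = {f: est.get(f, getattr(defaults, f)) for f in fields}
    # clip tiny negative noise-driven fraction estimates into the valid domain
    for f in fields[:4]:
        values[f] = min(max(values[f], 0.0), 0.999)
    defaulted = {f for f in fields if f not in est}
    return EstimationResult(CorrectionParams(**values), segment_counts=counts,
                            defaulted=defaulted, backgrounds=bg)
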