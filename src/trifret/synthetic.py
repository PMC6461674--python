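"""Synthetic three-colour ALEX trace generator for nucleosome-sliding kinetics.

The generator has two stages.  ``sample_kinetics`` draws per-molecule
ground-truth event timelines: an exponentially distributed waiting time to
the onset of entry-side DNA movement, then an exponentially distributed lag
until exit-side movement begins, with the lag rate depending hyperbolically
(Michaelis-Menten) on ATP concentration,

    1 / tau_lag = k_max * [ATP] / (K_app + [ATP]).

Entry-side FRET (Cy5 -> Alexa750, E2) follows the characteristic
non-monotonic rise-then-fall of DNA being pulled onto the nucleosome and
then propagated past the dyad; exit-side FRET (Cy3 -> Cy5, E1) decreases
monotonically as DNA shifts off the exit side.  Both are piecewise linear.

``render_traces`` turns timelines into raw camera-frame intensities.  Under
532 nm excitation, photons absorbed by Cy3 cascade Cy3 -> Cy5 -> Alexa750
with efficiencies E1 and E2, so the three channels split as
(1-E1) : E1*(1-E2) : E1*E2; Cy5 is additionally direct-excited by a
fraction d_cy5_532 of the budget (and re-transfers to Alexa750 with E2).
Under 638 nm, Cy5 photons split (1-E2) : E2 with a direct-excited Alexa750
fraction d_a750_638.  Channel signals are scaled by per-dye detection
factors (g_cy5 = 1 by convention), mixed by linear bleedthrough, then
degraded by Poisson shot noise, Gaussian read noise and a constant
background.  Each dye photobleaches in a single step, exponentially in its
cumulative excitation exposure; Cy3 -> Alexa750 transfer is always zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from trifret.trace_io import Manifest, TraceSet


@dataclass
class KineticConfig:
    """Ground-truth kinetic and FRET-level parameters of one condition.

    Defaults reproduce the Chd1 / original-601-orientation condition at
    500 uM ATP: mean lag 4.9 s via k_max = (K_app + 500) / (4.9 * 500).
    """

    atp_uM: float = 500.0
    k_max: float = 560.0 / (4.9 * 500.0)   # 1/s, saturating lag rate
    K_app: float = 60.0                    # uM, half-saturation of the lag rate
    k_init: float = 0.2                    # 1/s, rate leaving the initial waiting state
    d_rise: float = 2.0                    # s, entry-FRET rise ramp
    d_fall: float = 3.0                    # s, entry-FRET fall ramp
    d_exit: float = 2.0                    # s, exit-FRET decrease ramp
    E_exit0: float = 0.75
    E_exit1: float = 0.25
    E_entry0: float = 0.15
    E_entry_peak: float = 0.75
    E_entry1: float = 0.45
    n_molecules: int = 185
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_max", "K_app", "k_init", "d_rise", "d_fall", "d_exit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("E_exit0", "E_exit1", "E_entry0", "E_entry_peak", "E_entry1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.E_entry_peak <= max(self.E_entry0, self.E_entry1):
            raise ValueError("E_entry_peak must exceed both E_entry0 and E_entry1")
        if self.E_exit1 >= self.E_exit0:
            raise ValueError("E_exit1 must be below E_exit0")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")

    @property
    def mean_lag_s(self) -> float:
        """Mean lag tau(ATP) = (K_app + S) / (k_max * S)."""
        if self.atp_uM <= 0:
            raise ValueError("atp_uM must be > 0 for a finite mean lag")
        return (self.K_app + self.atp_uM) / (self.k_max * self.atp_uM)

    @classmethod
    def for_mean_lag(cls, mean_lag_s: float, atp_uM: float = 500.0,
                     K_app: float = 60.0, **kwargs) -> "KineticConfig":
        """Config whose lag hyperbola gives ``mean_lag_s`` at ``atp_uM``."""
        k_max = (K_app + atp_uM) / (mean_lag_s * atp_uM)
        return cls(atp_uM=atp_uM, k_max=k_max, K_app=K_app, **kwargs)


@dataclass
class PhotoConfig:
    """Photophysics of the rendering stage.

    Detection scale factors are quantum-yield x detector-efficiency products
    relative to Cy5 (g_cy5 == 1 by convention).  Bleach rates are per second
    of cumulative exposure to the laser(s) that excite the dye: Cy3 sees only
    the 532 nm half of the ALEX cycle; Cy5 and Alexa750 see both halves.
    """

    photon_budget: float = 500.0           # expected photons per excitation frame
    g_cy3: float = 1.25
    g_a750: float = 0.8
    d_cy5_532: float = 0.05                # direct excitation of Cy5 at 532 nm
    d_a750_638: float = 0.05               # direct excitation of A750 at 638 nm
    b_cy3_to_cy5: float = 0.1              # bleedthrough fractions
    b_cy5_to_a750: float = 0.1
    bg_cy3: float = 10.0                   # background offsets per channel
    bg_cy5: float = 10.0
    bg_a750: float = 10.0
    read_noise_sd: float = 5.0
    bleach_rate_cy3: float = 2e-4          # 1/s of exposure
    bleach_rate_cy5: float = 2e-4
    bleach_rate_a750: float = 5e-4
    shot_noise: bool = True

    def __post_init__(self) -> None:
        for name in ("d_cy5_532", "d_a750_638", "b_cy3_to_cy5", "b_cy5_to_a750"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.g_cy3 <= 0 or self.g_a750 <= 0 or self.photon_budget <= 0:
            raise ValueError("scale factors and photon budget must be > 0")

    @classmethod
    def noiseless(cls, **kwargs) -> "PhotoConfig":
        """Crosstalk retained but no shot/read noise, background or bleaching."""
        base = dict(bg_cy3=0.0, bg_cy5=0.0, bg_a750=0.0, read_noise_sd=0.0,
                    bleach_rate_cy3=0.0, bleach_rate_cy5=0.0, bleach_rate_a750=0.0,
                    shot_noise=False)
        base.update(kwargs)
        return cls(**base)

    def to_correction_params(self):
        """Exact correction parameters for traces rendered with this config."""
        from trifret.correction import CorrectionParams

        return CorrectionParams(
            d_cy5_532=self.d_cy5_532, d_a750_638=self.d_a750_638,
            b_cy3_to_cy5=self.b_cy3_to_cy5, b_cy5_to_a750=self.b_cy5_to_a750,
            s_cy3=1.0 / self.g_cy3, s_a750=1.0 / self.g_a750,
        )


@dataclass
class EventTimeline:
    """Ground truth for one molecule: onsets, lag and piecewise-linear FRET."""

    molecule_id: int
    t_entry_onset: float
    t_lag: float
    config: KineticConfig = field(repr=False)
    bleach_cy3: float = math.inf
    bleach_cy5: float = math.inf
    bleach_a750: float = math.inf

    @property
    def t_exit_onset(self) -> float:
        return self.t_entry_onset + self.t_lag

    def e1(self, t: np.ndarray) -> np.ndarray:
        """Exit-side Cy3->Cy5 efficiency at times ``t`` (ignores bleaching)."""
        c = self.config
        xp = [self.t_exit_onset, self.t_exit_onset + c.d_exit]
        fp = [c.E_exit0, c.E_exit1]
        return np.interp(np.asarray(t, dtype=float), xp, fp)

    def e2(self, t: np.ndarray) -> np.ndarray:
        """Entry-side Cy5->A750 efficiency at times ``t`` (ignores bleaching)."""
        c = self.config
        xp = [self.t_entry_onset, self.t_entry_onset + c.d_rise,
              self.t_entry_onset + c.d_rise + c.d_fall]
        fp = [c.E_entry0, c.E_entry_peak, c.E_entry1]
        return np.interp(np.asarray(t, dtype=float), xp, fp)


def sample_kinetics(cfg: KineticConfig, rng: np.random.Generator,
                    photo: PhotoConfig | None = None) -> list[EventTimeline]:
    """Draw per-molecule event timelines (and bleach times if ``photo`` given).

    t_entry_onset ~ Exp(mean 1/k_init); t_lag ~ Exp(mean tau(ATP)).  Bleach
    times are exponential in exposure; Cy3 is exposed only during the 532 nm
    half of the ALEX cycle, so its wall-clock bleach time is doubled.
    """
    tau = cfg.mean_lag_s  # raises for atp_uM <= 0
    if not math.isfinite(tau):
        raise ValueError("mean lag is not finite for this configuration")
    t_entry = rng.exponential(1.0 / cfg.k_init, size=cfg.n_molecules)
    t_lag = rng.exponential(tau, size=cfg.n_molecules)

    def _bleach(rate: float, wall_factor: float) -> np.ndarray:
        if photo is None or rate <= 0:
            return np.full(cfg.n_molecules, math.inf)
        return wall_factor * rng.exponential(1.0 / rate, size=cfg.n_molecules)

    b3 = _bleach(photo.bleach_rate_cy3 if photo else 0.0, 2.0)
    b5 = _bleach(photo.bleach_rate_cy5 if photo else 0.0, 1.0)
    b7 = _bleach(photo.bleach_rate_a750 if photo else 0.0, 1.0)
    return [
        EventTimeline(i, t_entry[i], t_lag[i], cfg, b3[i], b5[i], b7[i])
        for i in range(cfg.n_molecules)
    ]


def _expected_channels(e1, e2, alive3, alive5, alive7, photo: PhotoConfig, is532):
    """Expected per-channel detected signal (before noise and background)."""
    N = photo.photon_budget
    e1eff = e1 * alive5          # transfer out of Cy3 needs a live Cy5
    e2eff = e2 * alive7          # transfer out of Cy5 needs a live A750
    # 532 nm: Cy3 cascade plus direct-excited Cy5
    s3 = photo.g_cy3 * N * (1.0 - e1eff) * alive3
    in5_532 = N * (e1eff * alive3 + photo.d_cy5_532) * alive5
    s5_532 = in5_532 * (1.0 - e2eff)
    s7_532 = photo.g_a750 * in5_532 * e2eff
    # 638 nm: Cy5 split plus direct-excited A750
    in5_638 = N * alive5
    s5_638 = in5_638 * (1.0 - e2eff)
    s7_638 = photo.g_a750 * (in5_638 * e2eff + N * photo.d_a750_638 * alive7)
    s3_det = np.where(is532, s3, 0.0)
    s5_src = np.where(is532, s5_532, s5_638)
    s7_src = np.where(is532, s7_532, s7_638)
    i_cy3 = s3_det
    i_cy5 = s5_src + photo.b_cy3_to_cy5 * s3_det
    i_a750 = s7_src + photo.b_cy5_to_a750 * s5_src
    return i_cy3, i_cy5, i_a750


def render_traces(timelines: list[EventTimeline], photo: PhotoConfig,
                  manifest: Manifest, rng: np.random.Generator,
                  duration_s: float = 120.0) -> TraceSet:
    """Render event timelines into raw alternating-excitation frame intensities."""
    dt = manifest.frame_interval_s
    p = manifest.alternation_period
    n_frames = int(round(duration_s / dt))
    frames = np.arange(n_frames)
    t = frames * dt
    is532 = ((frames // p) % 2) == 0
    parts = []
    for tl in timelines:
        e1 = tl.e1(t)
        e2 = tl.e2(t)
        alive3 = (t < tl.bleach_cy3).astype(float)
        alive5 = (t < tl.bleach_cy5).astype(float)
        alive7 = (t < tl.bleach_a750).astype(float)
        i3, i5, i7 = _expected_channels(e1, e2, alive3, alive5, alive7, photo, is532)
        if photo.shot_noise:
            i3 = rng.poisson(i3).astype(float)
            i5 = rng.poisson(i5).astype(float)
            i7 = rng.poisson(i7).astype(float)
        if photo.read_noise_sd > 0:
            i3 = i3 + rng.normal(0.0, photo.read_noise_sd, n_frames)
            i5 = i5 + rng.normal(0.0, photo.read_noise_sd, n_frames)
            i7 = i7 + rng.normal(0.0, photo.read_noise_sd, n_frames)
        parts.append(pd.DataFrame({
            "molecule_id": tl.molecule_id, "frame": frames, "time_s": t,
            "excitation": np.where(is532, 532, 638),
            "I_cy3": i3 + photo.bg_cy3,
            "I_cy5": i5 + photo.bg_cy5,
            "I_a750": i7 + photo.bg_a750,
        }))
    return TraceSet(pd.concat(parts, ignore_index=True), manifest)


def ground_truth_table(timelines: list[EventTimeline]) -> pd.DataFrame:
    """True onset, lag and bleach times per molecule (benchmark for detection)."""
    cols = ["molecule_id", "t_entry_s", "t_exit_s", "t_lag_s",
            "bleach_cy3_s", "bleach_cy5_s", "bleach_a750_s"]
    rows = [
        (tl.molecule_id, tl.t_entry_onset, tl.t_exit_onset, tl.t_lag,
         tl.bleach_cy3, tl.bleach_cy5, tl.bleach_a750)
        for tl in timelines
    ]
    return pd.DataFrame(rows, columns=cols)


def simulate_dataset(kin: KineticConfig, photo: PhotoConfig | None = None,
                     manifest: Manifest | None = None,
                     duration_s: float = 120.0):
    """Convenience: timelines + rendered TraceSet + truth table from one seed."""
    if photo is None:
        photo = PhotoConfig()
    if manifest is None:
        manifest = Manifest(atp_uM=kin.atp_uM, seed=kin.seed)
    else:
        manifest = replace(manifest, atp_uM=kin.atp_uM, seed=kin.seed)
    rng = np.random.default_rng(kin.seed)
    timelines = sample_kinetics(kin, rng, photo)
    traces = render_traces(timelines, photo, manifest, rng, duration_s=duration_s)
    return timelines, traces, ground_truth_table(timelines)
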