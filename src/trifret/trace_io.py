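"""Reading, writing and validation of three-channel ALEX intensity traces.

A trace table is a plain TSV with one row per molecule-frame and the exact
column order ``molecule_id, frame, time_s, excitation, I_cy3, I_cy5, I_a750``;
``excitation`` is 532 or 638 (nm).  Each dataset carries a flat key-value
manifest recording the frame interval, the excitation alternation period
and the experimental condition.  Frames are 0-based, times are seconds from
acquisition start, and intensities are background-subtracted detector units
(negative values allowed).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACE_COLUMNS = ["molecule_id", "frame", "time_s", "excitation", "I_cy3", "I_cy5", "I_a750"]
EXCITATIONS = (532, 638)

#: tolerance on frame-interval regularity (seconds)
TIME_TOL = 1e-6


class TraceFormatError(ValueError):
    """Raised when a trace file violates the column contract."""


class TraceValidationError(ValueError):
    """Raised when trace contents violate a dataset invariant."""


@dataclass
class Manifest:
    """Acquisition metadata for one trace set."""

    frame_interval_s: float = 0.1
    alternation_period: int = 1
    atp_uM: float = 500.0
    remodeller: str = "Chd1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.alternation_period < 1:
            raise ValueError("alternation_period must be >= 1")

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for key in ("frame_interval_s", "alternation_period", "atp_uM", "remodeller", "seed"):
                val = getattr(self, key)
                if val is not None:
                    fh.write(f"{key}\t{val}\n")

    @classmethod
    def read(cls, path: str | os.PathLike) -> "Manifest":
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("\t")
                kv[key.strip()] = val.strip()
        return cls(
            frame_interval_s=float(kv.get("frame_interval_s", 0.1)),
            alternation_period=int(kv.get("alternation_period", 1)),
            atp_uM=float(kv.get("atp_uM", 500.0)),
            remodeller=kv.get("remodeller", "Chd1"),
            seed=int(kv["seed"]) if "seed" in kv else None,
        )


@dataclass
class TraceSet:
    """Per-molecule raw three-channel intensity frames plus manifest."""

    frames: pd.DataFrame
    manifest: Manifest

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.frames.columns]
        if missing:
            raise TraceFormatError(f"trace table missing column(s): {', '.join(missing)}")
        self.frames = self.frames[TRACE_COLUMNS].reset_index(drop=True)

    @property
    def molecule_ids(self) -> np.ndarray:
        return self.frames["molecule_id"].unique()

    def molecule(self, molecule_id: int) -> pd.DataFrame:
        return self.frames[self.frames["molecule_id"] == molecule_id]

    def validate(self) -> None:
        """Check all per-molecule invariants; raise TraceValidationError on failure."""
        df = self.frames
        bad_exc = ~df["excitation"].isin(EXCITATIONS)
        if bad_exc.any():
            row = df[bad_exc].iloc[0]
            raise TraceValidationError(
                f"molecule {row['molecule_id']} frame {row['frame']}: "
                f"excitation {row['excitation']} not in {EXCITATIONS}"
            )
        p = self.manifest.alternation_period
        dt = self.manifest.frame_interval_s
        for mol, g in df.groupby("molecule_id", sort=False):
            frames = g["frame"].to_numpy()
            if np.any(np.diff(frames) <= 0):
                i = int(np.argmax(np.diff(frames) <= 0))
                raise TraceValidationError(
                    f"molecule {mol}: frame indices not strictly increasing at frame {frames[i + 1]}"
                )
            times = g["time_s"].to_numpy()
            if np.any(np.abs(np.diff(times) - dt * np.diff(frames)) > TIME_TOL):
                raise TraceValidationError(
                    f"molecule {mol}: time steps inconsistent with frame_interval_s={dt}"
                )
            exc = g["excitation"].to_numpy()
            expected = np.where((frames // p) % 2 == 0, 532, 638)
            if np.any(exc != expected):
                i = int(np.argmax(exc != expected))
                raise TraceValidationError(
                    f"molecule {mol}: excitation pattern breaks alternation "
                    f"(period {p}) at frame {frames[i]}"
                )


@dataclass
class AlexSeries:
    """Time-aligned 532/638 intensity records, one row per ALEX cycle.

    Columns: molecule_id, time_s (midpoint of the paired blocks),
    time_532_s, time_638_s (the blocks' own times), I532_cy3, I532_cy5,
    I532_a750, I638_cy5, I638_a750.  ``n_dropped`` counts unpaired trailing
    frames per molecule; ``skipped`` lists molecules with fewer than 2 frames.
    """

    frames: pd.DataFrame
    n_dropped: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)

    def molecule(self, molecule_id: int) -> pd.DataFrame:
        return self.frames[self.frames["molecule_id"] == molecule_id]


def write_traces(traces: TraceSet, path: str | os.PathLike, manifest_path: str | os.PathLike | None = None) -> None:
    """Write a trace table as TSV (full float precision) and optionally its manifest."""
    df = traces.frames.copy()
    df["molecule_id"] = df["molecule_id"].astype(int)
    df["frame"] = df["frame"].astype(int)
    df["excitation"] = df["excitation"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    if manifest_path is not None:
        traces.manifest.write(manifest_path)


def read_traces(path: str | os.PathLike, manifest_path: str | os.PathLike) -> TraceSet:
    """Read and validate a trace table + manifest.

    Raises TraceFormatError for header problems and TraceValidationError for
    invariant violations (naming the molecule and frame).
    """
    manifest = Manifest.read(manifest_path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in TRACE_COLUMNS if c not in header]
        if missing:
            raise TraceFormatError(f"trace table missing column(s): {', '.join(missing)}")
        df = pd.read_csv(
            io.StringIO(fh.read()), sep="\t", names=header,
            dtype={"molecule_id": np.int64, "frame": np.int64, "excitation": np.int64},
        )
    ts = TraceSet(df, manifest)
    ts.validate()
    return ts


def _blocks(g: pd.DataFrame) -> tuple[list, list]:
    """Collapse consecutive same-excitation runs into (time, channel-means) blocks."""
    exc = g["excitation"].to_numpy()
    run_id = np.concatenate([[0], np.cumsum(exc[1:] != exc[:-1])])
    b532, b638 = [], []
    for _, blk in g.groupby(run_id, sort=False):
        rec = (
            blk["time_s"].mean(),
            blk["I_cy3"].mean(),
            blk["I_cy5"].mean(),
            blk["I_a750"].mean(),
            len(blk),
        )
        (b532 if blk["excitation"].iat[0] == 532 else b638).append(rec)
    return b532, b638


def pair_alex_frames(traces: TraceSet, manifest: Manifest | None = None) -> AlexSeries:
    """Pair alternating 532/638 excitation blocks into aligned ALEX records.

    Each record joins one 532 block with its nearest-in-time 638 block (the
    i-th of each in time order, since excitation strictly alternates); the
    record timestamp is the midpoint of the two block times.  Unpaired
    trailing blocks are dropped and counted; molecules with fewer than two
    frames are skipped.
    """
    if manifest is None:
        manifest = traces.manifest
    rows = []
    n_dropped: dict = {}
    skipped: list = []
    for mol, g in traces.frames.groupby("molecule_id", sort=False):
        if len(g) < 2:
            skipped.append(mol)
            continue
        b532, b638 = _blocks(g)
        n = min(len(b532), len(b638))
        dropped = sum(b[4] for b in b532[n:]) + sum(b[4] for b in b638[n:])
        if dropped:
            n_dropped[mol] = dropped
        for (t5, c3, c5, a7, _), (t6, _, c5r, a7r, _) in zip(b532[:n], b638[:n]):
            rows.append((mol, 0.5 * (t5 + t6), t5, t6, c3, c5, a7, c5r, a7r))
    df = pd.DataFrame(
        rows,
        columns=["molecule_id", "time_s", "time_532_s", "time_638_s",
                 "I532_cy3", "I532_cy5", "I532_a750", "I638_cy5", "I638_a750"],
    )
    return AlexSeries(df, n_dropped=n_dropped, skipped=skipped)
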