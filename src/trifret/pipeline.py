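"""End-to-end convenience: raw traces -> corrected FRET -> event table.

Chains frame pairing, photobleach detection, crosstalk correction, FRET
computation and onset extraction with one call, mirroring how the analysis
is run on a full dataset.
"""

from __future__ import annotations

import pandas as pd

from trifret.correction import CorrectionParams, FretTraceSet, apply_corrections, compute_fret, default_denom_floor
from trifret.detection import DetectionParams, EventTable, detect_all_bleach, extract_events
from trifret.trace_io import TraceSet, pair_alex_frames


def analyze_traces(traces: TraceSet, params: CorrectionParams,
                   background: dict | None = None,
                   detection: DetectionParams | None = None,
                   denom_floor: float | None = None,
                   bleach_table: pd.DataFrame | None = None
                   ) -> tuple[FretTraceSet, EventTable]:
    """Run the full single-dataset analysis; returns (FRET traces, events)."""
    if detection is None:
        detection = DetectionParams()
    if bleach_table is None:
        bleach_table = detect_all_bleach(traces, params=detection, corrections=params)
    aligned = pair_alex_frames(traces)
    corrected = apply_corrections(aligned, params, background=background)
    if denom_floor is None:
        denom_floor = default_denom_floor()
    fret = compute_fret(corrected, denom_floor=denom_floor, bleach_table=bleach_table)
    events = extract_events(fret, params=detection, bleach_table=bleach_table)
    return fret, events
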