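"""Adjacent-peak-pair resolution and the transformed model response.

The pair resolution of two consecutive peaks i and j = i+1 is

    R_ij = 2 * (RT(j) - RT(i)) / (W_half(i) + W_half(j))

with retention times RT and full widths at half height W_half, both in
minutes.  The regression response is y = log10(R_ij + 1), which
homogenizes the error distribution across well- and poorly-separated
pairs.  A negative gap (elution order swapped by noise) is floored to
R = 0: for optimization purposes a swapped pair is maximally
unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from crocinopt.simulate import Chromatogram, N_ANALYTES, Peak

__all__ = [
    "ResolutionRecord",
    "pair_resolution",
    "adjacent_resolutions",
    "records_to_frame",
]


@dataclass(frozen=True)
class ResolutionRecord:
    condition_id: str
    pair: tuple[int, int]  # (i, i+1) in elution order
    R: float
    y: float  # log10(R + 1)


def pair_resolution(peak_i: Peak, peak_j: Peak) -> float:
    """R_ij of two consecutive peaks, floored at 0 for swapped orders."""
    if peak_i.w_half <= 0 or peak_j.w_half <= 0:
        raise ValueError("peak widths must be positive")
    r = 2.0 * (peak_j.rt - peak_i.rt) / (peak_i.w_half + peak_j.w_half)
    return max(0.0, r)


def adjacent_resolutions(chromatogram: Chromatogram) -> list[ResolutionRecord]:
    """The 21 consecutive-pair resolution records of one chromatogram."""
    peaks = {p.analyte_id: p for p in chromatogram.peaks}
    missing = [i for i in range(1, N_ANALYTES + 1) if i not in peaks]
    if missing:
        raise ValueError(f"chromatogram is missing analytes {missing}")
    records = []
    for i in range(1, N_ANALYTES):
        r = pair_resolution(peaks[i], peaks[i + 1])
        records.append(
            ResolutionRecord(
                condition_id=chromatogram.condition.id,
                pair=(i, i + 1),
                R=r,
                y=float(np.log10(r + 1.0)),
            )
        )
    return records


def records_to_frame(records: list[ResolutionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition_id": [r.condition_id for r in records],
            "i": [r.pair[0] for r in records],
            "j": [r.pair[1] for r in records],
            "R": [r.R for r in records],
            "y": [r.y for r in records],
        }
    )
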