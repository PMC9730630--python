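"""Editing-level quantification from Sanger chromatogram peak heights.

At a partially edited adenosine the cDNA trace shows superimposed A and G
peaks; the editing percentage is estimated as 100*G/(A+G) from
baseline-subtracted peak heights at the basecall position (peak area is
available behind a flag). For reverse-strand reads the expected primary
base is T and the channels are complement-swapped before the ratio is
formed, so forward and reverse reads of the same molecule agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import BASES
from .synthdata import ChromatogramTrace

CHANNEL_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_CHANNEL = {"A": "T", "C": "G", "G": "C", "T": "A"}


def peak_height(trace: ChromatogramTrace, base_index: int, channel: str,
                half_window: int = 4, mode: str = "height") -> float:
    """Baseline-subtracted channel signal near one basecall.

    ``mode="height"`` takes the maximum intensity within ``half_window``
    scan points of the basecall position; ``mode="area"`` sums the window.
    The baseline is the channel's median over the whole trace (flat
    channels therefore read as 0). Negative results clip to 0.
    """
    if channel not in CHANNEL_INDEX:
        raise ValueError(f"unknown channel {channel!r}")
    if not 0 <= base_index < len(trace.basecalls):
        raise IndexError("base_index outside basecall range")
    ci = CHANNEL_INDEX[channel]
    center = int(trace.base_positions[base_index])
    lo = max(0, center - half_window)
    hi = min(len(trace.intensities), center + half_window + 1)
    window = trace.intensities[lo:hi, ci]
    baseline = float(np.median(trace.intensities[:, ci]))
    if mode == "height":
        raw = float(window.max())
        return max(0.0, raw - baseline)
    if mode == "area":
        raw = float(np.sum(window - baseline))
        return max(0.0, raw)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class EditingEstimate:
    percent: float | None
    flag: str                # "ok" or "no-signal"
    a_height: float
    g_height: float


def estimate_editing(trace: ChromatogramTrace, base_index: int,
                     strand: str = "+", half_window: int = 4,
                     signal_floor: float = 0.0, mode: str = "height"
                     ) -> EditingEstimate:
    """Editing percentage 100*G/(A+G) at one basecall, clamped to [0, 100].

    On the forward strand the expected primary base is A and the edited
    allele appears in the G channel. On the reverse strand the read shows
    T with editing in the C channel, so channels are complement-swapped.
    When A+G falls at or below ``signal_floor`` the estimate is withheld
    with flag "no-signal".
    """
    if strand not in "+-":
        raise ValueError(f"invalid strand {strand!r}")
    chan_a, chan_g = ("A", "G") if strand == "+" else ("T", "C")
    expected = "A" if strand == "+" else "T"
    called = trace.basecalls[base_index]
    if called not in (expected, "G" if strand == "+" else "C", "N"):
        raise ValueError(
            f"basecall {called!r} at index {base_index} is not consistent "
            f"with an edited adenosine on strand {strand}")
    h_a = peak_height(trace, base_index, chan_a, half_window, mode)
    h_g = peak_height(trace, base_index, chan_g, half_window, mode)
    total = h_a + h_g
    if total <= signal_floor or total == 0.0:
        return EditingEstimate(None, "no-signal", h_a, h_g)
    percent = float(np.clip(100.0 * h_g / total, 0.0, 100.0))
    return EditingEstimate(percent, "ok", h_a, h_g)


def batch_quantify(traces: dict[str, ChromatogramTrace],
                   manifest: pd.DataFrame,
                   half_window: int = 4,
                   signal_floor: float = 0.0,
                   mode: str = "height") -> pd.DataFrame:
    """Quantify a batch of traces against a site manifest.

    ``manifest`` columns: trace_id, chrom, pos, patient, tissue,
    base_index, strand. Returns a long level table (chrom, pos, patient,
    tissue, level, flag) on the same 0-1 scale as the sequencing-based
    level matrix, so the result feeds the profiling and association
    statistics unchanged.
    """
    required = {"trace_id", "chrom", "pos", "patient", "tissue",
                "base_index", "strand"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    rows = []
    for _, row in manifest.iterrows():
        trace = traces[row["trace_id"]]
        est = estimate_editing(trace, int(row["base_index"]),
                               strand=row["strand"], half_window=half_window,
                               signal_floor=signal_floor, mode=mode)
        level = est.percent / 100.0 if est.percent is not None else np.nan
        rows.append((row["chrom"], int(row["pos"]), row["patient"],
                     row["tissue"], level, est.flag))
    return pd.DataFrame(rows, columns=["chrom", "pos", "patient", "tissue",
                                       "level", "flag"])
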