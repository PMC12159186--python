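"""Eye-movement control analyses.

The central statistic is the gaze bias: the trial is cut into 0.1 s bins,
each bin's mean gaze position is assigned the colour of the nearest
stimulus, and the bias is the fraction of valid bins assigned the target
colour.  Under colour-independent fixation on balanced displays this
fraction averages ~0.5; values near 1 indicate overt orienting toward the
target colour and would confound a covert-attention interpretation of the
tagging-response modulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GazeTrace, StimulusLayout

GAZE_BIN = 0.1  # s


@dataclass
class GazeBias:
    """Per-trial gaze-bias outcome."""

    fraction: float
    n_target_bins: int
    n_valid_bins: int
    n_bins: int


def gaze_bias(trace: GazeTrace, layout: StimulusLayout, target_colour: str,
              bin_duration: float = GAZE_BIN,
              summary: str = "mean") -> GazeBias:
    """Fraction of time bins whose gaze falls nearest a target-colour item.

    Bins fully or partly blink-contaminated are excluded, as are bins with
    an exact nearest-stimulus distance tie between colours.
    """
    if layout.set_size == 0:  # pragma: no cover - layout forbids this
        raise ValueError("empty layout")
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    n_bins = int(np.floor(trace.duration / bin_duration))
    if n_bins == 0:
        raise ValueError("trace shorter than one bin")
    samples_per_bin = int(round(bin_duration * trace.fs))
    valid = trace.valid_mask()
    reduce = np.mean if summary == "mean" else np.median

    n_target = 0
    n_valid = 0
    for b in range(n_bins):
        sl = slice(b * samples_per_bin, (b + 1) * samples_per_bin)
        v = valid[sl]
        if not v.any():
            continue
        gx = reduce(trace.x[sl][v])
        gy = reduce(trace.y[sl][v])
        dist = np.hypot(layout.positions[:, 0] - gx, layout.positions[:, 1] - gy)
        nearest = np.min(dist)
        at_min = np.isclose(dist, nearest)
        colours = set(layout.colours[at_min])
        if len(colours) > 1:
            continue  # equidistant colour tie: bin excluded entirely
        n_valid += 1
        if colours.pop() == target_colour:
            n_target += 1
    if n_valid == 0:
        raise ValueError("all bins invalid (blinks or ties)")
    return GazeBias(fraction=n_target / n_valid, n_target_bins=n_target,
                    n_valid_bins=n_valid, n_bins=n_bins)


def mean_gaze_bias(traces, layouts, target_colours,
                   bin_duration: float = GAZE_BIN) -> float:
    """Gaze bias averaged over trials."""
    vals = [gaze_bias(tr, lay, tc, bin_duration).fraction
            for tr, lay, tc in zip(traces, layouts, target_colours)]
    return float(np.mean(vals))


def event_counts_by_split(traces, trials: pd.DataFrame,
                          split: pd.Series | None = None) -> pd.DataFrame:
    """Mean saccade and blink counts per condition cell and RT split.

    ``trials`` must carry a ``"split"`` column (or pass ``split``) with
    "fast"/"slow" labels; ``traces`` is aligned with ``trials`` rows.
    """
    trials = trials.copy()
    if split is not None:
        trials["split"] = split
    if "split" not in trials.columns:
        raise ValueError("trials need a 'split' column (see behaviour.median_split)")
    trials = trials.reset_index(drop=True)
    trials["n_saccades"] = [len(tr.saccade_events) for tr in traces]
    trials["n_blinks"] = [len(tr.blink_events) for tr in traces]
    out = (trials.groupby(["condition", "set_size", "split"], observed=True)
           [["n_saccades", "n_blinks"]].agg(["mean", "count"]))
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()


@dataclass
class FixationHeatmap:
    density: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    central_fraction: float  # fraction of samples within the 1 deg box


def fixation_heatmap(traces, extent: float = 5.0, resolution: int = 50,
                     central_halfwidth: float = 1.0) -> FixationHeatmap:
    """2-D gaze-sample density over the display and central fixation share.

    ``central_fraction`` reports the share of valid samples within
    ``central_halfwidth`` degrees of the fixation point in both axes.
    """
    xs, ys = [], []
    for tr in traces:
        v = tr.valid_mask()
        xs.append(tr.x[v])
        ys.append(tr.y[v])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size == 0:
        raise ValueError("no valid gaze samples")
    edges = np.linspace(-extent, extent, resolution + 1)
    hist, xe, ye = np.histogram2d(x, y, bins=[edges, edges])
    total = hist.sum()
    density = hist / total if total > 0 else hist
    central = np.mean((np.abs(x) <= central_halfwidth)
                      & (np.abs(y) <= central_halfwidth))
    return FixationHeatmap(density=density, x_edges=xe, y_edges=ye,
                           central_fraction=float(central))
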