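"""Trial-resolved fluorescence preprocessing for olfactory neural datasets.

Piriform-style traces are smoothed with a centered moving average (window 5),
a baseline mean and SD are taken over the 30 frames before odor onset, and a
trial elicits a response when the post-onset maximum (30 frames) strictly
exceeds mu + 3*sigma.  The (odorant, neuron) activity is the fraction of
elicited trials.  Glomerular dF/F matrices are median-subtracted per
glomerulus and the negative (odor-evoked) deflections are normalized by the
glomerulus's mean squared deviation from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class TrialTraces:
    frames: np.ndarray  # trials x time
    onset: int
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one trial")
        if not 0 <= self.onset <= self.frames.shape[1]:
            raise ValueError("onset outside trace")


@dataclass(frozen=True)
class BaselineStats:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class NeuralConfig:
    smooth_window: int = 5
    baseline_frames: int = 30
    response_frames: int = 30
    sigma_mult: float = 3.0
    smooth_mode: str = "centered"  # or "trailing"
    baseline_source: str = "raw"  # or "smoothed"

    def __post_init__(self) -> None:
        if min(self.smooth_window, self.baseline_frames, self.response_frames) < 1:
            raise ValueError("window sizes must be positive")
        if self.smooth_mode not in ("centered", "trailing"):
            raise ValueError(f"unknown smooth_mode {self.smooth_mode!r}")
        if self.baseline_source not in ("raw", "smoothed"):
            raise ValueError(f"unknown baseline_source {self.baseline_source!r}")


def smooth_trace(trace: np.ndarray, window: int = 5, mode: str = "centered") -> np.ndarray:
    """Moving-average smoothing; the window truncates at the trace edges.

    ``centered`` averages frames [t − w//2, t + w//2] clipped to the trace;
    ``trailing`` averages [t − w + 1, t].
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if window < 1 or window > n:
        raise ValueError(f"window {window} outside [1, {n}]")
    kernel = np.ones(window)
    if mode == "centered":
        sums = np.convolve(trace, kernel, mode="same")
        counts = np.convolve(np.ones(n), kernel, mode="same")
    elif mode == "trailing":
        sums = np.convolve(trace, kernel, mode="full")[: n]
        counts = np.convolve(np.ones(n), kernel, mode="full")[: n]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return sums / counts


def baseline_stats(trace: np.ndarray, onset: int, n_baseline: int = 30) -> BaselineStats:
    """Mean and population SD over the n_baseline frames immediately pre-onset."""
    trace = np.asarray(trace, dtype=float)
    if onset < n_baseline:
        raise ValueError(f"onset {onset} leaves fewer than {n_baseline} baseline frames")
    window = trace[onset - n_baseline : onset]
    return BaselineStats(mu=float(window.mean()), sigma=float(window.std(ddof=0)))


def trial_elicited(trace: np.ndarray, onset: int, cfg: NeuralConfig = NeuralConfig()) -> bool:
    """Does a single trial elicit a response?

    The trace is smoothed first; the trial responds iff the maximum of the
    smoothed curve over the response window strictly exceeds
    mu + sigma_mult * sigma of the baseline.  By default the baseline
    statistics are established on the raw activities: estimating sigma from
    the smoothed curve deflates it by roughly sqrt(window), which makes a
    3-sigma threshold fire on noise far more often than its nominal rate
    (``baseline_source='smoothed'`` selects that variant anyway).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < onset + cfg.response_frames:
        raise ValueError("trace too short for the response window")
    smoothed = smooth_trace(trace, cfg.smooth_window, cfg.smooth_mode)
    stats_source = trace if cfg.baseline_source == "raw" else smoothed
    stats = baseline_stats(stats_source, onset, cfg.baseline_frames)
    peak = float(smoothed[onset : onset + cfg.response_frames].max())
    return peak > stats.mu + cfg.sigma_mult * stats.sigma


def elicitation_rate(traces: TrialTraces, cfg: NeuralConfig = NeuralConfig()) -> float:
    """Fraction of trials elicited for one (odorant, neuron) pair."""
    flags = [trial_elicited(row, traces.onset, cfg) for row in traces.frames]
    return float(np.mean(flags))


def elicitation_matrix(
    dataset: Mapping[tuple[str, str], TrialTraces], cfg: NeuralConfig = NeuralConfig()
) -> pd.DataFrame:
    """Odorant x neuron matrix of average elicitation rates."""
    odorants = sorted({od for od, _ in dataset})
    neurons = sorted({nr for _, nr in dataset})
    out = pd.DataFrame(np.nan, index=odorants, columns=neurons)
    for (od, nr), traces in dataset.items():
        if traces.frames.shape[0] == 0:
            raise ValueError(f"empty trial set for ({od}, {nr})")
        out.loc[od, nr] = elicitation_rate(traces, cfg)
    if out.isna().any().any():
        raise ValueError("dataset does not cover the full odorant x neuron grid")
    return out


def glomerular_scores(dff: np.ndarray, denominator: str = "msd") -> np.ndarray:
    """Normalized odor-evoked scores for an odorant x glomerulus dF/F matrix.

    Per glomerulus (column): subtract the median across odorants so zero is a
    typical baseline response; keep the negative (odor-evoked) deflections;
    divide by the column's mean squared deviation from zero (``msd``) or its
    root (``rms``).
    """
    dff = np.asarray(dff, dtype=float)
    if dff.ndim != 2 or dff.shape[0] < 2:
        raise ValueError("need an odorant x glomerulus matrix with >= 2 odorants")
    if denominator not in ("msd", "rms"):
        raise ValueError(f"unknown denominator {denominator!r}")
    centered = dff - np.median(dff, axis=0, keepdims=True)
    msd = np.mean(centered**2, axis=0)
    if np.any(msd == 0):
        cols = np.nonzero(msd == 0)[0].tolist()
        raise ValueError(f"constant glomerulus columns (zero deviation): {cols}")
    denom = msd if denominator == "msd" else np.sqrt(msd)
    evoked = np.minimum(centered, 0.0)
    return evoked / denom


# -- I/O -----------------------------------------------------------------

def read_trial_manifest(manifest_path) -> dict[tuple[str, str], TrialTraces]:
    """Load traces from a manifest CSV (odorant, neuron, path, onset).

    Each referenced CSV holds one row per trial (no header).
    """
    import os

    manifest = pd.read_csv(manifest_path, dtype={"odorant": str, "neuron": str})
    base = os.path.dirname(str(manifest_path))
    out: dict[tuple[str, str], TrialTraces] = {}
    for row in manifest.itertuples():
        path = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        frames = np.loadtxt(path, delimiter=",", ndmin=2)
        out[(row.odorant, row.neuron)] = TrialTraces(frames=frames, onset=int(row.onset))
    return out
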