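"""ERP averaging, component measurement and statistics.

Component amplitudes follow the measurement rules of the analysis: peak
latency is the polarity-consistent extremum inside the canonical window
(P1 30-75, N1 80-105, P2 110-125, N2 130-180, P3 200-500 ms, inclusive),
amplitude is the mean over the 10 ms window centred on the peak latency,
and the P2 amplitude is the N1-P2 peak-to-peak difference. Statistics are
one-sample and paired two-tailed t-tests with Benjamini-Hochberg FDR
correction across the nine channels and paired Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DEVIANT, STANDARD, EpochSet

COMPONENT_WINDOWS_MS: dict[str, tuple[float, float]] = {
    "P1": (30.0, 75.0),
    "N1": (80.0, 105.0),
    "P2": (110.0, 125.0),
    "N2": (130.0, 180.0),
    "P3": (200.0, 500.0),
}

AMPLITUDE_HALF_WINDOW_MS = 5.0  # "10 ms around the peak latency"


class DegenerateVarianceError(ValueError):
    """Raised when a t statistic or effect size is undefined (zero SD)."""


@dataclass
class ERPAverage:
    """Per-class average waveforms for every channel."""

    stimulus_class: str
    channels: tuple[str, ...]
    time_ms: np.ndarray
    waveforms: np.ndarray      # (n_channels, n_samples) µV
    n_trials: np.ndarray       # per-channel retained-trial counts

    def channel(self, label: str) -> np.ndarray:
        return self.waveforms[list(self.channels).index(label)]


@dataclass
class DifferenceCurve:
    channels: tuple[str, ...]
    time_ms: np.ndarray
    waveforms: np.ndarray

    def channel(self, label: str) -> np.ndarray:
        return self.waveforms[list(self.channels).index(label)]


@dataclass(frozen=True)
class ComponentMeasure:
    component: str
    window_ms: tuple[float, float]
    peak_latency_ms: float
    amplitude_uV: float
    amplitude_kind: str  # 'baseline_to_peak' | 'n1p2_peak_to_peak'


@dataclass
class StatResult:
    label: str
    t: float
    df: int
    p_uncorrected: float
    cohens_d: float | None = None
    p_fdr: float | None = None
    alpha: float = 0.05


def average_erp(epochs: EpochSet, stimulus_class: str) -> ERPAverage:
    """Mean over retained trials of one stimulus class, per channel."""
    cls = epochs.class_mask(stimulus_class)
    if not cls.any():
        raise ValueError(f"no trials of class {stimulus_class!r}")
    n_ch = len(epochs.channels)
    waves = np.empty((n_ch, epochs.time_ms.size))
    counts = np.empty(n_ch, dtype=int)
    for ci in range(n_ch):
        keep = cls & epochs.retained[:, ci]
        counts[ci] = keep.sum()
        if counts[ci] == 0:
            raise ValueError(
                f"no retained {stimulus_class!r} trials on channel "
                f"{epochs.channels[ci]}")
        waves[ci] = epochs.data[keep, ci].mean(axis=0)
    return ERPAverage(stimulus_class, tuple(epochs.channels),
                      epochs.time_ms.copy(), waves, counts)


def difference_curve(dev: ERPAverage, std: ERPAverage) -> DifferenceCurve:
    """Deviant-minus-standard average, pointwise per channel."""
    if tuple(dev.channels) != tuple(std.channels) or \
            dev.time_ms.shape != std.time_ms.shape or \
            not np.allclose(dev.time_ms, std.time_ms):
        raise ValueError("averages have mismatching channels or time axes")
    return DifferenceCurve(tuple(dev.channels), dev.time_ms.copy(),
                           dev.waveforms - std.waveforms)


def find_component_peak(waveform: np.ndarray, time_ms: np.ndarray,
                        component: str,
                        window_ms: tuple[float, float] | None = None) -> float:
    """Latency of the polarity-consistent extremum inside the (inclusive)
    component window; ties break to the earliest sample."""
    lo, hi = window_ms or COMPONENT_WINDOWS_MS[component]
    mask = (time_ms >= lo) & (time_ms <= hi)
    if not mask.any():
        raise ValueError(
            f"component window {lo}-{hi} ms is outside the epoch time axis")
    seg = np.asarray(waveform)[mask]
    idx = int(np.argmax(seg) if component.startswith("P") else np.argmin(seg))
    return float(time_ms[mask][idx])


def component_amplitude(waveform: np.ndarray, time_ms: np.ndarray,
                        component: str, peak_latency_ms: float,
                        n1_measure: ComponentMeasure | None = None
                        ) -> ComponentMeasure:
    """Mean amplitude over the 10 ms window centred on the peak latency.

    For P2 the amplitude is reported peak-to-peak relative to N1, so an N1
    measure from the same waveform must be supplied.
    """
    lo = peak_latency_ms - AMPLITUDE_HALF_WINDOW_MS
    hi = peak_latency_ms + AMPLITUDE_HALF_WINDOW_MS
    mask = (time_ms >= lo) & (time_ms <= hi)
    if not mask.any():
        raise ValueError("10 ms amplitude window outside the time axis")
    amp = float(np.asarray(waveform)[mask].mean())
    window = COMPONENT_WINDOWS_MS.get(component, (lo, hi))
    if component == "P2":
        if n1_measure is None:
            raise ValueError("P2 amplitude is N1-P2 peak-to-peak; an N1 "
                             "measure is required")
        return ComponentMeasure("P2", window, peak_latency_ms,
                                amp - n1_measure.amplitude_uV,
                                "n1p2_peak_to_peak")
    return ComponentMeasure(component, window, peak_latency_ms, amp,
                            "baseline_to_peak")


def measure_components(waveform: np.ndarray, time_ms: np.ndarray,
                       components: tuple[str, ...] = ("P1", "N1", "P2",
                                                      "N2", "P3"),
                       peak_latencies_ms: dict[str, float] | None = None,
                       ) -> dict[str, ComponentMeasure]:
    """Measure several components on one waveform.

    If ``peak_latencies_ms`` is given (e.g. latencies determined on a grand
    average, or canonical template latencies for an unbiased fixed-window
    analysis), amplitudes are taken around those latencies; otherwise peaks
    are searched on this waveform.
    """
    out: dict[str, ComponentMeasure] = {}
    order = [c for c in ("P1", "N1", "P2", "N2", "P3") if c in components]
    for comp in order:
        if peak_latencies_ms and comp in peak_latencies_ms:
            lat = peak_latencies_ms[comp]
        else:
            lat = find_component_peak(waveform, time_ms, comp)
        out[comp] = component_amplitude(waveform, time_ms, comp, lat,
                                        n1_measure=out.get("N1"))
    return out


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def one_sample_t(values, label: str = "", alpha: float = 0.05) -> StatResult:
    """Two-tailed one-sample t-test against zero, df = n - 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    if np.std(v, ddof=1) == 0:
        raise DegenerateVarianceError("zero variance; t undefined")
    res = stats.ttest_1samp(v, 0.0)
    return StatResult(label, float(res.statistic), v.size - 1,
                      float(res.pvalue), alpha=alpha)


def cohens_d_paired(a, b) -> float:
    """Paired Cohen's d: mean of the differences over their sample SD."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    sd = np.std(d, ddof=1)
    if sd == 0:
        if np.mean(d) == 0:
            return 0.0
        raise DegenerateVarianceError(
            "all differences identical but nonzero; effect size infinite")
    return float(np.mean(d) / sd)


def paired_t(a, b, label: str = "", alpha: float = 0.05) -> StatResult:
    """Two-tailed paired t-test (equivalently one-sample t on a - b),
    with paired Cohen's d attached."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    if np.std(diffs, ddof=1) == 0:
        if np.all(diffs == 0):
            return StatResult(label, 0.0, a.size - 1, 1.0, cohens_d=0.0,
                              alpha=alpha)
        raise DegenerateVarianceError("differences have zero variance")
    res = one_sample_t(diffs, label=label, alpha=alpha)
    res.cohens_d = cohens_d_paired(a, b)
    return res


def grouped_paired_t(a_by_channel: dict[str, np.ndarray],
                     b_by_channel: dict[str, np.ndarray],
                     channels: tuple[str, ...], label: str = "") -> StatResult:
    """Paired t on per-animal measures averaged over a channel group
    (e.g. the frontal or mid electrode row). Interpretation aid, not part
    of the per-channel family."""
    a = np.mean([a_by_channel[c] for c in channels], axis=0)
    b = np.mean([b_by_channel[c] for c in channels], axis=0)
    return paired_t(a, b, label=label)


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, rejection flags at level ``q``).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def erp_stats_table(measures: pd.DataFrame, sham_label: str = "sham",
                    q: float = 0.05) -> pd.DataFrame:
    """Treatment-vs-sham paired statistics per (treatment, channel,
    component), FDR-corrected within the 9-channel family of each
    (treatment, component).

    ``measures`` is tidy: columns animal, treatment, channel, component,
    amplitude_uV, peak_latency_ms.
    """
    rows = []
    sham = measures[measures.treatment == sham_label]
    for treatment, tgrp in measures.groupby("treatment"):
        if treatment == sham_label:
            continue
        for component, cgrp in tgrp.groupby("component"):
            block = []
            for channel, grp in cgrp.groupby("channel"):
                ref = sham[(sham.channel == channel)
                           & (sham.component == component)]
                merged = grp.merge(ref, on="animal",
                                   suffixes=("_t", "_s"))
                if len(merged) < 2:
                    continue
                res = paired_t(merged.amplitude_uV_t, merged.amplitude_uV_s,
                               label=f"{treatment}:{channel}:{component}")
                block.append({
                    "treatment": treatment, "channel": channel,
                    "component": component, "n": len(merged),
                    "mean_amplitude_uV": merged.amplitude_uV_t.mean(),
                    "sham_amplitude_uV": merged.amplitude_uV_s.mean(),
                    "t": res.t, "df": res.df, "p": res.p_uncorrected,
                    "cohens_d": res.cohens_d,
                })
            if block:
                p_adj, rej = bh_fdr([r["p"] for r in block], q=q)
                for r, pa, rj in zip(block, p_adj, rej):
                    r["p_fdr"] = pa
                    r["significant_fdr"] = bool(rj)
                rows.extend(block)
    return pd.DataFrame(rows)
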