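"""Grand-average ERP comparison across cohorts.

Per-cohort grand averages are computed subject-then-cohort (each subject's
trial average enters the cohort mean with equal weight), electrodes are
ranked by the smallest zero-lag Pearson correlation among the three cohort
pairs, and signed peak amplitudes are read out in component windows.  The
correlation statistic is computed on *unsmoothed* grand averages; the local
polynomial (Savitzky–Golay) smoother is available for reporting and plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .containers import Epochs, Erp

__all__ = [
    "COGNITIVE_ELECTRODES",
    "ElectrodeComparison",
    "grand_average",
    "smooth_waveform",
    "cross_correlation",
    "rank_electrodes",
    "peak_amplitude",
    "comparison_table",
]

#: The 26 posterior channels of the 256-channel geodesic net designated for
#: cognitive ERP observation.
COGNITIVE_ELECTRODES = (
    "E98", "E99", "E100", "E101", "E108", "E109", "E110", "E116", "E117",
    "E118", "E119", "E124", "E125", "E126", "E127", "E128", "E129", "E137",
    "E138", "E139", "E140", "E141", "E149", "E150", "E151", "E152",
)


@dataclass(frozen=True)
class ElectrodeComparison:
    """Pairwise cohort correlations at one electrode."""

    electrode_name: str
    r_AB: float
    r_AC: float
    r_BC: float
    peak_amplitude: dict

    def __post_init__(self) -> None:
        for r in (self.r_AB, self.r_AC, self.r_BC):
            if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
                raise ValueError(f"correlation {r} outside [-1, 1]")

    @property
    def min_r(self) -> float:
        return min(self.r_AB, self.r_AC, self.r_BC)


def grand_average(
    epochs_by_subject: dict[str, Epochs] | list[Epochs],
    cohort: str,
    condition: str | None = None,
    trial_weighted: bool = False,
) -> Erp:
    """Average subject trial-averages for one cohort (and condition).

    Unweighted by default so subjects with more surviving trials do not
    dominate; ``trial_weighted=True`` pools all trials instead.
    """
    if isinstance(epochs_by_subject, dict):
        all_epochs = list(epochs_by_subject.values())
    else:
        all_epochs = list(epochs_by_subject)
    selected = []
    for ep in all_epochs:
        if ep.cohort_label != cohort:
            continue
        if condition is not None:
            try:
                ep = ep.select_conditions({condition})
            except ValueError:
                continue
        selected.append(ep)
    if not selected:
        raise ValueError(f"no subjects for cohort {cohort!r}"
                         + (f", condition {condition!r}" if condition else ""))
    first = selected[0]
    for ep in selected[1:]:
        if ep.channel_names != first.channel_names or ep.n_times != first.n_times:
            raise ValueError("subjects have mismatching epoch grids")
    if trial_weighted:
        stacked = np.concatenate([ep.data for ep in selected], axis=0)
        wave = stacked.mean(axis=0)
    else:
        wave = np.mean([ep.average() for ep in selected], axis=0)
    return Erp(
        waveform=wave, fs=first.fs, tmin_ms=first.tmin_ms,
        channel_names=list(first.channel_names), cohort_label=cohort,
        condition=condition or "all", n_subjects=len(selected),
        n_trials_total=int(sum(ep.n_trials for ep in selected)),
    )


def smooth_waveform(waveform: np.ndarray, window_samples: int = 11,
                    poly_order: int = 2) -> np.ndarray:
    """Local least-squares polynomial (Savitzky–Golay) smoothing.

    Reproduces polynomial inputs of degree ≤ ``poly_order`` exactly;
    ``window_samples = 1`` is the identity.
    """
    waveform = np.asarray(waveform, dtype=float)
    if window_samples == 1:
        return waveform.copy()
    if window_samples % 2 == 0:
        raise ValueError("window_samples must be odd")
    if window_samples < poly_order + 2:
        raise ValueError("window must be >= poly_order + 2")
    if window_samples > waveform.shape[-1]:
        raise ValueError("window longer than the waveform")
    return savgol_filter(waveform, window_samples, poly_order, axis=-1)


def cross_correlation(erp_x: Erp, erp_y: Erp, electrode: str,
                      max_lag_samples: int = 0) -> float:
    """Zero-lag Pearson correlation of two grand averages at one electrode.

    With ``max_lag_samples > 0`` the maximum-|r| over the lag range is
    returned instead (secondary statistic).  Constant waveforms raise: their
    correlation is undefined.
    """
    x = erp_x.channel(electrode)
    y = erp_y.channel(electrode)
    if x.shape != y.shape:
        raise ValueError("ERPs are on different time grids")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            f"constant waveform at {electrode}: correlation undefined"
        )
    if max_lag_samples == 0:
        return float(np.corrcoef(x, y)[0, 1])
    best = -np.inf
    best_r = 0.0
    for lag in range(-max_lag_samples, max_lag_samples + 1):
        if lag >= 0:
            xs, ys = x[lag:], y[: len(y) - lag]
        else:
            xs, ys = x[:lag], y[-lag:]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            continue
        r = float(np.corrcoef(xs, ys)[0, 1])
        if abs(r) > best:
            best, best_r = abs(r), r
    return best_r


def peak_amplitude(erp: Erp, electrode: str,
                   window_ms: tuple[float, float]) -> tuple[float, float]:
    """Signed extremum (max |value|) and its latency within a window.

    Ties on |value| resolve to the earlier latency.
    """
    lo, hi = window_ms
    t = erp.times_ms
    sel = (t >= lo) & (t <= hi)
    if not sel.any():
        raise ValueError(f"window {window_ms} ms contains no samples")
    wave = erp.channel(electrode)[sel]
    times = t[sel]
    i = int(np.argmax(np.abs(wave)))  # argmax returns the first maximum
    return float(wave[i]), float(times[i])


def rank_electrodes(
    erp_a: Erp, erp_b: Erp, erp_c: Erp,
    electrode_set=COGNITIVE_ELECTRODES,
    peak_window_ms: tuple[float, float] | None = None,
) -> list[ElectrodeComparison]:
    """Rank electrodes ascending by the smallest cross-cohort correlation.

    Ties break by electrode name, so the ranking is a stable permutation of
    the input set.  The leading entries are the electrodes where the three
    cohorts' grand averages diverge most.
    """
    comparisons = []
    for name in electrode_set:
        try:
            r_ab = cross_correlation(erp_a, erp_b, name)
            r_ac = cross_correlation(erp_a, erp_c, name)
            r_bc = cross_correlation(erp_b, erp_c, name)
        except KeyError:
            raise ValueError(f"electrode {name!r} absent from the ERPs")
        peaks = {}
        if peak_window_ms is not None:
            for label, erp in (("A", erp_a), ("B", erp_b), ("C", erp_c)):
                peaks[label] = peak_amplitude(erp, name, peak_window_ms)
        comparisons.append(
            ElectrodeComparison(name, r_ab, r_ac, r_bc, peaks)
        )
    return sorted(comparisons, key=lambda c: (c.min_r, c.electrode_name))


def comparison_table(comparisons: list[ElectrodeComparison]) -> pd.DataFrame:
    """One CSV-ready row per electrode comparison, in rank order."""
    return pd.DataFrame([
        {
            "electrode": c.electrode_name,
            "r_AB": c.r_AB, "r_AC": c.r_AC, "r_BC": c.r_BC,
            "min_r": c.min_r,
        }
        for c in comparisons
    ])


def waveform_table(erp_a: Erp, erp_b: Erp, erp_c: Erp,
                   electrode: str) -> pd.DataFrame:
    """Per-electrode waveform export (time_ms, mean_A, mean_B, mean_C)."""
    return pd.DataFrame({
        "time_ms": erp_a.times_ms,
        "mean_A": erp_a.channel(electrode),
        "mean_B": erp_b.channel(electrode),
        "mean_C": erp_c.channel(electrode),
    })


def plot_comparison(erp_a: Erp, erp_b: Erp, erp_c: Erp, electrode: str,
                    smooth_window: int = 11, ax=None):
    """Overlay the three cohort grand averages at one electrode."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    for erp, color, label in [
        (erp_a, "tab:red", "A (COVID, brain fog)"),
        (erp_b, "tab:blue", "B (COVID, no fog)"),
        (erp_c, "tab:green", "C (control)"),
    ]:
        wave = smooth_waveform(erp.channel(electrode), smooth_window)
        ax.plot(erp.times_ms, wave, color=color, label=label)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (µV)")
    ax.set_title(electrode)
    ax.legend(fontsize=8)
    return ax
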