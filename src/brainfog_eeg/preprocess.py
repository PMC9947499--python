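"""Signal preprocessing.

Two fixed pipelines operate on continuous recordings:

* ERP pipeline — 0.1–30 Hz zero-phase band-pass, artifact masking,
  stimulus-locked segmentation (−200..+1000 ms) and pre-stimulus baseline
  correction.
* Classification pipeline — 1 Hz high-pass, scalp-channel selection
  (projected radius ≤ 0.5, 137 of 256 geodesic-net channels), 45–55 Hz
  line-noise band-stop, optional cleaning hook, downsampling to 125 Hz,
  common-average re-reference, 40 Hz low-pass.

All filters are zero-phase Butterworth (4th order by default) applied
forward–backward, so component latencies are not shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import signal as sps

from .containers import Epochs, Recording
from .synth import TrialSchedule

__all__ = [
    "PipelineConfig",
    "bandpass_filter",
    "highpass_filter",
    "lowpass_filter",
    "remove_line_noise",
    "select_scalp_channels",
    "resample",
    "rereference_to_mean",
    "reject_artifact_segments",
    "epoch",
    "baseline_correct",
    "run_erp_pipeline",
    "run_classification_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Cutoffs and thresholds for both preprocessing chains (Hz, µV, ms)."""

    erp_highpass_hz: float = 0.1
    erp_lowpass_hz: float = 30.0
    cls_highpass_hz: float = 1.0
    cls_lowpass_hz: float = 40.0
    line_band_hz: tuple[float, float] = (45.0, 55.0)
    target_fs_hz: float = 125.0
    scalp_radius_max: float = 0.5
    artifact_amplitude_uv: float | None = None
    artifact_window_ms: float = 200.0
    filter_order: int = 4
    epoch_tmin_ms: float = -200.0
    epoch_tmax_ms: float = 1000.0
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)

    def __post_init__(self) -> None:
        for lo, hi in [(self.erp_highpass_hz, self.erp_lowpass_hz),
                       (self.cls_highpass_hz, self.cls_lowpass_hz)]:
            if not (0 < lo < hi):
                raise ValueError(f"need 0 < highpass < lowpass, got ({lo}, {hi})")


def _check_cutoff(hz: float, fs: float) -> None:
    if hz >= fs / 2:
        raise ValueError(f"cutoff {hz} Hz is at or above Nyquist ({fs / 2} Hz)")
    if hz <= 0:
        raise ValueError(f"cutoff must be positive, got {hz}")


def _apply_sos(rec: Recording, sos: np.ndarray, stage: str) -> Recording:
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    meta = dict(rec.meta)
    meta.setdefault("pipeline", []).copy()
    meta["pipeline"] = list(meta.get("pipeline", [])) + [stage]
    return rec.copy_with(data=out, meta=meta)


def bandpass_filter(rec: Recording, low_hz: float, high_hz: float,
                    order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass applied forward–backward."""
    _check_cutoff(low_hz, rec.fs)
    _check_cutoff(high_hz, rec.fs)
    if low_hz >= high_hz:
        raise ValueError("band-pass requires low < high cutoff")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=rec.fs, output="sos")
    return _apply_sos(rec, sos, f"bandpass({low_hz},{high_hz})")


def highpass_filter(rec: Recording, cutoff_hz: float, order: int = 4) -> Recording:
    _check_cutoff(cutoff_hz, rec.fs)
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=rec.fs, output="sos")
    return _apply_sos(rec, sos, f"highpass({cutoff_hz})")


def lowpass_filter(rec: Recording, cutoff_hz: float, order: int = 4) -> Recording:
    _check_cutoff(cutoff_hz, rec.fs)
    sos = sps.butter(order, cutoff_hz, btype="lowpass", fs=rec.fs, output="sos")
    return _apply_sos(rec, sos, f"lowpass({cutoff_hz})")


def remove_line_noise(rec: Recording, band_hz: tuple[float, float] = (45.0, 55.0),
                      order: int = 4) -> Recording:
    """Zero-phase band-stop over the line band (default 45–55 Hz)."""
    lo, hi = band_hz
    if lo >= hi:
        raise ValueError(f"line band is inverted: {band_hz}")
    _check_cutoff(lo, rec.fs)
    _check_cutoff(hi, rec.fs)
    sos = sps.butter(order, [lo, hi], btype="bandstop", fs=rec.fs, output="sos")
    return _apply_sos(rec, sos, f"bandstop({lo},{hi})")


def select_scalp_channels(rec: Recording, radius_max: float = 0.5) -> Recording:
    """Retain channels whose montage projected radius is ≤ ``radius_max``."""
    if rec.montage is None:
        raise ValueError("recording has no montage; cannot select by radius")
    radii = {}
    for name in rec.channel_names:
        radii[name] = rec.montage.radius_of(name)
    keep = [i for i, name in enumerate(rec.channel_names)
            if radii[name] <= radius_max]
    if not keep:
        raise ValueError(f"no channels with radius <= {radius_max}")
    names = [rec.channel_names[i] for i in keep]
    return rec.copy_with(
        data=rec.data[keep],
        channel_names=names,
        montage=rec.montage.subset(names),
    )


def resample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase anti-aliased downsampling to ``target_fs``."""
    if target_fs > rec.fs:
        raise ValueError("upsampling is out of scope (target_fs > fs)")
    if target_fs == rec.fs:
        return rec
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(data=out, fs=target_fs)


def rereference_to_mean(rec: Recording) -> Recording:
    """Common-average reference: subtract the across-channel mean per sample."""
    if rec.n_channels < 2:
        raise ValueError("mean re-reference requires at least 2 channels")
    return rec.copy_with(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def reject_artifact_segments(
    rec: Recording, amplitude_threshold_uv: float, window_ms: float = 200.0
) -> tuple[Recording, np.ndarray]:
    """Sliding-window peak-to-peak artifact test.

    Returns the recording unchanged together with a boolean ``(n_channels,
    n_samples)`` mask marking samples inside any window whose peak-to-peak
    amplitude exceeds the threshold.  A fully masked recording raises.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    w = max(1, int(round(window_ms * rec.fs / 1000.0)))
    ptp = (maximum_filter1d(rec.data, size=w, axis=1, mode="nearest")
           - minimum_filter1d(rec.data, size=w, axis=1, mode="nearest"))
    exceed = ptp > amplitude_threshold_uv
    # mask every sample whose window neighborhood contains an exceedance
    mask = maximum_filter1d(exceed.astype(np.uint8), size=w, axis=1,
                            mode="constant") > 0
    if mask.all():
        raise ValueError("artifact threshold masks the entire recording")
    return rec, mask


def epoch(rec: Recording, schedule: TrialSchedule,
          tmin_ms: float = -200.0, tmax_ms: float = 1000.0,
          reject_mask: np.ndarray | None = None) -> Epochs:
    """Cut stimulus-locked segments around every schedule onset.

    Onsets whose window would extend past either end of the recording are
    dropped, as are (optionally) epochs overlapping an artifact mask.
    """
    if schedule.n_trials == 0:
        raise ValueError("schedule is empty")
    n_pre = int(round(-tmin_ms * rec.fs / 1000.0))
    n_len = int(round((tmax_ms - tmin_ms) * rec.fs / 1000.0))
    onsets = schedule.trials["onset_ms"].to_numpy(dtype=float)
    codes = schedule.condition_codes
    segments, kept_codes = [], []
    for onset, code in zip(onsets, codes):
        s0 = int(round(onset * rec.fs / 1000.0)) - n_pre
        s1 = s0 + n_len
        if s0 < 0 or s1 > rec.n_samples:
            continue
        if reject_mask is not None and reject_mask[:, s0:s1].any():
            continue
        segments.append(rec.data[:, s0:s1])
        kept_codes.append(code)
    if not segments:
        raise ValueError("no onset has a complete artifact-free window")
    return Epochs(
        data=np.stack(segments), fs=rec.fs, tmin_ms=tmin_ms, tmax_ms=tmax_ms,
        channel_names=list(rec.channel_names), condition_codes=kept_codes,
        subject_id=rec.subject_id, cohort_label=rec.cohort_label,
    )


def baseline_correct(epochs: Epochs,
                     window_ms: tuple[float, float] = (-200.0, 0.0)) -> Epochs:
    """Subtract each trial/channel's mean over the pre-stimulus window."""
    lo, hi = window_ms
    if lo >= hi:
        raise ValueError(f"empty baseline window {window_ms}")
    if lo < epochs.tmin_ms - 1e-9 or hi > epochs.tmax_ms + 1e-9:
        raise ValueError("baseline window outside the epoch span")
    t = epochs.times_ms
    sel = (t >= lo) & (t < hi)
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return replace(
        epochs, data=epochs.data - base, baseline_window_ms=(lo, hi)
    )


# ---------------------------------------------------------------------------
# fixed pipelines
# ---------------------------------------------------------------------------

def run_erp_pipeline(rec: Recording, schedule: TrialSchedule,
                     config: PipelineConfig | None = None) -> Epochs:
    """Band-pass → artifact mask → epoch → baseline-correct."""
    config = config or PipelineConfig()
    rec = bandpass_filter(rec, config.erp_highpass_hz, config.erp_lowpass_hz,
                          config.filter_order)
    mask = None
    if config.artifact_amplitude_uv is not None:
        rec, mask = reject_artifact_segments(
            rec, config.artifact_amplitude_uv, config.artifact_window_ms
        )
    ep = epoch(rec, schedule, config.epoch_tmin_ms, config.epoch_tmax_ms,
               reject_mask=mask)
    return baseline_correct(ep, config.baseline_window_ms)


def run_classification_pipeline(
    rec: Recording,
    config: PipelineConfig | None = None,
    cleaning_hook: Callable[[Recording], Recording] | None = None,
    select_channels: bool | None = None,
) -> Recording:
    """High-pass → scalp selection → line removal → cleaning hook →
    downsample → mean re-reference → low-pass.

    ``cleaning_hook`` is the pluggable stand-in for artifact-subspace and
    component-based cleaning stages; it receives and returns a Recording.
    ``select_channels`` defaults to "only when a montage is attached".
    """
    config = config or PipelineConfig()
    rec = highpass_filter(rec, config.cls_highpass_hz, config.filter_order)
    if select_channels is None:
        select_channels = rec.montage is not None
    if select_channels:
        rec = select_scalp_channels(rec, config.scalp_radius_max)
    rec = remove_line_noise(rec, config.line_band_hz, config.filter_order)
    if cleaning_hook is not None:
        rec = cleaning_hook(rec)
    rec = resample(rec, config.target_fs_hz)
    rec = rereference_to_mean(rec)
    rec = lowpass_filter(rec, config.cls_lowpass_hz, config.filter_order)
    if not np.isfinite(rec.data).all():
        raise ValueError("non-finite samples after preprocessing")
    return rec
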