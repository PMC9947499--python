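"""Synthetic study generator.

Emulates the three-cohort study design: per-subject resting-state EEG whose
suprathreshold events form branching-process cascades, plus event-related
trials for the three cognitive paradigms (face recognition, digit span, task
switching).  Every generator is a pure function of its configuration and an
integer seed, so the full downstream pipeline is testable without any
recorded data.

Cohorts
-------
A — post-COVID with brain-fog symptoms, B — post-COVID without symptoms,
C — never-COVID controls (40 subjects each in the emulated design).  Cohort
effects are parameterized as ERP amplitude scaling / latency shifts and a
shift of the resting-state branching parameter; defaults place the healthy
controls near the supercritical value measured for that group
(sigma = 1.1023) and give the COVID cohorts a lower branching parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Epochs, Montage, Recording
from .io import load_bundled_montage

__all__ = [
    "CohortSpec",
    "TrialSchedule",
    "CascadeSet",
    "DigitSpanConfig",
    "TaskSwitchingConfig",
    "FaceRecognitionConfig",
    "NoiseModel",
    "make_digit_span_schedule",
    "make_task_switching_schedule",
    "make_face_recognition_schedule",
    "simulate_branching_cascades",
    "sample_power_law_sizes",
    "render_resting_recording",
    "erp_template",
    "synthesize_erp_trials",
    "build_cohort_dataset",
    "default_cohort_specs",
    "subject_rng",
]

PARADIGMS = ("face_recognition", "digit_span", "task_switching")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one sub-cohort.

    ``erp_amplitude_scale`` / ``erp_latency_shift_ms`` act on the paradigm
    waveform templates; ``branching_parameter`` is the offspring mean of the
    resting-state cascade generator; ``size_exponent`` (negative) is used
    when avalanche sizes are drawn directly from a power law instead of the
    branching process; ``noise_sd_uv`` scales all backgrounds to microvolts.
    """

    label: str
    n_subjects: int = 40
    erp_amplitude_scale: float = 1.0
    erp_latency_shift_ms: float = 0.0
    branching_parameter: float = 1.0
    size_exponent: float = -1.5
    noise_sd_uv: float = 10.0

    def __post_init__(self) -> None:
        if self.label not in {"A", "B", "C"}:
            raise ValueError(f"cohort label must be A, B or C, got {self.label!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be >= 0")
        if self.branching_parameter < 0:
            raise ValueError("branching_parameter must be >= 0")
        if self.size_exponent >= 0:
            raise ValueError("size_exponent uses the negative sign convention")


def default_cohort_specs(
    delta_sigma: float = 0.15,
    n_subjects: int = 40,
    noise_sd_uv: float = 10.0,
) -> list[CohortSpec]:
    """The emulated study conditions.

    Controls (C) sit at the branching parameter measured for the healthy
    group (1.1023); both COVID cohorts (A, B) are shifted down by
    ``delta_sigma``.  ERP amplitudes are ordered B > A > C, matching the
    qualitative amplitude ordering reported for the cognitive electrodes.
    """
    sigma_c = 1.1023
    return [
        CohortSpec("A", n_subjects, erp_amplitude_scale=1.0,
                   erp_latency_shift_ms=8.0,
                   branching_parameter=sigma_c - delta_sigma,
                   noise_sd_uv=noise_sd_uv),
        CohortSpec("B", n_subjects, erp_amplitude_scale=1.2,
                   erp_latency_shift_ms=0.0,
                   branching_parameter=sigma_c - delta_sigma,
                   noise_sd_uv=noise_sd_uv),
        CohortSpec("C", n_subjects, erp_amplitude_scale=0.8,
                   erp_latency_shift_ms=0.0,
                   branching_parameter=sigma_c,
                   noise_sd_uv=noise_sd_uv),
    ]


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trials of one paradigm.

    ``trials`` columns: trial_index, condition_code, stimulus_payload,
    onset_ms (strictly increasing).
    """

    paradigm: str
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        required = {"trial_index", "condition_code", "stimulus_payload", "onset_ms"}
        if not required <= set(self.trials.columns):
            raise ValueError(f"schedule table needs columns {sorted(required)}")
        onsets = self.trials["onset_ms"].to_numpy(dtype=float)
        if len(onsets) == 0:
            raise ValueError("schedule has no trials")
        if not np.all(np.diff(onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def condition_codes(self) -> list[str]:
        return self.trials["condition_code"].tolist()

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# paradigm schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DigitSpanConfig:
    """Auditory digit span: blocks of increasing sequence length.

    The default per-length counts follow the study schedule — 10 three-digit
    and 10 four-digit sequences, 5 each of lengths 5–8, 9 nine-digit and 15
    ten-digit sequences (64 trials in total).
    """

    counts_per_length: dict[int, int] = field(default_factory=lambda: {
        3: 10, 4: 10, 5: 5, 6: 5, 7: 5, 8: 5, 9: 9, 10: 15,
    })
    alphabet: tuple[int, ...] = tuple(range(1, 11))
    listen_ms_per_digit: float = 800.0
    recall_gap_ms: float = 2500.0


def make_digit_span_schedule(
    config: DigitSpanConfig | None = None, seed: int = 0
) -> TrialSchedule:
    """One trial per digit sequence, ordered by increasing length.

    Within each length block every sequence is distinct.  Raises if a block
    requests more distinct sequences than the alphabet allows.
    """
    config = config or DigitSpanConfig()
    rng = np.random.default_rng(seed)
    n_digits = len(config.alphabet)
    rows = []
    onset = 0.0
    idx = 0
    for length in sorted(config.counts_per_length):
        count = config.counts_per_length[length]
        if count <= 0:
            continue
        n_possible = n_digits ** length
        if count > n_possible:
            raise ValueError(
                f"{count} distinct length-{length} sequences requested but only "
                f"{n_possible} exist over a {n_digits}-digit alphabet"
            )
        seen: set[tuple[int, ...]] = set()
        while len(seen) < count:
            seq = tuple(rng.choice(config.alphabet, size=length))
            seen.add(seq)
        for seq in sorted(seen):
            onset += config.recall_gap_ms + config.listen_ms_per_digit * length
            rows.append({
                "trial_index": idx,
                "condition_code": f"len{length}",
                "stimulus_payload": "-".join(map(str, seq)),
                "onset_ms": onset,
            })
            idx += 1
    if not rows:
        raise ValueError("digit-span schedule is empty")
    return TrialSchedule("digit_span", pd.DataFrame(rows))


@dataclass(frozen=True)
class TaskSwitchingConfig:
    """Letter/number pairs in the top or bottom screen section.

    A trial is a *letter* trial when the pair sits in the top section (the
    letter is task-relevant: respond if it is a vowel) and a *digit* trial
    when it sits in the bottom (respond if the number is even).  Defaults run
    until 75 letter and 75 digit targets have been shown (150 trials).
    """

    n_letter_trials: int = 75
    n_digit_trials: int = 75
    iti_ms: float = 2000.0
    letters: str = "AEIOUBCDFG"
    vowels: str = "AEIOU"


def make_task_switching_schedule(
    config: TaskSwitchingConfig | None = None, seed: int = 0
) -> TrialSchedule:
    config = config or TaskSwitchingConfig()
    if config.n_letter_trials <= 0 and config.n_digit_trials <= 0:
        raise ValueError("at least one target category must have trials")
    rng = np.random.default_rng(seed)
    kinds = ["letter"] * config.n_letter_trials + ["digit"] * config.n_digit_trials
    order = rng.permutation(len(kinds))
    rows = []
    for idx, k in enumerate(order):
        kind = kinds[k]
        letter = str(rng.choice(list(config.letters)))
        number = int(rng.integers(1, 10))
        position = "top" if kind == "letter" else "bottom"
        if kind == "letter":
            respond = letter in config.vowels
        else:
            respond = number % 2 == 0
        rows.append({
            "trial_index": idx,
            "condition_code": kind,
            "stimulus_payload": f"{letter}{number}@{position}",
            "onset_ms": (idx + 1) * config.iti_ms,
            "position": position,
            "correct_response": bool(respond),
        })
    return TrialSchedule("task_switching", pd.DataFrame(rows))


@dataclass(frozen=True)
class FaceRecognitionConfig:
    """Repeated 12-face sequences containing the studied faces.

    270 trials is not a whole number of 12-face blocks; the final block is
    truncated (configurable via ``truncate_last_block``).
    """

    study_set_size: int = 3
    sequence_length: int = 12
    n_trials: int = 270
    iti_ms: float = 1500.0
    truncate_last_block: bool = True


def make_face_recognition_schedule(
    config: FaceRecognitionConfig | None = None, seed: int = 0
) -> TrialSchedule:
    config = config or FaceRecognitionConfig()
    if config.study_set_size > config.sequence_length:
        raise ValueError("study set cannot exceed the face-sequence length")
    rng = np.random.default_rng(seed)
    faces = [f"face{j:02d}" for j in range(config.sequence_length)]
    known = set(faces[: config.study_set_size])
    rows = []
    idx = 0
    while idx < config.n_trials:
        block = rng.permutation(faces)
        for face in block:
            if idx >= config.n_trials:
                if not config.truncate_last_block:
                    pass  # finish the block anyway
                else:
                    break
            rows.append({
                "trial_index": idx,
                "condition_code": "known" if face in known else "unknown",
                "stimulus_payload": str(face),
                "onset_ms": (idx + 1) * config.iti_ms,
            })
            idx += 1
    return TrialSchedule("face_recognition", pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# branching-process cascades
# ---------------------------------------------------------------------------

class CascadeSet:
    """A batch of simulated avalanches from the Poisson branching process.

    Each cascade starts with one seed event on a uniformly random channel;
    every event in bin *t* spawns Poisson(sigma) offspring events in bin
    *t + 1*, each placed on a uniformly random channel.  A cascade ends when
    a bin is empty or the duration cap is reached (capped cascades are
    flagged — their size is censored).
    """

    def __init__(
        self,
        per_bin_counts: list[np.ndarray],
        channels: list[np.ndarray],
        n_channels: int,
        sigma_true: float,
        seed: int,
        capped: np.ndarray,
    ) -> None:
        self.per_bin_counts = per_bin_counts
        self.channels = channels
        self.n_channels = int(n_channels)
        self.sigma_true = float(sigma_true)
        self.seed = int(seed)
        self.capped = np.asarray(capped, dtype=bool)
        self.sizes = np.array([int(c.sum()) for c in per_bin_counts])
        self.durations = np.array([len(c) for c in per_bin_counts])

    def __len__(self) -> int:
        return len(self.per_bin_counts)

    def raster(self, i: int) -> np.ndarray:
        """Dense ``(n_channels, duration_bins)`` event-count grid of cascade i."""
        counts = self.per_bin_counts[i]
        grid = np.zeros((self.n_channels, len(counts)), dtype=int)
        offset = 0
        for b, c in enumerate(counts):
            ch = self.channels[i][offset:offset + c]
            np.add.at(grid[:, b], ch, 1)
            offset += c
        return grid


def simulate_branching_cascades(
    n_channels: int,
    sigma: float,
    n_avalanches: int,
    seed: int,
    max_duration: int = 100,
) -> CascadeSet:
    """Simulate ``n_avalanches`` independent branching-process cascades.

    Subcritical cascades (sigma < 1) have analytic mean size 1/(1 - sigma);
    at sigma = 1 the size distribution follows the critical -3/2 power law.
    For supercritical sigma choose ``max_duration`` with care: the expected
    event count grows like sigma**max_duration.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_avalanches < 1:
        raise ValueError("n_avalanches must be >= 1")
    if max_duration < 1:
        raise ValueError("max_duration must be >= 1")
    rng = np.random.default_rng(seed)

    # Vectorized over cascades: Poisson(sigma * counts) gives the next-bin
    # totals because a sum of independent Poisson(sigma) draws is Poisson.
    counts = np.ones(n_avalanches, dtype=np.int64)
    totals = [counts.copy()]
    for _ in range(1, max_duration):
        if not counts.any():
            break
        counts = rng.poisson(sigma * counts)
        if not counts.any():
            break
        totals.append(counts.copy())
    grid = np.stack(totals, axis=1)  # (n_avalanches, n_bins_max)
    # duration = bins up to (exclusive) the first empty bin
    alive = grid > 0
    durations = alive.argmin(axis=1)
    durations[alive.all(axis=1)] = grid.shape[1]
    capped_flags = (durations == max_duration) & (grid[:, -1] > 0) \
        if grid.shape[1] == max_duration else np.zeros(n_avalanches, bool)

    per_bin = [grid[i, : durations[i]].copy() for i in range(n_avalanches)]
    sizes = np.array([c.sum() for c in per_bin])
    all_channels = rng.integers(0, n_channels, size=int(sizes.sum()))
    splits = np.cumsum(sizes)[:-1]
    channels = [c.copy() for c in np.split(all_channels, splits)]
    return CascadeSet(per_bin, channels, n_channels, sigma, seed, capped_flags)


def sample_power_law_sizes(
    alpha: float, n: int, seed: int, x_min: int = 1
) -> np.ndarray:
    """Draw ``n`` sizes from the discrete power law P(s) ∝ s**alpha, s >= x_min.

    ``alpha`` is negative by convention (e.g. -1.5336).  For x_min = 1 this
    is the zeta (Zipf) distribution; larger x_min shifts a Zipf draw.
    """
    if alpha >= -1:
        raise ValueError("alpha must be < -1 for a normalizable distribution")
    if x_min < 1:
        raise ValueError("x_min must be >= 1")
    rng = np.random.default_rng(seed)
    if x_min == 1:
        return stats.zipf.rvs(-alpha, size=n, random_state=rng)
    # inverse-CDF on the Hurwitz-zeta tail for shifted support
    from scipy.special import zeta as hzeta

    a = -alpha
    norm = hzeta(a, x_min)
    u = rng.random(n)
    out = np.empty(n, dtype=np.int64)
    for i, ui in enumerate(u):
        lo, hi = x_min, x_min
        while 1.0 - hzeta(a, hi + 1) / norm < ui:
            hi = max(hi * 2, hi + 1)
        while lo < hi:
            mid = (lo + hi) // 2
            if 1.0 - hzeta(a, mid + 1) / norm >= ui:
                hi = mid
            else:
                lo = mid + 1
        out[i] = lo
    return out


# ---------------------------------------------------------------------------
# resting-state rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Background model: 1/f^exponent Gaussian noise plus optional line tone.

    The shaped background is z-scored per channel to unit SD before the line
    tone (peak amplitude in background-SD units) is added, so the
    suprathreshold statistics of the pure background are those of a unit
    Gaussian.
    """

    one_over_f_exponent: float = 1.0
    line_freq_hz: float = 50.0
    line_amplitude_sd: float = 0.0


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int,
    fs: float, exponent: float,
) -> np.ndarray:
    white = rng.standard_normal((n_channels, n_samples))
    if exponent == 0:
        shaped = white
    else:
        spec = np.fft.rfft(white, axis=1)
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        gain = np.zeros_like(freqs)
        gain[1:] = freqs[1:] ** (-exponent / 2.0)
        spec *= gain
        shaped = np.fft.irfft(spec, n=n_samples, axis=1)
    shaped -= shaped.mean(axis=1, keepdims=True)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def render_resting_recording(
    cascades: CascadeSet,
    fs: float = 250.0,
    duration_s: float = 300.0,
    noise_model: NoiseModel | None = None,
    event_amplitude_sd: float = 20.0,
    seed: int = 0,
    bin_ms: float = 24.0,
    guard_bins: int = 2,
    scale_uv: float = 10.0,
    channel_names: Sequence[str] | None = None,
    montage: Montage | None = None,
    subject_id: str = "",
    cohort_label: str = "",
) -> tuple[Recording, pd.DataFrame]:
    """Render cascades into a continuous noisy recording.

    Events are injected as deflections of ``event_amplitude_sd`` background
    SDs with random sign, aligned to the ``bin_ms`` bin grid; each event
    occupies one 8-ms base bin (one sample at 125 Hz, two at 250 Hz) so the
    detector's one-extremum-per-excursion rule maps 1:1 to ground truth.
    Cascades are separated by at least ``guard_bins`` empty bins.

    Returns the recording (microvolts; ``scale_uv`` microvolts per
    background SD) and a ground-truth table with one row per injected event
    (columns: cascade, bin, channel, sample, sign).
    """
    noise_model = noise_model or NoiseModel()
    rng = np.random.default_rng(seed)
    n_samples = int(round(fs * duration_s))
    n_channels = cascades.n_channels

    spb = fs * bin_ms / 1000.0
    if abs(spb - round(spb)) > 1e-9 or round(spb) < 1:
        raise ValueError(f"bin width {bin_ms} ms is not an integer number of "
                         f"samples at {fs} Hz")
    spb = int(round(spb))
    base_samples = max(1, int(round(fs * 0.008)))  # 8 ms base bin
    n_bins = n_samples // spb

    durations = cascades.durations
    occupied = int(durations.sum()) + guard_bins * (len(cascades) + 1)
    if occupied > n_bins:
        raise ValueError(
            f"{len(cascades)} cascades need {occupied} bins but the recording "
            f"holds only {n_bins}; increase duration_s or reduce cascades"
        )

    # distribute the spare bins uniformly over the gaps between cascades
    spare = n_bins - occupied
    extra = rng.multinomial(spare, np.full(len(cascades) + 1, 1.0 / (len(cascades) + 1)))
    start_bins = np.empty(len(cascades), dtype=int)
    cursor = guard_bins + extra[0]
    for i in range(len(cascades)):
        start_bins[i] = cursor
        cursor += durations[i] + guard_bins + extra[i + 1]

    signal = _one_over_f_noise(rng, n_channels, n_samples, fs,
                               noise_model.one_over_f_exponent)
    if noise_model.line_amplitude_sd > 0:
        t = np.arange(n_samples) / fs
        phases = rng.uniform(0, 2 * np.pi, size=n_channels)
        signal += noise_model.line_amplitude_sd * np.sin(
            2 * np.pi * noise_model.line_freq_hz * t[None, :] + phases[:, None]
        )

    slots_per_bin = max(1, spb // base_samples)
    truth_rows = []
    for i in range(len(cascades)):
        counts = cascades.per_bin_counts[i]
        offset = 0
        for b, c in enumerate(counts):
            ch = cascades.channels[i][offset:offset + c]
            offset += c
            g_bin = start_bins[i] + b
            for channel in ch:
                slot = int(rng.integers(0, slots_per_bin))
                s0 = g_bin * spb + slot * base_samples
                sign = 1.0 if rng.random() < 0.5 else -1.0
                signal[channel, s0:s0 + base_samples] += sign * event_amplitude_sd
                truth_rows.append({
                    "cascade": i, "bin": int(g_bin), "channel": int(channel),
                    "sample": int(s0), "sign": sign,
                })

    if channel_names is None:
        if montage is None and n_channels == 137:
            montage = load_bundled_montage()
            channel_names = montage.scalp_names(0.5)
            montage = montage.subset(list(channel_names))
        elif montage is not None:
            channel_names = montage.names[:n_channels]
        else:
            channel_names = [f"CH{i + 1:03d}" for i in range(n_channels)]

    rec = Recording(
        data=signal * scale_uv,
        fs=fs,
        channel_names=list(channel_names),
        montage=montage,
        subject_id=subject_id,
        cohort_label=cohort_label,
        meta={
            "generator": "render_resting_recording",
            "sigma_true": cascades.sigma_true,
            "n_cascades": len(cascades),
            "event_amplitude_sd": event_amplitude_sd,
            "bin_ms": bin_ms,
            "seed": seed,
        },
    )
    truth = pd.DataFrame(
        truth_rows, columns=["cascade", "bin", "channel", "sample", "sign"]
    )
    return rec, truth


# ---------------------------------------------------------------------------
# ERP trials
# ---------------------------------------------------------------------------

_COMPONENTS = {
    # (latency_ms, width_ms, amplitude_uv) per paradigm
    "face_recognition": [(100, 25, 2.0), (170, 30, -4.0), (400, 60, -3.0)],
    "digit_span": [(200, 35, -3.0), (300, 50, 4.0)],
    "task_switching": [(200, 35, -2.0), (500, 70, 3.0)],
}


def erp_template(
    paradigm: str,
    channel_names: Sequence[str],
    fs: float = 250.0,
    tmin_ms: float = -200.0,
    tmax_ms: float = 1000.0,
    spatial_profile: np.ndarray | None = None,
) -> np.ndarray:
    """Canonical noiseless waveform template, ``(n_channels, n_times)`` µV.

    Built from Gaussian-windowed components with paradigm-typical latencies
    (e.g. the 170-ms face-sensitive negativity).  The pre-stimulus segment is
    identically zero, so baseline correction is a no-op on the template.
    ``spatial_profile`` scales the template per channel (default: smooth
    cosine taper across the channel list).
    """
    if paradigm not in _COMPONENTS:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    n_times = int(round((tmax_ms - tmin_ms) * fs / 1000.0))
    t = tmin_ms + 1000.0 * np.arange(n_times) / fs
    wave = np.zeros(n_times)
    for lat, width, amp in _COMPONENTS[paradigm]:
        wave += amp * np.exp(-0.5 * ((t - lat) / width) ** 2)
    wave[t < 0] = 0.0
    n_ch = len(channel_names)
    if spatial_profile is None:
        spatial_profile = 0.75 + 0.25 * np.cos(
            np.linspace(0, np.pi, n_ch)
        )
    spatial_profile = np.asarray(spatial_profile, dtype=float)
    if spatial_profile.shape != (n_ch,):
        raise ValueError("spatial_profile must have one gain per channel")
    return spatial_profile[:, None] * wave[None, :]


def _shift_waveform(wave: np.ndarray, shift_samples: int) -> np.ndarray:
    """Shift along time with edge replication (positive = later)."""
    if shift_samples == 0:
        return wave
    out = np.empty_like(wave)
    if shift_samples > 0:
        out[..., shift_samples:] = wave[..., :-shift_samples]
        out[..., :shift_samples] = wave[..., :1]
    else:
        out[..., :shift_samples] = wave[..., -shift_samples:]
        out[..., shift_samples:] = wave[..., -1:]
    return out


def synthesize_erp_trials(
    template_waveform: np.ndarray,
    cohort_spec: CohortSpec,
    n_trials: int,
    seed: int,
    fs: float = 250.0,
    tmin_ms: float = -200.0,
    tmax_ms: float = 1000.0,
    channel_names: Sequence[str] | None = None,
    condition_codes: Sequence[str] | None = None,
    paradigm: str = "",
    subject_id: str = "",
) -> Epochs:
    """Trials = amplitude_scale x template(t - latency_shift) + Gaussian noise."""
    template_waveform = np.asarray(template_waveform, dtype=float)
    n_times = int(round((tmax_ms - tmin_ms) * fs / 1000.0))
    if template_waveform.ndim != 2 or template_waveform.shape[1] != n_times:
        raise ValueError(
            f"template grid {template_waveform.shape} does not match the "
            f"epoch window ({n_times} samples)"
        )
    n_channels = template_waveform.shape[0]
    if channel_names is None:
        channel_names = [f"CH{i + 1:03d}" for i in range(n_channels)]
    if condition_codes is None:
        condition_codes = ["stim"] * n_trials
    if len(condition_codes) != n_trials:
        raise ValueError("need one condition code per trial")

    rng = np.random.default_rng(seed)
    shift = int(round(cohort_spec.erp_latency_shift_ms * fs / 1000.0))
    base = cohort_spec.erp_amplitude_scale * _shift_waveform(template_waveform, shift)
    noise = rng.standard_normal((n_trials, n_channels, n_times))
    data = base[None, :, :] + cohort_spec.noise_sd_uv * noise
    return Epochs(
        data=data, fs=fs, tmin_ms=tmin_ms, tmax_ms=tmax_ms,
        channel_names=list(channel_names),
        condition_codes=list(condition_codes),
        subject_id=subject_id, cohort_label=cohort_spec.label,
        paradigm=paradigm,
        meta={"template_seed": seed, "latency_shift_samples": shift},
    )


# ---------------------------------------------------------------------------
# whole-cohort dataset
# ---------------------------------------------------------------------------

def subject_rng(master_seed: int, cohort_label: str, subject_index: int,
                stream: str = "") -> np.random.Generator:
    """Deterministic per-subject random stream derived from the master seed."""
    key = (ord(cohort_label[0]), subject_index) + tuple(stream.encode())
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=key)
    )


def _subject_seed(master_seed: int, cohort_label: str, subject_index: int,
                  stream: str) -> int:
    key = (ord(cohort_label[0]), subject_index) + tuple(stream.encode())
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class SubjectData:
    subject_id: str
    cohort_label: str
    resting: Recording | None
    resting_truth: pd.DataFrame | None
    epochs: dict[str, Epochs]


def build_cohort_dataset(
    cohort_specs: Sequence[CohortSpec] | None = None,
    seed: int = 0,
    duration_s: float = 300.0,
    fs: float = 250.0,
    n_channels: int = 137,
    cascade_rate_hz: float = 3.0,
    cascade_max_duration: int = 25,
    event_amplitude_sd: float = 20.0,
    noise_model: NoiseModel | None = None,
    paradigms: Sequence[str] = PARADIGMS,
    n_trials_per_paradigm: int | None = 60,
    erp_channel_names: Sequence[str] | None = None,
    include_resting: bool = True,
) -> list[SubjectData]:
    """Generate the full labeled dataset: one resting recording plus one
    epoch set per paradigm for every subject of every cohort.

    Per-subject seeds are derived deterministically from the master seed, so
    distinct subjects get distinct, reproducible signals.  ``cascade_rate_hz``
    sets how many cascades are seeded per second of resting signal;
    ``n_trials_per_paradigm`` caps the synthesized trials per paradigm (None
    = the paradigm's full default schedule).
    """
    if cohort_specs is None:
        cohort_specs = default_cohort_specs()
    if len(cohort_specs) == 0:
        raise ValueError("cohort_specs is empty")

    from . import erp_compare  # noqa: F401  (cognitive electrode list lives there)
    if erp_channel_names is None:
        erp_channel_names = erp_compare.COGNITIVE_ELECTRODES

    subjects: list[SubjectData] = []
    n_cascades = max(1, int(round(cascade_rate_hz * duration_s)))
    for spec in cohort_specs:
        for j in range(spec.n_subjects):
            sid = f"{spec.label}{j + 1:03d}"
            resting = truth = None
            if include_resting:
                cas_seed = _subject_seed(seed, spec.label, j, "cascades")
                ren_seed = _subject_seed(seed, spec.label, j, "render")
                cascades = simulate_branching_cascades(
                    n_channels, spec.branching_parameter, n_cascades,
                    seed=cas_seed, max_duration=cascade_max_duration,
                )
                resting, truth = render_resting_recording(
                    cascades, fs=fs, duration_s=duration_s,
                    noise_model=noise_model,
                    event_amplitude_sd=event_amplitude_sd,
                    seed=ren_seed, scale_uv=spec.noise_sd_uv,
                    subject_id=sid, cohort_label=spec.label,
                )
            epochs: dict[str, Epochs] = {}
            for paradigm in paradigms:
                sched_seed = _subject_seed(seed, spec.label, j, f"sched:{paradigm}")
                if paradigm == "face_recognition":
                    sched = make_face_recognition_schedule(seed=sched_seed)
                elif paradigm == "digit_span":
                    sched = make_digit_span_schedule(seed=sched_seed)
                else:
                    sched = make_task_switching_schedule(seed=sched_seed)
                codes = sched.condition_codes
                if n_trials_per_paradigm is not None:
                    codes = codes[:n_trials_per_paradigm]
                template = erp_template(paradigm, erp_channel_names, fs=fs)
                trial_seed = _subject_seed(seed, spec.label, j, f"trials:{paradigm}")
                epochs[paradigm] = synthesize_erp_trials(
                    template, spec, n_trials=len(codes), seed=trial_seed,
                    fs=fs, channel_names=erp_channel_names,
                    condition_codes=codes, paradigm=paradigm, subject_id=sid,
                )
            subjects.append(SubjectData(sid, spec.label, resting, truth, epochs))
    return subjects
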