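"""Synthetic EEG, behavioral and group-sample generators with ground truth.

Every generator is deterministic given its ``seed``: the same parameters and
seed produce byte-identical arrays and tables. The EEG generator emits the
exact list of injected events (:class:`GroundTruth`) so detector sensitivity
and precision can be measured without any recorded animal data.

What is emulated
----------------
* Background EEG: white, AR(2) low-pass ("1/f-like", the default) or pink
  noise at a requested RMS amplitude in microvolts.
* Epileptiform spikes: sharp biphasic transients (difference of two Gaussian
  lobes, total width ~25 ms) whose peak deviation is a fixed multiple of the
  baseline RMS (default 6x, comfortably above a 4x detection criterion).
* Spike-and-wave discharges (SWDs): trains of spike + half-sine slow-wave
  cycles repeating at a set component frequency (default 12 Hz), 4 or more
  components per train.
* Movement artifacts: large slow irregular deflections, annotated so the
  analysis can exclude them the way hand-marked artifacts are excluded.

Event onsets follow a homogeneous Poisson process; placements that would
overlap another event (with a guard interval) are rejected so the ground
truth stays unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .eeg_io import EEGRecording, EventTable

# Guard kept clear between any two injected events, and extra margin kept
# around artifacts, in seconds. Keeps ground truth unambiguous: no detected
# event can straddle two injected ones.
EVENT_GUARD_S = 1.0
ARTIFACT_GUARD_S = 2.0


@dataclass
class EEGSimParams:
    """Parameters of the synthetic EEG generator.

    Rates are events per hour of recording; amplitudes are relative to
    ``baseline_rms`` (microvolts).
    """

    duration: float = 60.0
    sampling_rate: float = 1000.0
    baseline_rms: float = 20.0
    noise_model: str = "ar2"  # white | ar2 | pink
    spike_rate: float = 120.0
    spike_amplitude_ratio: float = 6.0
    swd_rate: float = 30.0
    swd_component_freq: float = 12.0
    swd_components_range: tuple[int, int] = (5, 10)
    artifact_rate: float = 10.0
    artifact_amplitude_ratio: float = 12.0
    channel_label: str = "parietal_left"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.spike_amplitude_ratio <= 0:
            raise ValueError("spike_amplitude_ratio must be > 0")
        if min(self.spike_rate, self.swd_rate, self.artifact_rate) < 0:
            raise ValueError("event rates must be >= 0")
        lo, hi = self.swd_components_range
        if lo < 1 or hi < lo:
            raise ValueError("swd_components_range must satisfy 1 <= lo <= hi")
        if self.swd_component_freq <= 0:
            raise ValueError("swd_component_freq must be > 0")


@dataclass
class GroundTruth:
    """Injected events of a synthetic recording, sorted by start time."""

    events: EventTable

    def __post_init__(self) -> None:
        df = self.events.df
        for _, row in df.iterrows():
            comps = row["component_times"]
            if comps and (list(comps) != sorted(comps)):
                raise ValueError("component_times must be sorted")
        self.events = EventTable(df)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.events.df[self.events.df["kind"] == kind]

    @property
    def spike_times(self) -> np.ndarray:
        """Apex times of solitary spikes (SWD components not included)."""
        df = self.of_kind("spike")
        return np.array([0.5 * (s + e) for s, e in zip(df["start_s"], df["end_s"])])

    @property
    def all_sharp_transient_times(self) -> np.ndarray:
        """Solitary spike apexes plus every SWD component time, sorted."""
        times = list(self.spike_times)
        for comps in self.of_kind("swd")["component_times"]:
            times.extend(comps)
        return np.sort(np.asarray(times, dtype=float))

    def artifact_table(self) -> EventTable:
        return EventTable(self.of_kind("artifact"))


# ---------------------------------------------------------------------------
# waveform templates
# ---------------------------------------------------------------------------

def spike_template(fs: float, peak_uv: float) -> np.ndarray:
    """Biphasic sharp transient: difference of two Gaussian lobes.

    Main lobe sd 2 ms, opposing lobe sd 5 ms delayed 8 ms; total width about
    25 ms. Rescaled so the peak absolute value equals ``peak_uv``.
    """
    t = np.arange(-0.015, 0.030, 1.0 / fs)
    w = np.exp(-(t**2) / (2 * 0.002**2)) - 0.55 * np.exp(-((t - 0.008) ** 2) / (2 * 0.005**2))
    return peak_uv * w / np.max(np.abs(w))


def swd_cycle(fs: float, freq: float, peak_uv: float) -> tuple[np.ndarray, int]:
    """One spike-and-wave cycle of length 1/freq.

    A sharp spike of fixed ~25 ms width opens the cycle; a half-sine slow
    wave of opposite polarity and ~half the spike amplitude fills the rest
    of the period. Returns the cycle samples and the spike apex index.
    """
    period = int(round(fs / freq))
    t = np.arange(period) / fs
    spike_width = min(0.025, 0.5 / freq)
    spike = np.exp(-((t - 0.5 * spike_width) ** 2) / (2 * (0.12 * spike_width) ** 2))
    wave = np.zeros(period)
    wave_t = t >= spike_width
    dur = (period / fs) - spike_width
    wave[wave_t] = -0.5 * np.sin(np.pi * (t[wave_t] - spike_width) / dur)
    cyc = spike + wave
    cyc *= peak_uv / np.max(np.abs(cyc))
    return cyc, int(np.argmax(cyc))


def _artifact_waveform(rng: np.random.Generator, fs: float, peak_uv: float) -> np.ndarray:
    """Slow, large, irregular deflection 0.5-2 s long (movement-like)."""
    dur = rng.uniform(0.5, 2.0)
    n = int(round(dur * fs))
    slow = rng.standard_normal(n)
    # heavy low-pass -> slow wandering burst
    b, a = signal.butter(2, min(8.0 / (fs / 2), 0.99))
    slow = signal.filtfilt(b, a, slow)
    env = np.hanning(n)
    x = slow * env
    return peak_uv * x / np.max(np.abs(x))


def _background(rng: np.random.Generator, n: int, model: str, rms: float) -> np.ndarray:
    if model == "white":
        x = rng.standard_normal(n)
    elif model == "ar2":
        # low-pass AR(2), double pole at 0.9: 1/f-like falling spectrum with
        # a ~16 Hz corner, so the background has realistic low-frequency
        # power but little energy at spike sharpness scales
        e = rng.standard_normal(n + 2000)
        x = signal.lfilter([1.0], [1.0, -1.8, 0.81], e)[2000:]
    elif model == "pink":
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n)
        f[0] = f[1] if n > 1 else 1.0
        spec /= np.sqrt(f)
        x = np.fft.irfft(spec, n)
    else:
        raise ValueError(f"unknown noise_model {model!r}")
    sd = np.std(x)
    return rms * x / sd if sd > 0 else x


def _place_events(
    rng: np.random.Generator,
    duration: float,
    counts: dict[str, int],
    lengths: dict[str, float],
) -> list[tuple[float, str]]:
    """Poisson-count placement with overlap rejection.

    Artifacts are placed first (with the larger guard), then SWDs, then
    spikes. An event whose interval, padded by the guard, overlaps an already
    placed one is re-drawn; placements that cannot fit after many tries are
    dropped (rare at the default rates).
    """
    placed: list[tuple[float, float, str]] = []

    def clashes(s: float, e: float, kind: str) -> bool:
        for ps, pe, pk in placed:
            guard = ARTIFACT_GUARD_S if "artifact" in (kind, pk) else EVENT_GUARD_S
            if s - guard < pe and ps < e + guard:
                return True
        return False

    for kind in ("artifact", "swd", "spike"):
        length = lengths[kind]
        for _ in range(counts[kind]):
            for _attempt in range(200):
                s = rng.uniform(0.1, max(duration - length - 0.1, 0.1))
                if not clashes(s, s + length, kind):
                    placed.append((s, s + length, kind))
                    break
    return sorted([(s, k) for s, _e, k in placed])


def generate_eeg(params: EEGSimParams) -> tuple[EEGRecording, GroundTruth]:
    """Synthesize a single-channel EEG recording plus its ground truth.

    Returns the recording (microvolts) and a :class:`GroundTruth` whose event
    table lists every injected spike, SWD (with component times) and artifact.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n = int(round(params.duration * fs))
    x = _background(rng, n, params.noise_model, params.baseline_rms)

    hours = params.duration / 3600.0
    counts = {
        "spike": int(rng.poisson(params.spike_rate * hours)),
        "swd": int(rng.poisson(params.swd_rate * hours)),
        "artifact": int(rng.poisson(params.artifact_rate * hours)),
    }
    peak = params.spike_amplitude_ratio * params.baseline_rms
    lo, hi = params.swd_components_range
    max_swd_len = hi / params.swd_component_freq
    lengths = {"spike": 0.05, "swd": max_swd_len, "artifact": 2.0}
    slots = _place_events(rng, params.duration, counts, lengths)

    events: list[tuple] = []
    ch = params.channel_label
    for start, kind in slots:
        i0 = int(round(start * fs))
        if kind == "spike":
            tpl = spike_template(fs, peak)
            seg = slice(i0, i0 + len(tpl))
            if i0 + len(tpl) > n:
                continue
            x[seg] += tpl
            apex = start + np.argmax(np.abs(tpl)) / fs
            events.append((start, start + len(tpl) / fs, "spike", ch, [apex]))
        elif kind == "swd":
            n_comp = int(rng.integers(lo, hi + 1))
            cyc, apex_idx = swd_cycle(fs, params.swd_component_freq, peak)
            train = np.tile(cyc, n_comp)
            if i0 + len(train) > n:
                continue
            x[i0 : i0 + len(train)] += train
            comp_times = [start + (k * len(cyc) + apex_idx) / fs for k in range(n_comp)]
            events.append((start, start + len(train) / fs, "swd", ch, comp_times))
        else:
            wf = _artifact_waveform(rng, fs, params.artifact_amplitude_ratio * params.baseline_rms)
            if i0 + len(wf) > n:
                continue
            x[i0 : i0 + len(wf)] += wf
            events.append((start, start + len(wf) / fs, "artifact", ch, []))

    events.sort(key=lambda ev: ev[0])
    rec = EEGRecording(x[None, :], fs, [ch])
    return rec, GroundTruth(EventTable.from_events(events))


# ---------------------------------------------------------------------------
# behavioral trials
# ---------------------------------------------------------------------------

@dataclass
class GroupCurve:
    """Learning curve of one group: exponential decay toward an asymptote."""

    label: str
    n_mice: int
    learning_rate: float  # per-trial decay constant, >= 0
    asymptote: float
    start: float | None = None  # default: 3x asymptote
    noise_scale: float = 0.2

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    def mean_at(self, trial: int) -> float:
        """Expected value on 1-based trial index.

        Default starting level is 3x the asymptote; with no learning
        (rate 0) the curve is flat at the asymptote.
        """
        if self.start is None:
            start = self.asymptote if self.learning_rate == 0 else 3.0 * self.asymptote
        else:
            start = self.start
        return self.asymptote + (start - self.asymptote) * np.exp(
            -self.learning_rate * (trial - 1)
        )


@dataclass
class BehaviorSimDesign:
    """Design of a simulated training experiment (place-avoidance style).

    ``measure`` selects the noise family: ``entrances`` draws Poisson counts
    around the group curve; continuous measures draw lognormal multiplicative
    noise around it.
    """

    groups: Sequence[GroupCurve]
    n_trials: int = 9
    measure: str = "entrances"  # entrances | max_avoidance_time_s | path_length_cm | latency_s
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def generate_behavior_trials(design: BehaviorSimDesign) -> pd.DataFrame:
    """Long-format trial table: columns mouse_id, group, trial, value.

    With ``noise_scale == 0`` and ``learning_rate == 0`` every value equals
    the group asymptote exactly (degenerate check). Counts are non-negative
    integers for the entrance measure.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    mouse_no = 0
    for grp in design.groups:
        for _ in range(grp.n_mice):
            mouse_no += 1
            mid = f"m{mouse_no:03d}"
            for trial in range(1, design.n_trials + 1):
                mu = grp.mean_at(trial)
                if grp.noise_scale == 0:
                    val = float(mu)
                    if design.measure == "entrances":
                        val = float(np.round(val))
                elif design.measure == "entrances":
                    val = float(rng.poisson(max(mu, 0.0)))
                else:
                    val = float(mu * rng.lognormal(0.0, grp.noise_scale))
                rows.append(
                    {"mouse_id": mid, "group": grp.label, "trial": trial, "value": val}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group samples for the statistics pipeline
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    label: str
    n: int
    distribution: str = "normal"  # normal | lognormal | heavy_tailed
    location: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


@dataclass
class GroupSampleSpec:
    groups: Sequence[GroupSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")


def generate_group_samples(spec: GroupSampleSpec) -> pd.DataFrame:
    """Per-animal measurement table: columns mouse_id, group, value.

    ``lognormal`` groups use ``location``/``scale`` on the log scale (so the
    log transform restores normality); ``heavy_tailed`` draws Student t with
    3 degrees of freedom, shifted and scaled.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    i = 0
    for g in spec.groups:
        if g.distribution == "normal":
            vals = rng.normal(g.location, g.scale, g.n)
        elif g.distribution == "lognormal":
            vals = rng.lognormal(g.location, g.scale, g.n)
        elif g.distribution == "heavy_tailed":
            vals = g.location + g.scale * rng.standard_t(3, g.n)
        else:
            raise ValueError(f"unknown distribution {g.distribution!r}")
        for v in vals:
            i += 1
            rows.append({"mouse_id": f"m{i:03d}", "group": g.label, "value": float(v)})
    return pd.DataFrame(rows)
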