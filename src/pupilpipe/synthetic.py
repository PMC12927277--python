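"""Synthetic binocular pupillometry sessions.

Generates complete two-condition (sham / taVNS) stimulation studies with the
statistical structure the downstream analysis assumes: gamma-kernel
stimulation-locked dilations on a drifting tonic baseline, blinks as missing
sample runs, spike artifacts as step discontinuities, per-participant sensation
ratings whose taVNS-sham difference covaries (negatively by default) with the
sham response amplitude, and an optional right-eye lateralized response
component on taVNS trials.

Every quantity is reproducible from a single integer seed; each
participant x condition cell draws from an independent substream so the study
can be generated in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "EffectSpec",
    "SessionMeta",
    "RawRecording",
    "pupil_response_kernel",
    "simulate_recording",
    "simulate_study",
    "session_meta",
    "study_meta_table",
    "simulate_trial_table",
    "simulate_clean_epochs",
]

SHAM = "sham"
TAVNS = "taVNS"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Session layout: pulse timing, block structure and sampling.

    Defaults reproduce the study protocol: 94 participants, two conditions,
    3 blocks of 15 one-second pulses with a 25 s interstimulus interval,
    recorded at 1000 Hz. Trial length is ``pulse_duration + isi`` (26 s);
    onsets are spaced exactly one trial length apart.
    """

    n_participants: int = 94
    conditions: tuple[str, str] = (SHAM, TAVNS)
    n_blocks: int = 3
    pulses_per_block: int = 15
    pulse_duration: float = 1.0
    isi: float = 25.0
    sample_rate: float = 1000.0
    lead_in: float = 2.0  # seconds of recording before the first onset

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_blocks", "pulses_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.pulse_duration <= 0 or self.isi <= 0 or self.sample_rate <= 0:
            raise ValueError("pulse_duration, isi and sample_rate must be positive")
        if self.lead_in < 1.0:
            raise ValueError("lead_in must be >= 1 s to allow a baseline window")

    @property
    def trial_length(self) -> float:
        return self.pulse_duration + self.isi

    @property
    def n_events(self) -> int:
        return self.n_blocks * self.pulses_per_block

    @property
    def duration(self) -> float:
        """Total recording length in seconds (covers the last epoch)."""
        return self.lead_in + self.n_events * self.trial_length

    def condition_order(self, participant: int) -> tuple[str, str]:
        """Counterbalanced order: even-indexed participants start with sham."""
        if participant % 2 == 0:
            return self.conditions
        return (self.conditions[1], self.conditions[0])

    def onsets(self) -> np.ndarray:
        """Stimulation onset times in seconds."""
        return self.lead_in + np.arange(self.n_events) * self.trial_length


@dataclass(frozen=True)
class EffectSpec:
    """Generative parameters for one synthetic study.

    Amplitudes are percent dilation relative to the tonic baseline; artifact
    rates are events per minute; pupil units are the tracker's arbitrary units.
    ``stimulation_effect`` is the taVNS-minus-sham shift in response amplitude,
    ``lateralization_gain`` the mean extra right-eye response (percent, with
    trial-to-trial variability) on taVNS trials, and ``rating_coupling`` the
    slope (VAS points per percent dilation) linking a participant's sham
    response amplitude to their taVNS-sham sensation-rating difference.
    """

    response_amplitude_mean: float = 4.0
    response_amplitude_sd: float = 1.5
    response_latency: float = 1.3
    kernel_shape: float = 2.5
    stimulation_effect: float = 0.0
    lateralization_gain: float = 0.0
    lateralization_latency: float = 3.0  # s, the decoupling develops after the pulse
    block_slope: float = 0.0
    rating_coupling: float = -2.5
    rating_difference_mean: float = -0.46
    rating_difference_sd: float = 10.0
    trial_jitter_sd: float = 1.0
    stim_slope_sd: float = 1.0
    block_slope_sd: float = 0.3
    blink_rate: float = 8.0
    blink_duration_mean: float = 150.0  # ms
    spike_rate: float = 2.5
    spike_size: float = 0.5  # dip depth as a fraction of tonic_baseline
    noise_sd: float = 5.0
    eye_fluct_sd: float = 40.0  # units (RMS), per-eye independent slow component
    eye_fluct_freq: float = 0.45  # Hz
    hippus_sd: float = 120.0  # units (RMS), shared slow pupillary oscillation
    hippus_freq: float = 0.35  # Hz, nominal hippus frequency
    tonic_baseline: float = 4000.0
    drift_sd: float = 2.0  # units per sqrt(second), random walk
    amplitude_mean: float = 3.0  # mA, sham calibration level
    amplitude_sd: float = 0.8
    amplitude_condition_shift: float = -0.64  # taVNS minus sham, mA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tonic_baseline <= 0:
            raise ValueError("tonic_baseline must be positive")
        if self.response_latency <= 0:
            raise ValueError("response_latency must be positive")
        if self.kernel_shape <= 1:
            raise ValueError("kernel_shape must be > 1")
        for name in ("blink_rate", "spike_rate", "noise_sd", "drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_(self, **kwargs) -> "EffectSpec":
        return replace(self, **kwargs)


@dataclass
class SessionMeta:
    """Per participant x condition session metadata."""

    participant: int
    condition: str
    block_ratings: np.ndarray  # VAS 0-100, one per block
    amplitude_ma: float  # calibrated stimulation amplitude
    order_code: float  # -0.5 sham first, +0.5 taVNS first

    @property
    def mean_rating(self) -> float:
        return float(np.mean(self.block_ratings))

    def to_row(self) -> dict:
        row = {
            "participant": self.participant,
            "condition": self.condition,
            "amplitude_ma": self.amplitude_ma,
            "order_code": self.order_code,
            "mean_rating": self.mean_rating,
        }
        for b, r in enumerate(self.block_ratings):
            row[f"rating_block{b}"] = float(r)
        return row


@dataclass
class RawRecording:
    """Binocular 1000 Hz sample streams plus events for one session."""

    participant: int
    condition: str
    time_ms: np.ndarray
    left: np.ndarray
    right: np.ndarray
    events: pd.DataFrame  # onset_ms, duration_ms, block, trial_index, condition
    sample_rate: float

    def __post_init__(self) -> None:
        n = len(self.time_ms)
        if len(self.left) != n or len(self.right) != n:
            raise ValueError("sample columns must have equal length")
        if len(self.events) and self.events["onset_ms"].max() >= self.time_ms[-1]:
            raise ValueError("events must lie within the recording span")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.time_ms, "left_pupil": self.left, "right_pupil": self.right}
        )


# ---------------------------------------------------------------------------
# Response kernel
# ---------------------------------------------------------------------------

def pupil_response_kernel(t, latency: float, shape: float):
    """Unit-peak gamma-shaped event-locked dilation kernel.

    ``k(t) = (t/L)^(s-1) exp(-(t-L)(s-1)/L)`` for ``t > 0`` and 0 otherwise,
    with latency ``L`` (the time of the single interior maximum, where the
    kernel equals exactly 1) and dimensionless shape ``s > 1`` controlling
    rise/decay asymmetry.
    """
    if latency <= 0:
        raise ValueError("latency must be positive")
    if shape <= 1:
        raise ValueError("shape must be > 1")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    s1 = shape - 1.0
    out[pos] = (tp / latency) ** s1 * np.exp(-s1 * (tp - latency) / latency)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Participant-level latent traits
# ---------------------------------------------------------------------------

def _participant_rng(seed: int, participant: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(participant,)))


def _cell_rng(seed: int, participant: int, cond_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(participant, 1 + cond_index))
    )


def _meta_rng(seed: int, participant: int, cond_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(participant, 100 + cond_index))
    )


def session_meta(
    design: StudyDesign, effects: EffectSpec, participant: int, condition: str
) -> SessionMeta:
    """Session metadata, reproducible independently of the signal streams."""
    traits = _participant_traits(effects, participant)
    cond_index = design.conditions.index(condition)
    rng = _meta_rng(effects.seed, participant, cond_index)
    first = design.condition_order(participant)[0]
    level = traits["sham_rating_level"] + (
        traits["rating_difference"] if condition == TAVNS else 0.0
    )
    ratings = np.clip(level + rng.normal(0.0, 5.0, size=design.n_blocks), 0.0, 100.0)
    return SessionMeta(
        participant=participant,
        condition=condition,
        block_ratings=ratings,
        amplitude_ma=traits["amplitude_ma"][condition],
        order_code=-0.5 if first == SHAM else 0.5,
    )


def _participant_traits(effects: EffectSpec, participant: int) -> dict:
    """Latent traits shared across a participant's two sessions."""
    rng = _participant_rng(effects.seed, participant)
    amp = rng.normal(effects.response_amplitude_mean, effects.response_amplitude_sd)
    stim_dev = rng.normal(0.0, effects.stim_slope_sd)
    block_dev = rng.normal(0.0, effects.block_slope_sd)
    # rating difference covaries with the *sham* response amplitude
    drating = (
        effects.rating_difference_mean
        + effects.rating_coupling * (amp - effects.response_amplitude_mean)
        + rng.normal(0.0, effects.rating_difference_sd)
    )
    sham_rating_level = np.clip(rng.normal(50.0, 12.0), 5.0, 95.0)
    amp_ma_sham = max(0.5, rng.normal(effects.amplitude_mean, effects.amplitude_sd))
    amp_ma_tavns = max(
        0.1, amp_ma_sham + effects.amplitude_condition_shift + rng.normal(0.0, 0.3)
    )
    return {
        "amplitude": amp,
        "stim_dev": stim_dev,
        "block_dev": block_dev,
        "rating_difference": drating,
        "sham_rating_level": sham_rating_level,
        "amplitude_ma": {SHAM: amp_ma_sham, TAVNS: amp_ma_tavns},
    }


def _trial_amplitudes(
    design: StudyDesign, effects: EffectSpec, traits: dict, condition: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-trial response amplitude (percent dilation), shared by both eyes."""
    blocks = np.repeat(np.arange(design.n_blocks), design.pulses_per_block)
    is_tavns = float(condition == TAVNS)
    amp = (
        traits["amplitude"]
        + is_tavns * (effects.stimulation_effect + traits["stim_dev"])
        + (effects.block_slope + traits["block_dev"]) * blocks
        + rng.normal(0.0, effects.trial_jitter_sd, size=design.n_events)
    )
    return np.clip(amp, 0.0, None)


# ---------------------------------------------------------------------------
# Full-signal simulation
# ---------------------------------------------------------------------------

def _events_table(design: StudyDesign, condition: str) -> pd.DataFrame:
    onsets_ms = np.round(design.onsets() * 1000).astype(np.int64)
    return pd.DataFrame(
        {
            "onset_ms": onsets_ms,
            "duration_ms": np.full(design.n_events, int(design.pulse_duration * 1000)),
            "block": np.repeat(np.arange(design.n_blocks), design.pulses_per_block),
            "trial_index": np.tile(
                np.arange(design.pulses_per_block), design.n_blocks
            ),
            "condition": condition,
        }
    )


def simulate_recording(
    design: StudyDesign, effects: EffectSpec, participant: int, condition: str
) -> tuple[RawRecording, SessionMeta]:
    """Simulate one participant-condition session.

    Both eye traces are tonic baseline + random-walk drift + the sum of
    event-locked kernels (the right eye receives the lateralized extra
    component on taVNS trials) + Gaussian noise; blink runs are emitted as
    NaN in both eyes, spikes as transient step discontinuities. Identical
    (design, effects, participant, condition) yields bit-identical output.
    """
    if condition not in design.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cond_index = design.conditions.index(condition)
    traits = _participant_traits(effects, participant)
    rng = _cell_rng(effects.seed, participant, cond_index)

    fs = design.sample_rate
    n = int(round(design.duration * fs))
    t = np.arange(n) / fs
    time_ms = np.round(t * 1000).astype(np.int64)

    amps = _trial_amplitudes(design, effects, traits, condition, rng)
    lat_extra = np.zeros(design.n_events)
    if condition == TAVNS and effects.lateralization_gain > 0:
        lat_extra = np.clip(
            rng.normal(
                effects.lateralization_gain,
                0.6 * effects.lateralization_gain,
                size=design.n_events,
            ),
            0.0,
            None,
        )

    # event-locked responses via one kernel template added at each onset
    tmpl_len = int(round(design.trial_length * fs))
    tmpl = pupil_response_kernel(
        np.arange(1, tmpl_len + 1) / fs, effects.response_latency, effects.kernel_shape
    )
    tmpl_lat = pupil_response_kernel(
        np.arange(1, tmpl_len + 1) / fs,
        effects.lateralization_latency,
        effects.kernel_shape,
    )
    resp_shared = np.zeros(n)
    resp_right_extra = np.zeros(n)
    onsets_idx = np.round(design.onsets() * fs).astype(int)
    for k, i0 in enumerate(onsets_idx):
        i1 = min(n, i0 + tmpl_len)
        resp_shared[i0:i1] += amps[k] / 100.0 * effects.tonic_baseline * tmpl[: i1 - i0]
        if lat_extra[k] > 0:
            resp_right_extra[i0:i1] += (
                lat_extra[k] / 100.0 * effects.tonic_baseline * tmpl_lat[: i1 - i0]
            )

    # tonic drift reflects central arousal and is common to both eyes
    if effects.drift_sd > 0:
        drift = np.cumsum(rng.normal(0.0, effects.drift_sd / np.sqrt(fs), size=n))
    else:
        drift = np.zeros(n)

    def noise() -> np.ndarray:
        if effects.noise_sd == 0:
            return np.zeros(n)
        return rng.normal(0.0, effects.noise_sd, size=n)

    def eye_fluct() -> np.ndarray:
        # small per-eye slow oscillation (iris mechanics differ between
        # eyes); quasi-sinusoidal so its derivative stays bounded
        if effects.eye_fluct_sd == 0:
            return np.zeros(n)
        f = effects.eye_fluct_freq * rng.uniform(0.8, 1.2)
        return (
            effects.eye_fluct_sd
            * np.sqrt(2.0)
            * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        )

    # hippus: regular slow oscillation common to both eyes (centrally driven);
    # quasi-sinusoidal with slowly wandering phase and mild amplitude
    # modulation, so its derivative stays bounded as in real recordings
    if effects.hippus_sd > 0:
        f0 = effects.hippus_freq * rng.uniform(0.85, 1.15)
        fm = f0 * (1.0 + 0.15 * np.sin(2 * np.pi * 0.007 * t + rng.uniform(0, 2 * np.pi)))
        phase = 2 * np.pi * np.cumsum(fm) / fs
        am = 1.0 + 0.1 * np.sin(2 * np.pi * 0.013 * t + rng.uniform(0, 2 * np.pi))
        hippus = (
            effects.hippus_sd
            * np.sqrt(2.0)
            * am
            * np.sin(phase + rng.uniform(0, 2 * np.pi))
        )
    else:
        hippus = np.zeros(n)

    left = effects.tonic_baseline + hippus + drift + resp_shared + eye_fluct() + noise()
    right = (
        effects.tonic_baseline
        + hippus
        + drift
        + resp_shared
        + resp_right_extra
        + eye_fluct()
        + noise()
    )

    # artifact event times: eyelid events are refractory -- a blink (or
    # partial-lid occlusion) is not followed by another within ~2 s, so
    # candidate Poisson times closer than that to an accepted event are
    # thinned out. Placement is drawn jointly for dips and blinks so the
    # two artifact types keep the same minimum separation.
    dur_min = design.duration / 60.0
    refractory_s = 2.0
    n_spikes = rng.poisson(effects.spike_rate * dur_min)
    n_blinks = rng.poisson(effects.blink_rate * dur_min)
    cand = rng.uniform(0.0, design.duration, size=n_spikes + n_blinks)
    is_spike = np.zeros(len(cand), bool)
    is_spike[:n_spikes] = True
    order = rng.permutation(len(cand))
    cand, is_spike = cand[order], is_spike[order]
    t_order = np.argsort(cand)
    keep = []
    last = -np.inf
    for idx in t_order:
        if cand[idx] - last >= refractory_s:
            keep.append(idx)
            last = cand[idx]
    keep = np.asarray(keep, dtype=int)

    # spikes: transient occlusion dips (~50 ms) hitting both eyes together,
    # as when the eyelid partially covers the pupil
    spike_len = int(round(0.05 * fs))
    for s in cand[keep[is_spike[keep]]]:
        i0 = min(int(s * fs), max(0, n - spike_len))
        depth = effects.spike_size * effects.tonic_baseline * rng.uniform(0.5, 1.5)
        depth = min(depth, 0.9 * effects.tonic_baseline)
        left[i0 : i0 + spike_len] -= depth
        right[i0 : i0 + spike_len] -= depth

    # blinks: shared missing-sample runs in both eyes
    blink_starts = np.sort(cand[keep[~is_spike[keep]]])
    if len(blink_starts):
        durs = rng.gamma(
            3.0, effects.blink_duration_mean / 3000.0, size=len(blink_starts)
        )
        for s, d in zip(blink_starts, durs):
            i0, i1 = int(s * fs), min(n, int((s + d) * fs) + 1)
            left[i0:i1] = np.nan
            right[i0:i1] = np.nan

    events = _events_table(design, condition)
    rec = RawRecording(
        participant=participant,
        condition=condition,
        time_ms=time_ms,
        left=left,
        right=right,
        events=events,
        sample_rate=fs,
    )

    return rec, session_meta(design, effects, participant, condition)


def simulate_study(design: StudyDesign, effects: EffectSpec):
    """Yield (RawRecording, SessionMeta) for every participant x condition.

    A generator, so that full-size studies (94 x 2 sessions of ~20 minutes at
    1000 Hz) can be processed one session at a time without holding the whole
    study in memory. Condition order alternates across participants.
    """
    for p in range(design.n_participants):
        for condition in design.condition_order(p):
            yield simulate_recording(design, effects, p, condition)


def study_meta_table(design: StudyDesign, effects: EffectSpec) -> pd.DataFrame:
    """Session metadata for the whole study without simulating any signal."""
    rows = []
    for p in range(design.n_participants):
        for condition in design.condition_order(p):
            rows.append(session_meta(design, effects, p, condition).to_row())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Outcome-level generator (Monte-Carlo studies)
# ---------------------------------------------------------------------------

def simulate_trial_table(
    design: StudyDesign,
    effects: EffectSpec,
    rating_interaction: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate trial outcomes directly at the statistical-model level.

    Produces the same (trial table, meta table) surface as the full signal
    pipeline, drawing max-dilation outcomes from the mixed-model data
    generating process: participant random intercepts and slopes for
    stimulation and block, the fixed stimulation/block effects, an optional
    stimulation x rating-difference interaction (``rating_interaction``, in
    percent dilation per unit of the /100-scaled rating difference), and
    trial-level Gaussian noise. Intended for calibration and recovery studies
    where simulating the raw 1000 Hz signal for hundreds of replicates is
    unnecessary.
    """
    rows = []
    meta_rows = []
    for p in range(design.n_participants):
        traits = _participant_traits(effects, p)
        metas = {
            c: session_meta(design, effects, p, c) for c in design.conditions
        }
        # realized rating difference (what the analysis will regress on),
        # centered at the generative mean so fixed effects stay interpretable
        drating_scaled = (
            metas[TAVNS].mean_rating
            - metas[SHAM].mean_rating
            - effects.rating_difference_mean
        ) / 100.0
        for condition in design.condition_order(p):
            cond_index = design.conditions.index(condition)
            rng = _cell_rng(effects.seed, p, cond_index)
            stim_code = 0.5 if condition == TAVNS else -0.5
            blocks = np.repeat(np.arange(design.n_blocks), design.pulses_per_block)
            is_tavns = float(condition == TAVNS)
            y = (
                traits["amplitude"]
                + is_tavns * (effects.stimulation_effect + traits["stim_dev"])
                + (effects.block_slope + traits["block_dev"]) * blocks
                + rating_interaction * stim_code * drating_scaled
                + rng.normal(0.0, effects.trial_jitter_sd, size=design.n_events)
            )
            for k in range(design.n_events):
                rows.append(
                    {
                        "participant": p,
                        "condition": condition,
                        "block": int(blocks[k]),
                        "trial_index": k % design.pulses_per_block,
                        "max_dilation": y[k],
                        "auc": y[k] * 2.5,
                        "peak_latency": effects.response_latency,
                        "baseline": effects.tonic_baseline,
                        "excluded": False,
                        "reason": "",
                    }
                )
            meta_rows.append(metas[condition].to_row())
    return pd.DataFrame(rows), pd.DataFrame(meta_rows)


# ---------------------------------------------------------------------------
# Epoch-level generator (laterality Monte-Carlo studies)
# ---------------------------------------------------------------------------

def simulate_clean_epochs(
    effects: EffectSpec,
    n_participants: int = 20,
    n_trials: int = 30,
    t_start: float = -1.0,
    t_end: float = 6.0,
    out_rate: float = 100.0,
    epoch_noise_sd: float = 0.7,
):
    """Generate baseline-corrected percent-change epochs for both eyes.

    Yields ``(participant, condition, rel_time, left, right)`` with ``left``
    and ``right`` of shape (n_trials, n_samples). The two eyes share the
    per-trial response amplitude (yoked dilation) and a per-trial
    baseline-corrected hippus oscillation with random phase (the shared
    ongoing activity that keeps the across-trial left/right correlation high
    even before stimulation), plus independent sample noise; on taVNS trials
    the right eye adds a trial-varying lateralized response component of mean
    ``effects.lateralization_gain`` percent, which lowers the across-trial
    correlation after the pulse. Used for laterality calibration studies
    that do not need the raw-signal path.
    """
    rel_time = np.arange(round(t_start * out_rate), round(t_end * out_rate)) / out_rate
    kern = pupil_response_kernel(rel_time, effects.response_latency, effects.kernel_shape)
    kern_lat = pupil_response_kernel(
        rel_time, effects.lateralization_latency, effects.kernel_shape
    )
    for p in range(n_participants):
        traits = _participant_traits(effects, p)
        for ci, condition in enumerate((SHAM, TAVNS)):
            rng = _cell_rng(effects.seed, p, ci)
            amps = np.clip(
                traits["amplitude"]
                + rng.normal(0.0, effects.trial_jitter_sd, size=n_trials),
                0,
                None,
            )
            shared = amps[:, None] * kern[None, :]
            if effects.hippus_sd > 0:
                h_amp = effects.hippus_sd / effects.tonic_baseline * 100.0 * np.sqrt(2)
                freq = effects.hippus_freq * rng.uniform(0.85, 1.15, size=(n_trials, 1))
                phase = rng.uniform(0, 2 * np.pi, size=(n_trials, 1))
                hip = h_amp * np.sin(2 * np.pi * freq * rel_time[None, :] + phase)
                base = hip[:, (rel_time >= -1.0) & (rel_time < 0.0)].mean(
                    axis=1, keepdims=True
                )
                shared = shared + hip - base
            left = shared + rng.normal(0.0, epoch_noise_sd, size=shared.shape)
            right = shared + rng.normal(0.0, epoch_noise_sd, size=shared.shape)
            if condition == TAVNS and effects.lateralization_gain > 0:
                extra = np.clip(
                    rng.normal(
                        effects.lateralization_gain,
                        0.6 * effects.lateralization_gain,
                        size=n_trials,
                    ),
                    0,
                    None,
                )
                right = right + extra[:, None] * kern_lat[None, :]
            yield p, condition, rel_time, left, right
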