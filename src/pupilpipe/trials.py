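"""Stimulation-locked epochs, baseline correction, outcomes, exclusions.

Each stimulation onset defines a 26 s trial: 1 s pre-onset baseline window
plus the 1 s pulse and 25 s interstimulus interval. Traces are expressed as
percent change from the mean pupil size in the second before onset, and three
scalar outcomes are extracted over the post-onset analysis window (default
0-5 s): maximum percent dilation, its latency, and the trapezoid area under
the curve. Trials are excluded when their longest interpolated run exceeds
1 s or more than 50% of their samples are missing or interpolated (strict
inequalities; boundary cases are retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CleanRecording, INTERPOLATED, MISSING, VALID

__all__ = [
    "TrialEpoch",
    "TrialOutcome",
    "segment",
    "baseline_correct",
    "compute_outcomes",
    "apply_exclusions",
    "trial_table",
    "exclusion_summary",
]

BASELINE_S = 1.0
POST_S = 25.0


@dataclass
class TrialEpoch:
    """One stimulation-locked epoch on a -1 ... +25 s clock."""

    participant: int
    condition: str
    block: int
    trial_index: int
    rel_time: np.ndarray  # seconds from stimulation onset
    left: np.ndarray
    right: np.ndarray
    left_flags: np.ndarray
    right_flags: np.ndarray
    baseline_left: float = np.nan
    baseline_right: float = np.nan
    corrected: bool = False
    excluded: bool = False
    reason: str = ""

    @property
    def bad_mask(self) -> np.ndarray:
        """Samples where either eye is interpolated or missing."""
        return (self.left_flags != VALID) | (self.right_flags != VALID)

    @property
    def fraction_bad(self) -> float:
        return float(self.bad_mask.mean())

    @property
    def longest_bad_run_s(self) -> float:
        mask = self.bad_mask
        if not mask.any():
            return 0.0
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        runs = edges[1::2] - edges[::2]
        # rounded so a run of exactly (1 s * rate) samples compares equal
        # to 1.0 s rather than exceeding it through float noise
        dt = round(float(self.rel_time[1] - self.rel_time[0]), 9)
        return float(runs.max() * dt)

    @property
    def mean_trace(self) -> np.ndarray:
        """Binocular average trace (used for the scalar outcomes)."""
        return (self.left + self.right) / 2.0


@dataclass(frozen=True)
class TrialOutcome:
    """Scalar outcomes for one trial over the analysis window."""

    max_dilation: float  # percent change
    auc: float  # percent * seconds
    peak_latency: float  # seconds from onset
    baseline: float  # raw pupil units (binocular mean)
    low_quality: bool = False


def segment(clean: CleanRecording) -> list[TrialEpoch]:
    """Cut one epoch per stimulation event (onset - 1 s to onset + 25 s).

    The final trial of a block spans the same 26 s as all others. Epochs
    extending past the recording end are flagged truncated (and excluded).
    """
    if not clean.usable:
        return []
    dt_ms = 1000.0 / clean.rate
    n_pre = int(round(BASELINE_S * clean.rate))
    n_post = int(round(POST_S * clean.rate))
    n_epoch = n_pre + n_post
    rel_time = (np.arange(n_epoch) - n_pre) / clean.rate
    epochs = []
    for ev in clean.events.itertuples(index=False):
        i_on = int(round(ev.onset_ms / dt_ms))
        i0, i1 = i_on - n_pre, i_on + n_post
        truncated = i0 < 0 or i1 > len(clean.time_ms)
        lo, hi = max(i0, 0), min(i1, len(clean.time_ms))
        left = np.full(n_epoch, np.nan)
        right = np.full(n_epoch, np.nan)
        lf = np.full(n_epoch, MISSING, dtype=np.int8)
        rf = np.full(n_epoch, MISSING, dtype=np.int8)
        left[lo - i0 : hi - i0] = clean.left[lo:hi]
        right[lo - i0 : hi - i0] = clean.right[lo:hi]
        lf[lo - i0 : hi - i0] = clean.left_flags[lo:hi]
        rf[lo - i0 : hi - i0] = clean.right_flags[lo:hi]
        ep = TrialEpoch(
            participant=clean.participant,
            condition=clean.condition,
            block=int(ev.block),
            trial_index=int(ev.trial_index),
            rel_time=rel_time,
            left=left,
            right=right,
            left_flags=lf,
            right_flags=rf,
        )
        if truncated:
            ep.excluded, ep.reason = True, "truncated"
        epochs.append(ep)
    return epochs


def baseline_correct(epoch: TrialEpoch) -> TrialEpoch:
    """Express both eyes as percent change from the 1 s pre-onset mean.

    The baseline is the mean over [-1, 0) s (valid and interpolated samples
    alike); the trace becomes ``100 * (x - baseline) / baseline`` per eye.
    A non-positive or all-missing baseline marks the trial unusable.
    """
    base_mask = (epoch.rel_time >= -BASELINE_S) & (epoch.rel_time < 0)
    for eye in ("left", "right"):
        vals = getattr(epoch, eye)
        flags = getattr(epoch, f"{eye}_flags")
        ok = base_mask & (flags != MISSING) & np.isfinite(vals)
        if not ok.any():
            epoch.excluded, epoch.reason = True, "no_baseline"
            return epoch
        b = float(vals[ok].mean())
        if b <= 0:
            epoch.excluded, epoch.reason = True, "nonpositive_baseline"
            return epoch
        setattr(epoch, f"baseline_{eye}", b)
        setattr(epoch, eye, 100.0 * (vals - b) / b)
    epoch.corrected = True
    return epoch


def compute_outcomes(
    epoch: TrialEpoch, window: tuple[float, float] = (0.0, 5.0)
) -> TrialOutcome:
    """Max dilation, peak latency and trapezoid AUC over the analysis window.

    Outcomes are computed on the binocular mean percent-change trace. A
    window whose samples are all interpolated yields a low-quality flag but
    is still computed (the exclusion rules decide retention).
    """
    if not epoch.corrected:
        raise ValueError("epoch must be baseline-corrected first")
    lo, hi = window
    mask = (epoch.rel_time >= lo) & (epoch.rel_time <= hi)
    trace = epoch.mean_trace[mask]
    t = epoch.rel_time[mask]
    if not np.isfinite(trace).any():
        return TrialOutcome(np.nan, np.nan, np.nan, np.nan, low_quality=True)
    i_max = int(np.nanargmax(trace))
    auc = float(np.trapezoid(trace, t))
    low_quality = bool(epoch.bad_mask[mask].all())
    baseline = (epoch.baseline_left + epoch.baseline_right) / 2.0
    return TrialOutcome(
        max_dilation=float(trace[i_max]),
        auc=auc,
        peak_latency=float(t[i_max]),
        baseline=float(baseline),
        low_quality=low_quality,
    )


def apply_exclusions(
    epochs: list[TrialEpoch],
    max_interp_run_s: float = 1.0,
    max_bad_fraction: float = 0.5,
) -> tuple[list[TrialEpoch], pd.DataFrame]:
    """Flag trials failing the artifact-burden rules; report per reason.

    A trial is excluded iff its longest interpolated/missing run is strictly
    greater than ``max_interp_run_s`` seconds or its interpolated-or-missing
    fraction is strictly greater than ``max_bad_fraction``. Trials already
    flagged (truncated, unusable baseline) stay excluded. Returns the epochs
    (with flags set) and a per participant/condition/reason count table.
    """
    rows = []
    for ep in epochs:
        if not ep.excluded:
            if ep.longest_bad_run_s > max_interp_run_s:
                ep.excluded, ep.reason = True, "long_interpolated_run"
            elif ep.fraction_bad > max_bad_fraction:
                ep.excluded, ep.reason = True, "high_bad_fraction"
        rows.append(
            {
                "participant": ep.participant,
                "condition": ep.condition,
                "excluded": ep.excluded,
                "reason": ep.reason if ep.excluded else "retained",
            }
        )
    report = (
        pd.DataFrame(rows)
        .groupby(["participant", "condition", "reason"])
        .size()
        .rename("n_trials")
        .reset_index()
    )
    retained = [ep for ep in epochs if not ep.excluded]
    return retained, report


def exclusion_summary(n_excluded: int, n_total: int) -> dict:
    """Study-level exclusion bookkeeping with the rate as a percentage."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return {
        "n_excluded": int(n_excluded),
        "n_total": int(n_total),
        "percent_excluded": round(100.0 * n_excluded / n_total, 2),
    }


def trial_table(
    epoch_groups: list[list[TrialEpoch]],
    window: tuple[float, float] = (0.0, 5.0),
    max_interp_run_s: float = 1.0,
    max_bad_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-trial outcome table over many sessions, plus exclusion report.

    Each element of ``epoch_groups`` is one session's segmented epochs.
    Epochs are baseline-corrected, screened by the exclusion rules, and
    reduced to one row per trial; excluded trials keep their row with
    ``excluded=True`` and NaN outcomes.
    """
    all_rows = []
    report_parts = []
    for epochs in epoch_groups:
        for ep in epochs:
            if not ep.excluded:
                baseline_correct(ep)
        _, report = apply_exclusions(epochs, max_interp_run_s, max_bad_fraction)
        report_parts.append(report)
        for ep in epochs:
            row = {
                "participant": ep.participant,
                "condition": ep.condition,
                "block": ep.block,
                "trial_index": ep.trial_index,
                "excluded": ep.excluded,
                "reason": ep.reason,
            }
            if ep.excluded or not ep.corrected:
                row.update(
                    max_dilation=np.nan, auc=np.nan, peak_latency=np.nan, baseline=np.nan
                )
            else:
                out = compute_outcomes(ep, window)
                row.update(
                    max_dilation=out.max_dilation,
                    auc=out.auc,
                    peak_latency=out.peak_latency,
                    baseline=out.baseline,
                )
            all_rows.append(row)
    table = pd.DataFrame(all_rows)
    report = (
        pd.concat(report_parts, ignore_index=True)
        if report_parts
        else pd.DataFrame(columns=["participant", "condition", "reason", "n_trials"])
    )
    return table, report
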