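"""Binocular left/right pupil correlation and its early/late comparison.

For each participant and condition, the across-trial Pearson correlation
between the left and right percent-change traces is computed per 10 ms time
bin, Fisher z (atanh) transformed, and averaged over two trial segments:
"early" (1 s before stimulation onset through stimulation end) and "late"
(1 to 5 s after stimulation end). A mixed model on the transformed values,
with dummy-coded stimulation (sham reference) and time segment (early
reference) and their full interaction in both fixed and random parts, tests
whether unilateral stimulation decorrelates the two pupils after the pulse:
a lateralized taVNS response shows up as a negative Stimulation x Time
coefficient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lmm import FitResult, fit_mixed_model
from .synthetic import SHAM, TAVNS
from .trials import TrialEpoch

__all__ = [
    "binned_lr_correlation",
    "segment_and_transform",
    "laterality_table",
    "laterality_table_from_epochs",
    "fit_laterality_model",
    "CLIP",
]

CLIP = 1.0 - 1e-6  # |r| clipped here before atanh
PULSE_END_S = 1.0
EARLY = (-1.0, PULSE_END_S)
LATE = (PULSE_END_S + 1.0, PULSE_END_S + 5.0)


def binned_lr_correlation(
    rel_time: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    bin_ms: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Across-trial left/right Pearson correlation per time bin.

    ``left`` and ``right`` are (n_trials, n_samples) percent-change arrays on
    a shared epoch clock. Samples are averaged within each bin (at 100 Hz a
    10 ms bin is a single sample), then, for each bin, the correlation is
    taken across trials. Bins with zero variance in either eye are returned
    as NaN. Requires at least 3 trials.
    """
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    if left.shape != right.shape or left.ndim != 2:
        raise ValueError("left and right must be (n_trials, n_samples) and equal shape")
    if left.shape[0] < 3:
        raise ValueError("need at least 3 trials for an across-trial correlation")
    dt = float(rel_time[1] - rel_time[0])
    per_bin = max(1, int(round(bin_ms / 1000.0 / dt)))
    n_bins = left.shape[1] // per_bin
    bt = rel_time[: n_bins * per_bin : per_bin]
    l = left[:, : n_bins * per_bin].reshape(left.shape[0], n_bins, per_bin).mean(2)
    r = right[:, : n_bins * per_bin].reshape(right.shape[0], n_bins, per_bin).mean(2)
    lc = l - l.mean(axis=0)
    rc = r - r.mean(axis=0)
    num = (lc * rc).sum(axis=0)
    den = np.sqrt((lc**2).sum(axis=0) * (rc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(den > 0, num / den, np.nan)
    return bt, corr


def segment_and_transform(
    bin_time: np.ndarray,
    r: np.ndarray,
    restricted: bool = False,
    transform_first: bool = True,
) -> dict[str, dict]:
    """Average Fisher-z correlations over the early and late segments.

    Early covers [-1 s, stimulation end] on the onset-locked clock (or
    [0, stimulation end] for the temporally restricted variant); late covers
    1-5 s after stimulation end. Per-bin r values are clipped to
    ``|r| <= 1 - 1e-6`` and atanh-transformed before averaging (set
    ``transform_first=False`` to average raw r first and transform the mean).
    Undefined bins are dropped and counted; an empty segment yields no entry.
    """
    early_lo = 0.0 if restricted else EARLY[0]
    segments = {"early": (early_lo, EARLY[1]), "late": LATE}
    out = {}
    for name, (lo, hi) in segments.items():
        mask = (bin_time >= lo) & (bin_time <= hi)
        vals = r[mask]
        n_dropped = int(np.isnan(vals).sum())
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        clipped = np.clip(vals, -CLIP, CLIP)
        if transform_first:
            mean_z = float(np.arctanh(clipped).mean())
        else:
            mean_z = float(np.arctanh(np.clip(clipped.mean(), -CLIP, CLIP)))
        out[name] = {
            "mean_z": mean_z,
            "mean_r": float(vals.mean()),
            "n_bins": int(len(vals)),
            "n_dropped": n_dropped,
        }
    return out


def laterality_table(
    epoch_arrays,
    bin_ms: float = 10.0,
    restricted: bool = False,
    transform_first: bool = True,
) -> pd.DataFrame:
    """Per participant x condition x segment mean transformed correlations.

    ``epoch_arrays`` yields ``(participant, condition, rel_time, left,
    right)`` tuples with trial-stacked percent-change arrays (the output
    shape of the epoch generator, or of
    :func:`laterality_table_from_epochs`). Participant-conditions with fewer
    than 3 trials are skipped.
    """
    rows = []
    for participant, condition, rel_time, left, right in epoch_arrays:
        if left.shape[0] < 3:
            continue
        bt, corr = binned_lr_correlation(rel_time, left, right, bin_ms)
        segs = segment_and_transform(bt, corr, restricted, transform_first)
        for segment, vals in segs.items():
            rows.append(
                {
                    "participant": participant,
                    "condition": condition,
                    "segment": segment,
                    "mean_z": vals["mean_z"],
                    "mean_r": vals["mean_r"],
                    "n_bins": vals["n_bins"],
                    "n_trials": left.shape[0],
                }
            )
    return pd.DataFrame(rows)


def laterality_table_from_epochs(
    epochs_by_session: list[list[TrialEpoch]], **kwargs
) -> pd.DataFrame:
    """Build the laterality table from segmented, corrected trial epochs."""

    def gen():
        for epochs in epochs_by_session:
            retained = [ep for ep in epochs if not ep.excluded and ep.corrected]
            if not retained:
                continue
            yield (
                retained[0].participant,
                retained[0].condition,
                retained[0].rel_time,
                np.stack([ep.left for ep in retained]),
                np.stack([ep.right for ep in retained]),
            )

    return laterality_table(gen(), **kwargs)


def fit_laterality_model(
    table: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    rating_diff: pd.Series | None = None,
    df_method: str = "satterthwaite",
) -> FitResult:
    """Mixed model on the transformed correlations.

    Stimulation is dummy-coded (sham reference), time segment dummy-coded
    (early reference); fixed and random parts carry the full interaction
    (with the standard fallback ladder when the saturated random structure is
    degenerate). Passing ``labels`` adds a responder fixed effect (dummy,
    non-responders reference); passing ``rating_diff`` (a per-participant
    Series of coded rating differences) adds it as a fixed effect, each
    crossed with stimulation and time.
    """
    tab = table.copy()
    tab["stimulation"] = (tab["condition"] == TAVNS).astype(float)
    tab["time"] = (tab["segment"] == "late").astype(float)
    fixed = "mean_z ~ stimulation * time"
    if labels is not None:
        tab = tab.merge(labels[["participant", "responder"]], on="participant")
        fixed += " * responder"
    if rating_diff is not None:
        tab["rating_diff"] = tab["participant"].map(rating_diff)
        fixed += " * rating_diff"
    return fit_mixed_model(
        tab,
        fixed,
        groups="participant",
        re_formula="1 + stimulation * time",
        df_method=df_method,
    )
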