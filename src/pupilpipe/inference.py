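"""Design coding, the study's mixed-effects models, FDR time course,
responder classification, marginal means, and Steiger's Z.

Coding scheme (applied by :func:`code_design`):

* stimulation: effect-centered, sham = -0.5, taVNS = +0.5;
* block: linear term coded 0, 1, 2 in chronological order;
* amplitude: calibrated stimulation amplitude, z-standardized over the frame;
* rating_diff: per-participant mean taVNS rating minus mean sham rating,
  centered across participants, divided by 100 (range within -1 ... 1);
* order: effect-centered, sham-first = -0.5, taVNS-first = +0.5.

The trial-level model regresses an outcome (max dilation by default; AUC and
baseline variants share the contract) on stimulation, block, rating
difference, amplitude and order plus all stimulation interactions, with
random intercepts and slopes for stimulation and block per participant. The
time-resolved analysis refits the same model per 100 ms bin of the
percent-change trace and applies Benjamini-Hochberg FDR jointly across all
bins and fixed-effect terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lmm import FitResult, fit_mixed_model
from .synthetic import SHAM, TAVNS
from .trials import TrialEpoch

__all__ = [
    "MAIN_FIXED_FORMULA",
    "MAIN_RE_FORMULA",
    "code_design",
    "fit_main_model",
    "bin_epochs",
    "fit_timecourse",
    "bh_adjust",
    "classify_responders",
    "fit_meta_models",
    "estimate_marginal_means",
    "steiger_z",
]

MAIN_FIXED_TERMS = (
    "stimulation * amplitude_z + stimulation * block_code + "
    "stimulation * rating_diff + stimulation * order"
)
MAIN_FIXED_FORMULA = "{outcome} ~ " + MAIN_FIXED_TERMS
MAIN_RE_FORMULA = "1 + stimulation + block_code"


# ---------------------------------------------------------------------------
# Coding
# ---------------------------------------------------------------------------

def code_design(trial_table: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Build the coded model frame from retained trials and session metadata.

    Participants lacking either condition (in trials or metadata) are dropped
    with a warning. Re-coding an already coded frame is a no-op for the coded
    columns.
    """
    trials = trial_table[~trial_table.get("excluded", False)].copy()
    have_both = (
        trials.groupby("participant")["condition"].nunique().pipe(lambda s: s[s == 2])
    ).index
    meta_both = (
        meta.groupby("participant")["condition"].nunique().pipe(lambda s: s[s == 2])
    ).index
    keep = sorted(set(have_both) & set(meta_both))
    dropped = sorted(set(trials["participant"]) - set(keep))
    if dropped:
        warnings.warn(f"dropping participants missing a condition: {dropped}")
    trials = trials[trials["participant"].isin(keep)]
    meta = meta[meta["participant"].isin(keep)]

    ratings = meta.pivot_table(
        index="participant", columns="condition", values="mean_rating"
    )
    drating = ratings[TAVNS] - ratings[SHAM]
    drating_coded = (drating - drating.mean()) / 100.0

    frame = trials.merge(
        meta[["participant", "condition", "amplitude_ma", "order_code"]],
        on=["participant", "condition"],
        how="left",
    )
    frame["stimulation"] = np.where(frame["condition"] == TAVNS, 0.5, -0.5)
    frame["block_code"] = frame["block"].astype(float)
    amp = frame["amplitude_ma"].astype(float)
    frame["amplitude_z"] = (amp - amp.mean()) / amp.std(ddof=0)
    frame["rating_diff"] = frame["participant"].map(drating_coded)
    frame["order"] = frame["order_code"].astype(float)
    return frame.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Trial-level models
# ---------------------------------------------------------------------------

def fit_main_model(
    frame: pd.DataFrame,
    outcome: str = "max_dilation",
    df_method: str = "satterthwaite",
) -> FitResult:
    """REML fit of the trial-level model for ``outcome``.

    Fixed effects: stimulation, block, rating difference, amplitude, order,
    and all stimulation interactions; random intercept plus stimulation and
    block slopes per participant. The same contract serves the AUC and
    baseline outcome variants.
    """
    if frame["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    if frame["condition"].nunique() < 2:
        raise ValueError("both conditions must be present")
    return fit_mixed_model(
        frame.dropna(subset=[outcome]),
        MAIN_FIXED_FORMULA.format(outcome=outcome),
        groups="participant",
        re_formula=MAIN_RE_FORMULA,
        df_method=df_method,
    )


def bin_epochs(
    epochs_by_session: list[list[TrialEpoch]], bin_ms: float = 100.0
) -> pd.DataFrame:
    """Average the binocular percent-change trace into time bins per trial.

    Returns a long table (participant, condition, block, trial_index,
    bin_time, dilation) with one row per retained corrected trial and bin;
    ``bin_time`` is the bin's left edge in seconds on the epoch clock.
    """
    rows = []
    for epochs in epochs_by_session:
        for ep in epochs:
            if ep.excluded or not ep.corrected:
                continue
            dt = ep.rel_time[1] - ep.rel_time[0]
            per_bin = max(1, int(round(bin_ms / 1000.0 / dt)))
            n_bins = len(ep.rel_time) // per_bin
            trace = ep.mean_trace[: n_bins * per_bin].reshape(n_bins, per_bin)
            tstarts = ep.rel_time[: n_bins * per_bin : per_bin]
            means = trace.mean(axis=1)
            for tb, v in zip(tstarts, means):
                rows.append(
                    {
                        "participant": ep.participant,
                        "condition": ep.condition,
                        "block": ep.block,
                        "trial_index": ep.trial_index,
                        "bin_time": round(float(tb), 6),
                        "dilation": float(v),
                    }
                )
    return pd.DataFrame(rows)


def fit_timecourse(
    binned: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    df_method: str = "satterthwaite",
) -> pd.DataFrame:
    """Per-bin mixed models with joint Benjamini-Hochberg correction.

    ``binned`` is the output of :func:`bin_epochs`. Each bin is fitted with
    the main model's fixed and random structure on that bin's mean dilation;
    BH correction is applied jointly across all bins and non-intercept fixed
    effects, flagging bins significant at ``alpha``. Bins whose fit fails are
    retained with NaN entries.
    """
    rows = []
    for bin_time, sub in binned.groupby("bin_time"):
        tab = sub.rename(columns={"dilation": "max_dilation"})
        frame = code_design(tab.assign(excluded=False), meta)
        try:
            fit = fit_main_model(frame, df_method=df_method)
            for rec in fit.table.itertuples(index=False):
                rows.append(
                    {
                        "bin_time": bin_time,
                        "term": rec.term,
                        "estimate": rec.estimate,
                        "t": rec.t,
                        "p": rec.p,
                    }
                )
        except (RuntimeError, ValueError):
            rows.append(
                {
                    "bin_time": bin_time,
                    "term": "Intercept",
                    "estimate": np.nan,
                    "t": np.nan,
                    "p": np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    out["significant"] = False
    mask = (out["term"] != "Intercept") & np.isfinite(out["p"])
    if mask.any():
        out.loc[mask, "p_fdr"] = bh_adjust(out.loc[mask, "p"].to_numpy())
        out.loc[mask, "significant"] = out.loc[mask, "p_fdr"] < alpha
    return out


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone in rank)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-d array")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Responders and aggregate (meta) models
# ---------------------------------------------------------------------------

def classify_responders(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Label each participant by their condition-mean maximum dilation.

    A participant is a responder iff their mean max dilation over retained
    taVNS trials strictly exceeds the sham mean; ties count as non-responder.
    Participants missing a condition are left out.
    """
    trials = trial_table[~trial_table.get("excluded", False)]
    means = trials.pivot_table(
        index="participant", columns="condition", values="max_dilation", aggfunc="mean"
    )
    means = means.dropna(subset=[SHAM, TAVNS])
    out = pd.DataFrame(
        {
            "participant": means.index,
            "mean_sham": means[SHAM].to_numpy(),
            "mean_tavns": means[TAVNS].to_numpy(),
        }
    )
    out["responder"] = (out["mean_tavns"] > out["mean_sham"]).astype(int)
    return out.reset_index(drop=True)


def fit_meta_models(
    meta: pd.DataFrame, labels: pd.DataFrame, df_method: str = "satterthwaite"
) -> dict[str, FitResult]:
    """The four aggregate models for calibrated amplitude and mean rating.

    Each regresses a per participant x condition aggregate on stimulation
    (effect-centered) crossed with responder status (dummy, non-responder
    reference) or condition order (effect-centered), with a random intercept
    and stimulation slope per participant.
    """
    tab = meta.merge(labels[["participant", "responder"]], on="participant", how="inner")
    tab["stimulation"] = np.where(tab["condition"] == TAVNS, 0.5, -0.5)
    tab["order"] = tab["order_code"].astype(float)
    tab["amplitude"] = tab["amplitude_ma"].astype(float)
    tab["rating"] = tab["mean_rating"].astype(float)
    fits = {}
    for outcome in ("amplitude", "rating"):
        for moderator in ("responder", "order"):
            fits[f"{outcome}_by_{moderator}"] = fit_mixed_model(
                tab,
                f"{outcome} ~ stimulation * {moderator}",
                groups="participant",
                re_formula="1 + stimulation",
                df_method=df_method,
            )
    return fits


# ---------------------------------------------------------------------------
# Estimated marginal means
# ---------------------------------------------------------------------------

def _design_row(fit: FitResult, values: dict[str, float]) -> np.ndarray:
    """Model-matrix row at the requested covariate values.

    Unspecified covariates sit at their frame means; interaction columns are
    products of their factors.
    """
    x = np.empty(len(fit.terms))
    for i, term in enumerate(fit.terms):
        if term == "Intercept":
            x[i] = 1.0
            continue
        v = 1.0
        for factor in term.split(":"):
            if factor in values:
                v *= values[factor]
            elif factor in fit.frame_means:
                v *= fit.frame_means[factor]
            else:
                raise KeyError(f"no value or frame mean for term factor {factor!r}")
        x[i] = v
    return x


def estimate_marginal_means(
    fit: FitResult, rating_diff_values, alpha: float = 0.05
) -> pd.DataFrame:
    """Predicted dilation per condition and their contrast vs rating diff.

    Evaluates the fitted linear predictor at stimulation = -0.5 (sham) and
    +0.5 (taVNS) for each requested (coded) rating-difference value, other
    covariates held at their frame means. The taVNS - sham contrast and its
    delta-method standard error come from the fixed-effect covariance.
    Warns when a requested value lies outside the observed range.
    """
    lo, hi = fit.frame_ranges.get("rating_diff", (-np.inf, np.inf))
    rows = []
    for v in np.atleast_1d(rating_diff_values):
        if not lo <= v <= hi:
            warnings.warn(f"rating_diff={v} is outside the observed range")
        x_sham = _design_row(fit, {"stimulation": -0.5, "rating_diff": float(v)})
        x_tav = _design_row(fit, {"stimulation": 0.5, "rating_diff": float(v)})
        d = x_tav - x_sham
        pred_s = float(x_sham @ fit.fe_params)
        pred_t = float(x_tav @ fit.fe_params)
        contrast = float(d @ fit.fe_params)
        se = float(np.sqrt(d @ fit.fe_cov @ d))
        rows.append(
            {
                "rating_diff": float(v),
                "pred_sham": pred_s,
                "se_sham": float(np.sqrt(x_sham @ fit.fe_cov @ x_sham)),
                "pred_tavns": pred_t,
                "se_tavns": float(np.sqrt(x_tav @ fit.fe_cov @ x_tav)),
                "contrast": contrast,
                "contrast_se": se,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Steiger's Z for dependent correlations
# ---------------------------------------------------------------------------

def steiger_z(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Test the difference of two dependent correlations sharing a variable.

    ``r1`` and ``r2`` each correlate a common variable with two others whose
    inter-correlation is ``r12``; ``n`` is the shared sample size. Returns
    the Z statistic (positive when ``r1 > r2``) and the two-tailed p-value.
    """
    for r in (r1, r2, r12):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar = (r1 + r2) / 2.0
    psi = r12 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)
    sbar = psi / (1 - rbar**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - sbar)))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
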