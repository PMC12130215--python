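"""Behavioral performance, psychometrics, signal detection and group statistics.

Performance metric = (Hit# + CR#) / (Hit# + Miss# + CR# + FA#), over go and
no-go trials only.  Psychometric curves are binomial GLMs with a probit link
of lick on vibration frequency.  d' = Z(hit rate) - Z(false-alarm rate) per
50-trial block within (mouse, day), with a 0.5 correction for zero (or full)
counts, and its relation to block-mean decoder uncertainty is summarised by
Pearson's r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning, PerfectSeparationError

__all__ = [
    "BehaviorCounts",
    "PsychometricFit",
    "performance_metric",
    "dprime",
    "dprime_blocks",
    "fit_psychometric",
    "compare_groups",
    "corr_dprime_uncertainty",
]


@dataclass
class BehaviorCounts:
    hits: int
    misses: int
    correct_rejects: int
    false_alarms: int
    block_id: object = None

    def __post_init__(self):
        if min(self.hits, self.misses, self.correct_rejects, self.false_alarms) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n_go(self) -> int:
        return self.hits + self.misses

    @property
    def n_nogo(self) -> int:
        return self.correct_rejects + self.false_alarms

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, block_id=None) -> "BehaviorCounts":
        oc = trials["outcome"].value_counts()
        return cls(
            hits=int(oc.get("hit", 0)),
            misses=int(oc.get("miss", 0)),
            correct_rejects=int(oc.get("CR", 0)),
            false_alarms=int(oc.get("FA", 0)),
            block_id=block_id,
        )


def performance_metric(counts: BehaviorCounts) -> float:
    """(Hit# + CR#) / (Hit# + Miss# + CR# + FA#); probe/RO/UR never enter."""
    denom = counts.n_go + counts.n_nogo
    if denom == 0:
        raise ValueError("no go or no-go trials to score")
    return (counts.hits + counts.correct_rejects) / denom


def _corrected_rate(successes: int, n: int) -> float:
    """Rate with the 0.5 correction: zero counts -> 0.5, full counts -> n - 0.5."""
    s = float(successes)
    if s == 0:
        s = 0.5
    elif s == n:
        s = n - 0.5
    return s / n


def dprime(counts: BehaviorCounts) -> float:
    """Z(hit rate) - Z(false-alarm rate) with the zero-occurrence correction."""
    if counts.n_go == 0 or counts.n_nogo == 0:
        raise ValueError("d' needs both go and no-go trials")
    hr = _corrected_rate(counts.hits, counts.n_go)
    fr = _corrected_rate(counts.false_alarms, counts.n_nogo)
    return float(stats.norm.ppf(hr) - stats.norm.ppf(fr))


def dprime_blocks(
    trials: pd.DataFrame,
    block_size: int = 50,
    uncertainty: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-(mouse, day) 50-trial blocks with corrected d' and mean uncertainty.

    Trials are taken in session order; trailing partial blocks are dropped so
    block statistics stay identically distributed.  Blocks lacking either a go
    or a no-go trial are skipped with a warning.  ``uncertainty`` is an
    optional per-trial series aligned to ``trials`` (e.g. seed-averaged MCD
    variance) averaged within each block.
    """
    if uncertainty is not None:
        trials = trials.assign(_unc=np.asarray(uncertainty, dtype=float))
    rows = []
    for (mouse, day), g in trials.groupby(["mouse_id", "day"], sort=True):
        g = g.sort_values("trial_index")
        n_blocks = len(g) // block_size
        for b in range(n_blocks):
            blk = g.iloc[b * block_size : (b + 1) * block_size]
            counts = BehaviorCounts.from_trials(blk, block_id=(mouse, day, b))
            if counts.n_go == 0 or counts.n_nogo == 0:
                warnings.warn(
                    f"block {(mouse, day, b)} lacks go or no-go trials; skipped",
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "mouse_id": mouse,
                    "day": day,
                    "block": b,
                    "hits": counts.hits,
                    "false_alarms": counts.false_alarms,
                    "hit_rate": _corrected_rate(counts.hits, counts.n_go),
                    "fa_rate": _corrected_rate(counts.false_alarms, counts.n_nogo),
                    "dprime": dprime(counts),
                    "mean_uncertainty": float(blk["_unc"].mean()) if uncertainty is not None else np.nan,
                    "n_trials": len(blk),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PsychometricFit:
    """Probit GLM of lick on frequency: p(lick) = Phi(intercept + slope * f)."""

    intercept: float
    slope: float
    threshold_hz: float
    separation_flag: bool
    n_trials: int
    result: object = None

    def predict(self, freq) -> np.ndarray:
        return stats.norm.cdf(self.intercept + self.slope * np.asarray(freq, dtype=float))


def fit_psychometric(trials: pd.DataFrame) -> PsychometricFit:
    """Binomial probit regression of per-trial lick on vibration frequency.

    Uses go, no-go and probe trials (rows with a stimulus and a lick flag).
    The threshold is the frequency where the fitted curve crosses 0.5.
    Complete separation (or an all-one-class response) is flagged rather than
    raised; coefficients are then reported as fitted.
    """
    df = trials.dropna(subset=["frequency"])
    df = df[df["trial_type"].isin(["go", "no-go", "probe"])]
    y = df["lick"].astype(float).to_numpy()
    f = df["frequency"].to_numpy(dtype=float)
    if len(np.unique(f)) < 2:
        raise ValueError("need at least 2 distinct frequencies")
    separated = len(np.unique(y)) < 2
    # scale Hz to O(1) for optimizer conditioning; coefficients mapped back
    scale = 100.0
    x = sm.add_constant(f / scale)
    flagged = separated
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.GLM(y, x, family=sm.families.Binomial(sm.families.links.Probit())).fit()
        except (PerfectSeparationWarning, PerfectSeparationError):
            flagged = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(
                    y, x, family=sm.families.Binomial(sm.families.links.Probit())
                ).fit(maxiter=25)
    intercept = float(res.params[0])
    slope = float(res.params[1] / scale)
    threshold = -intercept / slope if slope != 0 else np.nan
    if not flagged and not np.all(np.isfinite(res.bse)):
        flagged = True
    return PsychometricFit(
        intercept=intercept,
        slope=slope,
        threshold_hz=float(threshold),
        separation_flag=bool(flagged),
        n_trials=len(df),
        result=res,
    )


def compare_groups(groups: dict, method: str = "anova_tukey", alpha: float = 0.05) -> dict:
    """One-way ANOVA gate with Tukey HSD pairs, or Bonferroni one-vs-rest t-tests.

    ``groups`` maps group name to a 1-d array of values.  With
    ``anova_tukey``, Tukey's HSD runs over all pairs only when the ANOVA p is
    below ``alpha``.  With ``bonferroni_ttests``, each group is compared with
    the pooled rest by an independent two-sample t-test and p-values are
    multiplied by the number of groups (clipped at 1).
    """
    names = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in names]
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in values):
        raise ValueError("each group needs at least 2 values")
    out = {}
    if method == "anova_tukey":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fstat, p = stats.f_oneway(*values)
        if not np.isfinite(p) or fstat <= 0:  # no between-group variance
            fstat, p = max(0.0, float(fstat)), 1.0
        out["anova"] = {"F": float(fstat), "p": float(p)}
        out["pairwise"] = None
        if p < alpha:
            flat = np.concatenate(values)
            labels = np.concatenate([[n] * len(v) for n, v in zip(names, values)])
            tk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
            out["pairwise"] = pd.DataFrame(
                tk.summary().data[1:], columns=tk.summary().data[0]
            )
    elif method == "bonferroni_ttests":
        rows = []
        m = len(names)
        for i, name in enumerate(names):
            rest = np.concatenate([v for j, v in enumerate(values) if j != i])
            t, p = stats.ttest_ind(values[i], rest)
            rows.append(
                {
                    "group": name,
                    "t": float(t),
                    "p_raw": float(p),
                    "p_bonferroni": float(min(1.0, p * m)),
                    "significant": bool(p * m < alpha),
                }
            )
        out["table"] = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def corr_dprime_uncertainty(blocks: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (with two-sided p) between block d' and block mean uncertainty."""
    d = blocks["dprime"].to_numpy(dtype=float)
    u = blocks["mean_uncertainty"].to_numpy(dtype=float)
    ok = np.isfinite(d) & np.isfinite(u)
    d, u = d[ok], u[ok]
    if len(d) < 3:
        raise ValueError("need at least 3 blocks")
    if np.ptp(d) == 0 or np.ptp(u) == 0:
        raise ValueError("a constant variable has no correlation")
    r, p = stats.pearsonr(d, u)
    return float(r), float(p)
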