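"""Rank-transformed repeated-measures group comparison across four conditions.

Each autonomic variable is observed once per subject per experimental
condition (ambulatory/bedrest x normoxia/hypoxia).  To blunt non-normality
the values are first replaced by their ranks over all (subject, condition)
cells of that variable (the rank-transform procedure, average ranks on
ties); a mixed model with condition as fixed factor and subject as random
intercept then yields the omnibus condition test, and six labeled paired
contrasts (letters a-f, one per condition pair) are evaluated on the ranks.

For a complete balanced design the random-intercept (compound-symmetry)
F test coincides with the classic two-way repeated-measures ANOVA F, which
is computed in closed form; incomplete designs fall back to a restricted
maximum likelihood fit (statsmodels MixedLM) with a Wald F approximation.
Contrasts are unadjusted by default; Holm adjustment is optional.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .datatypes import CONDITIONS, CONTRAST_PAIRS, DesignError

__all__ = [
    "conover_rank_transform",
    "RankConditionANOVA",
    "mixed_model_ranks",
    "paired_contrasts",
    "descriptive_table",
    "null_calibration",
]

log = logging.getLogger(__name__)


def conover_rank_transform(values) -> np.ndarray:
    """Average ranks over all non-missing cells; missing stays missing."""
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    mask = ~np.isnan(v)
    if mask.sum() < 2:
        warnings.warn("fewer than 2 non-missing values; variable skipped")
        return out
    out[mask] = sps.rankdata(v[mask], method="average")
    return out


def _pivot(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    wide = df.pivot_table(index="subject", columns="condition",
                          values=value_col, aggfunc="mean")
    cols = [c for c in CONDITIONS if c in wide.columns]
    return wide[cols]


class RankConditionANOVA(BaseEstimator):
    """Omnibus condition test and paired contrasts on rank-transformed data.

    Fit on a long-format frame with columns ``subject``, ``condition``,
    ``value`` (one variable at a time; missing cells allowed).

    Parameters
    ----------
    alpha : float
        Significance level for attaching contrast letters.
    holm : bool
        Apply Holm step-down adjustment to the six contrast p-values.
    method : {"auto", "closed_form", "mixedlm"}
        "auto" uses the closed-form repeated-measures F for complete
        balanced designs and MixedLM otherwise.

    Attributes
    ----------
    omnibus_p_ : float
    omnibus_f_ : float
    contrasts_ : pandas.DataFrame
        One row per letter: pair, estimate (rank scale), t, p.
    significant_letters_ : str
        Concatenated letters with p < alpha, e.g. ``"c f"``.
    method_ : str
        The computation path actually used.
    """

    def __init__(self, alpha: float = 0.05, holm: bool = False,
                 method: str = "auto"):
        self.alpha = alpha
        self.holm = holm
        self.method = method

    def fit(self, X: pd.DataFrame, y=None) -> "RankConditionANOVA":
        df = X.copy()
        need = {"subject", "condition", "value"}
        if not need.issubset(df.columns):
            raise DesignError(f"long-format frame must have columns {sorted(need)}")
        df = df.dropna(subset=["value"])
        # subjects must appear in >= 2 conditions to inform a within-subject test
        keep = df.groupby("subject")["condition"].nunique()
        df = df[df["subject"].isin(keep[keep >= 2].index)]
        if df["subject"].nunique() < 3:
            raise DesignError("need at least 3 subjects observed in >= 2 conditions")

        df["rank"] = conover_rank_transform(df["value"].to_numpy())
        if np.nanstd(df["rank"].to_numpy()) == 0:
            warnings.warn("zero variance after ranking; omnibus test skipped")
            self.omnibus_p_ = math.nan
            self.omnibus_f_ = math.nan
            self.contrasts_ = self._empty_contrasts()
            self.significant_letters_ = ""
            self.method_ = "degenerate"
            return self

        wide = _pivot(df, "rank")
        balanced = wide.notna().all(axis=None) and wide.shape[1] == len(CONDITIONS)
        if self.method == "closed_form" or (self.method == "auto" and balanced):
            self._fit_closed_form(wide)
        else:
            self._fit_mixedlm(df)

        sig = self.contrasts_[self.contrasts_["p"] < self.alpha]
        self.significant_letters_ = " ".join(sig.index)
        return self

    # -- complete balanced design: two-way repeated-measures ANOVA on ranks --
    def _fit_closed_form(self, wide: pd.DataFrame) -> None:
        y = wide.to_numpy(dtype=float)
        n, k = y.shape
        grand = y.mean()
        cond_means = y.mean(axis=0)
        subj_means = y.mean(axis=1)
        ss_cond = n * ((cond_means - grand) ** 2).sum()
        ss_subj = k * ((subj_means - grand) ** 2).sum()
        ss_tot = ((y - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        df_cond, df_err = k - 1, (n - 1) * (k - 1)
        ms_err = ss_err / df_err
        if ms_err <= 0:
            warnings.warn("zero residual variance; omnibus test degenerate")
            self.omnibus_f_ = math.nan
            self.omnibus_p_ = math.nan
            self.contrasts_ = self._empty_contrasts()
            self.method_ = "degenerate"
            return
        self.omnibus_f_ = float((ss_cond / df_cond) / ms_err)
        self.omnibus_p_ = float(sps.f.sf(self.omnibus_f_, df_cond, df_err))
        self.method_ = "closed_form"

        se = math.sqrt(2.0 * ms_err / n)
        rows = {}
        means = dict(zip(wide.columns, cond_means))
        for letter, (a, b) in CONTRAST_PAIRS.items():
            est = means[a] - means[b]
            t = est / se
            p = 2.0 * sps.t.sf(abs(t), df_err)
            rows[letter] = dict(pair=f"{a} vs {b}", estimate=est, t=t, p=p)
        self.contrasts_ = self._finish_contrasts(rows)

    # -- incomplete designs: REML mixed model with Wald F approximation --
    def _fit_mixedlm(self, df: pd.DataFrame) -> None:
        import statsmodels.formula.api as smf

        df = df.copy()
        df["condition"] = pd.Categorical(df["condition"], categories=CONDITIONS)
        k = df["condition"].nunique()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.mixedlm("rank ~ C(condition)", df,
                                  groups=df["subject"]).fit(reml=True)
            if not res.converged:
                raise RuntimeError("MixedLM did not converge")
            self.method_ = "mixedlm"
        except Exception as exc:       # fall back per the error contract
            log.warning("mixed model failed (%s); falling back to "
                        "repeated-measures ANOVA on available complete cases", exc)
            wide = _pivot(df, "rank").dropna()
            if len(wide) < 3 or wide.shape[1] < 2:
                raise DesignError("too few complete cases for fallback ANOVA")
            self._fit_closed_form(wide)
            self.method_ = "rm_anova_fallback"
            return

        names = list(res.model.exog_names)
        cond_terms = [i for i, nm in enumerate(names) if "condition" in nm]
        q = len(cond_terms)
        contrast = np.zeros((q, len(res.params)))
        for r, i in enumerate(cond_terms):
            contrast[r, i] = 1.0
        wald = res.wald_test(contrast, scalar=True)
        n_obs = len(df)
        n_subj = df["subject"].nunique()
        ddf = max(n_obs - n_subj - q, 1)
        f_stat = float(np.squeeze(wald.statistic)) / q
        self.omnibus_f_ = f_stat
        self.omnibus_p_ = float(sps.f.sf(f_stat, q, ddf))

        beta = res.fe_params
        cov = res.cov_params().iloc[:len(names), :len(names)].to_numpy()
        level_vec = {}
        for cond in CONDITIONS:
            v = np.zeros(len(names))
            v[0] = 1.0
            for i, nm in enumerate(names):
                if f"[T.{cond}]" in nm:
                    v[i] = 1.0
            level_vec[cond] = v
        rows = {}
        for letter, (a, b) in CONTRAST_PAIRS.items():
            v = level_vec[a] - level_vec[b]
            est = float(v @ beta.to_numpy()[:len(names)])
            se = math.sqrt(float(v @ cov @ v))
            if se == 0:
                rows[letter] = dict(pair=f"{a} vs {b}", estimate=est,
                                    t=math.nan, p=math.nan)
                continue
            t = est / se
            p = 2.0 * sps.t.sf(abs(t), ddf)
            rows[letter] = dict(pair=f"{a} vs {b}", estimate=est, t=t, p=p)
        self.contrasts_ = self._finish_contrasts(rows)

    def _finish_contrasts(self, rows: dict) -> pd.DataFrame:
        out = pd.DataFrame.from_dict(rows, orient="index")
        if self.holm and out["p"].notna().any():
            order = out["p"].sort_values().index
            m = out["p"].notna().sum()
            adj_prev = 0.0
            adj = {}
            for i, idx in enumerate(order):
                a = min(1.0, (m - i) * out.loc[idx, "p"])
                adj_prev = max(adj_prev, a)
                adj[idx] = adj_prev
            out["p"] = pd.Series(adj)
        return out

    @staticmethod
    def _empty_contrasts() -> pd.DataFrame:
        return pd.DataFrame(
            {letter: dict(pair=f"{a} vs {b}", estimate=math.nan,
                          t=math.nan, p=math.nan)
             for letter, (a, b) in CONTRAST_PAIRS.items()}).T


def mixed_model_ranks(df: pd.DataFrame, **kwargs) -> float:
    """Omnibus p-value of the rank mixed model (thin wrapper)."""
    return RankConditionANOVA(**kwargs).fit(df).omnibus_p_


def paired_contrasts(df: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """The six labeled paired contrasts on ranks (thin wrapper)."""
    return RankConditionANOVA(**kwargs).fit(df).contrasts_


def descriptive_table(df: pd.DataFrame, alpha: float = 0.05,
                      holm: bool = False) -> pd.DataFrame:
    """Mean +- SD per condition, omnibus p and significant letters per variable.

    ``df`` is long format with columns ``subject, condition, variable,
    value``.  Cells missing for some subjects are averaged over the
    available subjects, with the per-cell n recorded.
    """
    need = {"subject", "condition", "variable", "value"}
    if not need.issubset(df.columns):
        raise DesignError(f"expected long-format columns {sorted(need)}")
    rows = []
    for var, sub in df.groupby("variable", sort=False):
        row: dict = {"variable": var}
        for cond in CONDITIONS:
            vals = sub.loc[sub["condition"] == cond, "value"].dropna()
            row[f"{cond}_mean"] = vals.mean() if len(vals) else math.nan
            row[f"{cond}_sd"] = vals.std(ddof=1) if len(vals) > 1 else (
                0.0 if len(vals) == 1 else math.nan)
            row[f"{cond}_n"] = int(len(vals))
        try:
            model = RankConditionANOVA(alpha=alpha, holm=holm).fit(
                sub[["subject", "condition", "value"]])
            row["omnibus_p"] = model.omnibus_p_
            row["contrasts"] = model.significant_letters_
        except DesignError:
            row["omnibus_p"] = math.nan
            row["contrasts"] = ""
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def null_calibration(n_subjects: int = 11, n_reps: int = 2000, seed: int = 0,
                     alpha: float = 0.05, subject_sd: float = 1.0,
                     noise_sd: float = 1.0) -> dict:
    """Type-I error of the rank pipeline under the null, vectorized.

    Simulates ``n_reps`` complete 4-condition studies with a random subject
    intercept and iid noise, no condition effect; ranks each replicate over
    all cells and applies the closed-form repeated-measures F plus the six
    paired contrasts.  Returns the omnibus rejection rate and the per-letter
    rates at ``alpha``.
    """
    k = len(CONDITIONS)
    rng = np.random.default_rng(seed)
    y = (subject_sd * rng.standard_normal((n_reps, n_subjects, 1))
         + noise_sd * rng.standard_normal((n_reps, n_subjects, k)))
    flat = y.reshape(n_reps, -1)
    ranks = sps.rankdata(flat, axis=1).reshape(n_reps, n_subjects, k)

    grand = ranks.mean(axis=(1, 2), keepdims=True)
    cond_means = ranks.mean(axis=1, keepdims=True)
    subj_means = ranks.mean(axis=2, keepdims=True)
    ss_cond = (n_subjects * (cond_means - grand) ** 2).sum(axis=(1, 2))
    ss_subj = (k * (subj_means - grand) ** 2).sum(axis=(1, 2))
    ss_tot = ((ranks - grand) ** 2).sum(axis=(1, 2))
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond, df_err = k - 1, (n_subjects - 1) * (k - 1)
    ms_err = ss_err / df_err
    f = (ss_cond / df_cond) / ms_err
    p_omni = sps.f.sf(f, df_cond, df_err)

    cm = cond_means[:, 0, :]                      # (reps, k)
    se = np.sqrt(2.0 * ms_err / n_subjects)
    letter_rates = {}
    idx = {c: i for i, c in enumerate(CONDITIONS)}
    for letter, (a, b) in CONTRAST_PAIRS.items():
        t = (cm[:, idx[a]] - cm[:, idx[b]]) / se
        p = 2.0 * sps.t.sf(np.abs(t), df_err)
        letter_rates[letter] = float((p < alpha).mean())
    return {"omnibus_rate": float((p_omni < alpha).mean()),
            "letter_rates": letter_rates}
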