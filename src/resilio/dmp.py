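"""Per-CpG differential methylation with percentile-subset stratification.

The discovery cohort is dichotomized into high- and low-resilience groups;
percentile subsets progressively discard samples near the middle of the
score scale (100%, 90%, ..., 5% retained per tail). Each subset gets a
covariate-adjusted per-CpG linear model on M values with empirical-Bayes
variance moderation; probes passing p < .05 and |log2FC| > 0.5 are called
DMPs. Cross-subset consistency counting and a Spearman dose-response
statistic separate reproducible signal from the subset-specific noise that
raw-p calling inevitably admits.

Sign convention: the group coefficient (log2FC) is low-minus-high on the M
scale, so log2FC > 0 means hypermethylated in the LOW-resilience group.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .dataset import MethylationDataset
from .preprocessing import beta_to_m

log = logging.getLogger(__name__)

DEFAULT_STEPS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05)
DEFAULT_COVARIATES = ("age", "menstrual", "detection_mode", "er")
P_MAX = 0.05
LFC_MIN = 0.5


# ---------------------------------------------------------------------------
# percentile subsets
# ---------------------------------------------------------------------------

@dataclass
class SubsetSpec:
    """One percentile subset: the retained tails of both score groups."""

    label: str
    q: float
    low_ids: List[str]
    high_ids: List[str]
    summaries: Dict[str, float] = field(default_factory=dict)

    @property
    def score_diff(self) -> float:
        """High-group minus low-group mean score (grows toward distal subsets)."""
        return self.summaries["high_mean"] - self.summaries["low_mean"]

    @property
    def sample_ids(self) -> List[str]:
        return self.low_ids + self.high_ids


def subset_label(q: float) -> str:
    return f"{q * 100:g}%"


def make_subsets(samples: pd.DataFrame,
                 steps: Sequence[float] = DEFAULT_STEPS,
                 min_group_size: int = 3) -> List[SubsetSpec]:
    """Build percentile subsets by trimming each group toward its tail.

    For retention fraction ``q``, the low group keeps its ceil(q*n) lowest
    scorers and the high group its ceil(q*n) highest; ties broken by sample
    id (stable), which makes members(q') a subset of members(q) for q' < q.
    """
    low = samples[samples["resilience_group"] == "low"]
    high = samples[samples["resilience_group"] == "high"]
    low_sorted = low.sort_values(["cdrisc_score", "sample_id"],
                                 ascending=[True, True])
    high_sorted = high.sort_values(["cdrisc_score", "sample_id"],
                                   ascending=[False, True])
    out: List[SubsetSpec] = []
    for q in steps:
        n_low = math.ceil(q * len(low_sorted))
        n_high = math.ceil(q * len(high_sorted))
        if n_low < min_group_size or n_high < min_group_size:
            warnings.warn(f"subset {subset_label(q)} has <{min_group_size} "
                          "samples in a group; excluded")
            continue
        lo = low_sorted.head(n_low)
        hi = high_sorted.head(n_high)
        out.append(SubsetSpec(
            label=subset_label(q), q=q,
            low_ids=lo["sample_id"].tolist(),
            high_ids=hi["sample_id"].tolist(),
            summaries={
                "low_mean": float(lo["cdrisc_score"].mean()),
                "low_sd": float(lo["cdrisc_score"].std()),
                "low_min": float(lo["cdrisc_score"].min()),
                "low_max": float(lo["cdrisc_score"].max()),
                "high_mean": float(hi["cdrisc_score"].mean()),
                "high_sd": float(hi["cdrisc_score"].std()),
                "high_min": float(hi["cdrisc_score"].min()),
                "high_max": float(hi["cdrisc_score"].max()),
            },
        ))
    return out


# ---------------------------------------------------------------------------
# design matrix + moderated linear model
# ---------------------------------------------------------------------------

def _build_design(samples: pd.DataFrame, low_ids: Sequence[str],
                  high_ids: Sequence[str],
                  covariates: Sequence[str]) -> Tuple[pd.DataFrame, List[str]]:
    ids = list(low_ids) + list(high_ids)
    sub = samples.loc[ids]
    cols = {"intercept": np.ones(len(ids)),
            "group_low": np.array([1.0] * len(low_ids) + [0.0] * len(high_ids))}
    dropped: List[str] = []
    for cov in covariates:
        col = sub[cov]
        if pd.api.types.is_numeric_dtype(col):
            if col.nunique() < 2:
                dropped.append(cov)
                continue
            cols[cov] = col.to_numpy(float)
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                dropped.append(cov)
                continue
            for lv in levels[1:]:
                cols[f"{cov}[{lv}]"] = (col.astype(str) == lv).to_numpy(float)
    X = pd.DataFrame(cols, index=ids)
    # drop trailing columns until full rank (never the group term)
    while np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        drop_candidates = [c for c in X.columns[::-1]
                           if c not in ("intercept", "group_low")]
        if not drop_candidates:
            raise ValueError("design rank-deficient even without covariates")
        c = drop_candidates[0]
        dropped.append(c)
        X = X.drop(columns=[c])
    if dropped:
        log.warning("dropped rank-deficient/constant covariates: %s", dropped)
    return X, dropped


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is monotone decreasing)."""
    if y <= 1e-12:
        return np.inf
    from scipy.optimize import brentq

    f = lambda x: float(special.polygamma(1, x)) - y
    return float(brentq(f, 1e-8, 1e8, maxiter=200))


def fit_prior(s2: np.ndarray, df_residual: float,
              prior_df: Optional[float] = None) -> Tuple[float, float]:
    """Method-of-moments empirical Bayes on log variances.

    Returns ``(d0, s0_sq)``: the prior degrees of freedom and prior variance
    of the scaled inverse-chi-square prior on the true residual variances.
    With ``prior_df`` supplied (possibly ``inf``) only ``s0_sq`` is estimated.
    """
    s2 = np.maximum(np.asarray(s2, float), 1e-300)
    df = float(df_residual)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if prior_df is not None:
        d0 = float(prior_df)
    else:
        evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
        d0 = 2.0 * _trigamma_inverse(evar) if evar > 0 else np.inf
    if np.isinf(d0):
        s0_sq = float(np.exp(emean))
    else:
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0)
                             - np.log(d0 / 2.0)))
    return d0, s0_sq


def fit_dmp_model(ds: MethylationDataset,
                  low_ids: Sequence[str], high_ids: Sequence[str],
                  covariates: Sequence[str] = DEFAULT_COVARIATES,
                  prior_df: Optional[float] = None) -> pd.DataFrame:
    """Covariate-adjusted per-CpG OLS on M values with variance moderation.

    Returns a per-probe DataFrame (index = probe id) with the group
    coefficient (= log2FC, low minus high), moderated t, raw p, BH q,
    raw and posterior variances. Prior d0 and s0^2 live in ``.attrs``.
    """
    X, dropped = _build_design(ds.samples, low_ids, high_ids, covariates)
    # tiny subsets: shed covariates (last first) until residuals have >=1 df
    while X.shape[0] - X.shape[1] < 1 and X.shape[1] > 2:
        c = [c for c in X.columns if c not in ("intercept", "group_low")][-1]
        log.warning("dropping covariate %r to preserve residual df", c)
        dropped.append(c)
        X = X.drop(columns=[c])
    ids = X.index
    M = beta_to_m(ds.beta[ids]).to_numpy()  # probes x n
    Xa = X.to_numpy()
    n, k = Xa.shape
    df_res = n - k
    if df_res < 1:
        raise ValueError(f"no residual degrees of freedom (n={n}, k={k})")
    xtx_inv = np.linalg.inv(Xa.T @ Xa)
    pinv = xtx_inv @ Xa.T  # k x n
    coefs = M @ pinv.T  # probes x k
    resid = M - coefs @ Xa.T
    s2 = (resid ** 2).sum(axis=1) / df_res
    g = list(X.columns).index("group_low")
    se_unscaled = math.sqrt(xtx_inv[g, g])
    d0, s0_sq = fit_prior(s2, df_res, prior_df=prior_df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_res * s2) / (d0 + df_res)
        df_total = df_res + d0
    coef = coefs[:, g]
    t = coef / (np.sqrt(s2_post) * se_unscaled)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    fits = pd.DataFrame(
        {
            "coef": coef,
            "t": t,
            "p_value": p,
            "q_value": q,
            "s2": s2,
            "s2_post": s2_post,
        },
        index=ds.beta.index,
    )
    fits.attrs.update({
        "d0": d0, "s0_sq": s0_sq, "df_residual": df_res,
        "df_total": df_total, "se_unscaled": se_unscaled,
        "dropped_covariates": dropped, "n_low": len(low_ids),
        "n_high": len(high_ids),
        "sign_convention": "coef>0 = hypermethylated in low-resilience group",
    })
    return fits


def call_dmps(fits: pd.DataFrame, p_max: float = P_MAX,
              lfc_min: float = LFC_MIN) -> pd.DataFrame:
    """Flag DMPs: raw p < p_max AND |log2FC| > lfc_min; record direction."""
    out = fits.copy()
    out["dmp"] = (out["p_value"] < p_max) & (out["coef"].abs() > lfc_min)
    out["direction"] = np.where(out["coef"] > 0, "hyper", "hypo")
    out.attrs.update(fits.attrs)
    out.attrs.update({"p_max": p_max, "lfc_min": lfc_min})
    return out


# ---------------------------------------------------------------------------
# cross-subset consistency
# ---------------------------------------------------------------------------

def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=1)


def _max_consecutive_run(hits: np.ndarray) -> np.ndarray:
    """Row-wise longest run of True over ordered columns."""
    best = np.zeros(hits.shape[0], dtype=int)
    cur = np.zeros(hits.shape[0], dtype=int)
    for j in range(hits.shape[1]):
        cur = np.where(hits[:, j], cur + 1, 0)
        best = np.maximum(best, cur)
    return best


def consistency_scan(results: Mapping[str, pd.DataFrame],
                     subsets: Sequence[SubsetSpec]) -> pd.DataFrame:
    """Per-probe cross-subset DMP consistency and dose-response statistic.

    ``results`` maps subset label -> called fits (from :func:`call_dmps`);
    ``subsets`` supplies the 100% -> 5% ordering and per-subset group score
    differences. The dose-response statistic is the Spearman correlation of
    per-subset log2FC with the per-subset high-low mean score difference.
    """
    if len(subsets) < 2:
        raise ValueError("need >= 2 subset analyses")
    labels = [s.label for s in subsets]
    probes = results[labels[0]].index
    hits = np.column_stack([
        results[lb]["dmp"].reindex(probes).fillna(False).to_numpy(bool)
        for lb in labels
    ])
    coefs = np.column_stack([
        results[lb]["coef"].reindex(probes).to_numpy() for lb in labels
    ])
    score_diffs = np.array([s.score_diff for s in subsets])

    coef_ranks = _rank_rows(coefs)
    diff_ranks = stats.rankdata(score_diffs)
    cr = coef_ranks - coef_ranks.mean(axis=1, keepdims=True)
    dr = diff_ranks - diff_ranks.mean()
    denom = np.sqrt((cr ** 2).sum(axis=1) * (dr ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (cr @ dr) / denom

    out = pd.DataFrame(
        {
            "n_hits": hits.sum(axis=1),
            "max_consecutive_run": _max_consecutive_run(hits),
            "dose_response_stat": rho,
        },
        index=probes,
    )
    for j, lb in enumerate(labels):
        out[f"hit_{lb}"] = hits[:, j]
    out.attrs["subset_order"] = labels
    out.attrs["score_diffs"] = dict(zip(labels, score_diffs.tolist()))
    return out


# ---------------------------------------------------------------------------
# genomic-feature enrichment
# ---------------------------------------------------------------------------

def feature_enrichment(dmp_probe_ids: Sequence[str], manifest: pd.DataFrame,
                       background_ids: Optional[Sequence[str]] = None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Two-proportion test of DMP feature-class composition vs background.

    Background defaults to every probe in the manifest (i.e. all
    QC-passing probes when called on a filtered dataset).
    """
    dmp_ids = pd.Index(dmp_probe_ids)
    if len(dmp_ids) == 0:
        raise ValueError("empty DMP set")
    bg_ids = manifest.index if background_ids is None else pd.Index(background_ids)
    dmp_cls = manifest.loc[dmp_ids, "feature_class"]
    bg_cls = manifest.loc[bg_ids, "feature_class"]
    rows = []
    for cls in sorted(bg_cls.unique()):
        k_dmp = int((dmp_cls == cls).sum())
        k_bg = int((bg_cls == cls).sum())
        p_dmp = k_dmp / len(dmp_ids)
        p_bg = k_bg / len(bg_ids)
        if 0 < k_bg < len(bg_ids):
            stat, pval = proportions_ztest(
                [k_dmp, k_bg], [len(dmp_ids), len(bg_ids)]
            )
        else:
            stat, pval = np.nan, np.nan
        rows.append({
            "feature_class": cls,
            "n_dmp": k_dmp,
            "n_background": k_bg,
            "prop_dmp": p_dmp,
            "prop_background": p_bg,
            "z": stat,
            "p_value": pval,
            "direction": "over" if p_dmp > p_bg else "under",
            "significant": bool(pval < alpha) if np.isfinite(pval) else False,
        })
    return pd.DataFrame(rows).set_index("feature_class")
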