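"""Probe/sample QC, beta<->M transforms, batch adjustment, cell-type
deconvolution, and PCA-covariate association diagnostics.

The filter cascade mirrors standard EPIC pre-processing: (1) detection
p-value, (2) bead counts, (3) non-CpG probes, (4) SNP-related probes,
(5) multi-hit probes, (6) sex-chromosome probes. Each rule is an independent
predicate, so the surviving probe set does not depend on application order;
the report counts removals in the order applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.decomposition import PCA

from .dataset import BETA_EPS, MethylationDataset

log = logging.getLogger(__name__)

# "5% of samples" in the bead rule is applied per probe across samples
# (a probe is dropped when <3 beads in >=5% of its samples).
FILTER_RULES = [
    "detection_p", "bead_count", "non_cpg", "snp", "multihit", "sex_chrom",
]


@dataclass
class FilterReport:
    """Per-rule removal counts, in application order."""

    counts: pd.DataFrame  # columns: rule, probes_removed
    n_input: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return self.counts.copy()


def beta_to_m(beta, eps: float = BETA_EPS):
    """M = log2(beta / (1 - beta)), with beta clipped into [eps, 1-eps]."""
    arr = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    m = np.log2(arr / (1.0 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m


def m_to_beta(m):
    """Inverse logit2: beta = 2**M / (1 + 2**M)."""
    arr = np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(beta, index=m.index)
    return beta


def filter_probes(ds: MethylationDataset,
                  detection_p_max: float = 0.01,
                  min_beads: int = 3,
                  max_fail_fraction: float = 0.05):
    """Apply the six-rule probe filter cascade.

    Returns the filtered dataset and a :class:`FilterReport`. Rules relying
    on absent matrices (detection p, bead counts) are skipped with a warning.
    """
    keep = pd.Series(True, index=ds.beta.index)
    counts = []

    def apply(rule: str, fail_mask: pd.Series):
        removed = int((keep & fail_mask).sum())
        keep.loc[fail_mask] = False
        counts.append({"rule": rule, "probes_removed": removed})

    if ds.detection_p is not None:
        frac = (ds.detection_p > detection_p_max).mean(axis=1)
        apply("detection_p", frac > max_fail_fraction)
    else:
        warnings.warn("detection p matrix absent; detection filter skipped")
        counts.append({"rule": "detection_p", "probes_removed": 0})
    if ds.bead_counts is not None:
        frac = (ds.bead_counts < min_beads).mean(axis=1)
        apply("bead_count", frac >= max_fail_fraction)
    else:
        warnings.warn("bead count matrix absent; bead filter skipped")
        counts.append({"rule": "bead_count", "probes_removed": 0})
    apply("non_cpg", ~ds.manifest["probe_id"].str.startswith("cg"))
    apply("snp", ds.manifest["snp_flag"].astype(bool))
    apply("multihit", ds.manifest["multihit_flag"].astype(bool))
    apply("sex_chrom", ds.manifest["sex_chrom_flag"].astype(bool))

    retained = keep[keep].index
    if len(retained) == 0:
        raise ValueError("no probes survive the filter cascade")
    report = FilterReport(
        counts=pd.DataFrame(counts, columns=["rule", "probes_removed"]),
        n_input=ds.n_probes,
        n_retained=len(retained),
    )
    return ds.subset_probes(retained), report


def adjust_batch(ds: MethylationDataset,
                 batch: Optional[pd.Series] = None) -> MethylationDataset:
    """Per-probe, per-batch location/scale standardisation on the M scale.

    Each batch's M values are z-scored per probe (ddof=0) and mapped back to
    the probe's grand mean/SD, which removes batch location and scale shifts
    while preserving the per-probe grand mean and SD exactly.
    """
    if batch is None:
        batch = ds.samples["batch"]
    batch = batch.loc[ds.beta.columns]
    sizes = batch.value_counts()
    if (sizes < 2).any():
        singles = sizes[sizes < 2].index.tolist()
        raise ValueError(f"singleton batch(es) {singles}: cannot standardise")
    M = beta_to_m(ds.beta).to_numpy()
    grand_mean = M.mean(axis=1, keepdims=True)
    grand_sd = M.std(axis=1, ddof=0, keepdims=True)
    out = np.empty_like(M)
    for b in sizes.index:
        cols = (batch == b).to_numpy()
        sub = M[:, cols]
        bm = sub.mean(axis=1, keepdims=True)
        bs = sub.std(axis=1, ddof=0, keepdims=True)
        bs = np.where(bs < 1e-12, 1.0, bs)
        out[:, cols] = grand_mean + grand_sd * (sub - bm) / bs
    beta = m_to_beta(pd.DataFrame(out, index=ds.beta.index, columns=ds.beta.columns))
    return MethylationDataset(
        beta=beta, manifest=ds.manifest, samples=ds.samples,
        detection_p=ds.detection_p, bead_counts=ds.bead_counts,
        meta={**ds.meta, "batch_adjusted": True},
    )


@dataclass
class CellDeconvolution:
    """Estimated leukocyte fractions (samples x cell types) on the simplex."""

    fractions: pd.DataFrame
    residual_norm: pd.Series
    reference: str = "synthetic"


def deconvolve_cells(ds: MethylationDataset, reference: pd.DataFrame,
                     sum_weight: float = 1e3) -> CellDeconvolution:
    """Constrained projection of reference-probe beta onto cell profiles.

    Per sample, solves non-negative least squares of the observed beta at
    reference probes against the reference profiles, with a heavily weighted
    sum-to-one row enforcing the simplex constraint; the solution is then
    renormalised. Exact (residual ~0) for representable mixtures.
    """
    missing = reference.index.difference(ds.beta.index)
    if len(missing):
        raise ValueError(f"reference probes absent from dataset: {list(missing[:5])}")
    R = reference.to_numpy()
    A = np.vstack([R, sum_weight * np.ones((1, R.shape[1]))])
    obs = ds.beta.loc[reference.index].to_numpy()
    n_samples = obs.shape[1]
    fracs = np.empty((n_samples, R.shape[1]))
    resid = np.empty(n_samples)
    for j in range(n_samples):
        b = np.concatenate([obs[:, j], [sum_weight]])
        x, _ = optimize.nnls(A, b)
        s = x.sum()
        x = x / s if s > 0 else np.full_like(x, 1.0 / len(x))
        fracs[j] = x
        resid[j] = float(np.linalg.norm(R @ x - obs[:, j]))
    return CellDeconvolution(
        fractions=pd.DataFrame(fracs, index=ds.beta.columns,
                               columns=reference.columns),
        residual_norm=pd.Series(resid, index=ds.beta.columns),
    )


def pca_covariate_scan(ds: MethylationDataset,
                       covariates: Sequence[str],
                       n_components: int = 10,
                       random_state: int = 0):
    """PCA on centred M values + per-PC covariate association tests.

    Continuous covariates are tested with a Pearson correlation test,
    categorical ones with one-way ANOVA on the PC scores. Constant
    covariates are flagged and skipped (p = NaN).

    Returns ``(assoc, variance_explained)`` where ``assoc`` is a PCs x
    covariates DataFrame of p-values.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples for PCA")
    M = beta_to_m(ds.beta).to_numpy().T  # samples x probes
    M = M - M.mean(axis=0, keepdims=True)
    k = min(n_components, ds.n_samples - 1, M.shape[1])
    pca = PCA(n_components=k, svd_solver="randomized", random_state=random_state)
    scores = pca.fit_transform(M)
    varexp = pd.Series(pca.explained_variance_ratio_,
                       index=[f"PC{i+1}" for i in range(k)], name="variance_explained")

    pvals = {}
    for cov in covariates:
        col = ds.samples[cov]
        ps = []
        if col.nunique(dropna=True) < 2:
            log.warning("covariate %r constant; skipped in PCA scan", cov)
            pvals[cov] = [np.nan] * k
            continue
        numeric = pd.api.types.is_numeric_dtype(col)
        for i in range(k):
            if numeric:
                mask = col.notna().to_numpy()
                r = stats.pearsonr(scores[mask, i], col.to_numpy(float)[mask])
                ps.append(r.pvalue)
            else:
                groups = [scores[(col == lv).to_numpy(), i]
                          for lv in col.dropna().unique()]
                groups = [g for g in groups if len(g) > 1]
                if len(groups) < 2:
                    ps.append(np.nan)
                else:
                    ps.append(stats.f_oneway(*groups).pvalue)
        pvals[cov] = ps
    assoc = pd.DataFrame(pvals, index=varexp.index)
    return assoc, varexp
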