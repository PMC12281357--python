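"""Matched-triplet resampling random-forest classifier for resilience status.

Each low-resilience sample (score <= 50) is greedily matched with two
high-resilience samples (score >= 80) on tumour markers (ER/PR/HER2),
smoking (never-smokers only to never-smokers) and nearest age. Triplets are
the atomic unit of every split: across resampling iterations the triplet set
is partitioned into training (50%) / confirmation (20%) / test (30%),
features are CpGs inside training-set DMRs spanning >= 5 probes whose
fold-change direction replicates in the confirmation set, and a random
forest is tuned by nested stratified CV (k=5, m=3) maximizing Youden's
J = sensitivity + specificity - 1 (which also sets the probability
threshold, absorbing the 1:2 class imbalance). CpGs are ranked by how often
they are selected; the final model uses the top CpGs plus age and is
evaluated once on an independent validation cohort.

The positive class throughout is LOW resilience.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .dataset import MethylationDataset
from .dmp import _build_design
from .dmr import cluster_probes, find_bumps
from .preprocessing import beta_to_m

log = logging.getLogger(__name__)

LOW_MAX = 50.0
HIGH_MIN = 80.0
MATCH_CATEGORICAL = ("er", "pr", "her2")

DEFAULT_GRID = tuple(
    {"mtry": mtry, "n_trees": nt, "min_node": mn, "max_depth": md}
    for mtry in ("sqrt", "third", "all")
    for nt in (250, 500, 1000)
    for mn in (1, 5, 10)
    for md in (None, 4, 8)
)

# small grid for desk-scale runs: one well-behaved configuration
SMALL_GRID = ({"mtry": "sqrt", "n_trees": 100, "min_node": 1, "max_depth": None},)


# ---------------------------------------------------------------------------
# triplets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Triplet:
    low: str
    highs: Tuple[str, str]
    age_distances: Tuple[float, float]

    @property
    def sample_ids(self) -> List[str]:
        return [self.low, *self.highs]


@dataclass
class TripletSet:
    triplets: List[Triplet]
    excluded_lows: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.triplets)

    @property
    def sample_ids(self) -> List[str]:
        out: List[str] = []
        for t in self.triplets:
            out.extend(t.sample_ids)
        return out

    @property
    def low_ids(self) -> List[str]:
        return [t.low for t in self.triplets]

    @property
    def high_ids(self) -> List[str]:
        return [h for t in self.triplets for h in t.highs]


def build_triplets(samples: pd.DataFrame,
                   low_max: float = LOW_MAX,
                   high_min: float = HIGH_MIN) -> TripletSet:
    """Greedy 1:2 matching of low- to high-resilience samples.

    Lows are processed in ascending score order; for each, the two unused
    highs agreeing exactly on ER/PR/HER2 (and respecting the smoking rule:
    never-smoker lows take only never-smoker highs; ever-smoker lows prefer
    ever-smokers but may take never-smokers) with smallest |age difference|
    are taken, ties broken by sample id. Infeasible lows are excluded with
    a warning.
    """
    lows = samples[samples["cdrisc_score"] <= low_max].sort_values(
        ["cdrisc_score", "sample_id"])
    highs = samples[samples["cdrisc_score"] >= high_min]
    used: set = set()
    triplets: List[Triplet] = []
    excluded: List[str] = []
    for _, lo in lows.iterrows():
        cand = highs[~highs["sample_id"].isin(used)]
        for c in MATCH_CATEGORICAL:
            cand = cand[cand[c].astype(str) == str(lo[c])]
        if str(lo["smoking"]) == "never":
            cand = cand[cand["smoking"].astype(str) == "never"]
            smoke_pen = pd.Series(0.0, index=cand.index)
        else:
            smoke_pen = (cand["smoking"].astype(str) != str(lo["smoking"])).astype(float)
        if len(cand) < 2:
            log.warning("low sample %s has no feasible 1:2 match; excluded",
                        lo["sample_id"])
            excluded.append(lo["sample_id"])
            continue
        order = pd.DataFrame({
            "penalty": smoke_pen,
            "age_dist": (cand["age"] - lo["age"]).abs(),
            "sample_id": cand["sample_id"],
        }).sort_values(["penalty", "age_dist", "sample_id"])
        chosen = order.head(2)
        ids = tuple(chosen["sample_id"])
        used.update(ids)
        triplets.append(Triplet(
            low=lo["sample_id"], highs=ids,
            age_distances=tuple(float(d) for d in chosen["age_dist"]),
        ))
    return TripletSet(triplets=triplets, excluded_lows=excluded)


def split_triplets(ts: TripletSet,
                   fractions: Tuple[float, float, float] = (0.5, 0.2, 0.3),
                   seed: int = 0) -> Tuple[TripletSet, TripletSet, TripletSet]:
    """Partition whole triplets into train/confirm/test by largest remainder."""
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    n = len(ts)
    if n < 5:
        raise ValueError("need >= 5 triplets to split")
    raw = [f * n for f in fractions]
    sizes = [int(math.floor(r)) for r in raw]
    rem = n - sum(sizes)
    order = sorted(range(3), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in range(rem):
        sizes[order[i]] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    bounds = np.cumsum(sizes)[:-1]
    parts = np.split(perm, bounds)
    return tuple(
        TripletSet(triplets=[ts.triplets[i] for i in sorted(p)]) for p in parts
    )


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def _group_lfc(ds: MethylationDataset, probe_ids: Sequence[str],
               low_ids: Sequence[str], high_ids: Sequence[str]) -> pd.Series:
    M = beta_to_m(ds.beta.loc[probe_ids])
    return M[list(low_ids)].mean(axis=1) - M[list(high_ids)].mean(axis=1)


def select_features(ds: MethylationDataset, train: TripletSet,
                    confirm: TripletSet,
                    covariates: Sequence[str] = (),
                    min_probes: int = 5,
                    clusters=None,
                    **bump_kwargs) -> List[str]:
    """CpGs in training-set DMRs (>= min_probes) with replicating direction.

    Runs the bump finder on the training triplets' per-probe group
    coefficients, keeps CpGs inside candidate regions spanning at least
    ``min_probes`` probes, and retains those whose low-vs-high fold change
    has the same sign in the training and confirmation sets.
    """
    X, _ = _build_design(ds.samples, train.low_ids, train.high_ids, covariates)
    M = beta_to_m(ds.beta[X.index]).to_numpy()
    Xa = X.to_numpy()
    g = list(X.columns).index("group_low")
    pinv = np.linalg.inv(Xa.T @ Xa) @ Xa.T
    coef = pd.Series((M @ pinv.T)[:, g], index=ds.beta.index)
    if clusters is None:
        clusters = cluster_probes(ds.manifest)
    bumps = find_bumps(coef, ds.manifest, clusters=clusters, **bump_kwargs)
    bumps = bumps[bumps["n_probes"] >= min_probes]
    if len(bumps) == 0:
        return []
    cpgs: List[str] = []
    for pids in bumps["probe_ids"]:
        cpgs.extend(pids.split(";"))
    cpgs = list(dict.fromkeys(cpgs))
    lfc_train = _group_lfc(ds, cpgs, train.low_ids, train.high_ids)
    lfc_confirm = _group_lfc(ds, cpgs, confirm.low_ids, confirm.high_ids)
    keep = np.sign(lfc_train) == np.sign(lfc_confirm)
    return [c for c, k in zip(cpgs, keep) if k]


# ---------------------------------------------------------------------------
# Youden threshold + random forest tuning
# ---------------------------------------------------------------------------

def youden_threshold(y_true: np.ndarray, prob: np.ndarray) -> Tuple[float, float]:
    """Probability threshold maximizing J = sensitivity + specificity - 1.

    Exhaustive scan over the distinct predicted probabilities (prediction:
    positive iff prob >= threshold); ties on J resolved toward the higher
    threshold. Returns ``(threshold, J)``.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(prob, dtype=float)
    best_t, best_j = 1.0, -np.inf
    n_pos = max(int(y.sum()), 1)
    n_neg = max(int((1 - y).sum()), 1)
    for t in np.unique(p):
        pred = p >= t
        sens = float((pred & (y == 1)).sum()) / n_pos
        spec = float((~pred & (y == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and t > best_t):
            best_t, best_j = float(t), j
    return best_t, best_j


def sn_sp_at(y_true: np.ndarray, prob: np.ndarray,
             threshold: float) -> Tuple[float, float]:
    y = np.asarray(y_true, dtype=int)
    pred = np.asarray(prob) >= threshold
    n_pos = max(int(y.sum()), 1)
    n_neg = max(int((1 - y).sum()), 1)
    sens = float((pred & (y == 1)).sum()) / n_pos
    spec = float((~pred & (y == 0)).sum()) / n_neg
    return sens, spec


def _make_rf(cfg: Mapping, n_features: int, seed: int) -> RandomForestClassifier:
    mtry = cfg.get("mtry", "sqrt")
    if mtry == "sqrt":
        max_features = max(1, int(math.sqrt(n_features)))
    elif mtry == "third":
        max_features = max(1, n_features // 3)
    elif mtry == "all":
        max_features = n_features
    else:
        max_features = int(mtry)
    return RandomForestClassifier(
        n_estimators=int(cfg.get("n_trees", 500)),
        min_samples_leaf=int(cfg.get("min_node", 1)),
        max_depth=cfg.get("max_depth"),
        max_features=max_features,
        criterion="gini",
        random_state=seed,
        n_jobs=1,
    )


@dataclass
class TunedModel:
    model: RandomForestClassifier
    threshold: float
    config: Dict
    cv_table: pd.DataFrame
    cv_j: float
    cv_auc: float
    features: List[str]


def tune_and_fit_rf(X: pd.DataFrame, y: pd.Series,
                    grid: Sequence[Mapping] = SMALL_GRID,
                    k: int = 5, m: int = 3, seed: int = 0) -> TunedModel:
    """Grid search with m repeats of stratified k-fold CV maximizing mean J.

    Within each validation fold the threshold is the exhaustive-scan Youden
    maximiser. The winning configuration is refit on all data; the deployed
    threshold maximizes J over its pooled out-of-fold probabilities.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    yv = np.asarray(y, dtype=int)
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present")
    k_eff = min(k, int(np.bincount(yv).min()))
    if k_eff < 2:
        raise ValueError("minority class too small for CV")
    rows = []
    best = None
    for ci, cfg in enumerate(grid):
        js, aucs = [], []
        oof_prob = np.full(len(yv), np.nan)
        for rep in range(m):
            skf = StratifiedKFold(n_splits=k_eff, shuffle=True,
                                  random_state=(seed * 97 + rep) % (2 ** 31 - 1))
            for tr, va in skf.split(X, yv):
                rf = _make_rf(cfg, X.shape[1], seed=(seed * 131 + rep) % (2 ** 31 - 1))
                rf.fit(X.iloc[tr], yv[tr])
                prob = rf.predict_proba(X.iloc[va])[:, 1]
                _, j = youden_threshold(yv[va], prob)
                js.append(j)
                if len(np.unique(yv[va])) == 2:
                    aucs.append(roc_auc_score(yv[va], prob))
                if rep == m - 1:
                    oof_prob[va] = prob
        mean_j = float(np.mean(js))
        mean_auc = float(np.mean(aucs)) if aucs else np.nan
        rows.append({"config": ci, **cfg, "cv_j": mean_j, "cv_auc": mean_auc})
        if best is None or mean_j > best[0]:
            best = (mean_j, mean_auc, cfg, oof_prob)
    mean_j, mean_auc, cfg, oof_prob = best
    mask = np.isfinite(oof_prob)
    threshold, _ = youden_threshold(yv[mask], oof_prob[mask])
    final = _make_rf(cfg, X.shape[1], seed=(seed * 197) % (2 ** 31 - 1))
    final.fit(X, yv)
    return TunedModel(
        model=final, threshold=threshold, config=dict(cfg),
        cv_table=pd.DataFrame(rows), cv_j=mean_j, cv_auc=mean_auc,
        features=list(X.columns),
    )


# ---------------------------------------------------------------------------
# resampling iterations
# ---------------------------------------------------------------------------

@dataclass
class IterationResult:
    iteration: int
    seed: int
    selected_cpgs: List[str]
    config: Dict
    threshold: float
    test_auc: float
    test_sensitivity: float
    test_specificity: float
    degenerate: bool = False


def _feature_matrix(ds: MethylationDataset, cpgs: Sequence[str],
                    sample_ids: Sequence[str],
                    with_age: bool = False) -> pd.DataFrame:
    X = beta_to_m(ds.beta.loc[list(cpgs), list(sample_ids)]).T
    if with_age:
        X = X.copy()
        X["age"] = ds.samples.loc[list(sample_ids), "age"].to_numpy(float)
    return X


def _labels(ds: MethylationDataset, low_ids: Sequence[str],
            sample_ids: Sequence[str]) -> np.ndarray:
    low = set(low_ids)
    return np.array([1 if s in low else 0 for s in sample_ids])


def run_iterations(ds: MethylationDataset, ts: TripletSet,
                   n_iter: int = 500, base_seed: int = 0,
                   covariates: Sequence[str] = (),
                   min_probes: int = 5,
                   grid: Sequence[Mapping] = SMALL_GRID,
                   k: int = 5, m: int = 3,
                   clusters=None,
                   **bump_kwargs) -> Tuple[List[IterationResult], pd.DataFrame]:
    """The triplet-preserving resampling loop.

    Per iteration: split triplets 50/20/30, select DMR-based features,
    tune/fit the forest on train+confirm, evaluate AUC and SN/SP at the
    tuned threshold on the held-out test triplets. Fully reproducible from
    ``base_seed``. Returns the per-iteration log and the CpG frequency
    ranking (appearance counts over non-degenerate iterations).
    """
    if clusters is None:
        clusters = cluster_probes(ds.manifest)
    results: List[IterationResult] = []
    counts: Dict[str, int] = {}
    for i in range(n_iter):
        seed_i = (base_seed + i + 1) % (2 ** 31 - 1)
        train, confirm, test = split_triplets(ts, seed=seed_i)
        cpgs = select_features(ds, train, confirm, covariates=covariates,
                               min_probes=min_probes, clusters=clusters,
                               **bump_kwargs)
        if len(cpgs) < 2:
            results.append(IterationResult(
                iteration=i, seed=seed_i, selected_cpgs=cpgs, config={},
                threshold=np.nan, test_auc=np.nan, test_sensitivity=np.nan,
                test_specificity=np.nan, degenerate=True,
            ))
            continue
        fit_ids = train.sample_ids + confirm.sample_ids
        low_fit = train.low_ids + confirm.low_ids
        Xf = _feature_matrix(ds, cpgs, fit_ids)
        yf = _labels(ds, low_fit, fit_ids)
        try:
            tuned = tune_and_fit_rf(Xf, yf, grid=grid, k=k, m=m, seed=seed_i)
        except ValueError:
            results.append(IterationResult(
                iteration=i, seed=seed_i, selected_cpgs=cpgs, config={},
                threshold=np.nan, test_auc=np.nan, test_sensitivity=np.nan,
                test_specificity=np.nan, degenerate=True,
            ))
            continue
        test_ids = test.sample_ids
        Xt = _feature_matrix(ds, cpgs, test_ids)
        yt = _labels(ds, test.low_ids, test_ids)
        prob = tuned.model.predict_proba(Xt)[:, 1]
        auc = roc_auc_score(yt, prob) if len(np.unique(yt)) == 2 else np.nan
        sn, sp = sn_sp_at(yt, prob, tuned.threshold)
        for c in cpgs:
            counts[c] = counts.get(c, 0) + 1
        results.append(IterationResult(
            iteration=i, seed=seed_i, selected_cpgs=cpgs,
            config=tuned.config, threshold=tuned.threshold,
            test_auc=float(auc), test_sensitivity=sn, test_specificity=sp,
        ))
    ranking = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["probe_id", "count"],
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return results, ranking


def iterations_to_frame(results: Sequence[IterationResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "iteration": r.iteration,
            "seed": r.seed,
            "n_features": len(r.selected_cpgs),
            "threshold": r.threshold,
            "test_auc": r.test_auc,
            "test_sensitivity": r.test_sensitivity,
            "test_specificity": r.test_specificity,
            "degenerate": r.degenerate,
        }
        for r in results
    ])


# ---------------------------------------------------------------------------
# final model + validation
# ---------------------------------------------------------------------------

@dataclass
class FinalModel:
    tuned: TunedModel
    n_top: int
    cpgs: List[str]
    validation_auc: float
    validation_sensitivity: float
    validation_specificity: float
    roc: pd.DataFrame
    selection_table: pd.DataFrame


def finalize_and_validate(ranking: pd.DataFrame,
                          ds_classifier: MethylationDataset,
                          classifier_ts: TripletSet,
                          ds_validation: MethylationDataset,
                          validation_low_ids: Sequence[str],
                          n_top_grid: Sequence[int] = tuple(range(1, 11)),
                          grid: Sequence[Mapping] = SMALL_GRID,
                          k: int = 5, m: int = 3, seed: int = 0) -> FinalModel:
    """Pick n_top by CV AUC on the classifier set; validate once.

    Features are the top-n ranked CpGs plus age. Ties on CV AUC resolve to
    the smallest n_top. Validation samples must be disjoint from the
    classifier set.
    """
    if len(ranking) == 0:
        raise ValueError("empty feature ranking")
    overlap = set(ds_validation.beta.columns) & set(classifier_ts.sample_ids)
    if overlap:
        raise ValueError(f"validation samples overlap classifier set: "
                         f"{sorted(overlap)[:5]}")
    fit_ids = classifier_ts.sample_ids
    y = _labels(ds_classifier, classifier_ts.low_ids, fit_ids)
    rows = []
    best = None
    for n_top in n_top_grid:
        cpgs = ranking["probe_id"].head(n_top).tolist()
        cpgs = [c for c in cpgs if c in ds_validation.beta.index]
        if not cpgs:
            continue
        X = _feature_matrix(ds_classifier, cpgs, fit_ids, with_age=True)
        tuned = tune_and_fit_rf(X, y, grid=grid, k=k, m=m, seed=seed)
        rows.append({"n_top": n_top, "cv_auc": tuned.cv_auc, "cv_j": tuned.cv_j})
        if best is None or tuned.cv_auc > best[0]:
            best = (tuned.cv_auc, n_top, cpgs, tuned)
    if best is None:
        raise ValueError("no ranked CpG available in the validation dataset")
    _, n_top, cpgs, tuned = best
    val_ids = list(ds_validation.beta.columns)
    Xv = _feature_matrix(ds_validation, cpgs, val_ids, with_age=True)
    yv = _labels(ds_validation, validation_low_ids, val_ids)
    prob = tuned.model.predict_proba(Xv)[:, 1]
    auc = roc_auc_score(yv, prob) if len(np.unique(yv)) == 2 else np.nan
    sn, sp = sn_sp_at(yv, prob, tuned.threshold)
    fpr, tpr, thr = roc_curve(yv, prob)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return FinalModel(
        tuned=tuned, n_top=n_top, cpgs=cpgs,
        validation_auc=float(auc), validation_sensitivity=sn,
        validation_specificity=sp, roc=roc,
        selection_table=pd.DataFrame(rows),
    )
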