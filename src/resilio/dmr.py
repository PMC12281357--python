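"""Bump-hunting detection of differentially methylated regions.

Probes are grouped into genomic clusters (maximal runs with inter-probe gap
<= max_gap_bp). Within clusters the per-probe group coefficients from the
linear model are smoothed by a running mean; maximal same-sign runs whose
smoothed values exceed a global cutoff (a quantile of all |smoothed|
values) become candidate regions. Each region's area — the absolute sum of
the UNsmoothed coefficients over its probes — measures the strength of the
methylation difference. A label-permutation null on the per-permutation
maximum area yields family-wise region p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MethylationDataset
from .dmp import _build_design
from .preprocessing import beta_to_m

MAX_GAP_BP = 500
SMOOTH_WINDOW = 3
SMOOTH_MIN_PROBES = 3
CUTOFF_QUANTILE = 0.99

DMR_COLUMNS = ["region_id", "chrom", "start", "end", "n_probes", "probe_ids",
               "area", "mean_coef", "direction", "gene"]


@dataclass(frozen=True)
class ProbeCluster:
    """A maximal run of probes with inter-probe gaps <= max_gap_bp."""

    chrom: str
    probe_ids: Tuple[str, ...]
    positions: Tuple[int, ...]


def cluster_probes(manifest: pd.DataFrame,
                   max_gap_bp: int = MAX_GAP_BP) -> List[ProbeCluster]:
    """Partition the manifest into maximal gap-bounded probe clusters."""
    mf = manifest
    sorted_ok = True
    for c, grp in mf.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            sorted_ok = False
            break
    if not sorted_ok:
        warnings.warn("manifest not sorted by (chrom, pos); sorting internally")
        mf = mf.sort_values(["chrom", "pos"], kind="mergesort")
    clusters: List[ProbeCluster] = []
    for c, grp in mf.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        ids = grp.index.to_numpy()
        breaks = np.where(np.diff(pos) > max_gap_bp)[0] + 1
        for seg_ids, seg_pos in zip(np.split(ids, breaks), np.split(pos, breaks)):
            clusters.append(ProbeCluster(
                chrom=str(c),
                probe_ids=tuple(seg_ids),
                positions=tuple(int(p) for p in seg_pos),
            ))
    return clusters


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean with shrinking edge windows."""
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def find_bumps(coefs: pd.Series, manifest: pd.DataFrame,
               clusters: Optional[List[ProbeCluster]] = None,
               max_gap_bp: int = MAX_GAP_BP,
               smooth_window: int = SMOOTH_WINDOW,
               smooth_min_probes: int = SMOOTH_MIN_PROBES,
               cutoff_quantile: float = CUTOFF_QUANTILE,
               cutoff: Optional[float] = None) -> pd.DataFrame:
    """Candidate DMRs from per-probe group coefficients.

    ``coefs`` is indexed by probe id (the group term of the per-CpG model).
    The cutoff defaults to the ``cutoff_quantile`` of all |smoothed|
    coefficients genome-wide; pass ``cutoff`` to fix it explicitly.
    Regions are maximal same-sign runs of smoothed values above the cutoff;
    areas are computed from the unsmoothed coefficients. Singletons allowed.
    """
    if len(coefs) == 0:
        raise ValueError("empty coefficient set")
    if clusters is None:
        clusters = cluster_probes(manifest.loc[coefs.index], max_gap_bp=max_gap_bp)

    smoothed: Dict[str, np.ndarray] = {}
    all_sm: List[np.ndarray] = []
    raw: Dict[str, np.ndarray] = {}
    for ci, cl in enumerate(clusters):
        vals = coefs.reindex(list(cl.probe_ids)).to_numpy()
        sm = _smooth(vals, smooth_window) if len(vals) >= smooth_min_probes else vals.copy()
        key = f"c{ci}"
        smoothed[key] = sm
        raw[key] = vals
        all_sm.append(sm)
    if cutoff is None:
        cutoff = float(np.quantile(np.abs(np.concatenate(all_sm)), cutoff_quantile))

    rows = []
    rid = 0
    for ci, cl in enumerate(clusters):
        key = f"c{ci}"
        sm, vals = smoothed[key], raw[key]
        above = np.abs(sm) > cutoff
        sign = np.sign(sm)
        # run boundaries: above-cutoff AND constant sign
        start = None
        for i in range(len(sm) + 1):
            boundary = (
                i == len(sm) or not above[i]
                or (start is not None and sign[i] != sign[start])
            )
            if start is not None and boundary:
                seg = slice(start, i)
                area = float(np.abs(vals[seg].sum()))
                genes = [g for g in
                         manifest.loc[list(cl.probe_ids[seg]), "gene"].unique() if g]
                rows.append({
                    "region_id": f"dmr{rid:05d}",
                    "chrom": cl.chrom,
                    "start": cl.positions[start],
                    "end": cl.positions[i - 1],
                    "n_probes": i - start,
                    "probe_ids": ";".join(cl.probe_ids[seg]),
                    "area": area,
                    "mean_coef": float(vals[seg].mean()),
                    "direction": "hyper" if vals[seg].sum() > 0 else "hypo",
                    "gene": ";".join(genes),
                })
                rid += 1
                start = None
            if i < len(sm) and above[i] and start is None:
                start = i
    out = pd.DataFrame(rows, columns=DMR_COLUMNS)
    out.attrs.update({
        "cutoff": cutoff, "cutoff_quantile": cutoff_quantile,
        "max_gap_bp": max_gap_bp, "smooth_window": smooth_window,
        "smooth_min_probes": smooth_min_probes,
    })
    return out


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _group_coefficients(M: np.ndarray, X: np.ndarray, g: int) -> np.ndarray:
    pinv = np.linalg.inv(X.T @ X) @ X.T
    return (M @ pinv.T)[:, g]


def permute_null(ds: MethylationDataset,
                 low_ids: Sequence[str], high_ids: Sequence[str],
                 covariates: Sequence[str] = (),
                 n_perm: int = 100, seed: int = 0,
                 clusters: Optional[List[ProbeCluster]] = None,
                 observed: Optional[pd.DataFrame] = None,
                 **bump_kwargs):
    """Group-label permutation null for region areas.

    Covariate columns stay fixed; only the group indicator is permuted.
    Each permutation re-runs the coefficient fit and bump finder and records
    the maximum region area (0 when no region emerges). Per-region
    p = (1 + #{null max >= observed area}) / (1 + n_perm).

    Returns ``(observed_with_p, null_max_areas)``.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    X, _ = _build_design(ds.samples, low_ids, high_ids, covariates)
    ids = X.index
    M = beta_to_m(ds.beta[ids]).to_numpy()
    Xa = X.to_numpy()
    g = list(X.columns).index("group_low")
    if clusters is None:
        clusters = cluster_probes(ds.manifest)

    if observed is None:
        coef = pd.Series(_group_coefficients(M, Xa, g), index=ds.beta.index)
        observed = find_bumps(coef, ds.manifest, clusters=clusters, **bump_kwargs)

    null_max = np.empty(n_perm)
    group_col = Xa[:, g].copy()
    for b in range(n_perm):
        Xp = Xa.copy()
        Xp[:, g] = rng.permutation(group_col)
        coef_p = pd.Series(_group_coefficients(M, Xp, g), index=ds.beta.index)
        bumps_p = find_bumps(coef_p, ds.manifest, clusters=clusters, **bump_kwargs)
        null_max[b] = bumps_p["area"].max() if len(bumps_p) else 0.0

    out = observed.copy()
    out["perm_p"] = [
        (1.0 + float((null_max >= a).sum())) / (1.0 + n_perm)
        for a in out["area"]
    ]
    out.attrs.update(observed.attrs)
    out.attrs.update({"n_perm": n_perm, "seed": seed})
    return out, null_max


# ---------------------------------------------------------------------------
# cross-subset consistency
# ---------------------------------------------------------------------------

def _coordinate_bins(regions: pd.DataFrame) -> Dict[int, str]:
    """Merge overlapping gene-less regions into coordinate bins per chrom."""
    keys: Dict[int, str] = {}
    for chrom, grp in regions.groupby("chrom"):
        grp = grp.sort_values(["start", "end"])
        bin_start = bin_end = None
        members: List[int] = []
        def flush():
            for ix in members:
                keys[ix] = f"{chrom}:{bin_start}-{bin_end}"
        for ix, row in grp.iterrows():
            if bin_start is None or row["start"] > bin_end:
                if members:
                    flush()
                bin_start, bin_end = row["start"], row["end"]
                members = [ix]
            else:
                bin_end = max(bin_end, row["end"])
                members.append(ix)
        if members:
            flush()
    return keys


def dmr_consistency_scan(dmr_tables: Mapping[str, pd.DataFrame],
                         subset_order: Sequence[str]) -> pd.DataFrame:
    """Match regions across subsets and score presence/area trends.

    Regions sharing a gene label are matched by gene; gene-less regions are
    matched by coordinate overlap (>= 1 bp). For each region key the scan
    reports the per-subset presence vector, the longest consecutive run over
    the ordered subsets (100% -> 5%), and ``area_trend_stat``: the Spearman
    correlation of area with subset distality rank over subsets where the
    region is present (NaN when present in < 2 subsets).
    """
    if len(subset_order) < 2:
        raise ValueError("need >= 2 subset analyses")
    frames = []
    for lb in subset_order:
        t = dmr_tables.get(lb)
        if t is None or len(t) == 0:
            continue
        t = t.copy()
        t["subset"] = lb
        frames.append(t)
    if not frames:
        return pd.DataFrame(columns=["region_key", "n_present",
                                     "max_consecutive_run", "area_trend_stat"])
    allr = pd.concat(frames, ignore_index=True)
    gene_key = allr["gene"].str.split(";").str[0].fillna("")
    allr["region_key"] = gene_key
    no_gene = allr["region_key"] == ""
    if no_gene.any():
        bins = _coordinate_bins(allr.loc[no_gene])
        for ix, key in bins.items():
            allr.loc[ix, "region_key"] = key

    rank = {lb: i for i, lb in enumerate(subset_order)}
    rows = []
    for key, grp in allr.groupby("region_key"):
        present = np.zeros(len(subset_order), dtype=bool)
        areas = np.full(len(subset_order), np.nan)
        for _, r in grp.iterrows():
            j = rank[r["subset"]]
            present[j] = True
            areas[j] = max(areas[j], r["area"]) if np.isfinite(areas[j]) else r["area"]
        run = best = 0
        for p in present:
            run = run + 1 if p else 0
            best = max(best, run)
        pres_idx = np.where(present)[0]
        if len(pres_idx) >= 2 and np.ptp(areas[pres_idx]) > 0:
            trend = stats.spearmanr(pres_idx, areas[pres_idx]).statistic
        else:
            trend = np.nan
        row = {
            "region_key": key,
            "n_present": int(present.sum()),
            "max_consecutive_run": best,
            "area_trend_stat": trend,
        }
        for lb in subset_order:
            row[f"present_{lb}"] = bool(present[rank[lb]])
            row[f"area_{lb}"] = areas[rank[lb]]
        rows.append(row)
    out = pd.DataFrame(rows).set_index("region_key")
    out.attrs["subset_order"] = list(subset_order)
    return out


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive regions -> BED (0-based half-open) frame."""
    return pd.DataFrame({
        "chrom": dmrs["chrom"],
        "start": dmrs["start"] - 1,
        "end": dmrs["end"],
        "name": dmrs["region_id"],
        "score": dmrs["area"],
        "strand": ".",
    })
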