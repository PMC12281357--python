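"""Synthetic EPIC-like methylation cohorts with known ground truth.

The generator emulates the structure of a whole-blood Infinium EPIC study of
a tail-dichotomized psychometric trait (CD-RISC resilience score): bimodal
beta distributions, probe-level QC failure modes (detection p, bead counts,
SNP / multihit / non-CpG / sex-chromosome probes), covariate-linked global
structure, per-batch location/scale shifts, leukocyte cell-type mixing on
reference probes, and spiked differentially methylated regions whose M-scale
effect grows with distance of the trait score from the scale midpoint
(a dose-response architecture).

Everything is generated on the M scale (Gaussian per-probe baselines pushed
through the inverse logit), so downstream modelling on M values sees
well-behaved residuals and beta values stay off the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .dataset import FEATURE_CLASSES, MethylationDataset

# trait-score architecture of the tail-selected cohort: the low-resilience
# group spans [32, 65] (mean 56, SD 7.5) and the high group [77, 100]
# (mean 84, SD 5.5); the dose-response midpoint sits between the two ranges.
LOW_SCORE = dict(mean=56.0, sd=7.5, lo=32.0, hi=65.0)
HIGH_SCORE = dict(mean=84.0, sd=5.5, lo=77.0, hi=100.0)
SCORE_MIDPOINT = 71.0

DEFAULT_QC_RATES = {
    "detection": 0.04,
    "beads": 0.03,
    "non_cpg": 0.02,
    "snp": 0.03,
    "multihit": 0.02,
    "sex_chrom": 0.03,
}

DEFAULT_CELL_TYPES = ["neutrophil", "monocyte", "cd4t", "cd8t", "bcell", "nk"]
DEFAULT_CELL_ALPHA = [12.0, 2.0, 3.0, 2.0, 1.0, 1.0]


@dataclass(frozen=True)
class SpikedRegion:
    """A contiguous probe run carrying a dose-responsive group effect.

    ``max_effect`` is the M-scale low-vs-high group difference reached at the
    extreme tail of the score range; a sample with score ``s`` on the
    low-resilience side of the midpoint is shifted by
    ``sign * max_effect * (|s - midpoint| / half_range) ** dose_exponent``
    (sign +1 for ``direction='hyper'`` in the low group, -1 for ``'hypo'``);
    samples at or above the midpoint are the unshifted reference.
    """

    start_probe_index: int
    end_probe_index: int  # inclusive
    max_effect: float = 1.2
    dose_exponent: float = 1.0
    direction: str = "hyper"
    chromosome: Optional[str] = None
    feature_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end_probe_index < self.start_probe_index:
            raise ValueError("end_probe_index < start_probe_index")
        if self.max_effect < 0:
            raise ValueError("max_effect must be >= 0")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be 'hyper' or 'hypo'")

    @property
    def probe_indices(self) -> np.ndarray:
        return np.arange(self.start_probe_index, self.end_probe_index + 1)

    @property
    def sign(self) -> int:
        return 1 if self.direction == "hyper" else -1


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator."""

    n_probes: int = 20000
    n_samples: int = 425
    n_chromosomes: int = 8
    probe_spacing_bp: int = 1500
    spiked_regions: Tuple[SpikedRegion, ...] = ()
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.3, "menstrual": 0.3}
    )
    covariate_affected_fraction: float = 0.10
    batch_effects: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {"b1": (0.0, 1.0), "b2": (0.3, 1.15)}
    )
    cell_reference: Optional[pd.DataFrame] = None  # ref probes x cell types
    cell_alpha: Sequence[float] = field(default_factory=lambda: list(DEFAULT_CELL_ALPHA))
    cell_noise_sd: float = 0.0
    noise_sd: float = 0.5
    qc_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_QC_RATES))
    score_midpoint: float = SCORE_MIDPOINT
    score_half_range: Optional[float] = None  # default: midpoint - low range floor
    seed: int = 0
    array_seed: int = 777  # fixes probe baselines/manifest across cohorts

    def __post_init__(self) -> None:
        if self.n_probes <= 0 or self.n_samples <= 0:
            raise ValueError("n_probes and n_samples must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for r in self.spiked_regions:
            if r.end_probe_index >= self.n_probes:
                raise ValueError(
                    f"spiked region {r} exceeds n_probes={self.n_probes}"
                )

    @property
    def half_range(self) -> float:
        if self.score_half_range is not None:
            return self.score_half_range
        return max(self.score_midpoint - LOW_SCORE["lo"],
                   HIGH_SCORE["hi"] - self.score_midpoint)


@dataclass
class GroundTruth:
    """What the generator spiked, for scoring recovery downstream."""

    spiked_probes: Dict[str, List[str]]  # region label -> probe ids
    spiked_regions: pd.DataFrame  # label, chrom, start, end, max_effect, ...
    cell_fractions: Optional[pd.DataFrame]  # samples x cell types
    reference_probe_ids: List[str]

    @property
    def all_spiked_probe_ids(self) -> List[str]:
        out: List[str] = []
        for ids in self.spiked_probes.values():
            out.extend(ids)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, ids in self.spiked_probes.items():
            for pid in ids:
                rows.append({"region": label, "probe_id": pid})
        return pd.DataFrame(rows, columns=["region", "probe_id"])


# ---------------------------------------------------------------------------
# cell-type machinery
# ---------------------------------------------------------------------------

def default_cell_reference(n_ref_probes: int = 50,
                           cell_types: Sequence[str] = tuple(DEFAULT_CELL_TYPES),
                           seed: int = 12345) -> pd.DataFrame:
    """Well-separated per-cell-type mean beta profiles (probes x types).

    Profiles are drawn once from a Beta(0.4, 0.4) so each reference probe is
    near-fully methylated in some cell types and near-unmethylated in others,
    which is what makes reference probes informative for deconvolution.
    """
    rng = np.random.default_rng(seed)
    ref = rng.beta(0.4, 0.4, size=(n_ref_probes, len(cell_types)))
    ref = np.clip(ref, 0.02, 0.98)
    idx = [f"cg_ref_{i:04d}" for i in range(n_ref_probes)]
    return pd.DataFrame(ref, index=idx, columns=list(cell_types))


def mix_cell_types(fractions: pd.DataFrame, reference: pd.DataFrame,
                   noise_sd: float = 0.0,
                   rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Beta values at reference probes implied by per-sample cell fractions.

    ``fractions`` is samples x cell types on the simplex; ``reference`` is
    reference probes x cell types of mean beta. Returns probes x samples.
    """
    frac = fractions[reference.columns].to_numpy(dtype=float)
    if (frac < -1e-9).any():
        raise ValueError("cell fractions must be non-negative")
    sums = frac.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("cell fractions must sum to 1 per sample")
    beta = reference.to_numpy() @ frac.T
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        beta = beta + rng.normal(0.0, noise_sd, size=beta.shape)
    beta = np.clip(beta, 1e-3, 1 - 1e-3)
    return pd.DataFrame(beta, index=reference.index, columns=fractions.index)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _simulate_samples(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_samples
    n_low = n // 2 + n % 2
    n_high = n - n_low
    scores = np.concatenate([
        _truncnorm(rng, LOW_SCORE["mean"], LOW_SCORE["sd"],
                   LOW_SCORE["lo"], LOW_SCORE["hi"], n_low),
        _truncnorm(rng, HIGH_SCORE["mean"], HIGH_SCORE["sd"],
                   HIGH_SCORE["lo"], HIGH_SCORE["hi"], n_high),
    ])
    group = np.array(["low"] * n_low + ["high"] * n_high)
    order = rng.permutation(n)
    scores, group = scores[order], group[order]

    age = np.round(_truncnorm(rng, 62.0, 11.0, 28.0, 90.0, n), 1)
    menstrual = np.where(age >= 51, "post", "pre").astype(object)
    flip = rng.random(n) < 0.05  # imperfect age/menopause concordance
    menstrual[flip] = np.where(menstrual[flip] == "post", "pre", "post")
    detection_mode = rng.choice(["screening", "symptomatic"], size=n, p=[0.6, 0.4])
    er = rng.choice(["pos", "neg"], size=n, p=[0.86, 0.14])
    pr = rng.choice(["pos", "neg"], size=n, p=[0.68, 0.32])
    her2 = rng.choice(["neg", "pos"], size=n, p=[0.89, 0.11])
    smoking = rng.choice(["never", "ever"], size=n, p=[0.87, 0.13])
    batches = list(cfg.batch_effects) or ["b1"]
    batch = np.array(batches)[rng.integers(0, len(batches), size=n)]

    return pd.DataFrame(
        {
            "sample_id": [f"s{i:04d}" for i in range(n)],
            "cdrisc_score": np.round(scores, 1),
            "resilience_group": group,
            "age": age,
            "menstrual": menstrual,
            "detection_mode": detection_mode,
            "er": er,
            "pr": pr,
            "her2": her2,
            "smoking": smoking,
            "batch": batch,
        }
    ).set_index("sample_id", drop=False).rename_axis(None)


def _simulate_manifest(cfg: SimulationConfig, rng: np.random.Generator,
                       n_ref: int) -> pd.DataFrame:
    # rng here is the array-level generator: the manifest is a property of
    # the array/genome, shared by every cohort with the same array_seed.
    n = cfg.n_probes
    rates = dict(DEFAULT_QC_RATES)
    rates.update(cfg.qc_rates)

    # sex-chromosome probes occupy the final contiguous block -> coherent
    # chrom labels; all other failure classes are independent per probe.
    n_sex = int(round(rates["sex_chrom"] * n))
    n_auto = n - n_sex
    blocks = np.array_split(np.arange(n_auto), cfg.n_chromosomes)
    chrom = np.empty(n, dtype=object)
    for ci, blk in enumerate(blocks):
        chrom[blk] = f"chr{ci + 1}"
    chrom[n_auto:] = "chrX"
    sex_flag = np.zeros(n, dtype=bool)
    sex_flag[n_auto:] = True

    snp_flag = rng.random(n) < rates["snp"]
    multihit_flag = rng.random(n) < rates["multihit"]
    non_cpg = rng.random(n) < rates["non_cpg"]

    spiked_idx = np.concatenate([r.probe_indices for r in cfg.spiked_regions]) \
        if cfg.spiked_regions else np.array([], dtype=int)
    protected = np.zeros(n, dtype=bool)
    protected[spiked_idx] = True
    protected[:n_ref] = True  # cell-reference probes stay analysable
    snp_flag[protected] = False
    multihit_flag[protected] = False
    non_cpg[protected] = False

    probe_id = np.array(
        [f"ch.{i:08d}" if non_cpg[i] else f"cg{i:08d}" for i in range(n)],
        dtype=object,
    )

    # positions: mixture of tight (clusterable) and wide gaps, per chromosome
    gaps = np.where(
        rng.random(n) < 0.6,
        rng.integers(30, 400, size=n),
        rng.integers(600, 2 * cfg.probe_spacing_bp + 600, size=n),
    ).astype(np.int64)
    for r in cfg.spiked_regions:  # spiked runs must sit inside one cluster
        gaps[r.start_probe_index + 1: r.end_probe_index + 1] = rng.integers(
            40, 200, size=r.end_probe_index - r.start_probe_index
        )
    pos = np.empty(n, dtype=np.int64)
    for c in pd.unique(chrom):
        mask = chrom == c
        g = gaps[mask].copy()
        g[0] = rng.integers(10_000, 50_000)
        pos[mask] = np.cumsum(g)

    # gene blocks with intergenic stretches
    gene = np.empty(n, dtype=object)
    feature = np.empty(n, dtype=object)
    genic_classes = ["promoter", "5utr", "exon", "intron", "3utr",
                     "island", "shore", "shelf"]
    genic_w = np.array([0.10, 0.05, 0.15, 0.40, 0.05, 0.10, 0.10, 0.05])
    i = 0
    g_idx = 0
    while i < n:
        length = int(rng.integers(4, 25))
        end = min(i + length, n)
        if rng.random() < 0.65:
            gene[i:end] = f"GENE{g_idx:05d}"
            g_idx += 1
            feature[i:end] = rng.choice(genic_classes, size=end - i, p=genic_w)
        else:
            gene[i:end] = ""
            feature[i:end] = rng.choice(
                ["intergenic", "opensea", "shelf"], size=end - i, p=[0.6, 0.3, 0.1]
            )
        i = end
    for k, r in enumerate(cfg.spiked_regions):
        sl = slice(r.start_probe_index, r.end_probe_index + 1)
        gene[sl] = f"SPIKE{k:02d}"
        if r.feature_class is not None:
            if r.feature_class not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {r.feature_class!r}")
            feature[sl] = r.feature_class

    return pd.DataFrame(
        {
            "probe_id": probe_id,
            "chrom": chrom,
            "pos": pos,
            "gene": gene,
            "feature_class": feature,
            "snp_flag": snp_flag,
            "multihit_flag": multihit_flag,
            "sex_chrom_flag": sex_flag,
        }
    ).set_index("probe_id", drop=False).rename_axis(None)


def _simulate_qc_matrices(cfg: SimulationConfig, rng: np.random.Generator,
                          manifest: pd.DataFrame, protected: np.ndarray):
    n, m = cfg.n_probes, cfg.n_samples
    rates = dict(DEFAULT_QC_RATES)
    rates.update(cfg.qc_rates)

    detection_p = rng.uniform(0.0, 0.005, size=(n, m))
    det_fail = (rng.random(n) < rates["detection"]) & ~protected
    for i in np.where(det_fail)[0]:
        k = max(1, int(round(0.10 * m)))  # fails in ~10% of samples (> 5%)
        cols = rng.choice(m, size=k, replace=False)
        detection_p[i, cols] = rng.uniform(0.011, 0.2, size=k)

    bead_counts = rng.integers(5, 25, size=(n, m))
    bead_fail = (rng.random(n) < rates["beads"]) & ~protected & ~det_fail
    for i in np.where(bead_fail)[0]:
        k = max(1, int(np.ceil(0.96 * m)))  # >=3 beads in <5% of samples
        cols = rng.choice(m, size=k, replace=False)
        bead_counts[i, cols] = rng.integers(1, 3, size=k)

    return detection_p, bead_counts


def dose_response_shift(scores: np.ndarray, region: SpikedRegion,
                        midpoint: float, half_range: float) -> np.ndarray:
    """Per-sample M-scale shift for one spiked region (0 at/above midpoint)."""
    dist = np.clip((midpoint - np.asarray(scores, dtype=float)) / half_range, 0.0, None)
    return region.sign * region.max_effect * dist ** region.dose_exponent


def simulate_dataset(cfg: SimulationConfig) -> Tuple[MethylationDataset, GroundTruth]:
    """Generate a full synthetic cohort plus its ground truth.

    Deterministic given ``cfg`` (including ``cfg.seed``): two calls with the
    same config yield identical datasets.
    """
    rng = np.random.default_rng(cfg.seed)
    rng_array = np.random.default_rng(cfg.array_seed)
    samples = _simulate_samples(cfg, rng)
    n_ref = 0 if cfg.cell_reference is None else len(cfg.cell_reference)
    manifest = _simulate_manifest(cfg, rng_array, n_ref=n_ref)

    spiked_idx = np.concatenate([r.probe_indices for r in cfg.spiked_regions]) \
        if cfg.spiked_regions else np.array([], dtype=int)
    protected = np.zeros(cfg.n_probes, dtype=bool)
    protected[spiked_idx] = True
    protected[:n_ref] = True
    detection_p, bead_counts = _simulate_qc_matrices(cfg, rng, manifest, protected)

    # per-probe baseline M: three-component mixture -> bimodal beta;
    # array-level (shared across cohorts), like real probe methylation levels
    comp = rng_array.choice(3, size=cfg.n_probes, p=[0.4, 0.2, 0.4])
    mu = np.where(comp == 0, rng_array.normal(-3.5, 1.0, cfg.n_probes),
                  np.where(comp == 1, rng_array.normal(0.0, 1.5, cfg.n_probes),
                           rng_array.normal(3.5, 1.0, cfg.n_probes)))
    M = mu[:, None] + rng.normal(0.0, cfg.noise_sd,
                                 size=(cfg.n_probes, cfg.n_samples))

    # covariate-linked structure on random probe subsets
    for cov, effect in cfg.covariate_effects.items():
        if effect == 0:
            continue
        affected = rng_array.choice(
            cfg.n_probes,
            size=max(1, int(cfg.covariate_affected_fraction * cfg.n_probes)),
            replace=False,
        )
        if cov == "age":
            x = (samples["age"].to_numpy() - 62.0) / 11.0
        elif cov == "menstrual":
            x = (samples["menstrual"] == "pre").to_numpy(float)
        elif cov == "smoking":
            x = (samples["smoking"] == "ever").to_numpy(float)
        elif cov == "er":
            x = (samples["er"] == "pos").to_numpy(float)
        elif cov == "detection_mode":
            x = (samples["detection_mode"] == "screening").to_numpy(float)
        else:
            raise ValueError(f"unsupported covariate effect {cov!r}")
        M[affected] += effect * x[None, :]

    # batch location/scale shifts around the probe baseline
    for b, (loc, scale) in cfg.batch_effects.items():
        cols = (samples["batch"] == b).to_numpy()
        if cols.any() and (loc != 0.0 or scale != 1.0):
            M[:, cols] = mu[:, None] + loc + scale * (M[:, cols] - mu[:, None])

    # dose-responsive spikes (low-resilience side only; high side = reference)
    scores = samples["cdrisc_score"].to_numpy()
    for r in cfg.spiked_regions:
        shift = dose_response_shift(scores, r, cfg.score_midpoint, cfg.half_range)
        M[r.probe_indices[:, None], np.arange(cfg.n_samples)[None, :]] += shift[None, :]

    beta = expit(M * np.log(2.0))
    beta = np.clip(beta, 1e-3, 1 - 1e-3)
    beta = pd.DataFrame(beta, index=manifest.index, columns=samples.index)

    # overwrite reference probes with cell-type mixtures
    cell_fractions = None
    ref_ids: List[str] = []
    if cfg.cell_reference is not None:
        ref = cfg.cell_reference
        ref_ids = list(beta.index[:n_ref])
        frac = rng.dirichlet(np.asarray(cfg.cell_alpha, float), size=cfg.n_samples)
        cell_fractions = pd.DataFrame(frac, index=samples.index, columns=ref.columns)
        ref_local = pd.DataFrame(ref.to_numpy(), index=ref_ids, columns=ref.columns)
        mixed = mix_cell_types(cell_fractions, ref_local,
                               noise_sd=cfg.cell_noise_sd, rng=rng)
        beta.loc[ref_ids] = mixed.to_numpy()

    ds = MethylationDataset(
        beta=beta,
        manifest=manifest,
        samples=samples,
        detection_p=pd.DataFrame(detection_p, index=manifest.index,
                                 columns=samples.index),
        bead_counts=pd.DataFrame(bead_counts, index=manifest.index,
                                 columns=samples.index),
        meta={"seed": cfg.seed, "score_midpoint": cfg.score_midpoint,
              "score_half_range": cfg.half_range},
    )

    spiked_probes = {
        f"SPIKE{k:02d}": list(manifest.index[r.probe_indices])
        for k, r in enumerate(cfg.spiked_regions)
    }
    region_rows = []
    for k, r in enumerate(cfg.spiked_regions):
        ids = manifest.index[r.probe_indices]
        region_rows.append({
            "region": f"SPIKE{k:02d}",
            "chrom": manifest.loc[ids[0], "chrom"],
            "start": int(manifest.loc[ids[0], "pos"]),
            "end": int(manifest.loc[ids[-1], "pos"]),
            "n_probes": len(ids),
            "max_effect": r.max_effect,
            "dose_exponent": r.dose_exponent,
            "direction": r.direction,
        })
    truth = GroundTruth(
        spiked_probes=spiked_probes,
        spiked_regions=pd.DataFrame(
            region_rows,
            columns=["region", "chrom", "start", "end", "n_probes",
                     "max_effect", "dose_exponent", "direction"],
        ),
        cell_fractions=cell_fractions,
        reference_probe_ids=ref_ids,
    )
    return ds, truth


# ---------------------------------------------------------------------------
# canned scenarios
# ---------------------------------------------------------------------------

def null_scenario(n_probes: int = 10000, n_samples: int = 200,
                  seed: int = 0) -> SimulationConfig:
    """Pure-noise cohort: no spikes, no covariate/batch effects, no cells."""
    return SimulationConfig(
        n_probes=n_probes,
        n_samples=n_samples,
        spiked_regions=(),
        covariate_effects={},
        batch_effects={"b1": (0.0, 1.0)},
        cell_reference=None,
        seed=seed,
    )


def dose_response_scenario(n_probes: int = 4000, n_samples: int = 200,
                           max_effect: float = 1.2, dose_exponent: float = 1.0,
                           region_sizes: Sequence[int] = (8, 7, 6),
                           seed: int = 0,
                           with_cells: bool = False,
                           feature_class: Optional[str] = None) -> SimulationConfig:
    """Cohort with three spiked dose-responsive regions on distinct chromosomes."""
    n_ref = 50 if with_cells else 0
    starts = np.linspace(n_ref + 200, n_probes * 0.85, num=len(region_sizes)).astype(int)
    directions = ["hyper", "hypo", "hyper"]
    regions = tuple(
        SpikedRegion(
            start_probe_index=int(s),
            end_probe_index=int(s) + int(sz) - 1,
            max_effect=max_effect,
            dose_exponent=dose_exponent,
            direction=directions[i % 3],
            feature_class=feature_class,
        )
        for i, (s, sz) in enumerate(zip(starts, region_sizes))
    )
    return SimulationConfig(
        n_probes=n_probes,
        n_samples=n_samples,
        spiked_regions=regions,
        cell_reference=default_cell_reference(n_ref) if with_cells else None,
        seed=seed,
    )
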