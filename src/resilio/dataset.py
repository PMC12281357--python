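"""Core in-memory container for a methylation study.

A :class:`MethylationDataset` bundles the three tables every pipeline stage
consumes: a probes x samples beta matrix, a probe manifest with genomic
coordinates and QC flags, and a sample sheet with the trait score and
covariates. Optional detection p-value and bead-count matrices ride along for
probe filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = [
    "probe_id", "chrom", "pos", "gene", "feature_class",
    "snp_flag", "multihit_flag", "sex_chrom_flag",
]

SAMPLE_COLUMNS = [
    "sample_id", "cdrisc_score", "age", "menstrual", "detection_mode",
    "er", "pr", "her2", "smoking", "batch",
]

FEATURE_CLASSES = [
    "promoter", "5utr", "exon", "intron", "3utr", "intergenic",
    "island", "shore", "shelf", "opensea",
]

BETA_EPS = 1e-3


@dataclass
class MethylationDataset:
    """Beta matrix + probe manifest + sample sheet.

    Parameters
    ----------
    beta
        probes x samples DataFrame, values in (0, 1); index = probe ids,
        columns = sample ids.
    manifest
        Probe annotation indexed by probe id (chrom, pos 1-based, gene,
        feature_class, snp/multihit/sex flags).
    samples
        Sample sheet indexed by sample id (cdrisc_score, resilience_group,
        age, menstrual, detection_mode, er, pr, her2, smoking, batch).
    detection_p, bead_counts
        Optional matrices aligned with ``beta``.
    """

    beta: pd.DataFrame
    manifest: pd.DataFrame
    samples: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None
    bead_counts: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.beta.index.has_duplicates:
            dups = self.beta.index[self.beta.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids in beta matrix: {dups[:5]}")
        if self.beta.columns.has_duplicates:
            dups = self.beta.columns[self.beta.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in beta matrix: {dups[:5]}")
        missing_probes = self.beta.index.difference(self.manifest.index)
        if len(missing_probes):
            raise ValueError(
                f"beta probes absent from manifest: {list(missing_probes[:5])}"
            )
        missing_samples = self.beta.columns.difference(self.samples.index)
        if len(missing_samples):
            raise ValueError(
                f"beta samples absent from sample sheet: {list(missing_samples[:5])}"
            )
        # align (id-based, order-independent)
        self.manifest = self.manifest.loc[self.beta.index]
        self.samples = self.samples.loc[self.beta.columns]
        vals = self.beta.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("beta matrix contains NaN")
        out = (vals <= 0) | (vals >= 1)
        if out.any():
            # tolerate boundary touches within clipping epsilon
            bad = (vals < -BETA_EPS) | (vals > 1 + BETA_EPS)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    "beta out of (0,1) beyond epsilon at probe "
                    f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
                )
            clipped = np.clip(vals, BETA_EPS, 1 - BETA_EPS)
            self.beta = pd.DataFrame(clipped, index=self.beta.index,
                                     columns=self.beta.columns)
        for name in ("detection_p", "bead_counts"):
            mat = getattr(self, name)
            if mat is not None:
                if mat.shape != self.beta.shape:
                    raise ValueError(f"{name} shape {mat.shape} != beta {self.beta.shape}")
                setattr(self, name, mat.loc[self.beta.index, self.beta.columns])
        if (self.manifest["pos"] <= 0).any():
            raise ValueError("manifest positions must be positive (1-based)")

    # -- convenience ------------------------------------------------------
    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def m_values(self, eps: float = BETA_EPS) -> pd.DataFrame:
        """M = log2(beta / (1 - beta)) after epsilon clipping."""
        from .preprocessing import beta_to_m

        return beta_to_m(self.beta, eps=eps)

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        probe_ids = pd.Index(probe_ids)
        return replace(
            self,
            beta=self.beta.loc[probe_ids],
            manifest=self.manifest.loc[probe_ids],
            samples=self.samples,
            detection_p=None if self.detection_p is None else self.detection_p.loc[probe_ids],
            bead_counts=None if self.bead_counts is None else self.bead_counts.loc[probe_ids],
        )

    def subset_samples(self, sample_ids) -> "MethylationDataset":
        sample_ids = pd.Index(sample_ids)
        return replace(
            self,
            beta=self.beta[sample_ids],
            manifest=self.manifest,
            samples=self.samples.loc[sample_ids],
            detection_p=None if self.detection_p is None else self.detection_p[sample_ids],
            bead_counts=None if self.bead_counts is None else self.bead_counts[sample_ids],
        )
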