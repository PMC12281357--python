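"""Delimited-text readers/writers and run configuration.

Canonical interchange formats: beta matrix as TSV (probe id first column),
manifest and sample sheet as CSV, DMR tables as CSV plus BED (with the
1-based inclusive -> 0-based half-open conversion). Every written table can
be read back losslessly; alignment is by id, never by row order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd
import yaml

from .dataset import MANIFEST_COLUMNS, MethylationDataset


def write_dataset(ds: MethylationDataset, out_dir, prefix: str = "") -> Dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out_dir / f"{prefix}beta.tsv",
        "manifest": out_dir / f"{prefix}manifest.csv",
        "samples": out_dir / f"{prefix}samples.csv",
    }
    ds.beta.rename_axis("probe_id").to_csv(paths["beta"], sep="\t", float_format="%.6g")
    ds.manifest[MANIFEST_COLUMNS[1:]].rename_axis("probe_id").to_csv(paths["manifest"])
    ds.samples.drop(columns=["sample_id"], errors="ignore") \
        .rename_axis("sample_id").to_csv(paths["samples"])
    if ds.detection_p is not None:
        p = out_dir / f"{prefix}detection_p.tsv"
        ds.detection_p.rename_axis("probe_id").to_csv(p, sep="\t", float_format="%.4g")
        paths["detection_p"] = p
    if ds.bead_counts is not None:
        p = out_dir / f"{prefix}bead_counts.tsv"
        ds.bead_counts.rename_axis("probe_id").to_csv(p, sep="\t")
        paths["bead_counts"] = p
    return paths


def read_dataset(beta_path, manifest_path, samples_path,
                 detection_p_path=None, bead_counts_path=None) -> MethylationDataset:
    """Load the three core tables; id-aligned, order-independent."""
    beta = pd.read_csv(beta_path, sep="\t", index_col="probe_id").rename_axis(None)
    manifest = pd.read_csv(manifest_path, index_col="probe_id",
                           dtype={"snp_flag": bool, "multihit_flag": bool,
                                  "sex_chrom_flag": bool})
    manifest["gene"] = manifest["gene"].fillna("")
    manifest.insert(0, "probe_id", manifest.index)
    manifest = manifest.rename_axis(None)
    samples = pd.read_csv(samples_path, index_col="sample_id")
    samples.insert(0, "sample_id", samples.index)
    samples = samples.rename_axis(None)
    det = None if detection_p_path is None else pd.read_csv(
        detection_p_path, sep="\t", index_col="probe_id").rename_axis(None)
    beads = None if bead_counts_path is None else pd.read_csv(
        bead_counts_path, sep="\t", index_col="probe_id").rename_axis(None)
    return MethylationDataset(beta=beta, manifest=manifest, samples=samples,
                              detection_p=det, bead_counts=beads)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every stage toggle and threshold of the pipeline, serialisable to YAML."""

    out_dir: str = "resilio_out"
    seed: int = 0
    # synthetic inputs (used when beta_path is None)
    n_probes: int = 5000
    n_samples: int = 120
    n_validation_samples: int = 60
    spiked: bool = True
    max_effect: float = 1.2
    # or file inputs
    beta_path: Optional[str] = None
    manifest_path: Optional[str] = None
    samples_path: Optional[str] = None
    # preprocessing
    detection_p_max: float = 0.01
    min_beads: int = 3
    max_fail_fraction: float = 0.05
    adjust_batch_method: str = "standardize"  # or "none"
    # dmp
    steps: Sequence[float] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05)
    covariates: Sequence[str] = ("age", "menstrual", "detection_mode", "er")
    p_max: float = 0.05
    lfc_min: float = 0.5
    # dmr
    max_gap_bp: int = 500
    smooth_window: int = 3
    cutoff_quantile: float = 0.99
    n_perm: int = 50
    # classifier
    low_max: float = 50.0
    high_min: float = 80.0
    n_iter: int = 50
    min_probes: int = 5
    n_top_grid: Sequence[int] = tuple(range(1, 11))
    # stage toggles
    run_qc: bool = True
    run_dmp: bool = True
    run_dmr: bool = True
    run_classify: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["steps"] = list(self.steps)
        d["covariates"] = list(self.covariates)
        d["n_top_grid"] = list(self.n_top_grid)
        return d

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record for one pipeline run (no wall-clock fields, so a
    rerun with the same config and seed is byte-identical)."""

    config: dict
    config_hash: str
    seed: int
    version: str
    checksums: Dict[str, str] = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add_file(self, path) -> None:
        p = Path(path)
        self.checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True))
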