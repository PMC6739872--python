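"""File I/O and pipeline configuration.

NIfTI-1 volumes via nibabel; paradigms, ratings, stimulus tables and
statistical outputs as tab-separated text with headers; configuration as
a single YAML file validated into a PipelineConfig.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .synthetic import Paradigm, RatingsTable


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def read_volume(path):
    """Load a NIfTI volume. Returns (data array, affine)."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine


def write_volume(data: np.ndarray, affine: np.ndarray | None, path) -> None:
    """Write a NIfTI-1 volume (default 3 mm isotropic affine)."""
    if affine is None:
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))


def default_affine(voxel_size_mm: float = 3.0) -> np.ndarray:
    return np.diag([voxel_size_mm] * 3 + [1.0])


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_paradigm(paradigm: Paradigm, path) -> None:
    write_table(paradigm.to_frame(), path)


def read_paradigm(path, tr: float, volumes_per_run: int) -> Paradigm:
    return Paradigm.from_frame(read_table(path), tr=tr,
                               volumes_per_run=volumes_per_run)


def write_ratings(ratings: RatingsTable, loc_path, scale_path) -> None:
    write_table(ratings.location_ratings, loc_path)
    write_table(ratings.scale_ratings, scale_path)


def read_ratings(loc_path, scale_path) -> RatingsTable:
    return RatingsTable(location_ratings=read_table(loc_path),
                        scale_ratings=read_table(scale_path))


def table_digest(frame: pd.DataFrame) -> str:
    """Stable sha256 digest of a table's TSV serialisation."""
    text = frame.to_csv(sep="\t", index=False)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset."""

    n_subjects: int = 6
    rating_subjects: int = 19   # behavioral cohort (imaging subjects first)
    n_runs: int = 2
    blocks_per_run: int = 24
    tr: float = 2.5
    grid_shape: tuple[int, int, int] = (12, 30, 12)
    voxel_size_mm: float = 3.0
    axis: int = 1                      # posterior->anterior = increasing Y
    gradient_region: list = dc_field(
        default_factory=lambda: [[2, 7], [3, 27], [3, 9]])
    control_region: list = dc_field(
        default_factory=lambda: [[8, 12], [3, 27], [3, 9]])
    amplitude: float = 1.0             # percent signal change
    width: float = 1.0                 # scale units
    jitter_sd: float = 0.3             # scale units
    subject_slope_sd: float = 0.005    # scale/mm, across subjects
    ar: tuple[float, float] = (0.3, 0.2)
    innovation_sd: float = 0.5
    drift_amplitude: float = 0.3
    drift_period_s: float = 128.0
    baseline: float = 100.0

    def region_mask(self, which: str) -> np.ndarray:
        spans = {"gradient": self.gradient_region,
                 "control": self.control_region}[which]
        m = np.zeros(tuple(self.grid_shape), dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = spans
        m[x0:x1, y0:y1, z0:z1] = True
        return m


@dataclass
class PipelineConfig:
    """Thresholds, seeds and data sources for a full analysis run."""

    seed: int = 11
    alpha_voxel: float = 0.01      # FDR level for the voxel ANOVA
    r2_gate: float = 0.7           # Gaussian-fit gate
    n_perm: int = 1000             # permutation shuffles
    cluster_min: int = 5           # volumetric cluster threshold (voxels)
    connectivity: int = 6
    q_regions: float = 0.05        # FDR level across gradients
    subject_alpha: float = 0.05    # FDR level across subjects
    intensity_threshold: float = 50.0
    era_volumes: int = 10
    hrf: dict = dc_field(default_factory=dict)
    synthetic: SyntheticConfig = dc_field(default_factory=SyntheticConfig)
    run_subject_level: bool = True
    paths: dict = dc_field(default_factory=dict)

    def validate(self) -> None:
        for name, val, lo, hi in [("alpha_voxel", self.alpha_voxel, 0, 1),
                                  ("r2_gate", self.r2_gate, 0, 1),
                                  ("q_regions", self.q_regions, 0, 1),
                                  ("subject_alpha", self.subject_alpha, 0, 1)]:
            if not (lo < val < hi):
                raise ValueError(f"{name} must lie in ({lo}, {hi}), "
                                 f"got {val}")
        if self.n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {self.n_perm}")
        if self.cluster_min < 1:
            raise ValueError("cluster_min must be >= 1")
        for key, p in self.paths.items():
            if p and not Path(p).exists():
                raise FileNotFoundError(f"configured path {key} = {p} does "
                                        "not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", {})
        if "grid_shape" in syn:
            syn["grid_shape"] = tuple(syn["grid_shape"])
        if "ar" in syn:
            syn["ar"] = tuple(syn["ar"])
        cfg = cls(**{**raw, "synthetic": SyntheticConfig(**syn)})
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        syn = dict(self.synthetic.__dict__)
        syn["grid_shape"] = list(syn["grid_shape"])
        syn["ar"] = list(syn["ar"])
        d["synthetic"] = syn
        return d
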