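"""Region-of-interest summaries and parcellation overlap.

Per-scale group betas within externally supplied masks (scene-selective
regions, hippocampus, gradient segments), event-related averages of the
percent-signal-change time course following block onsets, and the
percent overlap of an activation with each label of a network
parcellation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glm as glm_mod

N_SCALES = 6


@dataclass
class RoiScaleSummary:
    """Group per-scale betas in a region: subject-mean first, then the
    across-subject mean and SE."""

    region: str
    mean: np.ndarray       # (6,)
    se: np.ndarray         # (6,)
    n: int
    subject_means: np.ndarray   # (n, 6)


def roi_betas(subject_beta_maps: list[np.ndarray], mask: np.ndarray,
              region_name: str = "") -> RoiScaleSummary:
    """Region-of-interest random-effects summary.

    Per subject, betas are averaged over the mask's voxels per scale;
    the across-subject mean and SE summarise the group.
    ``subject_beta_maps``: per subject (x, y, z, 6).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"mask for region {region_name!r} selects no voxels")
    per_subject = np.stack([np.asarray(b, dtype=float)[mask].mean(axis=0)
                            for b in subject_beta_maps])
    n = per_subject.shape[0]
    mean = per_subject.mean(axis=0)
    se = (per_subject.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 \
        else np.zeros(N_SCALES)
    return RoiScaleSummary(region=region_name, mean=mean, se=se, n=n,
                           subject_means=per_subject)


def event_related_average(bold_runs: list[np.ndarray], paradigm,
                          mask: np.ndarray, n_volumes: int = 10
                          ) -> np.ndarray:
    """Mean percent-signal-change course over ``n_volumes`` after each
    block onset, per scale, averaged over mask voxels, blocks and runs.

    Block onsets align to the nearest acquisition at or after the onset.
    Blocks whose window would run past the end of the run are dropped
    with a warning. Returns a (6, n_volumes) matrix.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no voxels")
    tr = paradigm.tr
    sums = np.zeros((N_SCALES, n_volumes))
    counts = np.zeros(N_SCALES, dtype=int)
    dropped = 0
    for run_idx, vol in enumerate(bold_runs):
        series = np.asarray(vol, dtype=float)[mask]      # (V, T)
        scaled, valid = glm_mod.percent_signal_change(series)
        course = scaled[valid].mean(axis=0)
        T = course.shape[0]
        for b in paradigm.blocks:
            if b.run != run_idx:
                continue
            start = int(np.ceil(b.onset / tr - 1e-9))
            if start + n_volumes > T:
                dropped += 1
                continue
            sums[b.scale - 1] += course[start:start + n_volumes]
            counts[b.scale - 1] += 1
    if dropped:
        warnings.warn(f"dropped {dropped} block(s) with truncated "
                      f"{n_volumes}-volume windows", stacklevel=2)
    if (counts == 0).any():
        warnings.warn("some scales contributed no blocks", stacklevel=2)
    with np.errstate(invalid="ignore"):
        return sums / np.where(counts > 0, counts, 1)[:, None]


def network_overlap(region: np.ndarray, parcellation: np.ndarray
                    ) -> pd.DataFrame:
    """Percent of a region's voxels falling in each parcellation label.

    Label 0 counts as unassigned. Percentages sum to 100 over labels plus
    the unassigned remainder.
    """
    region = np.asarray(region, dtype=bool)
    parc = np.asarray(parcellation)
    if region.shape != parc.shape:
        raise ValueError(f"region grid {region.shape} does not match "
                         f"parcellation grid {parc.shape}")
    total = int(region.sum())
    if total == 0:
        raise ValueError("region mask selects no voxels")
    labels_in = parc[region]
    rows = []
    for label in np.unique(parc):
        n = int((labels_in == label).sum())
        rows.append({"label": int(label),
                     "n_voxels": n,
                     "percent": 100.0 * n / total,
                     "assigned": label != 0})
    return pd.DataFrame(rows)
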