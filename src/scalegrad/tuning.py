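"""Identification and characterisation of scale-sensitive voxels.

A voxel is scale-sensitive when a repeated-measures ANOVA across its six
condition betas (subjects as the repeated factor) survives BH-FDR
correction over the analysis mask. Selected voxels are characterised two
ways: a bounded Gaussian tuning fit to the min-subtracted beta profile
(continuous preferred scale = the fitted center) and the ordinal scale of
maximal activity. Small isolated clusters can be removed with a
volumetric connected-component threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats
from statsmodels.stats.multitest import multipletests

N_SCALES = 6
SCALE_AXIS = np.arange(1, N_SCALES + 1, dtype=float)

#: Fit bounds: amplitude 0-100, center -100-100, width 0-100 (lower width
#: bound nudged off zero for numerical stability).
TUNING_BOUNDS = (np.array([0.0, -100.0, 1e-3]),
                 np.array([100.0, 100.0, 100.0]))
R2_GATE = 0.7


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova_scale(betas: np.ndarray):
    """Single-factor repeated-measures ANOVA over the six scale betas.

    ``betas``: (n_subjects, 6) or (n_subjects, V, 6) for many voxels at
    once. F = MS_condition / MS_(condition x subject), df (5, 5(n-1)).
    Returns (F, p); a voxel with no variance at all reports F=0, p=1.
    """
    B = np.asarray(betas, dtype=float)
    squeeze = B.ndim == 2
    if squeeze:
        B = B[:, None, :]
    n, V, k = B.shape
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 subjects")
    if k != N_SCALES:
        raise ValueError(f"expected {N_SCALES} conditions, got {k}")
    if not np.isfinite(B).all():
        raise ValueError("missing or non-finite cells are not supported")

    grand = B.mean(axis=(0, 2), keepdims=True)
    cond_mean = B.mean(axis=0, keepdims=True)
    subj_mean = B.mean(axis=2, keepdims=True)
    ss_cond = n * ((cond_mean - grand) ** 2).sum(axis=(0, 2))
    ss_subj = k * ((subj_mean - grand) ** 2).sum(axis=(0, 2))
    ss_tot = ((B - grand) ** 2).sum(axis=(0, 2))
    ss_err = np.maximum(ss_tot - ss_cond - ss_subj, 0.0)
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ms_err > 0, ms_cond / np.where(ms_err > 0, ms_err, 1.0),
                     np.where(ms_cond > 0, np.inf, 0.0))
    p = stats.f.sf(F, df_cond, df_err)
    p = np.where(F == 0, 1.0, p)
    if squeeze:
        return float(F[0]), float(p[0])
    return F, p


def fdr_bh(pvals: np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg step-up: returns (adjusted q-values, selected)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    selected, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, selected


# ---------------------------------------------------------------------------
# Gaussian tuning fits
# ---------------------------------------------------------------------------

@dataclass
class VoxelTuningFit:
    """Bounded Gaussian fit to a voxel's six condition betas.

    ``peak_scale`` is the fitted center clipped into the scale range
    [1, 6]; ``max_scale`` the ordinal argmax of the raw vector (ties to
    the lowest index); ``passes_gate`` requires a successful fit with
    r-squared above the gate.
    """

    amplitude: float
    center: float
    width: float
    r2: float
    peak_scale: float
    max_scale: int
    passes_gate: bool
    success: bool


def _gauss(params: np.ndarray, s: np.ndarray) -> np.ndarray:
    a, c, w = params
    return a * np.exp(-(s - c) ** 2 / (2.0 * w ** 2))


def _gauss_jac(params: np.ndarray, s: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, c, w = params
    e = np.exp(-(s - c) ** 2 / (2.0 * w ** 2))
    d_a = e
    d_c = a * e * (s - c) / w ** 2
    d_w = a * e * (s - c) ** 2 / w ** 3
    return np.column_stack([d_a, d_c, d_w])


def fit_gaussian_tuning(betas: np.ndarray, r2_gate: float = R2_GATE
                        ) -> VoxelTuningFit:
    """Fit amplitude * exp(-(s - center)^2 / (2 width^2)) to the
    min-subtracted beta vector at s = 1..6.

    Bounded nonlinear least squares with multi-start (center initialised
    at each scale) to avoid local minima for boundary-tuned voxels.
    r-squared is 1 - SS_res/SS_tot against the min-subtracted vector; a
    flat vector has undefined r-squared and fails the gate.
    """
    b = np.asarray(betas, dtype=float)
    if b.shape != (N_SCALES,) or not np.isfinite(b).all():
        raise ValueError(f"expected {N_SCALES} finite beta values")
    ms = int(np.argmax(b)) + 1
    y = b - b.min()
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot <= 0:
        return VoxelTuningFit(amplitude=0.0, center=np.nan, width=np.nan,
                              r2=np.nan, peak_scale=np.nan, max_scale=ms,
                              passes_gate=False, success=False)

    lo, hi = TUNING_BOUNDS
    a0 = float(np.clip(y.max(), 1e-3, hi[0]))
    best = None
    for c0 in SCALE_AXIS:
        try:
            res = optimize.least_squares(
                lambda p: _gauss(p, SCALE_AXIS) - y,
                x0=np.array([a0, c0, 1.0]),
                jac=lambda p: _gauss_jac(p, SCALE_AXIS, y),
                bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return VoxelTuningFit(amplitude=np.nan, center=np.nan, width=np.nan,
                              r2=np.nan, peak_scale=np.nan, max_scale=ms,
                              passes_gate=False, success=False)
    a, c, w = best.x
    ss_res = 2.0 * best.cost
    r2 = 1.0 - ss_res / ss_tot
    return VoxelTuningFit(amplitude=float(a), center=float(c), width=float(w),
                          r2=float(r2),
                          peak_scale=float(np.clip(c, 1.0, N_SCALES)),
                          max_scale=ms, passes_gate=bool(r2 > r2_gate),
                          success=True)


def fit_gaussian_tuning_map(betas: np.ndarray, r2_gate: float = R2_GATE):
    """Vectorised wrapper: fit every row of a (V, 6) beta matrix.

    Returns a dict of arrays (amplitude, center, width, r2, peak_scale,
    max_scale, passes_gate, success).
    """
    B = np.atleast_2d(np.asarray(betas, dtype=float))
    fits = [fit_gaussian_tuning(row, r2_gate=r2_gate) for row in B]
    return {
        "amplitude": np.array([f.amplitude for f in fits]),
        "center": np.array([f.center for f in fits]),
        "width": np.array([f.width for f in fits]),
        "r2": np.array([f.r2 for f in fits]),
        "peak_scale": np.array([f.peak_scale for f in fits]),
        "max_scale": np.array([f.max_scale for f in fits]),
        "passes_gate": np.array([f.passes_gate for f in fits]),
        "success": np.array([f.success for f in fits]),
    }


def max_scale(betas: np.ndarray) -> int | np.ndarray:
    """Ordinal scale of maximal activity; ties break to the lowest index."""
    b = np.asarray(betas, dtype=float)
    if not np.isfinite(b).all():
        raise ValueError("betas must be finite")
    return (np.argmax(b, axis=-1) + 1) if b.ndim > 1 else int(np.argmax(b)) + 1


# ---------------------------------------------------------------------------
# Cluster thresholding
# ---------------------------------------------------------------------------

@dataclass
class SelectivityMask:
    """Voxelwise scale-sensitivity statistics on the 3D grid."""

    F: np.ndarray
    p: np.ndarray
    q: np.ndarray
    selected: np.ndarray          # bool
    cluster_labels: np.ndarray | None = None


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def apply_cluster_threshold(selected: np.ndarray, min_voxels: int = 5,
                            connectivity: int = 6):
    """Drop connected components smaller than ``min_voxels``.

    ``connectivity`` is the 3D neighbourhood rule (6 faces, 18 +edges,
    26 +corners). Returns (filtered bool mask, cluster label volume with
    labels 1..k on surviving clusters).
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"unknown connectivity {connectivity}; "
                         f"use one of {sorted(_CONNECTIVITY)}")
    sel = np.asarray(selected, dtype=bool)
    structure = ndimage.generate_binary_structure(sel.ndim,
                                                  _CONNECTIVITY[connectivity])
    labels, n = ndimage.label(sel, structure=structure)
    if n == 0:
        return sel.copy(), labels
    sizes = ndimage.sum_labels(sel, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_voxels) + 1
    out = np.isin(labels, keep)
    relabel = np.zeros(n + 1, dtype=int)
    relabel[keep] = np.arange(1, len(keep) + 1)
    return out, relabel[labels]


def select_scale_sensitive(subject_betas: list[np.ndarray],
                           analysis_mask: np.ndarray,
                           alpha: float = 0.01, cluster_min: int = 5,
                           connectivity: int = 6) -> SelectivityMask:
    """Full voxel-selection path: RM-ANOVA over the analysis mask, BH-FDR
    at ``alpha``, volumetric cluster threshold.

    ``subject_betas``: per subject (x, y, z, 6) beta maps.
    """
    mask = np.asarray(analysis_mask, dtype=bool)
    stack = np.stack([b[mask] for b in subject_betas])   # (n, V, 6)
    F, p = rm_anova_scale(stack)
    q, sel = fdr_bh(p, q=alpha)
    shape = mask.shape
    F3 = np.full(shape, np.nan)
    p3 = np.full(shape, np.nan)
    q3 = np.full(shape, np.nan)
    s3 = np.zeros(shape, dtype=bool)
    F3[mask], p3[mask], q3[mask], s3[mask] = F, p, q, sel
    filtered, labels = apply_cluster_threshold(s3, min_voxels=cluster_min,
                                               connectivity=connectivity)
    return SelectivityMask(F=F3, p=p3, q=q3, selected=filtered,
                           cluster_labels=labels)
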