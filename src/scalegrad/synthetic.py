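"""Synthetic data with the statistical structure the analysis assumes.

Generates randomized block paradigms (6 spatial-scale conditions), ground
truth voxel tuning fields whose preferred scale drifts linearly along an
anatomical axis, simulated BOLD runs with AR-correlated noise, behavioral
ratings with target scale correlations, and nested geographic stimulus
sets whose inter-item distances grow log-linearly with scale.

Every generator is a pure function of its seed, and the BOLD simulator
uses the same Gaussian tuning form and HRF convolution the analysis
assumes, so downstream estimators can be validated closed-loop against
known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from . import glm

N_SCALES = 6
SCALE_NAMES = ["room", "building", "neighborhood", "city", "country",
               "continent"]

#: Block timing (s): 2.5 s target + 4 x 2.5 s comparison pairs, then fixation.
TARGET_DURATION = 2.5
COMPARISON_DURATION = 2.5
BLOCK_DURATION = TARGET_DURATION + 4 * COMPARISON_DURATION   # 12.5 s
FIXATION_DURATION = 7.5
LEAD_IN = 10.0   # initial fixation before the first block
TAIL = 10.0      # trailing acquisition after the last block's fixation

KM_PER_DEG = np.pi * 6371.0 / 180.0


# ---------------------------------------------------------------------------
# Paradigm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    run: int
    onset: float
    duration: float
    scale: int        # 1..6 (room .. continent)
    location: int
    task: str         # "spatial" | "lexical"


@dataclass
class Paradigm:
    """Randomized block design: equal per-scale block counts in each run."""

    n_runs: int
    tr: float
    volumes_per_run: int
    blocks: list[Block] = field(default_factory=list)

    @property
    def run_duration(self) -> float:
        return self.volumes_per_run * self.tr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(b.run, b.onset, b.duration, b.scale, b.location, b.task)
             for b in self.blocks],
            columns=["run", "onset", "duration", "scale", "location", "task"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, tr: float,
                   volumes_per_run: int) -> "Paradigm":
        blocks = [Block(int(r.run), float(r.onset), float(r.duration),
                        int(r.scale), int(r.location), str(r.task))
                  for r in frame.itertuples()]
        return cls(n_runs=len({b.run for b in blocks}), tr=tr,
                   volumes_per_run=volumes_per_run, blocks=blocks)

    def validate(self) -> None:
        for run in range(self.n_runs):
            rb = [b for b in self.blocks if b.run == run]
            onsets = [b.onset for b in rb]
            if not all(a < b for a, b in zip(onsets, onsets[1:])):
                raise ValueError(f"onsets not strictly increasing in run {run}")
            for b in rb:
                if b.onset + b.duration > self.run_duration + 1e-9:
                    raise ValueError(
                        f"block at {b.onset} s exceeds run length")
            counts = pd.Series([b.scale for b in rb]).value_counts()
            if counts.nunique() > 1:
                raise ValueError(f"unbalanced scales in run {run}: {dict(counts)}")


def generate_paradigm(n_runs: int = 4, blocks_per_run: int = 24,
                      tr: float = 2.5, seed: int = 0,
                      task: str = "spatial") -> Paradigm:
    """Randomized block paradigm with equal per-scale counts per run.

    Blocks last 12.5 s (target + four comparison pairs) and are separated
    by 7.5 s fixation; with the 24-block default each 200-volume run spans
    500 s at TR 2.5 s. Two locations per scale alternate across that
    scale's blocks.
    """
    if blocks_per_run % N_SCALES != 0:
        raise ValueError(
            f"blocks_per_run must be divisible by {N_SCALES} so each run is "
            f"scale-balanced; got {blocks_per_run}")
    rng = np.random.default_rng(seed)
    per_scale = blocks_per_run // N_SCALES
    volumes = int(np.ceil(
        (LEAD_IN + blocks_per_run * (BLOCK_DURATION + FIXATION_DURATION)
         + TAIL) / tr))
    blocks: list[Block] = []
    for run in range(n_runs):
        scales = np.repeat(np.arange(1, N_SCALES + 1), per_scale)
        order = rng.permutation(len(scales))
        scales = scales[order]
        # two locations per scale, alternating over that scale's blocks
        loc_counter = {s: 0 for s in range(1, N_SCALES + 1)}
        onset = LEAD_IN
        for s in scales:
            location = (s - 1) * 2 + 1 + (loc_counter[s] % 2)
            loc_counter[s] += 1
            blocks.append(Block(run=run, onset=onset, duration=BLOCK_DURATION,
                                scale=int(s), location=location, task=task))
            onset += BLOCK_DURATION + FIXATION_DURATION
    par = Paradigm(n_runs=n_runs, tr=tr, volumes_per_run=volumes,
                   blocks=blocks)
    par.validate()
    return par


# ---------------------------------------------------------------------------
# Ground-truth tuning fields
# ---------------------------------------------------------------------------

@dataclass
class TuningField:
    """Voxelwise ground-truth Gaussian tuning parameters on a 3D grid.

    Inside ``mask`` the tuning center is an affine function of the
    millimetre coordinate along ``axis`` plus bounded jitter, clipped to
    the scale range [1, 6]; outside, amplitude is zero (untuned voxels).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: float
    amplitude: np.ndarray
    center: np.ndarray
    width: np.ndarray
    mask: np.ndarray
    axis: int
    slope: float          # scale units per mm
    intercept: float

    def response(self) -> np.ndarray:
        """(V, 6) true per-scale response of every voxel (flattened grid)."""
        s = np.arange(1, N_SCALES + 1)
        a = self.amplitude.reshape(-1, 1)
        c = self.center.reshape(-1, 1)
        w = self.width.reshape(-1, 1)
        return a * np.exp(-(s - c) ** 2 / (2.0 * w ** 2))

    def truth_frame(self) -> pd.DataFrame:
        idx = np.arange(self.amplitude.size)
        return pd.DataFrame({
            "voxel": idx,
            "amplitude": self.amplitude.ravel(),
            "center": self.center.ravel(),
            "width": self.width.ravel(),
            "in_mask": self.mask.ravel().astype(int),
        })


def generate_tuning_field(shape: tuple[int, int, int],
                          gradient_mask: np.ndarray, axis: int = 1,
                          slope: float = 0.05, jitter_sd: float = 0.3,
                          seed: int = 0, intercept: float | None = None,
                          amplitude: float = 1.0, width: float = 1.0,
                          voxel_size_mm: float = 3.0) -> TuningField:
    """Ground-truth field whose tuning center drifts along one axis.

    ``slope`` is in scale units per millimetre along ``axis``. When
    ``intercept`` is None it is chosen so the noise-free centers span the
    mask extent symmetrically around scale 3.5. Centers are clipped to
    [1, 6]; voxels outside the mask are untuned (amplitude 0).
    """
    gradient_mask = np.asarray(gradient_mask, dtype=bool)
    if gradient_mask.shape != tuple(shape):
        raise ValueError("mask shape does not match grid shape")
    if not gradient_mask.any():
        raise ValueError("gradient mask is empty")
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    rng = np.random.default_rng(seed)
    coords_mm = np.indices(shape)[axis] * voxel_size_mm
    axis_vals = coords_mm[gradient_mask]
    if intercept is None:
        intercept = 3.5 - slope * (axis_vals.min() + axis_vals.max()) / 2.0

    center = np.full(shape, np.nan)
    amp = np.zeros(shape)
    wid = np.full(shape, width, dtype=float)
    jitter = rng.normal(0.0, jitter_sd, size=int(gradient_mask.sum())) \
        if jitter_sd > 0 else np.zeros(int(gradient_mask.sum()))
    center[gradient_mask] = np.clip(
        intercept + slope * axis_vals + jitter, 1.0, N_SCALES)
    amp[gradient_mask] = amplitude
    center[~gradient_mask] = 3.5   # irrelevant: amplitude 0
    return TuningField(shape=tuple(shape), voxel_size_mm=voxel_size_mm,
                       amplitude=amp, center=center, width=wid,
                       mask=gradient_mask, axis=axis, slope=slope,
                       intercept=float(intercept))


def merge_fields(base: TuningField, other: TuningField) -> TuningField:
    """Overlay ``other``'s tuned voxels onto ``base`` (disjoint masks)."""
    if base.shape != other.shape:
        raise ValueError("field shapes differ")
    out = TuningField(shape=base.shape, voxel_size_mm=base.voxel_size_mm,
                      amplitude=base.amplitude.copy(),
                      center=base.center.copy(), width=base.width.copy(),
                      mask=base.mask | other.mask, axis=base.axis,
                      slope=base.slope, intercept=base.intercept)
    m = other.mask
    out.amplitude[m] = other.amplitude[m]
    out.center[m] = other.center[m]
    out.width[m] = other.width[m]
    return out


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """AR(2) noise plus a low-frequency cosine drift over a positive baseline."""

    ar: tuple[float, float] = (0.3, 0.2)
    innovation_sd: float = 1.0
    drift_amplitude: float = 0.0
    drift_period_s: float = 128.0
    baseline: float = 100.0

    def validate(self) -> None:
        a1, a2 = self.ar
        # stationarity triangle for AR(2)
        if not (abs(a2) < 1 and a1 + a2 < 1 and a2 - a1 < 1):
            raise ValueError(f"AR coefficients {self.ar} are non-stationary")
        if self.baseline <= 0:
            raise ValueError("baseline intensity must be positive")


def simulate_bold(paradigm: Paradigm, field: TuningField, noise: NoiseSpec,
                  seed: int = 0, hrf_params: dict | None = None
                  ) -> list[np.ndarray]:
    """Simulate one 4D volume series (x, y, z, t) per run.

    Each voxel's series is baseline * (1 + sum_s r_s/100 * c_s(t)) + drift
    + AR(2) noise, where r_s is the voxel's Gaussian tuning response to
    scale s (percent-signal-change units) and c_s is the HRF-convolved
    boxcar for scale s, centered within the run. Centering makes the
    noise-free run mean exactly the baseline, so the percent-signal-change
    transform followed by the GLM recovers r_s to machine precision.
    """
    noise.validate()
    rng = np.random.default_rng(seed)
    design = glm.build_design_matrix(paradigm, hrf_params=hrf_params)
    resp = field.response()                         # (V, 6)
    V = resp.shape[0]
    nvol = paradigm.volumes_per_run
    t_run = np.arange(nvol) * paradigm.tr
    drift = noise.drift_amplitude * np.cos(2 * np.pi * t_run
                                           / noise.drift_period_s)
    runs_out = []
    for run in range(paradigm.n_runs):
        rows = design.runs == run
        X = design.matrix[rows][:, design.task_indices]   # (T, 6)
        Xc = X - X.mean(axis=0)
        task = resp @ Xc.T / 100.0                        # (V, T) fractional
        series = noise.baseline * (1.0 + task) + drift
        if noise.innovation_sd > 0:
            innov = rng.normal(0.0, noise.innovation_sd, size=(V, nvol))
            a1, a2 = noise.ar
            ar_noise = sp_signal.lfilter([1.0], [1.0, -a1, -a2], innov,
                                         axis=1)
            series = series + ar_noise
        runs_out.append(series.reshape(field.shape + (nvol,)))
    return runs_out


# ---------------------------------------------------------------------------
# Geographic stimulus sets
# ---------------------------------------------------------------------------

#: Default per-scale scatter (km) for neighborhood, city, country, continent.
DEFAULT_DISPERSION_KM = (0.5, 10.0, 500.0, 5000.0)
GEO_SCALES = (3, 4, 5, 6)


def generate_geo_stimuli(locations_per_scale: int = 2,
                         items_per_location: int = 8,
                         dispersion_km=DEFAULT_DISPERSION_KM,
                         seed: int = 0) -> pd.DataFrame:
    """Nested geographic stimulus sets for scales 3-6.

    Items scatter around a random center: each item lies at a Rayleigh
    distributed great-circle distance (scale = the per-scale dispersion)
    along a uniform random bearing, via the spherical destination-point
    formula — equivalent to isotropic Gaussian tangent-plane offsets at
    small dispersion and correct on the sphere at continental dispersion.
    Mean log pairwise distance grows with scale when dispersions do.
    Returns a table (scale, location, item, lat, lon) in decimal degrees.
    """
    if items_per_location < 2:
        raise ValueError("need at least 2 items per location for pairwise "
                         "distances")
    dispersion_km = np.asarray(dispersion_km, dtype=float)
    if len(dispersion_km) != len(GEO_SCALES):
        raise ValueError(f"one dispersion per scale {GEO_SCALES} required")
    if not (np.all(dispersion_km > 0)
            and np.all(np.diff(dispersion_km) > 0)):
        raise ValueError("dispersions must be positive and increasing with "
                         "scale")
    rng = np.random.default_rng(seed)
    rows = []
    loc_id = 0
    for scale, disp in zip(GEO_SCALES, dispersion_km):
        for _ in range(locations_per_scale):
            loc_id += 1
            clat = np.deg2rad(rng.uniform(-60.0, 60.0))
            clon = np.deg2rad(rng.uniform(-180.0, 180.0))
            delta = rng.rayleigh(disp, items_per_location) / 6371.0
            theta = rng.uniform(0.0, 2 * np.pi, items_per_location)
            lat_r = np.arcsin(np.sin(clat) * np.cos(delta)
                              + np.cos(clat) * np.sin(delta) * np.cos(theta))
            lon_r = clon + np.arctan2(
                np.sin(theta) * np.sin(delta) * np.cos(clat),
                np.cos(delta) - np.sin(clat) * np.sin(lat_r))
            lat = np.rad2deg(lat_r)
            lon = (np.rad2deg(lon_r) + 180.0) % 360.0 - 180.0
            for item in range(items_per_location):
                rows.append((scale, loc_id, item, lat[item], lon[item]))
    return pd.DataFrame(rows, columns=["scale", "location", "item", "lat",
                                       "lon"])


# ---------------------------------------------------------------------------
# Behavioral ratings
# ---------------------------------------------------------------------------

LOCATION_MEASURES = ("familiarity", "emotion", "difficulty")
SCALE_MEASURES = ("first_person", "third_person", "strategy_ground",
                  "strategy_map")

#: Target Pearson correlations of each measure with the scale index,
#: matching the reported behavioral effects: familiarity falls with scale
#: (r = -0.72), difficulty rises mildly (r = 0.39), first-person
#: perspective falls (r = -0.81) while third-person rises (r = 0.80).
DEFAULT_RATING_TARGETS = {
    "familiarity": -0.72,
    "emotion": 0.0,
    "difficulty": 0.39,
    "first_person": -0.81,
    "third_person": 0.80,
    "strategy_ground": -0.8,
    "strategy_map": 0.8,
}


@dataclass
class RatingsTable:
    """Per-subject ratings: location-level (familiarity/emotion/difficulty,
    1-7 per location) and scale-level (perspective and strategy, 1-7 per
    scale)."""

    location_ratings: pd.DataFrame   # subject, location, scale, <measures>
    scale_ratings: pd.DataFrame      # subject, scale, <measures>

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.location_ratings["subject"])

    @staticmethod
    def is_location_measure(measure: str) -> bool:
        if measure in LOCATION_MEASURES:
            return True
        if measure in SCALE_MEASURES:
            return False
        raise KeyError(f"unknown measure {measure!r}")

    def values_for(self, subject: int, measure: str) -> pd.DataFrame:
        """Subject's ratings of one measure with their scale index."""
        table = (self.location_ratings if self.is_location_measure(measure)
                 else self.scale_ratings)
        sub = table[table["subject"] == subject]
        cols = ["scale", measure] + (["location"]
                                     if "location" in sub.columns else [])
        return sub[cols].reset_index(drop=True)

    def z_scored(self, subject: int, measure: str) -> dict[int, float]:
        """Within-subject z-transform of one measure, keyed by location
        (location measures) or scale (scale measures). Zero-variance
        subjects map to all-zero weights."""
        sub = self.values_for(subject, measure)
        vals = sub[measure].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        key = "location" if self.is_location_measure(measure) else "scale"
        return dict(zip(sub[key].astype(int), z))


def generate_ratings(target_scale_correlations: dict[str, float] | None = None,
                     n_subjects: int = 19, seed: int = 0) -> RatingsTable:
    """Ratings whose expected correlation with scale matches each target.

    Each subject's rating of a measure is rho * z(scale) +
    sqrt(1 - rho^2) * noise, mapped affinely onto the 1-7 range (clipped);
    a target of +/-1 yields perfectly (anti-)ordered ratings.
    """
    targets = dict(DEFAULT_RATING_TARGETS)
    if target_scale_correlations:
        targets.update(target_scale_correlations)
    for m, rho in targets.items():
        if abs(rho) > 1:
            raise ValueError(f"target correlation for {m} must be in [-1, 1], "
                             f"got {rho}")
    rng = np.random.default_rng(seed)

    # 12 locations, two per scale, matching the paradigm's location ids
    loc_scale = np.repeat(np.arange(1, N_SCALES + 1), 2)
    locations = np.arange(1, 13)

    def draw(scales: np.ndarray, rho: float, per_scale: int = 1) -> np.ndarray:
        # For measures rated once per location, the analysis correlates the
        # per-scale mean with scale; averaging m same-scale locations damps
        # the noise, so the latent correlation is deflated to rho' with
        # rho'^2 = rho^2 / (m - rho^2 (m - 1)) to make the *analysed*
        # correlation match the target.
        m = per_scale
        rho_eff = np.sign(rho) * np.sqrt(rho ** 2 / (m - rho ** 2 * (m - 1)))
        z = (scales - scales.mean()) / scales.std()
        eps = rng.normal(0.0, 1.0, size=len(scales))
        u = rho_eff * z + np.sqrt(max(0.0, 1.0 - rho_eff ** 2)) * eps
        return np.clip(4.0 + 1.2 * u, 1.0, 7.0)

    loc_rows, scale_rows = [], []
    for subj in range(n_subjects):
        loc_vals = {m: draw(loc_scale.astype(float), targets[m], per_scale=2)
                    for m in LOCATION_MEASURES}
        for i, (loc, s) in enumerate(zip(locations, loc_scale)):
            loc_rows.append((subj, int(loc), int(s),
                             *(loc_vals[m][i] for m in LOCATION_MEASURES)))
        scales = np.arange(1, N_SCALES + 1, dtype=float)
        sc_vals = {m: draw(scales, targets[m]) for m in SCALE_MEASURES}
        for i, s in enumerate(scales):
            scale_rows.append((subj, int(s),
                               *(sc_vals[m][i] for m in SCALE_MEASURES)))
    loc_df = pd.DataFrame(loc_rows, columns=["subject", "location", "scale",
                                             *LOCATION_MEASURES])
    sc_df = pd.DataFrame(scale_rows, columns=["subject", "scale",
                                              *SCALE_MEASURES])
    return RatingsTable(location_ratings=loc_df, scale_ratings=sc_df)
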