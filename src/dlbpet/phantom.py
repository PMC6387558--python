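"""Synthetic brain phantoms for FDG-PET hypometabolism analysis.

This module builds a schematic 3-D "brain": an ellipsoidal tissue support
carrying a set of box-shaped parcels placed in anatomically plausible
relative positions (occipital parcels posterior, DLPFC anterior-superior,
posterior cingulate and precuneus medial).  On top of the atlas it
generates normative control scans and patient scans with disease-specific
regional uptake reductions, between-subject global-uptake variability and
voxel noise.  The geometry is deliberately schematic: only the topological
relations the downstream classification rules rely on (posterior vs
anterior, medial vs lateral, left vs right) are guaranteed.

Uptake model for a subject with global factor ``g`` and noise fraction
``s``::

    volume = g * template * (1 + s * N(0, 1))     inside the brain
    volume = 0                                    outside

so the noise standard deviation is a fixed fraction of local tissue
uptake and the global factor multiplies signal and noise alike (it must
cancel exactly under global mean scaling).
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROI_NAMES",
    "AUX_ROI_NAMES",
    "COMPOSITES",
    "AGE_REF",
    "AtlasROIs",
    "PatternTemplate",
    "CohortSpec",
    "SubjectScan",
    "make_atlas",
    "make_control",
    "make_patient",
    "make_cohort",
    "default_patterns",
]

#: The 14 analysis regions used for hallmark fractions and subtyping.
ROI_NAMES = (
    "calcarine",
    "cuneus",
    "superior_occipital",
    "middle_occipital",
    "inferior_occipital",
    "fusiform",
    "lingual",
    "inferior_temporal",
    "middle_temporal",
    "superior_temporal",
    "precuneus",
    "dlpfc",
    "posterior_cingulate",
    "angular",
)

#: Auxiliary parcels needed by the pattern rules but not part of the
#: 14-region feature set.
AUX_ROI_NAMES = ("parietal", "frontal_eye_field", "premotor_motor")

#: Composite regions used by the involvement rules.
COMPOSITES = {
    "occipital": (
        "calcarine",
        "cuneus",
        "superior_occipital",
        "middle_occipital",
        "inferior_occipital",
        "lingual",
    ),
    "temporo_parietal": (
        "inferior_temporal",
        "middle_temporal",
        "superior_temporal",
        "angular",
        "parietal",
        "fusiform",
    ),
    "pcc_precuneus": ("posterior_cingulate", "precuneus"),
    "dlpfc": ("dlpfc",),
    "frontal_eye_field": ("frontal_eye_field",),
    "premotor_motor": ("premotor_motor",),
}

#: Reference age (years) of the normative database; the optional age
#: effect on gray-matter uptake is expressed relative to this age.
AGE_REF = 64.68


@dataclass(frozen=True)
class AtlasROIs:
    """Labeled phantom atlas.

    ``masks`` maps every parcel name (14 analysis ROIs plus the auxiliary
    parcels) to a boolean volume; ``brain``, ``left`` and ``right`` are
    the tissue support and the two hemisphere masks.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: float
    masks: dict[str, np.ndarray]
    brain: np.ndarray
    left: np.ndarray
    right: np.ndarray

    def mask(self, name: str) -> np.ndarray:
        if name == "brain":
            return self.brain
        if name == "left_hemisphere":
            return self.left
        if name == "right_hemisphere":
            return self.right
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(f"unknown ROI {name!r}") from None

    def composite(self, names) -> np.ndarray:
        """Union of the named parcels (accepts a composite name too)."""
        if isinstance(names, str):
            names = COMPOSITES[names]
        out = np.zeros(self.shape, dtype=bool)
        for n in names:
            out |= self.mask(n)
        return out

    @property
    def gray_matter(self) -> np.ndarray:
        """Union of all parcels (the 'gray matter' of the phantom)."""
        return self.composite(list(self.masks))


@dataclass(frozen=True)
class SubjectScan:
    """One static uptake volume with its demographic metadata."""

    volume: np.ndarray
    voxel_size_mm: float
    age: float
    subject_id: str
    cohort: str
    pattern: str | None = None

    def with_volume(self, volume: np.ndarray) -> "SubjectScan":
        return dataclasses.replace(self, volume=volume)


@dataclass(frozen=True)
class PatternTemplate:
    """Regional uptake reductions defining one disease-like pattern.

    ``reductions`` maps ROI names to fractional uptake reductions in
    [0, 1).  If ``asymmetric`` the reductions are applied fully in the
    ``dominant`` hemisphere and divided by the cohort's asymmetry factor
    in the other one.
    """

    reductions: dict[str, float]
    asymmetric: bool = False
    dominant: str = "left"
    age_mean: float = AGE_REF
    age_sd: float = 9.35


def default_patterns() -> dict[str, PatternTemplate]:
    """Disease-specific templates at the package's default severities.

    Topographies: DLB-like = medial and lateral occipital plus
    temporo-parietal and frontal (DLPFC) involvement with a spared
    posterior cingulate; AD-like = bilateral temporo-parietal plus
    posterior cingulate/precuneus without occipital involvement;
    PCA-like = asymmetric posterior (occipital + temporo-parietal)
    hypometabolism with frontal-eye-field foci and no DLPFC involvement;
    PD-like = reductions confined to premotor/motor cortex.
    """
    tp = ("inferior_temporal", "middle_temporal", "superior_temporal",
          "angular", "parietal", "fusiform")
    occ = COMPOSITES["occipital"]
    dlb = {r: 0.25 for r in occ}
    dlb.update({r: 0.20 for r in tp})
    dlb["precuneus"] = 0.20
    dlb["dlpfc"] = 0.15
    add = {r: 0.25 for r in ("inferior_temporal", "middle_temporal",
                             "superior_temporal", "angular", "parietal")}
    add["posterior_cingulate"] = 0.25
    add["precuneus"] = 0.25
    pca = {r: 0.30 for r in occ}
    pca.update({r: 0.20 for r in tp})
    pca["frontal_eye_field"] = 0.25
    pd_ = {"premotor_motor": 0.25}
    return {
        "DLB": PatternTemplate(dlb, age_mean=72.4, age_sd=7.5),
        "ADD": PatternTemplate(add, age_mean=68.87, age_sd=6.28),
        "PCA": PatternTemplate(pca, asymmetric=True,
                               age_mean=68.87, age_sd=6.28),
        "PD": PatternTemplate(pd_, age_mean=62.47, age_sd=10.91),
    }


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults mirror the clinical series the pipeline is meant to emulate:
    112 normative controls aged 64.68 +/- 9.35 years, 72 DLB-like
    patients, 60 AD-like patients of whom 5 carry the posterior cortical
    atrophy variant, and 36 PD-like patients.
    """

    n_controls: int = 112
    n_patients: dict[str, int] = field(
        default_factory=lambda: {"DLB": 72, "ADD": 55, "PCA": 5, "PD": 36})
    control_age_mean: float = AGE_REF
    control_age_sd: float = 9.35
    patterns: dict[str, PatternTemplate] = field(default_factory=default_patterns)
    global_log_sd: float = 0.2
    noise_sd: float = 0.05
    asymmetry_factor: float = 8.0
    age_slope: float = 0.0
    gm_elevation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 0 or any(v < 0 for v in self.n_patients.values()):
            raise ValueError("cohort counts must be >= 0")
        for name, tmpl in self.patterns.items():
            for roi, r in tmpl.reductions.items():
                if not 0.0 <= r < 1.0:
                    raise ValueError(
                        f"reduction for {roi!r} in pattern {name!r} must be "
                        f"in [0, 1), got {r}")
        if self.asymmetry_factor < 1.0:
            raise ValueError("asymmetry_factor must be >= 1")


# ---------------------------------------------------------------------------
# Atlas construction
# ---------------------------------------------------------------------------

# Parcel layout in fractional grid coordinates.  x runs left->right
# (mirror axis), y posterior->anterior, z inferior->superior.  Lateral
# parcels are defined as a left-hemisphere box plus its mirror image;
# medial parcels straddle the midline symmetrically.  Bands are separated
# by >= 2-voxel gutters at the default 40x48x40 grid so that smoothing
# does not bleed a planted effect into a neighbouring composite.
_LATERAL_X = (0.125, 0.30)        # fraction of nx, left band (mirrored right)
_MEDIAL_HALFWIDTH = 0.0875        # fraction of nx, half-width about midline

_Y = {
    "occ": (0.0625, 0.1667),      # occipital band
    "post": (0.2292, 0.3333),     # posterior parietal / limbic band
    "temp": (0.3958, 0.5417),     # temporal / superior parietal band
    "premot": (0.6042, 0.7083),   # premotor / FEF band
    "front": (0.75, 0.8542),      # prefrontal band
}
_Z = {
    "low": (0.20, 0.325),
    "mid": (0.40, 0.525),
    "high": (0.60, 0.725),
    "dlpfc": (0.45, 0.60),
}

# name -> (medial?, y band, z band)
_LAYOUT = {
    "lingual": (True, "occ", "low"),
    "calcarine": (True, "occ", "mid"),
    "cuneus": (True, "occ", "high"),
    "inferior_occipital": (False, "occ", "low"),
    "middle_occipital": (False, "occ", "mid"),
    "superior_occipital": (False, "occ", "high"),
    "fusiform": (False, "post", "low"),
    "posterior_cingulate": (True, "post", "mid"),
    "precuneus": (True, "post", "high"),
    "angular": (False, "post", "high"),
    "inferior_temporal": (False, "temp", "low"),
    "middle_temporal": (False, "temp", "mid"),
    "superior_temporal": (False, "temp", "high"),
    "parietal": (True, "temp", "high"),
    "frontal_eye_field": (False, "premot", "mid"),
    "premotor_motor": (True, "premot", "high"),
    "dlpfc": (False, "front", "dlpfc"),
}

_MIN_ROI_VOXELS = 20


def _axis_range(frac_lo: float, frac_hi: float, n: int) -> tuple[int, int]:
    return int(round(frac_lo * n)), int(round(frac_hi * n))


def make_atlas(grid_shape=(40, 48, 40), voxel_size_mm: float = 4.0) -> AtlasROIs:
    """Build the deterministic phantom atlas.

    Raises ``ValueError`` naming the offending parcel if the grid is too
    small to host every parcel with at least 20 in-brain voxels, or if
    rounding makes two parcels collide.
    """
    nx, ny, nz = grid_shape
    if min(grid_shape) < 24:
        raise ValueError(
            f"cannot place ROIs: grid {grid_shape} is below the minimum of "
            "24 voxels per axis")

    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    brain = (((ii - cx) / (0.425 * nx)) ** 2
             + ((jj - cy) / (0.458 * ny)) ** 2
             + ((kk - cz) / (0.425 * nz)) ** 2) <= 1.0
    left = brain & (ii < cx)
    right = brain & (ii > cx)
    # odd nx would put one column exactly on the midline; exclude it from
    # both hemispheres so they stay disjoint and mirror-symmetric.

    x_lat_lo, x_lat_hi = _axis_range(*_LATERAL_X, nx)
    half_w = _MEDIAL_HALFWIDTH * nx

    masks: dict[str, np.ndarray] = {}
    occupancy = np.zeros(grid_shape, dtype=np.int16)
    for name, (medial, yb, zb) in _LAYOUT.items():
        y_lo, y_hi = _axis_range(*_Y[yb], ny)
        z_lo, z_hi = _axis_range(*_Z[zb], nz)
        box_yz = (jj >= y_lo) & (jj <= y_hi) & (kk >= z_lo) & (kk <= z_hi)
        if medial:
            box = box_yz & (np.abs(ii - cx) <= half_w)
        else:
            lat = (ii >= x_lat_lo) & (ii <= x_lat_hi)
            lat |= (ii >= nx - 1 - x_lat_hi) & (ii <= nx - 1 - x_lat_lo)
            box = box_yz & lat
        roi = box & brain
        if roi.sum() < _MIN_ROI_VOXELS:
            raise ValueError(
                f"cannot place ROIs: {name!r} has only {int(roi.sum())} "
                f"in-brain voxels (< {_MIN_ROI_VOXELS}) on grid {grid_shape}")
        occupancy += roi
        masks[name] = roi
    if occupancy.max() > 1:
        clash = [n for n, m in masks.items()
                 if (m & (occupancy > 1)).any()]
        raise ValueError(f"cannot place ROIs: parcels overlap: {clash}")

    return AtlasROIs(shape=tuple(grid_shape), voxel_size_mm=float(voxel_size_mm),
                     masks=masks, brain=brain, left=left, right=right)


# ---------------------------------------------------------------------------
# Scan synthesis
# ---------------------------------------------------------------------------

def template_volume(atlas: AtlasROIs, age: float, *, age_slope: float = 0.0,
                    gm_elevation: float = 0.0) -> np.ndarray:
    """Noise-free tissue template: 1.0 inside the brain, gray-matter
    parcels optionally elevated and linearly modulated by age.

    The age effect is regional (gray matter only) so that it survives
    global mean scaling and genuinely exercises the nuisance covariate.
    """
    vol = np.where(atlas.brain, 1.0, 0.0)
    if gm_elevation or age_slope:
        gm = atlas.gray_matter
        factor = (1.0 + gm_elevation) * (1.0 + age_slope * (age - AGE_REF))
        vol[gm] *= factor
    return vol


def _finalize(template: np.ndarray, atlas: AtlasROIs, rng: np.random.Generator,
              global_factor: float | None, global_log_sd: float,
              noise_sd: float) -> np.ndarray:
    if global_factor is None:
        global_factor = float(np.exp(rng.normal(0.0, global_log_sd)))
    vol = template.copy()
    if noise_sd > 0:
        vol = vol * (1.0 + noise_sd * rng.standard_normal(vol.shape))
    vol *= global_factor
    # keep in-brain voxels strictly positive (noise tail guard)
    vol[atlas.brain] = np.maximum(vol[atlas.brain], 1e-6)
    vol[~atlas.brain] = 0.0
    return vol


def make_control(atlas: AtlasROIs, age: float, seed, *,
                 noise_sd: float = 0.05, global_log_sd: float = 0.2,
                 global_factor: float | None = None, age_slope: float = 0.0,
                 gm_elevation: float = 0.0,
                 subject_id: str = "control") -> SubjectScan:
    """Draw one normative control scan."""
    if age <= 0:
        raise ValueError("age must be positive")
    rng = np.random.default_rng(seed)
    tmpl = template_volume(atlas, age, age_slope=age_slope,
                           gm_elevation=gm_elevation)
    vol = _finalize(tmpl, atlas, rng, global_factor, global_log_sd, noise_sd)
    return SubjectScan(vol, atlas.voxel_size_mm, float(age), subject_id,
                       "control")


def patient_template(atlas: AtlasROIs, template: PatternTemplate, age: float, *,
                     asymmetry_factor: float = 8.0, age_slope: float = 0.0,
                     gm_elevation: float = 0.0) -> np.ndarray:
    """Noise-free patient template: control template with each pattern
    ROI multiplied by (1 - reduction), hemisphere-weighted if the pattern
    is asymmetric."""
    vol = template_volume(atlas, age, age_slope=age_slope,
                          gm_elevation=gm_elevation)
    for roi, r in template.reductions.items():
        m = atlas.mask(roi)
        if template.asymmetric:
            dom = atlas.left if template.dominant == "left" else atlas.right
            other = atlas.right if template.dominant == "left" else atlas.left
            vol[m & dom] *= 1.0 - r
            vol[m & other] *= 1.0 - r / asymmetry_factor
        else:
            vol[m] *= 1.0 - r
    return vol


def make_patient(atlas: AtlasROIs, pattern_name: str, spec: CohortSpec,
                 age: float, seed, *, subject_id: str = "patient") -> SubjectScan:
    """Draw one patient scan with the named disease pattern."""
    if pattern_name not in spec.patterns:
        raise KeyError(f"unknown pattern {pattern_name!r}; "
                       f"available: {sorted(spec.patterns)}")
    if age <= 0:
        raise ValueError("age must be positive")
    rng = np.random.default_rng(seed)
    tmpl = patient_template(atlas, spec.patterns[pattern_name], age,
                            asymmetry_factor=spec.asymmetry_factor,
                            age_slope=spec.age_slope,
                            gm_elevation=spec.gm_elevation)
    vol = _finalize(tmpl, atlas, rng, None, spec.global_log_sd, spec.noise_sd)
    return SubjectScan(vol, atlas.voxel_size_mm, float(age), subject_id,
                       pattern_name, pattern=pattern_name)


def _truncated_normal_age(rng, mean, sd, low=18.0):
    while True:
        a = rng.normal(mean, sd)
        if a > low:
            return float(a)


def make_cohort(spec: CohortSpec, atlas: AtlasROIs | None = None):
    """Generate the full synthetic cohort.

    Returns ``(controls, patients, metadata)`` where metadata is a
    DataFrame with columns subject_id, age, cohort, pattern, seed.  Fully
    reproducible from ``spec.seed``.
    """
    if atlas is None:
        atlas = make_atlas()
    root = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_pat = sum(spec.n_patients.values())
    subj_seeds = root.integers(0, 2**31, size=spec.n_controls + n_pat)
    age_rng = np.random.default_rng(root.integers(0, 2**31))

    controls, patients, rows = [], [], []
    idx = 0
    for i in range(spec.n_controls):
        sid = f"c{i + 1:03d}"
        age = _truncated_normal_age(age_rng, spec.control_age_mean,
                                    spec.control_age_sd)
        scan = make_control(atlas, age, int(subj_seeds[idx]),
                            noise_sd=spec.noise_sd,
                            global_log_sd=spec.global_log_sd,
                            age_slope=spec.age_slope,
                            gm_elevation=spec.gm_elevation, subject_id=sid)
        controls.append(scan)
        rows.append((sid, age, "control", "", int(subj_seeds[idx])))
        idx += 1
    j = 0
    for pattern in spec.n_patients:
        tmpl = spec.patterns[pattern]
        for _ in range(spec.n_patients[pattern]):
            j += 1
            sid = f"p{j:03d}"
            age = _truncated_normal_age(age_rng, tmpl.age_mean, tmpl.age_sd)
            scan = make_patient(atlas, pattern, spec, age,
                                int(subj_seeds[idx]), subject_id=sid)
            patients.append(scan)
            rows.append((sid, age, pattern, pattern, int(subj_seeds[idx])))
            idx += 1

    meta = pd.DataFrame(rows, columns=["subject_id", "age", "cohort",
                                       "pattern", "seed"])
    return controls, patients, meta


def metadata_tsv(meta: pd.DataFrame) -> str:
    """Canonical TSV serialization of a cohort metadata table."""
    buf = _io.StringIO()
    meta.to_csv(buf, sep="\t", index=False, float_format="%.6f")
    return buf.getvalue()
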