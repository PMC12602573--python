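"""Experiment coordinate tables, stereotaxic spaces, and the analysis grid.

Input tables are delimited text with one row per reported activation focus.
Rows from the same participant sample (same ``study_id`` and
``experiment_id``) are merged into a single experiment with pooled foci, so
that no sample enters a meta-analysis more than once. Talairach-space rows
are harmonized to MNI152 with the linear Lancaster transform, whose
coefficients are data (config), not code: the SPM-calibrated variant is the
default, the FSL-calibrated one ships alongside it.

All statistical maps live on a :class:`BrainGrid` — a boolean mask plus a
voxel-to-mm affine. World coordinates are always mm; voxel indices are
0-based and only ever reached through the affine.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Moderator vocabularies. Missing values are coded explicitly as "missing".
MODERATOR_LEVELS = {
    "control_condition": {"congruent", "neutral", "neutral_word", "neutral_symbol"},
    "design": {"blocked", "mixed", "excluded"},
    "demand": {"yes", "no"},
    "material": {"color_word", "emotional", "other"},
}
MISSING = "missing"

# Lancaster et al. (2007) icbm2tal affines (MNI -> Talairach); the
# Talairach -> MNI direction is the matrix inverse. Two published
# calibrations exist, for SPM- and FSL-normalized data.
ICBM2TAL_SPM = np.array(
    [
        [0.9254, 0.0024, -0.0118, -1.0207],
        [-0.0048, 0.9316, -0.0871, -1.7667],
        [0.0152, 0.0883, 0.8924, 4.0926],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
ICBM2TAL_FSL = np.array(
    [
        [0.9464, 0.0034, -0.0026, -1.0680],
        [-0.0083, 0.9479, -0.0580, -1.0239],
        [0.0053, 0.0617, 0.9010, 3.1883],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
LANCASTER_VARIANTS = {"spm": ICBM2TAL_SPM, "fsl": ICBM2TAL_FSL}


@dataclass(frozen=True)
class Focus:
    """A reported peak coordinate, in mm (MNI152 after harmonization)."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Experiment:
    """One participant sample contributing foci to a meta-analysis."""

    study_id: str
    experiment_id: str
    n: int
    foci: list[Focus]
    moderators: dict[str, str] = field(default_factory=dict)
    source_space: str = "MNI"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"experiment {self.experiment_id}: n must be >= 1, got {self.n}")
        if not self.foci:
            raise ValueError(f"experiment {self.experiment_id}: needs at least one focus")
        for key, value in self.moderators.items():
            allowed = MODERATOR_LEVELS.get(key)
            if allowed is not None and value not in allowed and value != MISSING:
                raise ValueError(
                    f"experiment {self.experiment_id}: moderator {key}={value!r} "
                    f"not in {sorted(allowed)} or {MISSING!r}"
                )

    def foci_array(self) -> np.ndarray:
        return np.array([[f.x, f.y, f.z] for f in self.foci], dtype=float)


@dataclass
class BrainGrid:
    """Voxel lattice for all maps: shape, voxel-to-mm affine, boolean mask."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.mask.shape != tuple(self.shape):
            raise ValueError("mask shape does not match grid shape")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels_in_mask(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def mm_to_voxel(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Map mm coordinates to (fractional) voxel indices."""
        xyz_mm = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        homo = np.c_[xyz_mm, np.ones(len(xyz_mm))]
        return (homo @ inv.T)[:, :3]

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homo = np.c_[ijk, np.ones(len(ijk))]
        return (homo @ self.affine.T)[:, :3]

    def mask_voxel_centers_mm(self) -> np.ndarray:
        """mm coordinates of the centers of all in-mask voxels."""
        ijk = np.array(np.nonzero(self.mask)).T
        return self.voxel_to_mm(ijk)

    def contains_mm(self, xyz_mm: np.ndarray) -> np.ndarray:
        """True where the nearest voxel to each mm coordinate is in-mask."""
        ijk = np.rint(self.mm_to_voxel(xyz_mm)).astype(int)
        ok = np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=1)
        out = np.zeros(len(ijk), dtype=bool)
        out[ok] = self.mask[tuple(ijk[ok].T)]
        return out


@dataclass
class ExperimentSet:
    """A pool of experiments sharing one analysis grid."""

    experiments: list[Experiment]
    grid: BrainGrid | None = None

    def __len__(self) -> int:
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)

    def subset(self, **filters) -> "ExperimentSet":
        """Select experiments whose moderators match ``filters``.

        Each filter value may be a single level or an iterable of levels.
        Experiments with a missing code for a filtered moderator are dropped.
        """
        keep = []
        for exp in self.experiments:
            ok = True
            for key, levels in filters.items():
                if isinstance(levels, str):
                    levels = {levels}
                else:
                    levels = set(levels)
                if exp.moderators.get(key, MISSING) not in levels:
                    ok = False
                    break
            if ok:
                keep.append(exp)
        return ExperimentSet(keep, self.grid)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for exp in self.experiments:
            for f in exp.foci:
                row = {
                    "study_id": exp.study_id,
                    "experiment_id": exp.experiment_id,
                    "n": exp.n,
                    "space": "MNI",
                    "x": f.x,
                    "y": f.y,
                    "z": f.z,
                }
                row.update(exp.moderators)
                rows.append(row)
        return pd.DataFrame(rows)

    def write_table(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def tal_to_mni(foci: list[Focus] | np.ndarray, variant: str = "spm",
               matrix: np.ndarray | None = None) -> list[Focus] | np.ndarray:
    """Map Talairach coordinates to MNI152 with the linear Lancaster transform.

    ``matrix`` overrides the built-in ``variant`` ("spm" or "fsl")
    coefficients; it must be the MNI->TAL direction (it is inverted here).
    """
    if matrix is None:
        try:
            matrix = LANCASTER_VARIANTS[variant]
        except KeyError:
            raise ValueError(f"unknown Lancaster variant {variant!r}") from None
    inv = np.linalg.inv(np.asarray(matrix, dtype=float))
    as_focus = not isinstance(foci, np.ndarray)
    xyz = np.atleast_2d(
        np.array([[f.x, f.y, f.z] for f in foci]) if as_focus else np.asarray(foci, float)
    )
    out = (np.c_[xyz, np.ones(len(xyz))] @ inv.T)[:, :3]
    if as_focus:
        return [Focus(*row) for row in out]
    return out


def mni_to_tal(xyz: np.ndarray, variant: str = "spm") -> np.ndarray:
    """Inverse harmonization (MNI -> Talairach); mainly for round-trip checks."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    mat = LANCASTER_VARIANTS[variant]
    return (np.c_[xyz, np.ones(len(xyz))] @ mat.T)[:, :3]


REQUIRED_COLUMNS = ("study_id", "experiment_id", "n", "space", "x", "y", "z")


def read_experiment_table(path, grid: BrainGrid | None = None,
                          sep: str | None = None,
                          lancaster_variant: str = "spm") -> ExperimentSet:
    """Read a focus table and assemble one experiment per participant sample.

    Rows sharing (study_id, experiment_id) are one sample: their foci are
    pooled. Talairach rows (space == "TAL") are transformed to MNI; rows
    declared MNI (or SPM/FSL, treated as MNI) pass through unchanged.
    Raises on missing columns or an empty table; rows with non-numeric
    coordinates raise a ``ValueError`` listing the offending rows.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: table contains no rows")

    bad_rows = []
    for col in ("x", "y", "z"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_rows.extend(df.index[coerced.isna()].tolist())
        df[col] = coerced
    if bad_rows:
        raise ValueError(
            f"{path}: non-numeric coordinates in rows {sorted(set(bad_rows))}"
        )

    moderator_cols = [c for c in df.columns if c in MODERATOR_LEVELS]
    experiments = []
    for (study_id, experiment_id), group in sorted(
        df.groupby(["study_id", "experiment_id"], sort=True), key=lambda kv: kv[0]
    ):
        spaces = {str(s).upper() for s in group["space"]}
        unknown = spaces - {"MNI", "TAL", "SPM", "FSL"}
        if unknown:
            raise ValueError(f"unknown coordinate space label(s) {sorted(unknown)}")
        xyz = group[["x", "y", "z"]].to_numpy(dtype=float)
        is_tal = group["space"].str.upper().to_numpy() == "TAL"
        if is_tal.any():
            xyz[is_tal] = tal_to_mni(xyz[is_tal], variant=lancaster_variant)
        n_values = group["n"].unique()
        if len(n_values) > 1:
            warnings.warn(
                f"{study_id}/{experiment_id}: differing n across merged rows; "
                f"using the largest ({max(n_values)})"
            )
        moderators = {}
        for col in moderator_cols:
            vals = {str(v) for v in group[col].dropna() if str(v) != "nan"}
            moderators[col] = vals.pop() if len(vals) == 1 else MISSING
        experiments.append(
            Experiment(
                study_id=str(study_id),
                experiment_id=str(experiment_id),
                n=int(max(n_values)),
                foci=[Focus(*row) for row in xyz],
                moderators=moderators,
                source_space="MNI",
            )
        )
    logger.info("read %d experiments (%d foci) from %s",
                len(experiments), len(df), path)
    return ExperimentSet(experiments, grid)


def read_behavioral_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a behavioral summary table (one row per experiment).

    Required columns: study_id, experiment_id, n, mean_I, sd_I, mean_C, sd_C.
    Optional: r, t_paired, sd_diff, sd_is_se, moderator columns.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    required = ["study_id", "experiment_id", "n", "mean_I", "sd_I", "mean_C", "sd_C"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: table contains no rows")
    return df


def make_grid(volume) -> BrainGrid:
    """Build a :class:`BrainGrid` from a NIfTI image or (array, affine) pair."""
    if isinstance(volume, tuple):
        data, affine = volume
        data = np.asarray(data)
    else:
        img = volume if hasattr(volume, "get_fdata") else nib.load(str(volume))
        data = np.asarray(img.get_fdata())
        affine = img.affine
    if data.ndim != 3:
        raise ValueError(f"mask volume must be 3-D, got shape {data.shape}")
    mask = data > 0
    return BrainGrid(shape=tuple(data.shape), affine=np.asarray(affine), mask=mask)


def default_brain_grid(resolution: int = 2) -> BrainGrid:
    """Whole-brain MNI152 grid from the template bundled with nilearn."""
    from nilearn.datasets import load_mni152_brain_mask

    return make_grid(load_mni152_brain_mask(resolution=resolution))


def ellipsoid_grid(shape=(30, 36, 30), voxel_size_mm: float = 4.0,
                   semi_axes_frac=(0.85, 0.85, 0.85)) -> BrainGrid:
    """Compact head-shaped (ellipsoid) grid for simulations and tests.

    The affine centers the ellipsoid on mm-origin with isotropic voxels.
    """
    shape = tuple(int(s) for s in shape)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.array(shape) - 1) / 2.0
    idx = np.indices(shape, dtype=float)
    center = (np.array(shape) - 1) / 2.0
    semi = np.array(semi_axes_frac) * np.array(shape) / 2.0
    dist = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return BrainGrid(shape=shape, affine=affine, mask=dist <= 1.0)


def write_stat_map(values: np.ndarray, grid: BrainGrid, path) -> nib.Nifti1Image:
    """Write a per-voxel statistic as NIfTI-1; out-of-mask voxels are zeroed."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != tuple(grid.shape):
        raise ValueError(
            f"value array shape {values.shape} does not match grid {grid.shape}"
        )
    data = np.where(grid.mask, values, 0.0)
    img = nib.Nifti1Image(data, grid.affine)
    img.to_filename(str(path))
    return img


def merge_same_sample(experiments: list[Experiment]) -> list[Experiment]:
    """Pool foci of experiments from the same (study_id, experiment_id) sample."""
    merged: dict[tuple[str, str], Experiment] = {}
    for exp in experiments:
        key = (exp.study_id, exp.experiment_id)
        if key in merged:
            prev = merged[key]
            merged[key] = replace(prev, foci=prev.foci + exp.foci,
                                  n=max(prev.n, exp.n))
        else:
            merged[key] = exp
    return [merged[k] for k in sorted(merged)]
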