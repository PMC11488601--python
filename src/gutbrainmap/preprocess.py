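"""Preprocessing: abundance flooring/log/filtering, voxel masks, design assembly.

The predictor block is a compositional table of bacterial-family relative
abundances (RAs). Tiny RAs are floored at 1e-3 before the natural-log
transform (their logs would otherwise dominate the fit), rare families are
dropped by a prevalence filter (a family is kept only if at least 5% of
subjects carry it above 1% RA), and the retained log-RAs are standardized
together with the covariates (sex, age, BMI) into the design matrix every
voxelwise fit consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 1e-3
DEFAULT_MIN_SUBJECT_FRAC = 0.05
DEFAULT_MIN_RA = 0.01
COVARIATE_COLUMNS = ("sex", "age", "bmi")


class DataError(ValueError):
    """Raised when input tables violate the data contract."""


class AlignmentError(ValueError):
    """Raised when component tables do not index the same subjects."""


class MaskError(ValueError):
    """Raised when a voxel mask is empty or mismatched."""


@dataclass
class AbundanceTable:
    """Subjects x families relative-abundance table.

    ``values`` holds RAs in [0, 1]; ``zero_variance_families`` flags columns
    that became constant (e.g. all-zero columns after flooring).
    """

    subjects: list
    families: list
    values: np.ndarray
    zero_variance_families: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), len(self.families)):
            raise DataError(
                f"abundance matrix shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.families)} families"
            )
        if np.isnan(self.values).any():
            raise DataError("abundance table contains missing values")
        if (self.values < 0).any():
            raise DataError("abundance table contains negative entries")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.families)


@dataclass
class CovariateTable:
    """Per-subject nuisance covariates: sex (0/1), age (years), BMI (kg/m^2)."""

    subjects: list
    sex: np.ndarray
    age: np.ndarray
    bmi: np.ndarray

    def __post_init__(self):
        n = len(self.subjects)
        self.sex = np.asarray(self.sex, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.bmi = np.asarray(self.bmi, dtype=float)
        for name, arr in (("sex", self.sex), ("age", self.age), ("bmi", self.bmi)):
            if arr.shape != (n,):
                raise DataError(f"covariate {name!r} has shape {arr.shape}, expected ({n},)")
            if np.isnan(arr).any():
                raise DataError(f"covariate {name!r} contains missing values")
        if not np.isin(self.sex, (0.0, 1.0)).all():
            raise DataError("sex must be coded 0/1")
        if (self.age <= 0).any():
            raise DataError("age must be positive")
        if (self.bmi <= 0).any():
            raise DataError("BMI must be positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CovariateTable":
        cols = {c.lower(): c for c in df.columns}
        missing = [c for c in COVARIATE_COLUMNS if c not in cols]
        if missing:
            raise DataError(f"covariate table is missing columns: {missing}")
        return cls(
            list(df.index),
            df[cols["sex"]].to_numpy(float),
            df[cols["age"]].to_numpy(float),
            df[cols["bmi"]].to_numpy(float),
        )

    def matrix(self) -> np.ndarray:
        return np.column_stack([self.sex, self.age, self.bmi])


@dataclass
class ImageStack:
    """One aligned 3-D image per subject, sharing a shape and a voxel->world affine."""

    subjects: list
    data: np.ndarray  # (n_subjects, nx, ny, nz)
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[0] != len(self.subjects):
            raise DataError(
                f"image stack must be (n_subjects, nx, ny, nz); got {self.data.shape} "
                f"for {len(self.subjects)} subjects"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise DataError("affine must be 4x4")

    @property
    def shape(self) -> tuple:
        return self.data.shape[1:]


@dataclass
class VoxelMask:
    """Boolean analysis mask over the image lattice."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise MaskError("voxel mask is empty; lower the threshold fraction")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class StandardizationRecord:
    """Per-column means/sds used to standardize the design (for back-transforms)."""

    columns: list
    means: np.ndarray
    sds: np.ndarray

    def unstandardize(self, X: np.ndarray) -> np.ndarray:
        return X * self.sds + self.means


@dataclass
class DesignMatrix:
    """Standardized [log-RA families..., sex, age, bmi] design, one row per subject."""

    subjects: list
    families: list
    X: np.ndarray  # standardized, columns ordered families then covariates
    record: StandardizationRecord

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def columns(self) -> list:
        return list(self.families) + list(COVARIATE_COLUMNS)

    @property
    def family_block(self) -> np.ndarray:
        return self.X[:, : self.n_families]

    @property
    def covariate_block(self) -> np.ndarray:
        return self.X[:, self.n_families:]


def floor_abundances(table: AbundanceTable, floor: float = DEFAULT_FLOOR) -> AbundanceTable:
    """Replace every RA below ``floor`` with ``floor`` (no re-normalization).

    Flooring guards the subsequent log transform against near-zero RAs whose
    logs would approach minus infinity. Rows are deliberately not re-closed to
    sum 1: re-normalizing would perturb the abundance ratios that the
    log-linear coefficient patterns encode.
    """
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    if (table.values < 0).any():
        raise DataError("abundance table contains negative entries")
    floored = np.maximum(table.values, floor)
    zero_var = [
        fam for j, fam in enumerate(table.families) if np.ptp(floored[:, j]) == 0.0
    ]
    return AbundanceTable(table.subjects, table.families, floored, zero_variance_families=zero_var)


def log_transform(table: AbundanceTable) -> np.ndarray:
    """Element-wise natural log of a (floored) abundance table."""
    if (table.values <= 0).any():
        raise DataError("non-positive abundances passed to log_transform; apply floor_abundances first")
    return np.log(table.values)


def filter_families(
    table: AbundanceTable,
    min_subject_frac: float = DEFAULT_MIN_SUBJECT_FRAC,
    min_ra: float = DEFAULT_MIN_RA,
) -> AbundanceTable:
    """Prevalence filter: keep family f iff >= min_subject_frac of subjects have RA_f > min_ra.

    The fraction boundary is inclusive (``at least 5%``) while the abundance
    boundary is strict (``RAs > 1%``). Applied to the un-floored table; the
    floor (1e-3) sits well below min_ra so the two orders agree anyway.
    """
    if not (0 < min_subject_frac <= 1):
        raise ValueError(f"min_subject_frac must be in (0, 1], got {min_subject_frac}")
    n = len(table.subjects)
    frac = (table.values > min_ra).sum(axis=0) / n
    keep = frac >= min_subject_frac
    if not keep.any():
        raise DataError(
            "prevalence filter removed every family; relax min_subject_frac/min_ra"
        )
    kept = [f for f, k in zip(table.families, keep) if k]
    return AbundanceTable(
        table.subjects,
        kept,
        table.values[:, keep],
        zero_variance_families=[f for f in table.zero_variance_families if f in kept],
    )


def build_voxel_mask(
    stack: ImageStack,
    method: str = "mean_threshold",
    threshold_frac: float = 0.1,
    user_mask: np.ndarray | None = None,
) -> VoxelMask:
    """Analysis mask restricting voxelwise fits to tissue with appreciable signal.

    Default rule: include a voxel iff the across-subject mean image exceeds
    ``threshold_frac`` times a robust maximum (the 98th percentile of the mean
    image). A user-supplied mask is honored verbatim.
    """
    if user_mask is not None or method == "user":
        if user_mask is None:
            raise MaskError("method='user' requires a user_mask array")
        m = np.asarray(user_mask) != 0
        if m.shape != stack.shape:
            raise MaskError(f"user mask shape {m.shape} != image shape {stack.shape}")
        return VoxelMask(m)
    if method != "mean_threshold":
        raise ValueError(f"unknown mask method {method!r}")
    mean_img = stack.data.mean(axis=0)
    robust_max = np.percentile(mean_img, 98)
    return VoxelMask(mean_img > threshold_frac * robust_max)


def assemble_design(
    abundances: AbundanceTable,
    covariates: CovariateTable,
    floor: float = DEFAULT_FLOOR,
    min_subject_frac: float = DEFAULT_MIN_SUBJECT_FRAC,
    min_ra: float = DEFAULT_MIN_RA,
) -> DesignMatrix:
    """Floor -> log -> prevalence-filter the abundances, append covariates, standardize.

    Every column is standardized to mean 0, sd 1 so a single Ridge penalty is
    commensurable across regressors; the means/sds are recorded so coefficients
    can be reported back on the log-RA scale. Zero-variance columns are dropped
    with a warning (they carry no information and break standardization).
    """
    if list(abundances.subjects) != list(covariates.subjects):
        a, c = set(abundances.subjects), set(covariates.subjects)
        raise AlignmentError(
            "abundance and covariate tables disagree on subjects: "
            f"only-in-abundances={sorted(map(str, a - c))}, "
            f"only-in-covariates={sorted(map(str, c - a))}, "
            + ("ordering differs" if a == c else "")
        )
    kept = filter_families(abundances, min_subject_frac, min_ra)
    floored = floor_abundances(kept, floor)
    logs = log_transform(floored)
    raw = np.column_stack([logs, covariates.matrix()])
    columns = list(kept.families) + list(COVARIATE_COLUMNS)

    nonconstant = np.ptp(raw, axis=0) > 0
    if not nonconstant.all():
        dropped = [c for c, ok in zip(columns, nonconstant) if not ok]
        warnings.warn(f"dropping zero-variance design columns: {dropped}")
        logger.warning("dropping zero-variance design columns: %s", dropped)
    keep_fam = nonconstant[: len(kept.families)]
    families = [f for f, ok in zip(kept.families, keep_fam) if ok]
    columns = [c for c, ok in zip(columns, nonconstant) if ok]
    raw = raw[:, nonconstant]
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=0)
    X = (raw - means) / sds
    record = StandardizationRecord(columns, means, sds)
    return DesignMatrix(list(abundances.subjects), families, X, record)


# ---------------------------------------------------------------------------
# table / image I/O


def read_table(path) -> pd.DataFrame:
    """Read a TSV/CSV with a header row and the subject id in the first column."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df


def read_abundances(path) -> AbundanceTable:
    df = read_table(path)
    if df.isna().any().any():
        raise DataError(f"missing values in abundance table {path}")
    return AbundanceTable.from_dataframe(df)


def read_covariates(path) -> CovariateTable:
    df = read_table(path)
    if df.isna().any().any():
        raise DataError(f"missing values in covariate table {path}")
    return CovariateTable.from_dataframe(df)


def read_image_stack(paths, subjects=None) -> ImageStack:
    """Load one NIfTI per subject; all images must share shape and affine (tol 1e-4)."""
    import nibabel as nib

    paths = list(paths)
    if not paths:
        raise DataError("no image files supplied")
    imgs = [nib.load(str(p)) for p in paths]
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise DataError(f"images differ in shape: {sorted(shapes)}")
    affine = imgs[0].affine
    for p, im in zip(paths, imgs):
        if not np.allclose(im.affine, affine, atol=1e-4):
            raise DataError(f"image {p} affine differs from the first image beyond 1e-4")
    data = np.stack([np.asarray(im.dataobj, dtype=float) for im in imgs])
    if subjects is None:
        import os

        subjects = [os.path.basename(str(p)).split(".")[0] for p in paths]
    return ImageStack(list(subjects), data, affine)
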