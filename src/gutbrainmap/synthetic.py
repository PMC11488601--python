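"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the kind of study the pipeline targets: ~133 subjects
with (a) a compositional gut bacterial family table — heavy-tailed,
multicollinear, with a long tail of rare taxa mostly below the 1e-3 flooring
threshold; (b) spatially aligned 3-D images per subject in which a brain-like
ellipsoid of tissue carries covariate effects and noise, plus a small number
of planted spherical signal clusters whose voxel values follow the log-linear
generating model

    y = alpha + sum_f beta_f * ln(max(RA_f, 1e-3)) + gamma' cov + eps;

and (c) clinical scores correlated with the planted regions' mean signal.
Because the ground truth (which voxels and families carry signal) is
recorded, every downstream stage can be validated against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import STREAM_SCENARIO, stream_rng
from .preprocess import AbundanceTable, AlignmentError, CovariateTable, ImageStack

FLOOR = 1e-3
CLINICAL_SCORES = ("phq9", "tmt_a", "tmt_b", "stroop_cw", "digit_span")

_ABUND, _COVAR, _IMAGE, _CLINICAL = 0, 1, 2, 3  # rng sub-streams


class ScenarioError(ValueError):
    """Raised when a scenario parameter is invalid; names the offending field."""


@dataclass
class SignalCluster:
    """A planted spherical effect: voxels within ``radius`` of ``center`` carry
    the signed log-abundance effects ``betas`` of the listed family indices."""

    center: tuple
    radius: float
    families: tuple
    betas: tuple

    def voxel_indices(self, shape) -> np.ndarray:
        """Flat (C-order) indices of lattice points within Euclidean distance radius."""
        grid = np.indices(shape).reshape(3, -1)
        d2 = ((grid - np.asarray(self.center)[:, None]) ** 2).sum(axis=0)
        return np.flatnonzero(d2 <= self.radius**2)


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic cohort.

    Defaults mirror the cohort scale the pipeline targets (n=133 subjects)
    with a moderate family panel, 2 mm isotropic voxels, and covariate slopes
    and noise on the scale of the log-abundance effects.
    """

    n_subjects: int = 133
    n_families: int = 50
    image_shape: tuple = (16, 16, 16)
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    signal_clusters: list = field(default_factory=list)
    covariate_effects: tuple = (0.5, 0.02, 0.03)  # sex, age, BMI slopes
    noise_sd: float = 1.0
    clinical_effect: float = 0.0
    rare_family_fraction: float = 0.3
    seed: int = 0
    baseline: float = 100.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 20:
            raise ScenarioError(
                f"n_subjects={self.n_subjects}: need at least 20 subjects for 10-fold CV"
            )
        if self.n_families < 2:
            raise ScenarioError(f"n_families={self.n_families}: need at least 2 families")
        if len(self.image_shape) != 3 or any(s < 1 for s in self.image_shape):
            raise ScenarioError(f"image_shape={self.image_shape}: need a positive 3-D shape")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ScenarioError(f"voxel_size_mm={self.voxel_size_mm}: must be positive")
        if self.noise_sd <= 0:
            raise ScenarioError(f"noise_sd={self.noise_sd}: must be positive")
        if not 0 <= self.rare_family_fraction < 1:
            raise ScenarioError(
                f"rare_family_fraction={self.rare_family_fraction}: must be in [0, 1)"
            )
        if not -1 <= self.clinical_effect <= 1:
            raise ScenarioError(f"clinical_effect={self.clinical_effect}: must be in [-1, 1]")
        for c in self.signal_clusters:
            if not all(0 <= ci < si for ci, si in zip(c.center, self.image_shape)):
                raise ScenarioError(
                    f"signal_clusters: center {c.center} outside image_shape {self.image_shape}"
                )
            if c.radius <= 0:
                raise ScenarioError(f"signal_clusters: radius {c.radius} must be positive")
            if len(c.families) != len(c.betas):
                raise ScenarioError("signal_clusters: families and betas differ in length")
            if not all(np.isfinite(c.betas)):
                raise ScenarioError(f"signal_clusters: non-finite effect sizes {c.betas}")
            if not all(0 <= f < self.n_families for f in c.families):
                raise ScenarioError(
                    f"signal_clusters: family index out of range in {c.families}"
                )

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        for i, (v, s) in enumerate(zip(self.voxel_size_mm, self.image_shape)):
            aff[i, i] = v
            aff[i, 3] = -v * (s - 1) / 2.0
        return aff

    @classmethod
    def global_null(cls, **kwargs) -> "SyntheticScenario":
        """A scenario with every beta_f = 0: no voxel is associated with any family."""
        kwargs.pop("signal_clusters", None)
        return cls(signal_clusters=[], clinical_effect=kwargs.pop("clinical_effect", 0.0), **kwargs)

    @classmethod
    def planted(
        cls,
        center=None,
        radius: float = 2.0,
        families=(2, 3),
        betas=(1.0, -1.0),
        **kwargs,
    ) -> "SyntheticScenario":
        """One spherical cluster where the listed families carry signed effects.

        The default betas (+1, -1) encode an abundance-ratio pattern: the
        voxel rises with ln(RA_A / RA_B).
        """
        shape = kwargs.get("image_shape", (16, 16, 16))
        if center is None:
            center = tuple(s // 2 for s in shape)
        cluster = SignalCluster(tuple(center), radius, tuple(families), tuple(betas))
        kwargs.setdefault("clinical_effect", 0.4)
        return cls(signal_clusters=[cluster], **kwargs)


@dataclass
class TruthRecord:
    """Ground truth of one cohort: which voxels and families carry signal."""

    image_shape: tuple
    affine: np.ndarray
    clusters: list  # dicts with center/radius/families/betas/voxel_indices (flat)
    tissue_indices: np.ndarray  # flat indices of the brain-like ellipsoid

    @property
    def signal_indices(self) -> np.ndarray:
        if not self.clusters:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate([c["voxel_indices"] for c in self.clusters]))

    def signal_mask(self) -> np.ndarray:
        m = np.zeros(int(np.prod(self.image_shape)), dtype=bool)
        m[self.signal_indices] = True
        return m.reshape(self.image_shape)

    def to_json(self) -> str:
        return json.dumps(
            {
                "image_shape": list(self.image_shape),
                "affine": np.asarray(self.affine).tolist(),
                "tissue_indices": self.tissue_indices.tolist(),
                "clusters": [
                    {
                        "center": [int(v) for v in c["center"]],
                        "radius": float(c["radius"]),
                        "families": [int(f) for f in c["families"]],
                        "betas": [float(b) for b in c["betas"]],
                        "voxel_indices": np.asarray(c["voxel_indices"]).tolist(),
                    }
                    for c in self.clusters
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(
            image_shape=tuple(d["image_shape"]),
            affine=np.asarray(d["affine"]),
            clusters=[
                {
                    "center": tuple(c["center"]),
                    "radius": c["radius"],
                    "families": tuple(c["families"]),
                    "betas": tuple(c["betas"]),
                    "voxel_indices": np.asarray(c["voxel_indices"], dtype=int),
                }
                for c in d["clusters"]
            ],
            tissue_indices=np.asarray(d["tissue_indices"], dtype=int),
        )


@dataclass
class SyntheticCohort:
    """All component tables of one simulated study, indexed by the same subjects."""

    abundances: AbundanceTable
    covariates: CovariateTable
    images: ImageStack
    clinical: pd.DataFrame
    truth: TruthRecord

    def __post_init__(self):
        subs = list(self.abundances.subjects)
        for name, other in (
            ("covariates", list(self.covariates.subjects)),
            ("images", list(self.images.subjects)),
            ("clinical", list(self.clinical.index)),
        ):
            if other != subs:
                raise AlignmentError(f"{name} table subjects differ from abundance table")
        sums = self.abundances.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("abundance rows must sum to 1 within 1e-9")


def _subject_ids(n: int) -> list:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def _tissue_ellipsoid(shape) -> np.ndarray:
    """Boolean brain-like ellipsoid with semi-axes 0.45 x shape, centered."""
    grid = np.indices(shape).astype(float)
    center = (np.asarray(shape, float) - 1) / 2.0
    semi = 0.45 * np.asarray(shape, float)
    d = sum(((grid[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return d <= 1.0


def generate_abundances(scenario: SyntheticScenario) -> AbundanceTable:
    """Compositional family table: log-normal intensities closed to the simplex.

    Common families get geometrically decaying location parameters (a few
    dominant taxa, a long tail); a designated fraction of families is rare,
    with intensities tuned so >95% of their closed abundances fall below the
    1e-3 flooring threshold. Families 0 and 1 are strongly collinear on the
    log scale, the multicollinear case Ridge regression is built for.
    """
    rng = stream_rng(scenario.seed, STREAM_SCENARIO, _ABUND)
    n, p = scenario.n_subjects, scenario.n_families
    n_rare = int(round(scenario.rare_family_fraction * p))
    n_common = p - n_rare
    if n_common < 2:
        raise ScenarioError("rare_family_fraction leaves fewer than 2 common families")
    mu_common = np.linspace(2.0, -2.0, n_common)
    # expected total intensity; rare families sit ~3e-5 of it so closure keeps them tiny
    total = np.exp(mu_common + 0.5).sum()
    mu = np.concatenate([mu_common, np.full(n_rare, np.log(3e-5 * total))])
    x = rng.normal(size=(n, p)) + mu
    x[:, 1] = x[:, 0] + rng.normal(scale=0.2, size=n)  # collinear pair on the log scale
    intensities = np.exp(x)
    ra = intensities / intensities.sum(axis=1, keepdims=True)
    families = [f"Family{j:03d}" for j in range(p)]
    return AbundanceTable(_subject_ids(n), families, ra)


def generate_covariates(scenario: SyntheticScenario) -> CovariateTable:
    """Sex/age/BMI with the marginal structure of a middle-aged, high-BMI cohort."""
    rng = stream_rng(scenario.seed, STREAM_SCENARIO, _COVAR)
    n = scenario.n_subjects
    sex = (rng.random(n) < 0.69).astype(float)
    age = np.clip(rng.normal(46.7, 10.7, size=n), 22.0, 66.0)
    bmi = np.clip(rng.normal(35.3, 10.9, size=n), 19.0, 63.0)
    return CovariateTable(_subject_ids(n), sex, age, bmi)


def generate_images(
    scenario: SyntheticScenario,
    abundances: AbundanceTable,
    covariates: CovariateTable,
) -> tuple[ImageStack, TruthRecord]:
    """One 3-D image per subject, with planted clusters and a tissue background.

    Inside the tissue ellipsoid every voxel carries baseline + covariate
    effects + Gaussian noise; voxels inside a planted cluster additionally
    carry sum_f beta_f * ln(max(RA_f, 1e-3)). Outside the tissue the
    intensity is near zero, which is what makes mask construction meaningful.
    """
    if list(abundances.subjects) != list(covariates.subjects):
        raise AlignmentError("abundances and covariates are not row-aligned")
    rng = stream_rng(scenario.seed, STREAM_SCENARIO, _IMAGE)
    n = len(abundances.subjects)
    shape = tuple(scenario.image_shape)
    nvox = int(np.prod(shape))
    tissue = _tissue_ellipsoid(shape).ravel()
    cov_term = covariates.matrix() @ np.asarray(scenario.covariate_effects, float)

    data = rng.normal(scale=0.01, size=(n, nvox))  # near-zero background
    t_idx = np.flatnonzero(tissue)
    eps = rng.normal(scale=scenario.noise_sd, size=(n, len(t_idx)))
    data[:, t_idx] = scenario.baseline + cov_term[:, None] + eps

    log_ra = np.log(np.maximum(abundances.values, FLOOR))
    clusters = []
    for c in scenario.signal_clusters:
        vox = c.voxel_indices(shape)
        signal = log_ra[:, list(c.families)] @ np.asarray(c.betas, float)
        data[:, vox] += signal[:, None]
        clusters.append(
            {
                "center": tuple(c.center),
                "radius": float(c.radius),
                "families": tuple(c.families),
                "betas": tuple(c.betas),
                "voxel_indices": vox,
            }
        )
    stack = ImageStack(list(abundances.subjects), data.reshape((n,) + shape), scenario.affine)
    truth = TruthRecord(shape, scenario.affine, clusters, t_idx)
    return stack, truth


def generate_clinical(
    scenario: SyntheticScenario,
    images: ImageStack,
    truth: TruthRecord,
) -> pd.DataFrame:
    """Clinical scores driven by the planted regions' mean signal.

    Each score is clinical_effect * z(region mean) + sqrt(1 - effect^2) * noise,
    so the population correlation with the region mean equals clinical_effect.
    Scores mirror standard depression and cognition instruments
    on a standardized scale. With clinical_effect = 0 the scores are
    independent of the images.
    """
    rng = stream_rng(scenario.seed, STREAM_SCENARIO, _CLINICAL)
    n = len(images.subjects)
    c = float(scenario.clinical_effect)
    sig = truth.signal_indices
    if sig.size == 0 and c != 0.0:
        raise ScenarioError(
            "clinical_effect != 0 requires a non-empty truth record (planted clusters)"
        )
    if sig.size:
        region = images.data.reshape(n, -1)[:, sig].mean(axis=1)
        z = (region - region.mean()) / region.std(ddof=0)
    else:
        z = np.zeros(n)
    scores = {}
    for name in CLINICAL_SCORES:
        noise = rng.normal(size=n)
        scores[name] = c * z + np.sqrt(max(0.0, 1.0 - c**2)) * noise
    return pd.DataFrame(scores, index=pd.Index(images.subjects, name="subject_id"))


def default_clusters(
    n: int,
    shape,
    radius: float = 2.0,
    families=(2, 3),
    betas=(1.0, -1.0),
) -> list:
    """n planted clusters at fixed tissue-interior positions.

    The first sits at the volume center; further ones step along the axes by
    a fifth of the extent, staying well inside the tissue ellipsoid.
    """
    center = np.asarray(shape) // 2
    offsets = [(0, 0, 0)]
    for axis in range(3):
        for sign in (1, -1):
            o = [0, 0, 0]
            o[axis] = sign * max(1, shape[axis] // 5)
            offsets.append(tuple(o))
    if n > len(offsets):
        raise ScenarioError(f"at most {len(offsets)} default clusters supported, got {n}")
    return [
        SignalCluster(tuple(center + np.asarray(offsets[i])), radius, tuple(families), tuple(betas))
        for i in range(n)
    ]


def generate_cohort(scenario: SyntheticScenario) -> SyntheticCohort:
    """The full cohort: abundances, covariates, images, clinical scores, truth."""
    abundances = generate_abundances(scenario)
    covariates = generate_covariates(scenario)
    images, truth = generate_images(scenario, abundances, covariates)
    clinical = generate_clinical(scenario, images, truth)
    return SyntheticCohort(abundances, covariates, images, clinical, truth)


# ---------------------------------------------------------------------------
# on-disk layout


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write abundances/covariates/clinical TSVs, per-subject NIfTIs, truth.json."""
    import nibabel as nib

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", float_format="%.12g")
    ab = cohort.abundances.to_dataframe()
    ab.index.name = "subject_id"
    ab.to_csv(outdir / "abundances.tsv", **fmt)
    cov = pd.DataFrame(
        {"sex": cohort.covariates.sex, "age": cohort.covariates.age, "bmi": cohort.covariates.bmi},
        index=pd.Index(cohort.covariates.subjects, name="subject_id"),
    )
    cov.to_csv(outdir / "covariates.tsv", **fmt)
    cohort.clinical.rename_axis("subject_id").to_csv(outdir / "clinical.tsv", **fmt)
    for i, sub in enumerate(cohort.images.subjects):
        img = nib.Nifti1Image(cohort.images.data[i].astype(np.float32), cohort.images.affine)
        nib.save(img, str(outdir / "images" / f"{sub}.nii.gz"))
    (outdir / "truth.json").write_text(cohort.truth.to_json())
    return outdir


def load_cohort(indir) -> SyntheticCohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    from .preprocess import read_abundances, read_covariates, read_image_stack, read_table

    indir = Path(indir)
    abundances = read_abundances(indir / "abundances.tsv")
    covariates = read_covariates(indir / "covariates.tsv")
    clinical = read_table(indir / "clinical.tsv")
    paths = [indir / "images" / f"{s}.nii.gz" for s in abundances.subjects]
    images = read_image_stack(paths, subjects=abundances.subjects)
    truth = TruthRecord.from_json((indir / "truth.json").read_text())
    return SyntheticCohort(abundances, covariates, images, clinical, truth)
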