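"""Model/Results interface tying the pipeline stages together.

:class:`MicrobiomeBrainModel` is built from the cohort data (abundance,
covariate and image tables); ``fit()`` runs the voxelwise cross-validated
Ridge RSS-ratio map and its Freedman-Lane/TFCE permutation inference and
returns a :class:`MicrobiomeBrainResults` carrying the maps, the permutation
null, a ``summary()`` table, and the post-hoc analyses (family
contributions, subgroup reruns, clinical correlations).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import _seeds, association, inference, posthoc, preprocess
from .association import DEFAULT_K, DEFAULT_LAMBDA_GRID, FoldAssignment
from .inference import ClusterReport, ClusterThresholds, InferenceResult, PermutationTest, TfceParams, report_clusters
from .preprocess import (
    AbundanceTable,
    CovariateTable,
    DesignMatrix,
    ImageStack,
    VoxelMask,
    assemble_design,
    build_voxel_mask,
)

logger = logging.getLogger(__name__)


class MicrobiomeBrainModel:
    """Voxelwise microbiome-brain association model for one imaging modality.

    Parameters
    ----------
    abundances, covariates, images
        The cohort tables; subjects must match in content and order.
    mask
        Optional boolean analysis mask; otherwise derived from the mean image.
    clinical
        Optional per-subject clinical-score table used by the post-hoc
        correlation analysis.
    """

    def __init__(
        self,
        abundances: AbundanceTable,
        covariates: CovariateTable,
        images: ImageStack,
        mask: np.ndarray | None = None,
        clinical: pd.DataFrame | None = None,
        floor: float = preprocess.DEFAULT_FLOOR,
        min_subject_frac: float = preprocess.DEFAULT_MIN_SUBJECT_FRAC,
        min_ra: float = preprocess.DEFAULT_MIN_RA,
        mask_threshold_frac: float = 0.1,
        K: int = DEFAULT_K,
        lambdas: np.ndarray = DEFAULT_LAMBDA_GRID,
        lambda_rule: str = "gcv",
        tfce_params: TfceParams | None = None,
        perm_scheme: str = "orthogonal",
    ):
        self.abundances = abundances
        self.covariates = covariates
        self.images = images
        self.clinical = clinical
        self.K = K
        self.lambdas = np.asarray(lambdas, dtype=float)
        self.lambda_rule = lambda_rule
        self.tfce_params = tfce_params or TfceParams()
        self.perm_scheme = perm_scheme
        self.design: DesignMatrix = assemble_design(
            abundances, covariates, floor=floor, min_subject_frac=min_subject_frac, min_ra=min_ra
        )
        if mask is not None:
            self.mask = build_voxel_mask(images, method="user", user_mask=mask)
        else:
            self.mask = build_voxel_mask(images, threshold_frac=mask_threshold_frac)
        logger.info(
            "model: %d subjects, %d retained families, %d in-mask voxels",
            len(self.design.subjects),
            self.design.n_families,
            self.mask.n_voxels,
        )

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "MicrobiomeBrainModel":
        """Build from a :class:`~gutbrainmap.synthetic.SyntheticCohort`."""
        kwargs.setdefault("clinical", cohort.clinical)
        return cls(cohort.abundances, cohort.covariates, cohort.images, **kwargs)

    @classmethod
    def from_files(
        cls,
        abundances_path,
        covariates_path,
        image_paths,
        clinical_path=None,
        mask_path=None,
        **kwargs,
    ) -> "MicrobiomeBrainModel":
        """Build from on-disk TSV tables and per-subject NIfTI images."""
        abundances = preprocess.read_abundances(abundances_path)
        covariates = preprocess.read_covariates(covariates_path)
        images = preprocess.read_image_stack(image_paths, subjects=abundances.subjects)
        clinical = preprocess.read_table(clinical_path) if clinical_path else None
        mask = None
        if mask_path:
            import nibabel as nib

            mask = np.asarray(nib.load(str(mask_path)).dataobj) != 0
        return cls(abundances, covariates, images, mask=mask, clinical=clinical, **kwargs)

    def fit(self, n_perms: int = 250, seed: int = 0, progress: bool = False) -> "MicrobiomeBrainResults":
        """Run the RSS-ratio map and its permutation inference.

        ``seed`` is the master seed: fold assignment and every permutation
        descend from it through named streams, so refitting with the same
        seed reproduces the result exactly and a staged permutation budget
        can be extended without invalidating earlier draws.
        """
        folds = FoldAssignment.create(
            len(self.design.subjects),
            K=self.K,
            seed=_seeds.stream_rng(seed, _seeds.STREAM_FOLDS).integers(2**31),
        )
        test = PermutationTest(
            self.design,
            self.images,
            self.mask,
            folds,
            seed=seed,
            lambdas=self.lambdas,
            lambda_rule=self.lambda_rule,
            tfce_params=self.tfce_params,
            perm_scheme=self.perm_scheme,
        )
        result = test.run(n_perms=n_perms, progress=progress)
        return MicrobiomeBrainResults(self, test, result, master_seed=seed)


class MicrobiomeBrainResults:
    """Fitted maps, permutation null, and post-hoc accessors for one model fit."""

    def __init__(
        self,
        model: MicrobiomeBrainModel,
        test: PermutationTest,
        result: InferenceResult,
        master_seed: int,
        thresholds: ClusterThresholds | None = None,
    ):
        self.model = model
        self._test = test
        self.inference = result
        self.master_seed = master_seed
        self.thresholds = thresholds or ClusterThresholds()

    # -- core accessors -----------------------------------------------------

    @property
    def stat_map(self) -> association.StatMap:
        return self.inference.stat_map

    @property
    def design(self) -> DesignMatrix:
        return self.model.design

    @property
    def folds(self) -> FoldAssignment:
        return self._test.folds

    @property
    def n_perms(self) -> int:
        return self.inference.n_perms

    def clusters(self, thresholds: ClusterThresholds | None = None) -> ClusterReport:
        return report_clusters(self.inference, thresholds or self.thresholds)

    def extend_permutations(self, extra: int) -> "MicrobiomeBrainResults":
        """Grow the permutation budget; equals a single larger run bit-for-bit."""
        result = self._test.extend(self.inference, extra)
        return MicrobiomeBrainResults(
            self.model, self._test, result, self.master_seed, self.thresholds
        )

    # -- post-hoc -----------------------------------------------------------

    def _scheme(self) -> inference.PermutationScheme:
        return self.inference.scheme

    def family_contributions(self, report: ClusterReport | None = None) -> pd.DataFrame:
        report = report if report is not None else self.clusters()
        peaks = report.peak_voxels()
        if not peaks:
            return pd.DataFrame(
                columns=["peak_id", "i", "j", "k", "family", "coefficient", "p", "stars"]
            )
        return posthoc.family_contributions(
            peaks,
            self.design,
            self.model.images,
            self._scheme(),
            mask=self.inference.mask,
            lambdas=self.model.lambdas,
        )

    def peak_values(self, report: ClusterReport | None = None) -> pd.DataFrame:
        """Per-subject image value at each reported cluster peak."""
        report = report if report is not None else self.clusters()
        cols = {}
        for row_id, ijk in zip(report.table["cluster_id"], report.peak_voxels()):
            cols[f"peak_{row_id}"] = self.model.images.data[(slice(None),) + ijk]
        return pd.DataFrame(cols, index=pd.Index(self.design.subjects, name="subject_id"))

    def clinical_correlations(
        self, clinical: pd.DataFrame | None = None, report: ClusterReport | None = None
    ) -> pd.DataFrame:
        clinical = clinical if clinical is not None else self.model.clinical
        if clinical is None:
            raise ValueError("no clinical table available; pass one explicitly")
        pv = self.peak_values(report)
        if pv.empty or pv.shape[1] == 0:
            return pd.DataFrame(
                columns=["peak_id", "variable", "r", "p", "n_used", "q",
                         "fdr_significant", "nominal_significant"]
            )
        return posthoc.clinical_correlations(pv, clinical)

    def subgroup_rerun(
        self, subgroup: np.ndarray, label: str = "subgroup", report: ClusterReport | None = None
    ) -> posthoc.SubgroupResult:
        report = report if report is not None else self.clusters()
        peaks = report.peak_voxels()
        if not peaks:
            raise ValueError("no reported clusters; nothing to recompute in the subgroup")
        return posthoc.subgroup_rerun(
            subgroup,
            peaks,
            self.design,
            self.model.images,
            self.folds,
            label=label,
            lambdas=self.model.lambdas,
            lambda_rule=self.model.lambda_rule,
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fit and the surviving clusters."""
        ratios = self.stat_map.in_mask_ratios()
        rep = self.clusters()
        lines = [
            "Microbiome-brain association (cross-validated Ridge RSS ratio)",
            "=" * 62,
            f"subjects:            {len(self.design.subjects)}",
            f"retained families:   {self.design.n_families}",
            f"in-mask voxels:      {int(self.inference.mask.sum())}",
            f"CV folds:            {self.folds.K}",
            f"permutations:        {self.n_perms} (min attainable p = {self.inference.min_p():.4g})",
            f"RSS ratio median:    {np.nanmedian(ratios):.4f}",
            f"RSS ratio max:       {np.nanmax(ratios):.4f}",
            f"clusters reported:   {len(rep)} "
            f"(FWE<{self.thresholds.fwe_alpha}; "
            f"uncorr p<{self.thresholds.uncorrected_p} & ratio>{self.thresholds.min_ratio})",
        ]
        if len(rep):
            lines.append("")
            lines.append(
                rep.table[inference.TSV_COLUMNS].to_string(
                    index=False, float_format=lambda v: f"{v:.4g}"
                )
            )
        return "\n".join(lines)

    def save(self, outdir) -> Path:
        """Write maps (NIfTI) and tables (TSV) for this fit."""
        import nibabel as nib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        aff = self.stat_map.affine

        def _save(name, arr):
            nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), aff), str(outdir / name))

        _save("rss_ratio.nii.gz", self.stat_map.ratio)
        _save("rss_covariates.nii.gz", self.stat_map.rss_covariates)
        _save("rss_full.nii.gz", self.stat_map.rss_full)
        _save("tfce.nii.gz", self.inference.tfce_map)
        _save("p_uncorrected.nii.gz", self.inference.p_uncorrected)
        _save("p_fwe.nii.gz", self.inference.p_fwe)
        _save("mask.nii.gz", self.inference.mask.astype(np.float32))
        pd.DataFrame({"max_tfce": self.inference.null_max_tfce}).to_csv(
            outdir / "null_max_tfce.tsv", sep="\t", index_label="perm", float_format="%.10g"
        )
        self.clusters().write(outdir / "clusters.tsv")
        return outdir

    def plot_stat_map(self, axis: int = 2, index: int | None = None, ax=None):
        """Show one slice of the RSS-ratio map (requires matplotlib)."""
        import matplotlib.pyplot as plt

        ratio = self.stat_map.ratio
        if index is None:
            index = ratio.shape[axis] // 2
        sl = np.take(ratio, index, axis=axis)
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(sl.T, origin="lower", cmap="magma")
        ax.set_title(f"RSS ratio, slice {index} along axis {axis}")
        plt.colorbar(im, ax=ax, label="RSS ratio")
        return ax
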