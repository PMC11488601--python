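"""End-to-end orchestration: preprocess -> association -> inference -> posthoc.

Each stage can also be run on its own against a run directory; everything a
later stage needs that is cheap to recompute (design matrix, fold
assignment, permutation scheme) is re-derived deterministically from the
config and master seed rather than deserialized, so stages compose without
hidden state.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, resolve_image_paths
from .model import MicrobiomeBrainModel, MicrobiomeBrainResults
from .posthoc import SubgroupTooSmallError

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _check_inputs(config: RunConfig) -> None:
    for name in ("abundances", "covariates"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"{name} file not found: {path!r}")
    if config.clinical and not Path(config.clinical).exists():
        raise FileNotFoundError(f"clinical file not found: {config.clinical!r}")
    resolve_image_paths(config.images)


def build_model(config: RunConfig) -> MicrobiomeBrainModel:
    config.validate()
    _check_inputs(config)
    return MicrobiomeBrainModel.from_files(
        config.abundances,
        config.covariates,
        resolve_image_paths(config.images),
        clinical_path=config.clinical or None,
        mask_path=config.mask or None,
        floor=config.floor,
        min_subject_frac=config.min_subject_frac,
        min_ra=config.min_ra,
        mask_threshold_frac=config.mask_threshold_frac,
        K=config.k_folds,
        lambdas=config.lambda_grid,
        lambda_rule=config.lambda_rule,
        tfce_params=config.tfce_params(),
        perm_scheme=config.perm_scheme,
    )


def fit_model(model: MicrobiomeBrainModel, config: RunConfig, progress: bool = True) -> MicrobiomeBrainResults:
    if 0 < config.stage_perms < config.n_perms:
        logger.info(
            "staged permutations: %d now, extending to %d", config.stage_perms, config.n_perms
        )
        results = model.fit(n_perms=config.stage_perms, seed=config.seed, progress=progress)
        return results.extend_permutations(config.n_perms - config.stage_perms)
    return model.fit(n_perms=config.n_perms, seed=config.seed, progress=progress)


def _covariate_clinical_frame(model: MicrobiomeBrainModel) -> pd.DataFrame:
    cov = pd.DataFrame(
        {"sex": model.covariates.sex, "age": model.covariates.age, "bmi": model.covariates.bmi},
        index=pd.Index(model.covariates.subjects, name="subject_id"),
    )
    if model.clinical is not None:
        cov = cov.join(model.clinical, how="left")
    return cov


def posthoc_tables(model, report, scheme, folds, config: RunConfig, outdir: Path) -> None:
    """Write contributions/clinical-correlation/subgroup tables for given peaks."""
    from . import posthoc as ph

    peaks = report.peak_voxels()
    if peaks:
        contributions = ph.family_contributions(
            peaks, model.design, model.images, scheme, mask=model.mask.mask,
            lambdas=config.lambda_grid,
        )
    else:
        contributions = pd.DataFrame(
            columns=["peak_id", "i", "j", "k", "family", "coefficient", "p", "stars"]
        )
    contributions.to_csv(outdir / "contributions.tsv", sep="\t", index=False, float_format="%.6g")
    if model.clinical is not None and peaks:
        cols = {
            f"peak_{cid}": model.images.data[(slice(None),) + ijk]
            for cid, ijk in zip(report.table["cluster_id"], peaks)
        }
        pv = pd.DataFrame(cols, index=pd.Index(model.design.subjects, name="subject_id"))
        corr = ph.clinical_correlations(pv, model.clinical)
        corr.to_csv(outdir / "clinical_correlations.tsv", sep="\t", index=False, float_format="%.6g")
    sub_rows = []
    if config.subgroups and peaks:
        frame = _covariate_clinical_frame(model)
        for label, query in config.subgroups.items():
            flags = frame.eval(query).to_numpy(dtype=bool)
            try:
                res = ph.subgroup_rerun(
                    flags, peaks, model.design, model.images, folds, label=label,
                    lambdas=config.lambda_grid, lambda_rule=config.lambda_rule,
                )
            except SubgroupTooSmallError as e:
                logger.warning("subgroup %r skipped: %s", label, e)
                sub_rows.append({"subgroup": label, "n": int(flags.sum()),
                                 "mean_delta": np.nan, "note": "too few subjects"})
                continue
            for _, r in res.table.iterrows():
                sub_rows.append(
                    {
                        "subgroup": label,
                        "n": res.n_subjects,
                        "peak_id": int(r["peak_id"]),
                        "ratio_full": r["ratio_full"],
                        "ratio_subgroup": r["ratio_subgroup"],
                        "delta": r["delta"],
                        "mean_delta": res.mean_delta,
                        "note": "",
                    }
                )
    if sub_rows:
        pd.DataFrame(sub_rows).to_csv(outdir / "subgroups.tsv", sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig, progress: bool = True) -> Path:
    """Execute all stages and write maps, tables and a provenance record.

    Identical config + seed yields byte-identical tables and numerically
    identical maps.
    """
    config.validate()
    _check_inputs(config)  # input problems surface directly, not as stage errors
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings = {}

    def timed(stage, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as e:  # noqa: BLE001 - rewrap with the stage name
            raise StageError(stage, e) from e
        timings[stage] = round(time.perf_counter() - t0, 3)
        return out

    model = timed("preprocess", build_model, config)
    results = timed("association+inference", fit_model, model, config, progress)
    timed("save-maps", results.save, outdir)
    report = results.clusters(config.thresholds())
    report.table.to_csv(outdir / "peaks.tsv", sep="\t", index=False, float_format="%.6g")
    timed(
        "posthoc", posthoc_tables, model, report, results._scheme(), results.folds, config, outdir
    )

    provenance = {
        "package": {"gutbrainmap": __version__},
        "versions": _versions(),
        "config": config.to_dict(),
        "seed": config.seed,
        "n_perms": results.n_perms,
        "n_subjects": len(results.design.subjects),
        "n_families_retained": results.design.n_families,
        "n_mask_voxels": int(results.inference.mask.sum()),
        "stage_seconds": timings,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    logger.info("run complete: %s", outdir)
    return outdir


def _versions() -> dict:
    import nibabel
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
    }


# ---------------------------------------------------------------------------
# individual stages (resumable against a run directory)


def stage_preprocess(config: RunConfig) -> Path:
    """Write the standardized design matrix and the analysis mask."""
    import nibabel as nib

    model = build_model(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = pd.DataFrame(
        model.design.X, index=pd.Index(model.design.subjects, name="subject_id"),
        columns=model.design.columns,
    )
    design.to_csv(outdir / "design.tsv", sep="\t", float_format="%.12g")
    record = {
        "columns": list(model.design.record.columns),
        "means": model.design.record.means.tolist(),
        "sds": model.design.record.sds.tolist(),
    }
    (outdir / "standardization.json").write_text(json.dumps(record, indent=1))
    nib.save(
        nib.Nifti1Image(model.mask.mask.astype(np.float32), model.images.affine),
        str(outdir / "mask.nii.gz"),
    )
    return outdir


def stage_map(config: RunConfig) -> Path:
    """Write the RSS-ratio map and its components (no permutations)."""
    import nibabel as nib

    from . import _seeds
    from .association import FoldAssignment, rss_ratio_map

    model = build_model(config)
    folds = FoldAssignment.create(
        len(model.design.subjects), K=config.k_folds,
        seed=_seeds.stream_rng(config.seed, _seeds.STREAM_FOLDS).integers(2**31),
    )
    smap = rss_ratio_map(
        model.design, model.images, model.mask, folds,
        lambdas=config.lambda_grid, lambda_rule=config.lambda_rule,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, arr in (
        ("rss_ratio.nii.gz", smap.ratio),
        ("rss_covariates.nii.gz", smap.rss_covariates),
        ("rss_full.nii.gz", smap.rss_full),
    ):
        nib.save(nib.Nifti1Image(np.asarray(arr, np.float32), smap.affine), str(outdir / name))
    return outdir


def stage_infer(config: RunConfig) -> Path:
    """Run the permutation inference and write p-maps and the cluster report."""
    model = build_model(config)
    results = fit_model(model, config)
    outdir = Path(config.outdir)
    results.save(outdir)
    results.clusters(config.thresholds()).table.to_csv(
        outdir / "peaks.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return outdir


def stage_posthoc(config: RunConfig) -> Path:
    """Post-hoc tables for an already-inferred run directory.

    Peaks are read from peaks.tsv; the permutation scheme and fold
    assignment are re-derived from the master seed, so no permutation maps
    need to be stored.
    """
    from . import _seeds
    from .association import FoldAssignment
    from .inference import ClusterReport, PermutationScheme

    outdir = Path(config.outdir)
    peaks_path = outdir / "peaks.tsv"
    if not peaks_path.exists():
        raise FileNotFoundError(f"peaks table not found: {peaks_path}; run the infer stage first")
    model = build_model(config)
    report = ClusterReport(pd.read_csv(peaks_path, sep="\t"))
    folds = FoldAssignment.create(
        len(model.design.subjects), K=config.k_folds,
        seed=_seeds.stream_rng(config.seed, _seeds.STREAM_FOLDS).integers(2**31),
    )
    n = len(model.design.subjects)
    n_units = n - 4 if config.perm_scheme == "orthogonal" else n  # 4 = intercept + 3 covariates
    scheme = PermutationScheme.create(n_units, config.n_perms, config.seed)
    posthoc_tables(model, report, scheme, folds, config, outdir)
    return outdir
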