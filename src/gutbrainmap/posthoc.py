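"""Post-hoc analyses at the voxels the inference stage flagged.

Three follow-ups mirror how such findings are normally unpacked: (1) which
bacterial families drive each peak, read off the signed Ridge coefficients of
a full-data refit, with per-family residual-permutation p-values that reuse
the voxelwise inference's permutation stream; (2) robustness of the RSS ratios in
subgroups (overweight/obesity, diet, smoking, medication strata); and (3)
Pearson correlations between the peak signals and clinical scores, corrected
across all peak x score tests with the Benjamini-Hochberg false discovery
rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .association import DEFAULT_LAMBDA_GRID, FoldAssignment, GcvRidge, RatioEngine
from .inference import PermutationScheme
from .preprocess import DesignMatrix, ImageStack, MaskError


class SubgroupTooSmallError(ValueError):
    """Raised when a subgroup is too small for K-fold cross-validation."""


def significance_class(p: float) -> str:
    """Tiered significance label for family contributions."""
    if p < 1e-6:
        return "<1e-06"
    if p < 1e-3:
        return "<0.001"
    if p < 0.01:
        return "<0.01"
    return ""


def _stars(p: float) -> str:
    return {"<1e-06": "***", "<0.001": "**", "<0.01": "*"}.get(significance_class(p), "")


def family_contributions(
    peaks: list,
    design: DesignMatrix,
    stack: ImageStack,
    scheme: PermutationScheme,
    mask: np.ndarray | None = None,
    lambdas: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> pd.DataFrame:
    """Signed per-family Ridge coefficients at each peak, with permutation p-values.

    The full-data Ridge model is refitted at every peak voxel; coefficients
    are reported per family on the log-abundance scale (back-transformed
    through the standardization record, which preserves signs).

    The p-value of a family is computed against its own residual-permutation
    null: the nuisance model for family f keeps the covariates AND all other
    families (fitted by the same GCV Ridge), its residuals are permuted with
    the permutation stream and budget of the voxelwise inference, and the
    full model — penalty held at the observed fit's GCV choice — is refitted
    on each surrogate. Keeping the other families in the nuisance is what
    makes an uninvolved family's p uniform at a genuine signal voxel: a
    global-null surrogate would scatter the real signal into the noise and
    distort every coefficient's null.
    """
    if mask is not None:
        for ijk in peaks:
            if not mask[tuple(ijk)]:
                raise MaskError(f"peak {tuple(ijk)} lies outside the analysis mask")
    ridge = GcvRidge(design.X, lambdas=lambdas)
    n = len(design.subjects)
    nf = design.n_families
    fam_sds = design.record.sds[:nf]
    # per-family nuisance designs (all columns but f), shared across peaks
    nuisance = [
        GcvRidge(np.delete(design.X, f, axis=1), lambdas=lambdas) for f in range(nf)
    ]
    # subject-level permutations from the same master stream and budget as the
    # voxelwise inference (its scheme may live in the covariate-complement
    # space and therefore have a different unit count)
    subj_scheme = PermutationScheme.create(n, scheme.B, scheme.seed)
    perms = np.stack([subj_scheme.permutation(b) for b in range(subj_scheme.B)])
    rows = []
    for peak_id, ijk in enumerate(peaks, start=1):
        y = stack.data[(slice(None),) + tuple(ijk)]
        sol = ridge.fit(y)
        obs = np.abs(sol.coef[:nf])
        pvals = np.empty(nf)
        for f in range(nf):
            nsol = nuisance[f].fit(y)
            g = nuisance[f].predict(nsol)
            e = y - g
            surro = g[None, :] + e[perms]  # (B, n); row 0 is y itself
            surro[0] = y
            coef_b = ridge.coef_single(surro.T, sol.lambda_, f)
            pvals[f] = float(np.mean(np.abs(coef_b) >= obs[f]))
        coefs_logra = sol.coef[:nf] / fam_sds
        for j, fam in enumerate(design.families):
            rows.append(
                {
                    "peak_id": peak_id,
                    "i": ijk[0],
                    "j": ijk[1],
                    "k": ijk[2],
                    "family": fam,
                    "coefficient": coefs_logra[j],
                    "p": pvals[j],
                    "stars": _stars(pvals[j]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SubgroupResult:
    """Recomputed RSS ratios at the reported peaks within one subject subgroup."""

    label: str
    n_subjects: int
    table: pd.DataFrame  # peak_id, ratio_full, ratio_subgroup, delta

    @property
    def mean_delta(self) -> float:
        return float(self.table["delta"].mean())


def subgroup_rerun(
    subgroup: np.ndarray,
    peaks: list,
    design: DesignMatrix,
    stack: ImageStack,
    folds: FoldAssignment,
    label: str = "subgroup",
    lambdas: np.ndarray = DEFAULT_LAMBDA_GRID,
    lambda_rule: str = "gcv",
) -> SubgroupResult:
    """RSS ratios at the reported peaks, recomputed on a subject subgroup.

    Folds are freshly assigned within the subgroup from the same fold seed,
    so the full-cohort subgroup reproduces the original assignment and yields
    deltas of exactly zero. Subgroups smaller than 2K subjects are refused:
    10-fold cross-validation is not meaningful there.
    """
    subgroup = np.asarray(subgroup, dtype=bool)
    if subgroup.shape != (len(design.subjects),):
        raise ValueError("subgroup must be a boolean flag per subject")
    n_sub = int(subgroup.sum())
    if n_sub < 2 * folds.K:
        raise SubgroupTooSmallError(
            f"subgroup {label!r} has {n_sub} subjects; need at least {2 * folds.K} for K={folds.K}"
        )
    Y = np.column_stack([stack.data[(slice(None),) + tuple(ijk)] for ijk in peaks])

    engine_full = RatioEngine(design, folds, lambdas=lambdas, lambda_rule=lambda_rule)
    ratio_full, _, _ = engine_full.rss_ratio(Y)

    sub_design = DesignMatrix(
        [s for s, keep in zip(design.subjects, subgroup) if keep],
        design.families,
        design.X[subgroup],
        design.record,
    )
    sub_folds = FoldAssignment.create(n_sub, K=folds.K, seed=folds.seed)
    engine_sub = RatioEngine(sub_design, sub_folds, lambdas=lambdas, lambda_rule=lambda_rule)
    ratio_sub, _, _ = engine_sub.rss_ratio(Y[subgroup])

    table = pd.DataFrame(
        {
            "peak_id": np.arange(1, len(peaks) + 1),
            "ratio_full": ratio_full,
            "ratio_subgroup": ratio_sub,
            "delta": ratio_sub - ratio_full,
        }
    )
    return SubgroupResult(label=label, n_subjects=n_sub, table=table)


def clinical_correlations(
    peak_values: pd.DataFrame,
    clinical: pd.DataFrame,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations between peak signals and clinical scores, BH-corrected.

    Correlations use pairwise-complete observations (clinical instruments
    often have per-test missingness); the Benjamini-Hochberg q-values span
    all peak x variable tests of the run. Two reporting tiers are flagged:
    FDR q < alpha and nominal p < 0.05. Constant vectors leave r undefined
    and are excluded from the BH family with a warning.
    """
    if list(peak_values.index) != list(clinical.index):
        clinical = clinical.reindex(peak_values.index)
    rows = []
    for peak in peak_values.columns:
        for var in clinical.columns:
            x = peak_values[peak].astype(float)
            y = clinical[var].astype(float)
            ok = x.notna() & y.notna()
            n_used = int(ok.sum())
            if n_used < 3:
                warnings.warn(f"fewer than 3 complete pairs for ({peak}, {var}); skipped")
                continue
            xs, ys = x[ok].to_numpy(), y[ok].to_numpy()
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                warnings.warn(
                    f"correlation undefined for ({peak}, {var}): constant vector; "
                    "excluded from the FDR family"
                )
                continue
            r, p = stats.pearsonr(xs, ys)
            rows.append({"peak_id": peak, "variable": var, "r": r, "p": p, "n_used": n_used})
    df = pd.DataFrame(rows, columns=["peak_id", "variable", "r", "p", "n_used"])
    if len(df):
        _, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
        df["q"] = q
        df["fdr_significant"] = df["q"] < fdr_alpha
        df["nominal_significant"] = df["p"] < 0.05
    else:
        df["q"] = []
        df["fdr_significant"] = []
        df["nominal_significant"] = []
    return df
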