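"""Permutation inference for the RSS-ratio map: Freedman-Lane, TFCE, FWE.

The null hypothesis at every voxel is that the bacterial families add nothing
beyond the covariates. Freedman-Lane surrogates realize that null while
preserving the covariate structure: the covariate-only model is fitted once,
its residuals are permuted across subjects, the fitted covariate part is
added back, and the entire RSS-ratio pipeline (cross-validation and penalty
selection included) is rerun on the surrogate outcome. Voxelwise uncorrected
p-values come from the per-voxel null of the ratio; family-wise error (FWE)
control across voxels comes from the permutation distribution of the
map-wide maximum of the TFCE-enhanced statistic.

TFCE (threshold-free cluster enhancement) integrates cluster extent^E x
height^H over all thresholds of the nonnegative statistic
s = max(RSS_ratio - 1, 0), giving cluster-like sensitivity without committing
to a single cluster-forming threshold.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _seeds
from .association import DEFAULT_LAMBDA_GRID, FoldAssignment, RatioEngine, StatMap
from .preprocess import DesignMatrix, ImageStack, VoxelMask

logger = logging.getLogger(__name__)

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class TfceParams:
    """TFCE parameters: extent exponent E, height exponent H, step dh, connectivity.

    E=0.5, H=2 and 26-connectivity are the de-facto standard choices for 3-D
    statistic maps. dh=None means each map is integrated in 100 equal steps up
    to its own maximum.
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    connectivity: int = 26

    def __post_init__(self):
        if self.E < 0 or self.H < 0:
            raise ValueError("TFCE exponents must be nonnegative")
        if self.dh is not None and self.dh <= 0:
            raise ValueError(f"TFCE step dh must be positive, got {self.dh}")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError(f"connectivity must be one of 6/18/26, got {self.connectivity}")

    @property
    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[self.connectivity])


def ratio_excess(ratio: np.ndarray) -> np.ndarray:
    """The enhanced quantity s = max(ratio - 1, 0); NaN (outside mask) maps to 0.

    Null RSS ratios center near 1, and TFCE needs a nonnegative statistic
    anchored at 0, so the excess over 1 is what gets enhanced.
    """
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(ratio), 0.0, np.maximum(ratio - 1.0, 0.0))


def tfce_heights(smax: float, dh: float | None) -> tuple[np.ndarray, float]:
    """The threshold ladder (heights, step) used to integrate a map up to smax."""
    if smax <= 0:
        return np.empty(0), 0.0
    if dh is None:
        step = smax / 100.0
        return smax * (np.arange(1, 101) / 100.0), step
    n = int(math.floor(smax / dh + 1e-9))
    return dh * np.arange(1, n + 1), dh


def tfce(stat: np.ndarray, mask: np.ndarray | None = None, params: TfceParams = TfceParams()) -> np.ndarray:
    """TFCE-enhance a nonnegative 3-D statistic map.

    TFCE(v) = sum over thresholds h = dh, 2dh, ... <= s(v) of
    e_h(v)^E * h^H * dh, where e_h(v) is the size of the connected component
    containing v in the supra-threshold set {s >= h}.
    """
    s = np.asarray(stat, dtype=float)
    if s.ndim != 3:
        raise ValueError("TFCE expects a 3-D map")
    s = np.where(np.isnan(s), 0.0, s)
    if mask is not None:
        s = np.where(mask, s, 0.0)
    if (s < 0).any():
        raise ValueError("TFCE input must be nonnegative; apply ratio_excess first")
    out = np.zeros_like(s)
    smax = float(s.max())
    heights, step = tfce_heights(smax, params.dh)
    if heights.size == 0:
        return out
    structure = params.structure
    eps = step * 1e-9  # guard float noise in h = i*dh against s(v) == h
    for h in heights:
        supra = s >= h - eps
        if not supra.any():
            break
        lab, _ = ndimage.label(supra, structure=structure)
        sizes = np.bincount(lab.ravel())
        out[supra] += sizes[lab[supra]] ** params.E * h**params.H * step
    return out


# ---------------------------------------------------------------------------
# permutations


@dataclass
class PermutationScheme:
    """Subject-index permutations derived from a master seed; the first is identity.

    Permutations are sampled uniformly without enforcing distinctness (n! far
    exceeds any practical B at study scale); for degenerate n <= 7 the scheme
    enumerates all n! permutations exhaustively instead.
    """

    n_subjects: int
    B: int
    seed: int
    exhaustive: bool = False
    _perms: list = field(default_factory=list, repr=False)

    @classmethod
    def create(cls, n_subjects: int, B: int, seed: int) -> "PermutationScheme":
        if B < 1:
            raise ValueError("need at least one permutation (the identity)")
        if n_subjects <= 7:
            perms = [np.array(p) for p in itertools.permutations(range(n_subjects))]
            logger.info(
                "n=%d <= 7: enumerating all %d permutations exhaustively", n_subjects, len(perms)
            )
            return cls(n_subjects, len(perms), seed, exhaustive=True, _perms=perms)
        return cls(n_subjects, B, seed)

    def permutation(self, b: int) -> np.ndarray:
        if not 0 <= b < self.B:
            raise IndexError(f"permutation index {b} out of range [0, {self.B})")
        if self.exhaustive:
            return self._perms[b]
        return _seeds.permutation_for(self.seed, b, self.n_subjects)

    def extended(self, extra: int) -> "PermutationScheme":
        if self.exhaustive:
            return self
        return replace(self, B=self.B + extra)


def freedman_lane_surrogate(
    y: np.ndarray,
    Z: np.ndarray,
    perm: np.ndarray,
    gamma: np.ndarray | None = None,
    resid: np.ndarray | None = None,
) -> np.ndarray:
    """Freedman-Lane surrogate outcome y* = Z gamma-hat + P eps-hat.

    Z must contain the intercept column; the reduced model is an ordinary
    least-squares fit of y on Z, whose residuals sum to zero, so the surrogate
    preserves the mean of y under any permutation. The identity permutation
    returns y itself.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    perm = np.asarray(perm)
    if gamma is None:
        gamma, *_ = np.linalg.lstsq(Z, y, rcond=None)
    if resid is None:
        resid = y - Z @ gamma
    if len(resid) != len(perm):
        raise ValueError(f"residual length {len(resid)} != permutation length {len(perm)}")
    if np.array_equal(perm, np.arange(len(perm))):
        return y.copy()
    return Z @ gamma + np.asarray(resid)[perm]


class SurrogateFactory:
    """Null outcomes from residual permutation under the covariate-only model.

    Two schemes are available. ``orthogonal`` (the default) permutes the
    reduced-model residuals inside an orthonormal basis of the orthogonal
    complement of the covariate column space: every surrogate keeps exactly
    the same covariate-aligned component and the same residual energy as the
    observed data, which makes the non-pivotal CV-RSS-ratio statistic
    exchangeable across permutations (exactly so for Gaussian errors).
    ``freedman_lane`` is the textbook construction y* = Z gamma-hat + P
    eps-hat; it is kept selectable but, for a cross-validated statistic, it
    converts part of the exchangeable noise into consistently fittable
    covariate signal and measurably miscalibrates the null at small n.

    In both schemes permutation 0 is the identity and reproduces the
    observed outcome exactly.
    """

    def __init__(self, Z: np.ndarray, Y: np.ndarray, method: str = "orthogonal"):
        if method not in ("orthogonal", "freedman_lane"):
            raise ValueError(f"unknown surrogate method {method!r}")
        self.method = method
        Z = np.asarray(Z, dtype=float)
        self.Y = np.asarray(Y, dtype=float)
        self.n, self.q = Z.shape
        gamma, *_ = np.linalg.lstsq(Z, self.Y, rcond=None)
        self.gamma = gamma
        self.fitted = Z @ gamma
        self.resid = self.Y - self.fitted
        if method == "orthogonal":
            Qfull, _ = np.linalg.qr(Z, mode="complete")
            self.Q = Qfull[:, self.q:]  # n x (n - q), orthonormal, Q'Z = 0
            self.core = self.Q.T @ self.resid
            self.n_units = self.n - self.q
        else:
            self.n_units = self.n

    def surrogate(self, b: int, scheme: "PermutationScheme") -> np.ndarray:
        if b == 0:
            return self.Y
        perm = scheme.permutation(b)
        if self.method == "orthogonal":
            return self.fitted + self.Q @ self.core[perm]
        return self.fitted + self.resid[perm]


def permutation_pvalues(observed: np.ndarray, null_stats: np.ndarray) -> np.ndarray:
    """p = #{b : stat_b >= observed} / B, the identity permutation included in the null.

    The smallest attainable p is therefore 1/B (0.004 at B = 250).
    """
    null_stats = np.asarray(null_stats, dtype=float)
    if null_stats.size == 0:
        raise ValueError("empty permutation null")
    observed = np.asarray(observed, dtype=float)
    B = null_stats.shape[0]
    return (null_stats >= observed[None, ...]).sum(axis=0) / B


def fwe_correct(observed_tfce: np.ndarray, null_max: np.ndarray) -> np.ndarray:
    """FWE p(v) = #{b : max-over-mask TFCE_b >= TFCE_obs(v)} / B (identity included)."""
    null_max = np.asarray(null_max, dtype=float)
    if null_max.size == 0:
        raise ValueError("empty max-TFCE null")
    obs = np.asarray(observed_tfce, dtype=float)
    return (null_max[:, None] >= obs.ravel()[None, :]).sum(axis=0).reshape(obs.shape) / len(null_max)


# ---------------------------------------------------------------------------
# the full permutation test


@dataclass
class InferenceResult:
    """Observed TFCE map, p-maps, and the permutation null behind them.

    ``p_fwe`` is clipped from below at ``p_uncorrected`` so the family-wise
    p-value never undercuts the voxelwise one (taking the elementwise maximum
    of two valid p-values keeps FWE control and enforces the expected
    ordering between the corrected and uncorrected maps).
    """

    stat_map: StatMap
    tfce_map: np.ndarray
    p_uncorrected: np.ndarray
    p_fwe: np.ndarray
    null_max_tfce: np.ndarray
    null_ratios: np.ndarray  # (B, n_in_mask_voxels)
    n_perms: int
    tfce_params: TfceParams
    seed: int
    scheme: PermutationScheme | None = None

    @property
    def mask(self) -> np.ndarray:
        return self.stat_map.mask

    def min_p(self) -> float:
        return 1.0 / self.n_perms


class PermutationTest:
    """Freedman-Lane permutation test of the microbiota block over a voxel mask.

    Precomputes the per-fold Ridge factorizations and the reduced-model
    (covariate-only OLS) fit once; each permutation replays the complete
    RSS-ratio pipeline on the surrogate outcomes. Runs can be staged: an
    initial budget (e.g. 50) extended later (e.g. by 200) reproduces exactly
    the single larger run, because permutation b is a pure function of the
    master seed and b.
    """

    def __init__(
        self,
        design: DesignMatrix,
        stack: ImageStack,
        mask: VoxelMask,
        folds: FoldAssignment,
        seed: int,
        lambdas: np.ndarray = DEFAULT_LAMBDA_GRID,
        lambda_rule: str = "gcv",
        tfce_params: TfceParams = TfceParams(),
        perm_scheme: str = "orthogonal",
    ):
        self.design = design
        self.stack = stack
        self.mask = mask
        self.folds = folds
        self.seed = int(seed)
        self.tfce_params = tfce_params
        self.engine = RatioEngine(design, folds, lambdas=lambdas, lambda_rule=lambda_rule)
        self.Y = stack.data[:, mask.mask]
        n = self.Y.shape[0]
        Z = np.column_stack([np.ones(n), design.covariate_block])
        self.surrogates = SurrogateFactory(Z, self.Y, method=perm_scheme)

    def _ratio_for(self, b: int, scheme: PermutationScheme) -> np.ndarray:
        ratio, _, _ = self.engine.rss_ratio(self.surrogates.surrogate(b, scheme))
        return ratio

    def _embed(self, values: np.ndarray) -> np.ndarray:
        out = np.full(self.stack.shape, np.nan)
        out[self.mask.mask] = values
        return out

    def _tfce_of(self, ratios: np.ndarray) -> np.ndarray:
        s = np.zeros(self.stack.shape)
        s[self.mask.mask] = np.maximum(ratios - 1.0, 0.0)
        return tfce(s, params=self.tfce_params)

    def run(self, n_perms: int = 250, progress: bool = False) -> InferenceResult:
        scheme = PermutationScheme.create(self.surrogates.n_units, n_perms, self.seed)
        null_ratios = np.empty((scheme.B, self.Y.shape[1]))
        for b in range(scheme.B):
            null_ratios[b] = self._ratio_for(b, scheme)
            if progress and (b + 1) % 25 == 0:
                logger.info("permutation %d/%d", b + 1, scheme.B)
        return self._assemble(null_ratios, scheme)

    def extend(self, result: InferenceResult, extra_perms: int) -> InferenceResult:
        """Add permutations to an earlier result; equals one larger run bit-for-bit."""
        scheme = PermutationScheme.create(self.surrogates.n_units, result.n_perms, self.seed)
        if scheme.exhaustive:
            logger.info("exhaustive scheme already complete; nothing to extend")
            return result
        scheme = scheme.extended(extra_perms)
        new = np.empty((extra_perms, self.Y.shape[1]))
        for i, b in enumerate(range(result.n_perms, scheme.B)):
            new[i] = self._ratio_for(b, scheme)
        return self._assemble(np.vstack([result.null_ratios, new]), scheme)

    def _assemble(self, null_ratios: np.ndarray, scheme: PermutationScheme) -> InferenceResult:
        B = null_ratios.shape[0]
        obs_ratio = null_ratios[0]
        null_max = np.empty(B)
        tfce_obs = None
        for b in range(B):
            t = self._tfce_of(null_ratios[b])
            if b == 0:
                tfce_obs = t
            null_max[b] = t[self.mask.mask].max()
        p_unc_flat = permutation_pvalues(obs_ratio, null_ratios)
        p_fwe = fwe_correct(tfce_obs, null_max)
        p_unc = self._embed(p_unc_flat)
        p_fwe = np.where(self.mask.mask, np.maximum(p_fwe, np.where(np.isnan(p_unc), 0, p_unc)), np.nan)
        ratio_map = self._embed(obs_ratio)
        _, rss_cov, rss_full = self.engine.rss_ratio(self.Y)
        stat_map = StatMap(
            ratio=ratio_map,
            rss_covariates=self._embed(rss_cov),
            rss_full=self._embed(rss_full),
            mask=self.mask.mask,
            affine=self.stack.affine,
        )
        return InferenceResult(
            stat_map=stat_map,
            tfce_map=tfce_obs,
            p_uncorrected=p_unc,
            p_fwe=p_fwe,
            null_max_tfce=null_max,
            null_ratios=null_ratios,
            n_perms=B,
            tfce_params=self.tfce_params,
            seed=self.seed,
            scheme=scheme,
        )


# ---------------------------------------------------------------------------
# cluster reporting


@dataclass
class ClusterThresholds:
    """Reporting regimes: FWE < alpha, plus exploratory uncorrected-p + ratio floor."""

    fwe_alpha: float = 0.05
    uncorrected_p: float = 0.004
    min_ratio: float = 1.33


TSV_COLUMNS = ["cluster_id", "x", "y", "z", "rss_ratio", "cs", "p_type", "p_value"]


@dataclass
class ClusterReport:
    """One row per surviving cluster: peak world coordinates, ratio, size, p."""

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def write(self, path) -> None:
        self.table[TSV_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")

    def peak_voxels(self) -> list[tuple[int, int, int]]:
        return [tuple(map(int, ijk)) for ijk in self.table[["i", "j", "k"]].to_numpy()]


def _clusters_for(surviving: np.ndarray, ratio: np.ndarray, p_map: np.ndarray, structure) -> list[dict]:
    rows = []
    lab, nlab = ndimage.label(surviving, structure=structure)
    for c in range(1, nlab + 1):
        members = np.flatnonzero(lab.ravel() == c)
        ratios = ratio.ravel()[members]
        # peak = in-cluster voxel with maximal ratio; ties resolve to the
        # lexicographically smallest voxel index (argmax returns the first).
        peak_flat = members[int(np.argmax(ratios))]
        ijk = np.unravel_index(peak_flat, ratio.shape)
        rows.append(
            {
                "i": ijk[0],
                "j": ijk[1],
                "k": ijk[2],
                "rss_ratio": float(ratio[ijk]),
                "cs": int(len(members)),
                "p_value": float(p_map[ijk]),
            }
        )
    return rows


def report_clusters(
    result: InferenceResult,
    thresholds: ClusterThresholds = ClusterThresholds(),
    connectivity: int | None = None,
) -> ClusterReport:
    """Group surviving voxels into clusters and report peaks, sizes and p-values.

    Two regimes are evaluated: the primary FWE < alpha map, and the
    exploratory regime (uncorrected p below its threshold AND RSS ratio above
    the reporting floor). An empty report is a legitimate outcome.
    """
    conn = connectivity if connectivity is not None else result.tfce_params.connectivity
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[conn])
    ratio = result.stat_map.ratio
    mask = result.mask
    with np.errstate(invalid="ignore"):
        fwe_surv = mask & (result.p_fwe < thresholds.fwe_alpha)
        unc_surv = (
            mask
            & (result.p_uncorrected < thresholds.uncorrected_p)
            & (ratio > thresholds.min_ratio)
        )
    rows = []
    for p_type, surv, pmap in (
        ("fwe", fwe_surv, result.p_fwe),
        ("uncorrected", unc_surv, result.p_uncorrected),
    ):
        for r in _clusters_for(surv, ratio, pmap, structure):
            r["p_type"] = p_type
            rows.append(r)
    if not rows:
        df = pd.DataFrame(columns=TSV_COLUMNS + ["i", "j", "k"])
        return ClusterReport(df)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["p_type", "rss_ratio", "i", "j", "k"], ascending=[True, False, True, True, True]
    ).reset_index(drop=True)
    df["cluster_id"] = np.arange(1, len(df) + 1)
    world = nib_affine_apply(result.stat_map.affine, df[["i", "j", "k"]].to_numpy())
    df[["x", "y", "z"]] = world
    return ClusterReport(df[TSV_COLUMNS + ["i", "j", "k"]])


def nib_affine_apply(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Voxel indices -> world (scanner/atlas) coordinates through the image affine."""
    ijk = np.atleast_2d(ijk)
    return (affine[:3, :3] @ ijk.T + affine[:3, 3:4]).T
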