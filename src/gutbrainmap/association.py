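"""Per-voxel Ridge fits and the cross-validated RSS-ratio statistic.

For each voxel v the association between the microbiota and the brain is
measured by

    RSS_ratio(v) = RSS_covariates(v) / RSS_full(v),

where both residual sums of squares are 10-fold cross-validated: the Ridge
models (full = log-abundances + sex/age/BMI; reduced = covariates only) are
trained on nine tenths of the subjects — including column standardization and
penalty selection — and the RSS is accumulated over the held-out tenths.
Ratios above 1 mean the bacterial families improve out-of-sample prediction
of the voxel beyond the covariates alone; cross-validation is what keeps the
added high-dimensional block from inflating the statistic by overfitting.

All voxels share the same design matrix, so the per-fold Ridge solutions for
every voxel and every penalty reduce to a handful of matrix products against
a single per-fold SVD; :class:`CVPlan` precomputes those factors once and is
reused across the thousands of permutation replays the inference stage needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import DesignMatrix, ImageStack, VoxelMask

DEFAULT_K = 10
DEFAULT_LAMBDA_GRID = np.logspace(-3, 3, 20)

_RANK_TOL = 1e-12


class FoldError(ValueError):
    """Raised when a cross-validation fold is unusable."""


@dataclass
class FoldAssignment:
    """Deterministic K-fold split; labels in 1..K, fold sizes differing by <= 1."""

    K: int
    labels: np.ndarray
    seed: int

    @classmethod
    def create(cls, n_subjects: int, K: int = DEFAULT_K, seed: int = 0) -> "FoldAssignment":
        if K < 2 or K > n_subjects:
            raise FoldError(f"K={K} folds for {n_subjects} subjects is not valid")
        order = np.random.default_rng(seed).permutation(n_subjects)
        labels = np.empty(n_subjects, dtype=int)
        labels[order] = np.arange(n_subjects) % K + 1
        return cls(K=K, labels=labels, seed=seed)

    @property
    def n_subjects(self) -> int:
        return len(self.labels)

    def test_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def train_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels != k)


@dataclass
class RidgeSolution:
    """A single Ridge fit: penalty, unpenalized intercept, slope per design column."""

    lambda_: float
    intercept: float
    coef: np.ndarray


def fit_ridge(X: np.ndarray, y: np.ndarray, lambda_: float) -> RidgeSolution:
    """Closed-form Ridge: minimize ||y - a - Xb||^2 + lambda * ||b||^2.

    The intercept is not penalized (fits via centering). At lambda = 0 with a
    collinear design the normal equations are singular; the minimum-norm
    least-squares solution is returned with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambda_ < 0:
        raise ValueError(f"lambda must be nonnegative, got {lambda_}")
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one row per element of y")
    if X.shape[0] < 2:
        raise ValueError("ridge fit needs at least 2 observations")
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    p = X.shape[1]
    if p == 0:
        return RidgeSolution(lambda_, float(ym), np.zeros(0))
    if lambda_ == 0:
        coef, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
        if rank < p:
            warnings.warn(
                "design is rank-deficient at lambda=0; returning the minimum-norm solution"
            )
    else:
        A = Xc.T @ Xc + lambda_ * np.eye(p)
        coef = np.linalg.solve(A, Xc.T @ yc)
    return RidgeSolution(float(lambda_), float(ym - xm @ coef), coef)


class _FoldFactor:
    """Per-fold SVD factorization of the training design, shared across outcomes.

    Training columns are standardized with training means/sds (zero-sd columns
    get sd 1, i.e. stay constant-zero after centering). With Xs = U S V', the
    ridge solution for every penalty on the grid is a reweighting of U'y, so
    training RSS (for GCV), effective df and held-out predictions for all
    penalties come from one pass of matrix products.
    """

    def __init__(self, X: np.ndarray, train: np.ndarray, test: np.ndarray, lambdas: np.ndarray):
        self.train = train
        self.test = test
        self.n_train = len(train)
        Xt = X[train]
        self.mu = Xt.mean(axis=0)
        sd = Xt.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        self.sd = sd
        Xt_s = (Xt - self.mu) / sd
        if X.shape[1] == 0:
            self.r = 0
            return
        U, s, Vt = np.linalg.svd(Xt_s, full_matrices=False)
        keep = s > (s[0] * _RANK_TOL if s.size and s[0] > 0 else np.inf)
        self.U = np.ascontiguousarray(U[:, keep])
        self.s = s[keep]
        self.r = int(keep.sum())
        Xv_s = (X[test] - self.mu) / sd
        self.G = np.ascontiguousarray(Xv_s @ Vt[keep].T)  # (n_test, r)
        s2 = self.s**2
        lam = np.asarray(lambdas, dtype=float)[:, None]
        d = s2 / (s2 + lam)  # (L, r) shrinkage factors
        self.w_train = 2 * d - d * d  # weights for training RSS
        self.df = d.sum(axis=1) + 1.0  # effective dof incl. intercept
        self.f = self.s / (s2 + lam)  # (L, r) coefficient reweighting
        # (L * n_test, r) stacked prediction operators, one block per lambda
        self.GF = np.ascontiguousarray(
            (self.G[None, :, :] * self.f[:, None, :]).reshape(-1, self.r)
        )


class CVPlan:
    """Precomputed cross-validation machinery for one design + fold assignment.

    ``rss(Y)`` returns the cross-validated RSS for every column of Y (one
    outcome per voxel) under the configured penalty-selection rule. Chunking
    over voxels gives results identical to one-voxel-at-a-time processing.
    """

    def __init__(
        self,
        X: np.ndarray,
        folds: FoldAssignment,
        lambdas: np.ndarray = DEFAULT_LAMBDA_GRID,
        lambda_rule: str = "gcv",
    ):
        X = np.asarray(X, dtype=float)
        if X.shape[0] != folds.n_subjects:
            raise FoldError(
                f"design has {X.shape[0]} rows but folds cover {folds.n_subjects} subjects"
            )
        lambdas = np.asarray(lambdas, dtype=float)
        if lambdas.size == 0 or (lambdas < 0).any():
            raise ValueError("lambda grid must be non-empty and nonnegative")
        if lambda_rule not in ("gcv", "fixed"):
            raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
        self.lambdas = np.sort(lambdas)
        self.lambda_rule = lambda_rule
        self.folds = folds
        self.n, self.p = X.shape
        self._factors = []
        for k in range(1, folds.K + 1):
            train = folds.train_indices(k)
            test = folds.test_indices(k)
            if len(train) < 2:
                raise FoldError(f"fold {k} leaves fewer than 2 training subjects")
            self._factors.append(_FoldFactor(X, train, test, self.lambdas))

    def rss(self, Y: np.ndarray, return_lambdas: bool = False):
        """Cross-validated RSS per outcome column (summed over all held-out subjects)."""
        Y = np.asarray(Y, dtype=float)
        squeeze = Y.ndim == 1
        if squeeze:
            Y = Y[:, None]
        if Y.shape[0] != self.n:
            raise FoldError(f"Y has {Y.shape[0]} rows, expected {self.n}")
        V = Y.shape[1]
        L = len(self.lambdas)
        total = np.zeros(V)
        chosen = np.zeros((len(self._factors), V)) if return_lambdas else None
        for fi, F in enumerate(self._factors):
            Yt = Y[F.train]
            ym = Yt.mean(axis=0)
            Ytc = Yt - ym
            Yv = Y[F.test]
            if F.r == 0 or self.p == 0:
                # intercept-only model: predict the training mean
                total += ((Yv - ym) ** 2).sum(axis=0)
                if chosen is not None:
                    chosen[fi] = self.lambdas[-1]
                continue
            A = F.U.T @ Ytc  # (r, V)
            preds = (F.GF @ A).reshape(L, len(F.test), V) + ym
            err2 = ((Yv[None, :, :] - preds) ** 2).sum(axis=1)  # (L, V)
            if self.lambda_rule == "fixed" and L == 1:
                sel = np.zeros(V, dtype=int)
            else:
                sq = (Ytc**2).sum(axis=0)
                rss_train = sq[None, :] - F.w_train @ (A * A)  # (L, V)
                np.maximum(rss_train, 0.0, out=rss_train)
                denom = np.maximum(1.0 - F.df / F.n_train, 1e-12) ** 2
                gcv = rss_train / denom[:, None]
                # ties break toward the larger penalty
                sel = L - 1 - np.argmin(gcv[::-1], axis=0)
            total += err2[sel, np.arange(V)]
            if chosen is not None:
                chosen[fi] = self.lambdas[sel]
        if squeeze:
            total = total[0]
            if chosen is not None:
                chosen = chosen[:, 0]
        return (total, chosen) if return_lambdas else total

    def rss_path(self, y: np.ndarray) -> np.ndarray:
        """Cross-validated RSS for each penalty on the grid (no per-fold selection)."""
        y = np.asarray(y, dtype=float)
        L = len(self.lambdas)
        out = np.zeros(L)
        for F in self._factors:
            yt = y[F.train]
            ym = yt.mean()
            if F.r == 0:
                out += ((y[F.test] - ym) ** 2).sum()
                continue
            A = F.U.T @ (yt - ym)
            preds = (F.GF @ A).reshape(L, len(F.test)) + ym
            out += ((y[F.test][None, :] - preds) ** 2).sum(axis=1)
        return out


def select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    folds: FoldAssignment,
    grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> float:
    """The grid penalty minimizing K-fold CV RSS; ties broken toward the larger penalty."""
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 1:
        return float(grid[0])
    plan = CVPlan(X, folds, lambdas=grid, lambda_rule="fixed")
    path = plan.rss_path(y)
    return float(grid[len(grid) - 1 - int(np.argmin(path[::-1]))])


def cv_rss(
    X: np.ndarray,
    y: np.ndarray,
    folds: FoldAssignment,
    lambdas: np.ndarray = DEFAULT_LAMBDA_GRID,
    lambda_rule: str = "gcv",
) -> float:
    """Cross-validated residual sum of squares for one outcome.

    Standardization and penalty selection happen strictly inside each training
    part; the held-out squared errors are summed over all subjects.
    """
    plan = CVPlan(X, folds, lambdas=lambdas, lambda_rule=lambda_rule)
    return float(plan.rss(y))


class GcvRidge:
    """Full-data Ridge with the penalty chosen by GCV over a grid.

    Shares the SVD across outcomes, so refitting the same design on many
    (surrogate) outcomes — as the permutation-based contribution p-values
    require — costs a few matrix-vector products per outcome. Coefficients
    are returned on the scale of the supplied (already standardized) columns.
    """

    def __init__(self, X: np.ndarray, lambdas: np.ndarray = DEFAULT_LAMBDA_GRID):
        X = np.asarray(X, dtype=float)
        self._X = X
        self.n, self.p = X.shape
        self.lambdas = np.sort(np.asarray(lambdas, dtype=float))
        self.xm = X.mean(axis=0)
        Xc = X - self.xm
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        keep = s > (s[0] * _RANK_TOL if s.size and s[0] > 0 else np.inf)
        self.U, self.s, self.Vt = U[:, keep], s[keep], Vt[keep]
        s2 = self.s**2
        lam = self.lambdas[:, None]
        d = s2 / (s2 + lam)
        self.w_train = 2 * d - d * d
        self.df = d.sum(axis=1) + 1.0
        self.f = self.s / (s2 + lam)

    def fit(self, y: np.ndarray, lambda_: float | None = None) -> RidgeSolution:
        """GCV-selected fit, or — with ``lambda_`` given — a fixed-penalty fit.

        The fixed-penalty path lets permutation nulls replay exactly the
        estimator that produced an observed coefficient.
        """
        y = np.asarray(y, dtype=float)
        ym = y.mean()
        yc = y - ym
        A = self.U.T @ yc
        if lambda_ is None:
            rss = np.maximum((yc**2).sum() - self.w_train @ (A * A), 0.0)
            gcv = rss / np.maximum(1.0 - self.df / self.n, 1e-12) ** 2
            L = len(self.lambdas)
            sel = L - 1 - int(np.argmin(gcv[::-1]))  # ties toward the larger penalty
        else:
            sel = int(np.argmin(np.abs(self.lambdas - lambda_)))
        coef = self.Vt.T @ (self.f[sel] * A)
        return RidgeSolution(float(self.lambdas[sel]), float(ym - self.xm @ coef), coef)

    def coef_single(self, Y: np.ndarray, lambda_: float, index: int) -> np.ndarray:
        """Coefficient ``index`` of the fixed-penalty fit, for every column of Y."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
        A = self.U.T @ (Y - Y.mean(axis=0))
        sel = int(np.argmin(np.abs(self.lambdas - lambda_)))
        return (self.Vt.T[index] * self.f[sel]) @ A

    def predict(self, sol: RidgeSolution, X: np.ndarray | None = None) -> np.ndarray:
        X = self._X if X is None else np.asarray(X, dtype=float)
        return sol.intercept + X @ sol.coef


@dataclass
class StatMap:
    """RSS-ratio map on the analysis mask (NaN outside), with its RSS components."""

    ratio: np.ndarray
    rss_covariates: np.ndarray
    rss_full: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def in_mask_ratios(self) -> np.ndarray:
        return self.ratio[self.mask]


class RatioEngine:
    """Covariate-only and full-model CV plans sharing one fold assignment."""

    def __init__(
        self,
        design: DesignMatrix,
        folds: FoldAssignment,
        lambdas: np.ndarray = DEFAULT_LAMBDA_GRID,
        lambda_rule: str = "gcv",
    ):
        self.design = design
        self.folds = folds
        self.plan_full = CVPlan(design.X, folds, lambdas=lambdas, lambda_rule=lambda_rule)
        self.plan_cov = CVPlan(design.covariate_block, folds, lambdas=lambdas, lambda_rule=lambda_rule)

    def rss_ratio(self, Y: np.ndarray):
        """(ratio, rss_cov, rss_full) per outcome column of Y."""
        rss_full = np.atleast_1d(self.plan_full.rss(Y))
        rss_cov = np.atleast_1d(self.plan_cov.rss(Y))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = rss_cov / rss_full
        if (rss_full == 0).any():
            warnings.warn("RSS of the full model is exactly 0 at some voxels; ratio set to +inf")
            ratio = np.where(rss_full == 0, np.inf, ratio)
        return ratio, rss_cov, rss_full


def rss_ratio_map(
    design: DesignMatrix,
    stack: ImageStack,
    mask: VoxelMask,
    folds: FoldAssignment,
    lambdas: np.ndarray = DEFAULT_LAMBDA_GRID,
    lambda_rule: str = "gcv",
) -> StatMap:
    """Voxelwise RSS-ratio map: covariate-only CV RSS over full-model CV RSS.

    Both models use the same fold assignment at every voxel, so fold noise
    cancels from the comparison and the map is deterministic given the data
    and the fold seed.
    """
    if list(design.subjects) != list(stack.subjects):
        from .preprocess import AlignmentError

        raise AlignmentError("design matrix and image stack disagree on subjects")
    if mask.mask.shape != stack.shape:
        from .preprocess import MaskError

        raise MaskError(f"mask shape {mask.mask.shape} != image shape {stack.shape}")
    engine = RatioEngine(design, folds, lambdas=lambdas, lambda_rule=lambda_rule)
    Y = stack.data[:, mask.mask]
    ratio, rss_cov, rss_full = engine.rss_ratio(Y)

    def fill(vals):
        out = np.full(stack.shape, np.nan)
        out[mask.mask] = vals
        return out

    return StatMap(
        ratio=fill(ratio),
        rss_covariates=fill(rss_cov),
        rss_full=fill(rss_full),
        mask=mask.mask,
        affine=stack.affine,
    )
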