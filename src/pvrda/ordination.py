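"""Constrained ordination and phylogenetic-eigenvector machinery.

Two estimators carry the statistical core:

* :class:`PCoA` — principal coordinate analysis of a (patristic)
  distance matrix by eigen-decomposition of the Gower-double-centred
  matrix ``-1/2 J D^2 J``.  Axes are scaled so the sum of squared
  coordinates on axis k equals its eigenvalue; axes with non-positive
  eigenvalues are dropped (their count and magnitude share reported).

* :class:`RDA` — redundancy analysis with optional covariates (partial
  RDA).  Responses are centred (optionally standardised); with
  covariates W, both responses and predictors are first replaced by
  their residuals from a least-squares projection on [1, W].  The
  constrained variation is the Frobenius norm of the projection of Y
  onto the predictor column space; significance comes from a
  Monte-Carlo permutation test of the trace pseudo-F statistic, by
  default permuting the reduced-model residuals of Y with the
  covariates held fixed.

Forward selection of PCoA axes against a trait matrix
(:class:`ForwardAxisSelector`) adds, at each step, the axis explaining
the most additional trait variation and admits it if its conditional
permutation p-value passes ``alpha``.

All permutation machinery is vectorised over permutations: the
projectors are precomputed once and applied to the stacked permuted
response array in a single tensor contraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError

__all__ = [
    "PCoA",
    "RDA",
    "ForwardAxisSelector",
    "PermutationResult",
    "SingleTraitResult",
    "AxisSelection",
    "pcoa",
    "rda",
    "permutation_test",
    "single_trait_test",
    "select_axes",
    "bonferroni",
    "build_design",
]

_RANK_TOL = 1e-9


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_frame(x, what: str) -> pd.DataFrame:
    if isinstance(x, pd.DataFrame):
        return x
    if isinstance(x, pd.Series):
        return x.to_frame()
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, columns=[f"{what}{i}" for i in range(arr.shape[1])])


def _aligned_matrices(Y, X, W=None):
    """Align on a shared species index (when frames) and return arrays."""
    yf = _as_frame(Y, "y")
    xf = _as_frame(X, "x")
    frames = [yf, xf]
    wf = None
    if W is not None:
        wf = _as_frame(W, "w")
        frames.append(wf)
    have_index = all(not isinstance(f.index, pd.RangeIndex) for f in frames)
    if have_index:
        common = yf.index
        for f in frames[1:]:
            if set(f.index) != set(common):
                only_y = set(common) - set(f.index)
                only_f = set(f.index) - set(common)
                raise ValidationError(
                    f"species sets differ between response and design; "
                    f"only in response: {sorted(only_y)}; "
                    f"only in design: {sorted(only_f)}")
        xf = xf.loc[common]
        if wf is not None:
            wf = wf.loc[common]
    else:
        if len(xf) != len(yf) or (wf is not None and len(wf) != len(yf)):
            raise ValidationError("row counts differ between inputs")
    return yf, xf, wf


def _residual_projector(W: np.ndarray | None, n: int) -> np.ndarray:
    """Matrix of the residual-maker of [1, W] (annihilates intercept+covariates)."""
    ones = np.ones((n, 1))
    Z = ones if W is None or W.shape[1] == 0 else np.hstack([ones, W])
    # pseudo-inverse projection; rank deficiency handled by lstsq/SVD
    H = Z @ np.linalg.pinv(Z, rcond=1e-10)
    return np.eye(n) - H


def _matrix_rank(M: np.ndarray) -> int:
    if M.size == 0:
        return 0
    s = np.linalg.svd(M, compute_uv=False)
    if s.size == 0:
        return 0
    return int(np.sum(s > s[0] * _RANK_TOL)) if s[0] > 0 else 0


def _hat_projector(X: np.ndarray,
                   floor: float = 0.0) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto the column space of X, and its rank.

    ``floor`` is an absolute singular-value cutoff; it guards against a
    design that is numerically annihilated by covariate residualisation
    being treated as full rank through its round-off remnants.
    """
    n = X.shape[0]
    if X.shape[1] == 0:
        return np.zeros((n, n)), 0
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        return np.zeros((n, n)), 0
    keep = s > max(s[0] * _RANK_TOL, floor)
    Uk = U[:, keep]
    return Uk @ Uk.T, int(keep.sum())


def _design_floor(X: np.ndarray) -> float:
    """Absolute rank cutoff: 1e-9 of the centred design's largest scale."""
    Xc = X - X.mean(axis=0)
    s0 = np.linalg.norm(Xc, 2) if Xc.size else 0.0
    return 1e-9 * s0


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

class PCoA(BaseEstimator, TransformerMixin):
    """Principal coordinate analysis of a symmetric distance matrix.

    Parameters
    ----------
    correction : {None, "lingoes"}
        Optional additive correction for negative eigenvalues (adds
        ``2c`` to all squared off-diagonal distances with
        ``c = -lambda_min``).  Default: no correction — covariate use
        needs only the real-axis coordinates, and the dropped negative
        share is reported instead.
    eig_tol : float
        Relative tolerance below which an eigenvalue counts as zero.

    Attributes (after :meth:`fit`)
    ------------------------------
    eigenvalues_ : ndarray, all eigenvalues, descending.
    coordinates_ : DataFrame, species x positive axes ("PCo1", ...);
        axis k is scaled so its squared coordinates sum to eigenvalue k.
    n_negative_eigenvalues_ : int
    negative_inertia_, positive_inertia_ : float
    """

    def __init__(self, correction: str | None = None, eig_tol: float = 1e-9):
        self.correction = correction
        self.eig_tol = eig_tol

    def fit(self, distances, y=None) -> "PCoA":
        if isinstance(distances, pd.DataFrame):
            labels = [str(i) for i in distances.index]
            D = distances.to_numpy(dtype=float)
        else:
            D = np.asarray(distances, dtype=float)
            labels = [f"s{i}" for i in range(D.shape[0])]
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValidationError("distance matrix must be square")
        n = D.shape[0]
        if n < 3:
            raise ValidationError("PCoA needs at least 3 points")
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValidationError("distance matrix must be symmetric")
        if (D < 0).any():
            raise ValidationError("distances must be non-negative")
        if not np.allclose(np.diag(D), 0, atol=1e-8):
            raise ValidationError("distance matrix diagonal must be zero")

        D2 = D ** 2
        if self.correction == "lingoes":
            lam_min = self._gower_eigvals(D2).min()
            if lam_min < 0:
                c = -lam_min
                off = ~np.eye(n, dtype=bool)
                D2 = D2.copy()
                D2[off] += 2.0 * c
        elif self.correction is not None:
            raise ValidationError("correction must be None or 'lingoes'")

        B = self._gower(D2)
        lam, vec = np.linalg.eigh(B)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        tol = self.eig_tol * max(abs(lam[0]), 1.0) if lam.size else 0.0
        pos = lam > tol
        coords = vec[:, pos] * np.sqrt(lam[pos])
        self.eigenvalues_ = lam
        self.coordinates_ = pd.DataFrame(
            coords, index=labels,
            columns=[f"PCo{k + 1}" for k in range(int(pos.sum()))])
        self.n_negative_eigenvalues_ = int(np.sum(lam < -tol))
        self.negative_inertia_ = float(-lam[lam < -tol].sum())
        self.positive_inertia_ = float(lam[pos].sum())
        self.n_samples_ = n
        return self

    def fit_transform(self, distances, y=None) -> pd.DataFrame:
        return self.fit(distances).coordinates_

    def transform(self, distances=None) -> pd.DataFrame:
        """Return the fitted coordinates (PCoA has no out-of-sample map)."""
        return self.coordinates_

    @staticmethod
    def _gower(D2: np.ndarray) -> np.ndarray:
        n = D2.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        return -0.5 * J @ D2 @ J

    @classmethod
    def _gower_eigvals(cls, D2: np.ndarray) -> np.ndarray:
        return np.linalg.eigvalsh(cls._gower(D2))


def pcoa(distances, correction: str | None = None) -> PCoA:
    """Fit a :class:`PCoA` on ``distances`` and return the fitted object."""
    return PCoA(correction=correction).fit(distances)


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

class RDA(BaseEstimator):
    """Redundancy analysis with optional covariates (partial RDA).

    Parameters
    ----------
    standardize : bool
        Divide centred response columns by their standard deviation.
        Off by default: 0/1 traits already share a scale.

    Attributes (after :meth:`fit`)
    ------------------------------
    grand_total_ss_ : float, total SS of the centred responses before
        covariate removal.
    total_ss_, explained_ss_, residual_ss_ : float, decomposition after
        covariate removal (``explained + residual == total``).
    covariate_ss_ : float, SS absorbed by the covariates.
    explained_fraction_ : float, explained / post-covariate total.
    explained_fraction_total_ : float, explained / pre-covariate total.
    rank_, covariate_rank_ : int, effective ranks q and c.
    pseudo_f_ : float, (SSexp/q) / (SSres/(n-1-q-c)).
    eigenvalues_ : ndarray, constrained-axis eigenvalues.
    species_scores_, trait_scores_ : DataFrames on the constrained axes.
    """

    def __init__(self, standardize: bool = False):
        self.standardize = standardize

    def fit(self, X, Y, covariates=None) -> "RDA":
        yf, xf, wf = _aligned_matrices(Y, X, covariates)
        Yr = yf.to_numpy(dtype=float)
        Xr = xf.to_numpy(dtype=float)
        Wr = wf.to_numpy(dtype=float) if wf is not None else None
        n = Yr.shape[0]
        if np.isnan(Yr).any() or np.isnan(Xr).any() or \
                (Wr is not None and np.isnan(Wr).any()):
            raise ValidationError(
                "RDA inputs must be complete; handle missing values first")

        Yc = Yr - Yr.mean(axis=0)
        if self.standardize:
            sd = Yc.std(axis=0, ddof=1)
            if (sd == 0).any():
                raise ValidationError(
                    "zero-variance response column cannot be standardised")
            Yc = Yc / sd
        grand_total = float((Yc ** 2).sum())

        Rw = _residual_projector(Wr, n)
        c = _matrix_rank(Wr - Wr.mean(axis=0)) if Wr is not None else 0
        Yres = Rw @ Yc
        Xres = Rw @ Xr
        Hx, q = _hat_projector(Xres, floor=_design_floor(Xr))
        if n <= q + c + 1:
            raise ValidationError(
                f"too few species (n={n}) for rank(X)={q} and rank(W)={c}")
        Yhat = Hx @ Yres
        explained = float((Yhat ** 2).sum())
        total = float((Yres ** 2).sum())
        residual = total - explained

        self.n_samples_ = n
        self.rank_ = q
        self.covariate_rank_ = c
        self.grand_total_ss_ = grand_total
        self.total_ss_ = total
        self.explained_ss_ = explained
        self.residual_ss_ = residual
        self.covariate_ss_ = grand_total - total
        self.explained_fraction_ = explained / total if total > 0 else 0.0
        self.explained_fraction_total_ = (
            explained / grand_total if grand_total > 0 else 0.0)
        dof_res = n - 1 - q - c
        self.pseudo_f_ = (np.inf if residual <= 0 else
                          (explained / q) / (residual / dof_res)
                          if q > 0 else 0.0)

        # constrained axes from the SVD of the fitted values
        U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
        keep = s > (s[0] * _RANK_TOL if s.size and s[0] > 0 else np.inf)
        U, s, Vt = U[:, keep], s[keep], Vt[keep]
        self.eigenvalues_ = s ** 2 / (n - 1)
        axes = [f"RDA{k + 1}" for k in range(s.size)]
        self.species_scores_ = pd.DataFrame(U * s, index=yf.index,
                                            columns=axes)
        self.trait_scores_ = pd.DataFrame(Vt.T, index=yf.columns,
                                          columns=axes)
        # regression coefficients of the residualised design (for signs)
        self.coef_ = np.linalg.pinv(Xres, rcond=1e-10) @ Yres
        self._yf, self._xf, self._wf = yf, xf, wf
        return self

    def factor_centroids(self, factor: pd.Series) -> pd.DataFrame:
        """Centroids of species scores per level of a categorical factor."""
        f = factor.loc[self.species_scores_.index]
        return self.species_scores_.groupby(f.astype(str)).mean()


@dataclass(frozen=True)
class PermutationResult:
    pseudo_f: float
    pvalue: float
    nperm: int
    n_ge: int             # permutations with F* >= F
    explained_fraction: float
    explained_fraction_total: float
    rank: int
    covariate_rank: int


def rda(Y, X, covariates=None, standardize: bool = False) -> RDA:
    """Fit an :class:`RDA` of ``Y`` on ``X`` (optionally partial on covariates)."""
    return RDA(standardize=standardize).fit(X, Y, covariates=covariates)


def permutation_test(Y, X, covariates=None, nperm: int = 1999, seed=None,
                     scheme: str = "reduced",
                     standardize: bool = False) -> PermutationResult:
    """Monte-Carlo permutation test of the RDA trace pseudo-F.

    ``scheme="reduced"`` (default) permutes the residuals of Y from the
    reduced model [1, W], adding them back to the reduced-model fitted
    values, with covariates held fixed — the standard scheme for
    partial constrained ordination.  ``scheme="free"`` permutes raw
    response rows.  p = (1 + #{F* >= F}) / (1 + nperm).
    """
    if nperm < 1:
        raise ValidationError("nperm must be >= 1")
    if scheme not in ("reduced", "free"):
        raise ValidationError("scheme must be 'reduced' or 'free'")
    model = RDA(standardize=standardize).fit(X, Y, covariates=covariates)
    yf, xf, wf = model._yf, model._xf, model._wf
    Yc = yf.to_numpy(dtype=float)
    Yc = Yc - Yc.mean(axis=0)
    if standardize:
        Yc = Yc / Yc.std(axis=0, ddof=1)
    n = Yc.shape[0]
    Wr = wf.to_numpy(dtype=float) if wf is not None else None
    Rw = _residual_projector(Wr, n)
    Xr = xf.to_numpy(dtype=float)
    Hx, q = _hat_projector(Rw @ Xr, floor=_design_floor(Xr))
    c = model.covariate_rank_
    dof_res = n - 1 - q - c

    fitted_reduced = Yc - Rw @ Yc  # projection of Y on [1, W]
    resid_reduced = Rw @ Yc

    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((nperm, n)), axis=1)
    if scheme == "reduced":
        Ystar = fitted_reduced[None, :, :] + resid_reduced[idx]
    else:
        Ystar = Yc[idx]
    # residualise permuted responses on covariates, project on design
    Yres = np.einsum("ij,pjk->pik", Rw, Ystar)
    Yhat = np.einsum("ij,pjk->pik", Hx, Yres)
    ss_exp = (Yhat ** 2).sum(axis=(1, 2))
    ss_tot = (Yres ** 2).sum(axis=(1, 2))
    ss_res = ss_tot - ss_exp
    with np.errstate(divide="ignore", invalid="ignore"):
        f_star = (ss_exp / q) / (ss_res / dof_res)
    f_star = np.where(ss_res <= 0, np.inf, f_star)

    f_obs = model.pseudo_f_
    n_ge = int(np.sum(f_star >= f_obs - 1e-12 * max(1.0, abs(f_obs))))
    if not np.isfinite(f_obs):
        n_ge = int(np.sum(np.isinf(f_star)))
    p = (1 + n_ge) / (1 + nperm)
    return PermutationResult(
        pseudo_f=f_obs, pvalue=p, nperm=nperm, n_ge=n_ge,
        explained_fraction=model.explained_fraction_,
        explained_fraction_total=model.explained_fraction_total_,
        rank=q, covariate_rank=c)


@dataclass(frozen=True)
class SingleTraitResult:
    trait: str | None
    predictor: str | None
    sign: int | None              # +1/-1 for continuous predictors, else None
    explained_fraction: float     # of the pre-covariate trait SS
    explained_fraction_partial: float  # of the post-covariate SS
    pseudo_f: float
    pvalue: float
    nperm: int
    n_used: int
    dropped_species: tuple = ()
    excluded: bool = False


def single_trait_test(trait, predictor, covariates=None, nperm: int = 1999,
                      seed=None, scheme: str = "reduced",
                      trait_name: str | None = None,
                      predictor_name: str | None = None) -> SingleTraitResult:
    """Single-response RDA permutation test with sign reporting.

    Species with a missing trait value are dropped for this test (the
    predictor and covariates are subset accordingly).  The sign of the
    relationship comes from the regression coefficient of the
    residualised predictor; factors (non-numeric predictors) report no
    sign and enter as a centred indicator design.
    """
    t = trait if isinstance(trait, pd.Series) else pd.Series(trait)
    tname = trait_name if trait_name is not None else t.name
    keep = t.notna()
    dropped = tuple(t.index[~keep].astype(str))
    t = t[keep]
    if t.nunique() < 2:
        return SingleTraitResult(
            trait=tname, predictor=predictor_name, sign=None,
            explained_fraction=np.nan, explained_fraction_partial=np.nan,
            pseudo_f=np.nan, pvalue=np.nan, nperm=nperm, n_used=int(keep.sum()),
            dropped_species=dropped, excluded=True)

    p = predictor if isinstance(predictor, pd.Series) else pd.Series(predictor)
    pname = predictor_name if predictor_name is not None else p.name
    p = p.loc[t.index]
    is_factor = not pd.api.types.is_numeric_dtype(p)
    if is_factor:
        X = build_design(p.to_frame(pname or "factor"))
    else:
        X = p.to_frame(pname or "x")
    W = None
    if covariates is not None:
        W = _as_frame(covariates, "w").loc[t.index]

    res = permutation_test(t.to_frame(tname or "trait"), X, covariates=W,
                           nperm=nperm, seed=seed, scheme=scheme)
    sign = None
    if not is_factor:
        model = RDA().fit(X, t.to_frame(tname or "trait"), covariates=W)
        beta = float(model.coef_[0, 0])
        sign = 1 if beta > 0 else (-1 if beta < 0 else 0)
    return SingleTraitResult(
        trait=tname, predictor=pname, sign=sign,
        explained_fraction=res.explained_fraction_total,
        explained_fraction_partial=res.explained_fraction,
        pseudo_f=res.pseudo_f, pvalue=res.pvalue, nperm=nperm,
        n_used=len(t), dropped_species=dropped)


def bonferroni(pvals, m: int | None = None, families=None):
    """Bonferroni adjustment ``min(1, m * p)``.

    ``families`` may give a family label per p-value; each family's size
    is then its own m.  Without families, m defaults to the number of
    p-values.
    """
    p = np.asarray(pvals, dtype=float)
    if families is not None:
        fam = np.asarray(families)
        out = np.empty_like(p)
        for label in np.unique(fam):
            mask = fam == label
            out[mask] = np.minimum(1.0, p[mask] * int(mask.sum()))
        return out
    mm = m if m is not None else p.size
    return np.minimum(1.0, p * mm)


def build_design(predictors: pd.DataFrame) -> pd.DataFrame:
    """Expand a predictor table into a centred numeric design matrix.

    Continuous columns are centred; categorical columns become a full
    (non-reference) indicator block, also centred.  Rank deficiency
    introduced by full coding is handled downstream via pseudo-inverse
    projection, which avoids arbitrary reference-level choices.
    """
    blocks = []
    for col in predictors.columns:
        s = predictors[col]
        if pd.api.types.is_numeric_dtype(s):
            blocks.append((s - s.mean()).to_frame(str(col)))
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=str(col),
                                     dtype=float)
            dummies = dummies.reindex(sorted(dummies.columns), axis=1)
            blocks.append(dummies - dummies.mean())
    return pd.concat(blocks, axis=1)


# ---------------------------------------------------------------------------
# forward selection of PCoA axes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxisSelection:
    axes: tuple          # selected axis names, in selection order
    pvalues: tuple       # per-step permutation p of the admitted axis
    cumulative_r2: tuple  # cumulative fraction of trait SS explained
    n_candidates: int
    alpha: float
    nperm: int

    def as_dict(self) -> dict:
        return {
            "axes": list(self.axes),
            "pvalues": list(self.pvalues),
            "cumulative_r2": list(self.cumulative_r2),
            "n_candidates": self.n_candidates,
            "alpha": self.alpha,
            "nperm": self.nperm,
        }


class ForwardAxisSelector(BaseEstimator):
    """Greedy forward selection of PCoA axes against a trait matrix.

    At each step the axis adding the most explained trait variation
    (RDA fit conditioned on the already-selected axes) is identified
    and admitted if its conditional permutation p-value is at most
    ``alpha``; selection stops the first time the best candidate fails.
    Rows are sorted by species label internally, which makes the
    selection invariant to a joint row permutation of the inputs.

    Attributes (after :meth:`fit`)
    ------------------------------
    selection_ : AxisSelection
    selected_axes_ : list of axis names
    coordinates_ : the selected coordinate columns (original row order)
    """

    def __init__(self, alpha: float = 0.05, nperm: int = 999, seed=None,
                 max_axes: int | None = None, scheme: str = "reduced"):
        self.alpha = alpha
        self.nperm = nperm
        self.seed = seed
        self.max_axes = max_axes
        self.scheme = scheme

    def fit(self, coordinates, traits) -> "ForwardAxisSelector":
        coords = coordinates.coordinates_ if isinstance(coordinates, PCoA) \
            else _as_frame(coordinates, "PCo")
        Yf = _as_frame(traits, "trait")
        if Yf.shape[1] == 0 or Yf.shape[0] == 0:
            raise ValidationError("empty trait matrix")
        if set(coords.index) != set(Yf.index):
            raise ValidationError(
                "coordinates and traits must share a species set")
        order = sorted(Yf.index.astype(str))
        Yf = Yf.loc[order]
        coords_sorted = coords.loc[order]

        Yc = Yf.to_numpy(dtype=float)
        Yc = Yc - Yc.mean(axis=0)
        total_ss = float((Yc ** 2).sum())
        if total_ss <= 0:
            raise ValidationError("trait matrix has zero variance")

        remaining = list(coords_sorted.columns)
        selected: list[str] = []
        pvals: list[float] = []
        cum_r2: list[float] = []
        # keep residual degrees of freedom for the downstream partial
        # tests: never select more than n - 3 axes
        limit = min(self.max_axes or len(remaining),
                    max(Yf.shape[0] - 3, 0))
        if isinstance(self.seed, np.random.SeedSequence):
            ss = self.seed
        else:
            ss = np.random.SeedSequence(
                self.seed if self.seed is not None else 0)
        step = 0
        while remaining and len(selected) < limit:
            if self.alpha <= 0:
                break
            W = coords_sorted[selected] if selected else None
            best_axis, best_gain = None, -np.inf
            for ax in remaining:
                model = RDA().fit(coords_sorted[[ax]], Yf, covariates=W)
                if model.explained_ss_ > best_gain:
                    best_gain, best_axis = model.explained_ss_, ax
            step_seed = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=ss.spawn_key + (step,))
            res = permutation_test(
                Yf, coords_sorted[[best_axis]], covariates=W,
                nperm=self.nperm,
                seed=np.random.default_rng(step_seed),
                scheme=self.scheme)
            if res.pvalue > self.alpha:
                break
            selected.append(best_axis)
            remaining.remove(best_axis)
            pvals.append(res.pvalue)
            full = RDA().fit(coords_sorted[selected], Yf)
            cum_r2.append(full.explained_fraction_total_)
            step += 1
            if cum_r2[-1] >= 1.0 - 1e-10:
                break  # nothing left to explain; F would degenerate

        self.selection_ = AxisSelection(
            axes=tuple(selected), pvalues=tuple(pvals),
            cumulative_r2=tuple(cum_r2),
            n_candidates=len(coords_sorted.columns),
            alpha=self.alpha, nperm=self.nperm)
        self.selected_axes_ = list(selected)
        self.coordinates_ = coords[selected]
        return self

    def transform(self, coordinates=None) -> pd.DataFrame:
        return self.coordinates_


def select_axes(coordinates, traits, alpha: float = 0.05, nperm: int = 999,
                seed=None, scheme: str = "reduced") -> AxisSelection:
    """Functional wrapper over :class:`ForwardAxisSelector`."""
    sel = ForwardAxisSelector(alpha=alpha, nperm=nperm, seed=seed,
                              scheme=scheme).fit(coordinates, traits)
    return sel.selection_
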