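"""Compositional analysis of signature exposures.

Exposure vectors live on the simplex (non-negative, summing to 1), so
group comparisons use the isometric log-ratio (ILR) transform: a bijection
from the D-part simplex interior to R^(D-1) in which ordinary linear
models are valid. We use pivot coordinates,

    z_j = sqrt((D-j)/(D-j+1)) * ln( x_j / gm(x_{j+1}, ..., x_D) ),

built from an orthonormal basis V (D x D-1) with z = V' ln x and inverse
x = softmax(V z). Zeros are handled by multiplicative replacement before
the transform.

The global differential-abundance test fits, per ILR coordinate, a linear
mixed model with a fixed group effect and a random patient intercept, and
combines the slope z-scores into a joint Wald chi-square with one degree
of freedom per coordinate. Excluding a signature renormalises the
subcomposition before transforming (the "partial" ILR analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "ilr_basis", "zero_replace", "ilr_transform", "inverse_ilr",
    "CompositionalAbundanceModel", "fit_global_abundance_model",
    "inverse_ilr_group_means", "ILRModelFit",
]


def ilr_basis(D: int) -> np.ndarray:
    """Orthonormal pivot-coordinate ILR basis, shape (D, D-1)."""
    if D < 2:
        raise ValueError("need at least 2 parts")
    V = np.zeros((D, D - 1))
    for j in range(1, D):
        r = D - j
        V[j - 1, j - 1] = np.sqrt(r / (r + 1))
        V[j:, j - 1] = -np.sqrt(r / (r + 1)) / r
    return V


def zero_replace(x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Multiplicative zero replacement: parts below eps are floored at eps
    and the remainder rescaled so the vector stays on the simplex."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    x = np.asarray(x, dtype=float)
    out = np.array(x, copy=True)
    small = out < eps
    if not small.any():
        return out / out.sum()
    k = int(small.sum())
    if k >= x.shape[-1]:
        return np.full_like(out, 1.0 / x.shape[-1])
    out[small] = eps
    rest = ~small
    out[rest] *= (1.0 - eps * k) / out[rest].sum()
    return out


def ilr_transform(e: np.ndarray, basis: np.ndarray | None = None,
                  zero_floor: float = 1e-3) -> np.ndarray:
    """Pivot-coordinate ILR of a simplex vector (length D -> D-1)."""
    e = np.asarray(e, dtype=float)
    if (e < 0).any() or abs(e.sum() - 1) > 1e-6:
        raise ValueError("input must be a simplex vector")
    x = zero_replace(e, eps=zero_floor)
    V = ilr_basis(len(x)) if basis is None else np.asarray(basis)
    return V.T @ np.log(x)


def inverse_ilr(z: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Inverse ILR: coordinates (D-1) back to the simplex (D)."""
    z = np.asarray(z, dtype=float)
    V = ilr_basis(len(z) + 1) if basis is None else np.asarray(basis)
    clr = V @ z
    x = np.exp(clr - clr.max())
    return x / x.sum()


@dataclass
class ILRModelFit:
    """Per-coordinate mixed-model estimates and the global Wald test."""

    signatures: list
    basis: np.ndarray
    intercepts: np.ndarray        # beta0 per coordinate
    slopes: np.ndarray            # beta1 (group effect) per coordinate
    slope_se: np.ndarray
    random_effect_var: np.ndarray
    wald_statistic: float
    df: int
    pvalue: float
    group_levels: tuple = ("A", "B")
    warnings_: list = field(default_factory=list)

    @property
    def n_coordinates(self) -> int:
        return len(self.slopes)


class CompositionalAbundanceModel(BaseEstimator):
    """Global differential-abundance test for signature exposures.

    Parameters
    ----------
    exclude : sequence of str
        Signatures dropped before the transform; the remaining
        subcomposition is renormalised (needs >= 3 parts left, i.e. >= 2
        ILR coordinates).
    zero_floor : float
        Multiplicative zero-replacement threshold.

    fit(exposures, groups, patients) expects `exposures` as a DataFrame
    (samples x signatures), `groups` as a two-level label per sample and
    `patients` as the random-intercept grouping. Fitted attributes:
    wald_statistic_, pvalue_, fit_ (an :class:`ILRModelFit`).
    """

    def __init__(self, exclude: tuple = (), zero_floor: float = 1e-3):
        self.exclude = tuple(exclude)
        self.zero_floor = zero_floor

    def fit(self, exposures: pd.DataFrame, groups, patients):
        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        keep = [c for c in exposures.columns if c not in self.exclude]
        if len(keep) < 3:
            raise ValueError("need >= 2 ILR coordinates after exclusion")
        X = exposures[keep].to_numpy(float)
        X = X / X.sum(axis=1, keepdims=True)
        Z = np.stack([ilr_transform(row, zero_floor=self.zero_floor) for row in X])

        groups = np.asarray(groups)
        levels = tuple(pd.unique(groups))
        if len(levels) != 2:
            raise ValueError("groups must have exactly two levels")
        g = (groups == levels[1]).astype(float)
        patients = np.asarray(patients)

        n_coord = Z.shape[1]
        intercepts = np.zeros(n_coord)
        slopes = np.zeros(n_coord)
        ses = np.zeros(n_coord)
        revar = np.zeros(n_coord)
        notes = []
        exog = np.column_stack([np.ones_like(g), g])
        singleton = pd.Series(patients).value_counts().max() == 1

        if self._is_balanced_paired(patients, g):
            # Balanced paired design: the random-intercept GLS solution is
            # available in closed form — the group slope is the mean paired
            # difference with its empirical standard error. Identical to the
            # mixed-model asymptotics, without iterative fitting.
            d_rows, y0_rows = [], []
            for pid in pd.unique(patients):
                idx = np.flatnonzero(patients == pid)
                i0 = idx[g[idx] == 0][0]
                i1 = idx[g[idx] == 1][0]
                y0_rows.append(Z[i0])
                d_rows.append(Z[i1] - Z[i0])
            D = np.stack(d_rows)
            Y0 = np.stack(y0_rows)
            n_pairs = len(D)
            if n_pairs < 3:
                raise ValueError("need >= 3 pairs for the paired model")
            slopes = D.mean(axis=0)
            ses = D.std(axis=0, ddof=1) / np.sqrt(n_pairs)
            intercepts = Y0.mean(axis=0)
            within = D.var(axis=0, ddof=1) / 2.0
            total = np.stack([Y0, Y0 + D]).reshape(-1, n_coord).var(axis=0, ddof=1)
            revar = np.maximum(total - within, 0.0)
            self._finalise(keep, intercepts, slopes, ses, revar, levels, notes)
            return self

        for j in range(n_coord):
            y = Z[:, j]
            fitted = None
            if not singleton:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        warnings.simplefilter("ignore", RuntimeWarning)
                        warnings.simplefilter("ignore", UserWarning)
                        md = sm.MixedLM(y, exog, groups=patients)
                        res = md.fit(reml=True, method="lbfgs")
                    if np.isfinite(res.bse[1]) and res.bse[1] > 0:
                        fitted = (res.params[0], res.params[1], res.bse[1],
                                  float(np.atleast_2d(res.cov_re)[0, 0]))
                except Exception as exc:  # singular fit or optimiser failure
                    notes.append(f"coordinate {j}: mixed fit failed ({exc}); OLS fallback")
            if fitted is None:
                if not singleton:
                    notes.append(f"coordinate {j}: OLS fallback (fixed effects only)")
                ols = sm.OLS(y, exog).fit()
                fitted = (ols.params[0], ols.params[1], ols.bse[1], 0.0)
            intercepts[j], slopes[j], ses[j], revar[j] = fitted

        self._finalise(keep, intercepts, slopes, ses, revar, levels, notes)
        return self

    @staticmethod
    def _is_balanced_paired(patients: np.ndarray, g: np.ndarray) -> bool:
        for pid in pd.unique(patients):
            idx = np.flatnonzero(patients == pid)
            if len(idx) != 2 or set(g[idx]) != {0.0, 1.0}:
                return False
        return True

    def _finalise(self, keep, intercepts, slopes, ses, revar, levels, notes):
        n_coord = len(slopes)
        if np.allclose(slopes, 0.0, atol=1e-12):
            wald, p = 0.0, 1.0
        else:
            z2 = (slopes / ses) ** 2
            wald = float(z2.sum())
            p = float(stats.chi2.sf(wald, df=n_coord))
        self.fit_ = ILRModelFit(
            signatures=list(keep), basis=ilr_basis(len(keep)),
            intercepts=intercepts, slopes=slopes, slope_se=ses,
            random_effect_var=revar, wald_statistic=wald,
            df=n_coord, pvalue=p, group_levels=levels, warnings_=notes,
        )
        self.wald_statistic_ = wald
        self.pvalue_ = p


def fit_global_abundance_model(exposures: pd.DataFrame, groups, patients,
                               exclude: tuple = (),
                               zero_floor: float = 1e-3) -> ILRModelFit:
    """Fit the ILR mixed model and global Wald test; see
    :class:`CompositionalAbundanceModel`."""
    model = CompositionalAbundanceModel(exclude=exclude, zero_floor=zero_floor)
    model.fit(exposures, groups, patients)
    return model.fit_


def inverse_ilr_group_means(fit: ILRModelFit) -> tuple:
    """Group composition summaries: inverse ILR of the intercepts and of
    intercepts + slopes (reference and contrast group respectively)."""
    ref = inverse_ilr(fit.intercepts, basis=fit.basis)
    alt = inverse_ilr(fit.intercepts + fit.slopes, basis=fit.basis)
    return ref, alt
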