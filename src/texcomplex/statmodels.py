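"""The linking statistics: correlation sweeps, PCA on rank scores, the
weighted-sum complexity model, and single-factor analysis.

Two fitted models follow the Model/Results idiom: construct the model
from data, call ``fit()``, read estimates and diagnostics off the
returned results object (``summary()`` renders a table).

* :class:`VTCModel` — predicted visual texture complexity as a
  weighted sum (no intercept) of predictor columns,
  ``VTC_p = X k``, with ``k`` chosen to minimize the mean squared
  error against the observed complexity scores.  Used both for the
  attribute-level model (predictors = rank scores of randomness,
  color variation, strongness, regularity, repetitiveness) and the
  texture-measure model (predictors = global sigma, CoM entropy,
  uniform LBP, Gabor sigma).
* :class:`SingleFactorModel` — one-common-factor analysis of
  standardized texture measures: loadings and specific variances
  (uniquenesses) reveal which measures are driven by the shared
  latent dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from sklearn.decomposition import FactorAnalysis as _SkFactorAnalysis

from .psychophysics import VRSVector, rescale_0_10

#: canonical attribute column order (complexity, randomness, color
#: variation, strongness, regularity, repetitiveness, homogeneity)
ATTRIBUTES = ("Cpx", "R", "CV", "S", "Rg", "Rp", "H")


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with its two-sided t-test p-value."""
    r, p = _sstats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def correlation_sweep(features: pd.DataFrame, vrs: VRSVector | np.ndarray) -> pd.DataFrame:
    """Correlate every feature cell against the complexity scores.

    ``features`` is a long table with columns ``sample_id``, ``space``,
    ``channel``, ``feature``, ``params``, ``value``; one correlation is
    computed per (space, channel, feature, params) cell, after min-max
    rescaling of the feature values to 0..10 (Pearson r is unaffected
    by the rescale; it is kept for comparability of the reported
    tables).  Constant cells are flagged with NaN r.
    """
    scores = vrs.rescaled if isinstance(vrs, VRSVector) else np.asarray(vrs, float)
    ids = (
        list(vrs.sample_ids)
        if isinstance(vrs, VRSVector) and vrs.sample_ids is not None
        else sorted(features["sample_id"].unique())
    )
    score_of = dict(zip(ids, scores))
    rows = []
    for key, cell in features.groupby(["space", "channel", "feature", "params"], sort=True):
        cell = cell.set_index("sample_id")["value"]
        missing = [i for i in ids if i not in cell.index]
        if missing:
            raise ValueError(f"feature cell {key} missing samples: {missing}")
        x = cell.loc[ids].to_numpy(dtype=float)
        y = np.asarray([score_of[i] for i in ids])
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            r, p = float("nan"), float("nan")
        else:
            r, p = pearson_corr(rescale_0_10(x), y)
        rows.append(dict(zip(("space", "channel", "feature", "params"), key)) | {"r": r, "p": p, "n": len(ids)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA on the attribute rank scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCAResult:
    """Eigenstructure of the covariance of the (0..10) attribute scores."""

    coefficients: pd.DataFrame  # variables x components
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray

    def cumulative_variance(self, k: int) -> float:
        return float(self.explained_variance_ratio[:k].sum())


def pca_vrs(table: pd.DataFrame) -> PCAResult:
    """PCA of the attribute-score table on the covariance matrix.

    Columns are mean-centered but not standardized (the scores share
    the 0..10 scale); component coefficients are unit-norm, sign-fixed
    so each component's largest-magnitude coefficient is positive.
    """
    X = table.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for k in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, k])), k] < 0:
            evecs[:, k] = -evecs[:, k]
    coeffs = pd.DataFrame(
        evecs, index=table.columns, columns=[f"PC{i + 1}" for i in range(evecs.shape[1])]
    )
    return PCAResult(
        coefficients=coeffs,
        eigenvalues=evals,
        explained_variance_ratio=evals / evals.sum(),
    )


# ---------------------------------------------------------------------------
# Weighted-sum complexity model
# ---------------------------------------------------------------------------


class VTCModel:
    """Weighted-sum model VTC_p = X k, fitted by least squares.

    No intercept: the model is a pure weighted sum of the predictor
    columns, so minimizing the mean squared error against the observed
    complexity scores reduces to ordinary least squares through the
    origin.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Observed complexity scores (the regression target).
    exog : array-like, shape (n, p)
        Predictor columns.
    labels : sequence of str, optional
        Predictor names for the summary table.
    """

    def __init__(self, endog, exog, labels=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog must have the same number of rows")
        self.labels = list(labels) if labels is not None else [f"k{i + 1}" for i in range(self.exog.shape[1])]
        if len(self.labels) != self.exog.shape[1]:
            raise ValueError("one label per predictor column required")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, target: str, predictors: list[str]) -> "VTCModel":
        return cls(data[target].to_numpy(), data[predictors].to_numpy(), labels=predictors)

    def fit(self) -> "VTCResults":
        X, y = self.exog, self.endog
        cond = float(np.linalg.cond(X))
        k, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient predictors (rank {rank} < {X.shape[1]}, condition number {cond:.3g})"
            )
        fitted = X @ k
        resid = y - fitted
        mse = float(resid @ resid) / len(y)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else float("nan")
        r = pearson_corr(y, fitted)[0] if np.ptp(fitted) > 0 else float("nan")
        # classical OLS (no-intercept) standard errors
        dof = max(len(y) - X.shape[1], 1)
        s2 = float(resid @ resid) / dof
        bse = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        return VTCResults(model=self, params=k, bse=bse, fittedvalues=fitted, mse=mse, rsquared=r2, r=r, condition_number=cond)


@dataclass(frozen=True)
class VTCResults:
    """Estimates and diagnostics of a fitted weighted-sum model."""

    model: VTCModel
    params: np.ndarray
    bse: np.ndarray
    fittedvalues: np.ndarray
    mse: float
    rsquared: float
    r: float
    condition_number: float

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.params, index=self.model.labels, name="k")

    def predict(self, exog) -> np.ndarray:
        return np.atleast_2d(np.asarray(exog, dtype=float)) @ self.params

    def summary(self) -> str:
        lines = [
            "Weighted-sum complexity model (no intercept)",
            f"  n = {len(self.model.endog)}, predictors = {len(self.params)}",
            f"  MSE = {self.mse:.4f}   R^2 = {self.rsquared:.4f}   r(target, fitted) = {self.r:.4f}",
            f"  condition number = {self.condition_number:.3g}",
            "",
            f"  {'predictor':<16}{'coef':>10}{'std err':>10}",
        ]
        for lab, k, se in zip(self.model.labels, self.params, self.bse):
            lines.append(f"  {lab:<16}{k:>10.4f}{se:>10.4f}")
        return "\n".join(lines)


def fit_vtc(target, predictors, labels=None) -> VTCResults:
    """Convenience wrapper: fit the weighted-sum model in one call."""
    t = target.rescaled if isinstance(target, VRSVector) else target
    return VTCModel(t, predictors, labels=labels).fit()


# ---------------------------------------------------------------------------
# Single-factor analysis
# ---------------------------------------------------------------------------


class SingleFactorModel:
    """One-common-factor model of standardized texture measures.

    Each standardized measure x_j = lambda_j f + e_j with a shared
    latent factor f and specific variance psi_j = Var(e_j); for
    standardized inputs lambda_j^2 + psi_j ~= 1.  Extraction is by
    maximum likelihood.
    """

    def __init__(self, measures, labels=None):
        X = np.atleast_2d(np.asarray(measures, dtype=float))
        if X.shape[0] < 3 or X.shape[1] < 2:
            raise ValueError("need at least 3 rows and 2 measures")
        self.measures = X
        self.labels = list(labels) if labels is not None else [f"x{j + 1}" for j in range(X.shape[1])]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, columns: list[str] | None = None) -> "SingleFactorModel":
        cols = columns if columns is not None else list(data.columns)
        return cls(data[cols].to_numpy(), labels=cols)

    def fit(self, max_iter: int = 2000, tol: float = 1e-4) -> "SingleFactorResults":
        X = self.measures
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant measure column cannot be factor-analyzed")
        Z = (X - X.mean(axis=0)) / sd
        fa = _SkFactorAnalysis(n_components=1, max_iter=max_iter, tol=tol)
        fa.fit(Z)
        if fa.n_iter_ >= max_iter:
            warnings.warn(f"factor analysis did not converge in {max_iter} iterations", stacklevel=2)
        loadings = fa.components_[0].copy()
        if loadings[np.argmax(np.abs(loadings))] < 0:
            loadings = -loadings
        psi = fa.noise_variance_.copy()
        heywood = psi < 0.005
        psi = np.maximum(psi, 0.005)  # Heywood guard: specific variance floor
        return SingleFactorResults(
            model=self,
            loadings=loadings,
            specific_variances=psi,
            heywood_flags=heywood,
            n_iter=int(fa.n_iter_),
            log_likelihood=float(fa.loglike_[-1]),
        )


@dataclass(frozen=True)
class SingleFactorResults:
    model: SingleFactorModel
    loadings: np.ndarray
    specific_variances: np.ndarray
    heywood_flags: np.ndarray = field(repr=False)
    n_iter: int = 0
    log_likelihood: float = float("nan")

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "loading": self.loadings,
                "specific_variance": self.specific_variances,
            },
            index=self.model.labels,
        )

    def summary(self) -> str:
        lines = [
            "Single common factor analysis (maximum likelihood)",
            f"  n = {self.model.measures.shape[0]}, measures = {len(self.loadings)}, iterations = {self.n_iter}",
            "",
            f"  {'measure':<16}{'loading':>10}{'spec var':>10}",
        ]
        for lab, lo, ps, hw in zip(self.model.labels, self.loadings, self.specific_variances, self.heywood_flags):
            mark = "  (Heywood, clipped)" if hw else ""
            lines.append(f"  {lab:<16}{lo:>10.3f}{ps:>10.3f}{mark}")
        return "\n".join(lines)


def single_factor_analysis(measures, labels=None) -> SingleFactorResults:
    """Convenience wrapper around :class:`SingleFactorModel`."""
    return SingleFactorModel(measures, labels=labels).fit()
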