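"""BLASSO: L1-penalized logistic regression with per-gene penalty factors.

The model minimizes the mean logistic negative log-likelihood plus a weighted
L1 penalty,

    min_{b0, beta}  (1/n) sum_i log(1 + exp(-(2 y_i - 1)(b0 + x_i beta)))
                    + lam * sum_j gamma_j |beta_j|,

where the penalty factor gamma_j in [0, 1] encodes prior knowledge about gene
j: gamma_j = 1 is the standard LASSO treatment, gamma_j -> 0 progressively
exempts the gene from regularization (gamma_j = 0 leaves it unpenalized, as
in plain logistic regression).  The intercept is never penalized.  Features
are standardized internally; coefficients are reported on the original scale.

Usage follows the model/results idiom::

    model = Blasso.from_dataset(ds, penalty)
    res = model.fit(lam=0.05)       # -> BlassoResults
    res.signature                   # genes with nonzero coefficients
    path = model.fit_path()         # glmnet-style warm-started lambda grid
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._cd import fit_cd
from .data_io import ExpressionDataset
from .priors import PenaltyVector

__all__ = [
    "Blasso",
    "BlassoResults",
    "RegularizationPath",
    "DegenerateLabelsError",
    "ConvergenceWarning",
]


class DegenerateLabelsError(ValueError):
    """Labels contain a single class; the log-odds are unbounded."""


class ConvergenceWarning(UserWarning):
    pass


class Blasso:
    """Weighted-L1 logistic model for a fixed design and penalty vector.

    Parameters
    ----------
    endog : array-like of shape (n,)
        Binary outcome in {0, 1}.
    exog : array-like of shape (n, p)
        Feature matrix (samples x genes).
    penalty_factors : PenaltyVector or array-like, optional
        Per-feature L1 factors gamma in [0, 1]; defaults to all ones
        (standard LASSO).
    feature_names : list of str, optional
    standardize : bool, default True
        Scale features to unit variance internally (coefficients are always
        reported on the original scale).  With ``False`` the penalty applies
        to raw-scale coefficients, as in ``glmnet(standardize=FALSE)``;
        columns are still centered against the intercept.
    """

    def __init__(self, endog, exog, penalty_factors=None, feature_names=None,
                 standardize=True):
        y = np.asarray(endog)
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("exog must be 2-d with one row per label")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary in {0, 1}")
        self.endog = y.astype(float)
        self.exog = X
        n, p = X.shape
        if penalty_factors is None:
            penalty_factors = PenaltyVector.ones(p)
        elif not isinstance(penalty_factors, PenaltyVector):
            penalty_factors = PenaltyVector.override(penalty_factors)
        if len(penalty_factors) != p:
            raise ValueError(
                f"{len(penalty_factors)} penalty factors for {p} features"
            )
        self.penalty = penalty_factors
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(p)]
        self.feature_names = list(feature_names)
        # internal standardization (population sd; constant columns untouched)
        self.standardize = bool(standardize)
        self._center = X.mean(axis=0)
        if self.standardize:
            sd = X.std(axis=0)
            self._scale = np.where(sd > 0, sd, 1.0)
        else:
            self._scale = np.ones(p)
        # column-major layout: coordinate descent walks columns contiguously
        self._Xs = np.asfortranarray((X - self._center) / self._scale)
        # column mean-squares of the working design (1.0 when standardized)
        self._xvar = np.einsum("ij,ij->j", self._Xs, self._Xs) / n

    @classmethod
    def from_dataset(cls, ds: ExpressionDataset, penalty_factors=None,
                     standardize: bool = True) -> "Blasso":
        return cls(ds.labels, ds.matrix, penalty_factors, ds.gene_symbols,
                   standardize=standardize)

    @property
    def nobs(self) -> int:
        return self.exog.shape[0]

    @property
    def nfeatures(self) -> int:
        return self.exog.shape[1]

    def _check_labels(self) -> None:
        if self.endog.min() == self.endog.max():
            raise DegenerateLabelsError("all labels belong to one class")

    def lambda_max(self) -> float:
        """Smallest lam at which every penalized coefficient is zero.

        With homogeneous penalties this is the classic
        ``max_j |x_j . (y - ybar)| / (n gamma_j)``: the KKT condition at the
        null model (intercept at the empirical log-odds).  When some features
        are unpenalized (gamma = 0) they stay in the model at every lam, so
        the score must be taken at their restricted maximum-likelihood fit
        rather than at the null model.
        """
        self._check_labels()
        gam = self.penalty.gamma
        pos = gam > 0
        if not pos.any():
            raise ValueError("lambda_max undefined: all penalty factors are zero")
        free = ~pos
        if free.any():
            sub = Blasso(
                self.endog, self.exog[:, free],
                penalty_factors=np.zeros(int(free.sum())),
                standardize=self.standardize,
            )
            with warnings.catch_warnings():
                # a separable unpenalized subset has no finite MLE; the
                # truncated fit still pins the penalized-feature scores
                warnings.simplefilter("ignore", ConvergenceWarning)
                prob = sub.fit(0.0, tol=1e-10, max_sweeps=20_000).predict(
                    self.exog[:, free]
                )
            resid = self.endog - prob
            # the profiled score carries the MLE solver's tolerance; nudge
            # above it so the boundary KKT tie still resolves to beta = 0
            nudge = 1e-6
        else:
            resid = self.endog - self.endog.mean()
            nudge = 1e-10
        score = np.abs(self._Xs[:, pos].T @ resid) / self.nobs
        return float((score / gam[pos]).max()) * (1.0 + nudge)

    def lambda_grid(
        self, n_lambdas: int = 100, lambda_min_ratio: float | None = None
    ) -> np.ndarray:
        """Geometric grid from lambda_max down to lambda_max * ratio."""
        if n_lambdas < 2:
            raise ValueError("need at least 2 lambda values")
        if lambda_min_ratio is None:
            lambda_min_ratio = 0.01 if self.nfeatures > self.nobs else 1e-4
        lmax = self.lambda_max()
        return lmax * np.power(
            lambda_min_ratio, np.linspace(0.0, 1.0, n_lambdas)
        )

    def fit(
        self,
        lam: float,
        start: "BlassoResults | None" = None,
        tol: float = 1e-7,
        max_sweeps: int = 100_000,
        kkt_tol: float | None = None,
    ) -> "BlassoResults":
        """Fit at a single regularization rate ``lam``.

        ``lam`` must be positive unless every feature is unpenalized.
        ``start`` warm-starts from a previous fit of the same model.
        Convergence requires a full sweep with max coefficient change below
        ``tol`` or a KKT violation below ``kkt_tol`` (default ``tol / 10``).
        """
        self._check_labels()
        gam = self.penalty.gamma
        if lam < 0 or (lam == 0 and gam.any()):
            raise ValueError("lam must be > 0 when any feature is penalized")
        if start is not None:
            beta = start._beta_std.copy()
            b0 = start._b0_std
        else:
            beta = np.zeros(self.nfeatures)
            b0 = float(np.log(self.endog.mean() / (1.0 - self.endog.mean())))
        if kkt_tol is None:
            kkt_tol = tol / 10.0
        b0, nsw, trace, converged = fit_cd(
            self._Xs, self._xvar, self.endog, gam, float(lam), beta, b0, tol,
            max_sweeps, kkt_tol
        )
        res = BlassoResults(self, beta, float(b0), float(lam), nsw,
                            np.asarray(trace), bool(converged))
        if not converged:
            warnings.warn(
                f"coordinate descent did not converge in {max_sweeps} sweeps "
                f"(KKT violation {res.kkt_violation:.2e})",
                ConvergenceWarning,
            )
        return res

    def fit_path(
        self,
        n_lambdas: int = 100,
        lambda_min_ratio: float | None = None,
        lambdas: np.ndarray | None = None,
        tol: float = 1e-7,
        max_sweeps: int = 100_000,
        kkt_tol: float | None = None,
    ) -> "RegularizationPath":
        """Warm-started fits over a decreasing lambda grid."""
        if lambdas is None:
            lambdas = self.lambda_grid(n_lambdas, lambda_min_ratio)
        lambdas = np.asarray(lambdas, dtype=float)
        if (np.diff(lambdas) >= 0).any():
            raise ValueError("lambda grid must be strictly decreasing")
        fits: list[BlassoResults] = []
        prev = None
        for lam in lambdas:
            prev = self.fit(lam, start=prev, tol=tol, max_sweeps=max_sweeps,
                            kkt_tol=kkt_tol)
            fits.append(prev)
        return RegularizationPath(lambdas, fits)


@dataclass
class BlassoResults:
    """Fitted BLASSO coefficients and diagnostics at one (lam, gamma)."""

    model: Blasso
    _beta_std: np.ndarray
    _b0_std: float
    lam: float
    n_sweeps: int
    objective_trace: np.ndarray
    converged: bool

    @property
    def params(self) -> np.ndarray:
        """Coefficients on the original feature scale."""
        return self._beta_std / self.model._scale

    @property
    def intercept(self) -> float:
        return float(
            self._b0_std - np.sum(self._beta_std * self.model._center / self.model._scale)
        )

    @property
    def gamma(self) -> PenaltyVector:
        return self.model.penalty

    @property
    def epsilon(self) -> float:
        return self.model.penalty.epsilon

    @property
    def signature(self) -> frozenset:
        """Genes with nonzero coefficients."""
        nz = np.flatnonzero(self._beta_std)
        return frozenset(self.model.feature_names[j] for j in nz)

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self._beta_std))

    @property
    def kkt_violation(self) -> float:
        """Max violation of the subgradient optimality conditions.

        For zero coefficients the score must satisfy |g_j| <= lam * gamma_j;
        for nonzero ones g_j = -lam * gamma_j * sign(beta_j); the intercept
        score must vanish.  Computed on the standardized scale.
        """
        m = self.model
        eta = self._b0_std + m._Xs @ self._beta_std
        prob = 1.0 / (1.0 + np.exp(-eta))
        g = m._Xs.T @ (prob - m.endog) / m.nobs
        thr = self.lam * m.penalty.gamma
        zero = self._beta_std == 0
        viol = np.where(
            zero,
            np.maximum(np.abs(g) - thr, 0.0),
            np.abs(g + thr * np.sign(self._beta_std)),
        )
        return float(max(viol.max(initial=0.0), abs(np.mean(prob - m.endog))))

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.params

    def predict(self, X) -> np.ndarray:
        """Probability of class 1."""
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table (gene_symbol, beta, gamma)."""
        return pd.DataFrame(
            {
                "gene_symbol": self.model.feature_names,
                "beta": self.params,
                "gamma": self.model.penalty.gamma,
            }
        )

    def save(self, coef_path, meta_path=None) -> None:
        """Write the coefficient TSV and a JSON header of fit metadata."""
        self.to_frame().to_csv(coef_path, sep="\t", index=False)
        if meta_path is not None:
            meta = {
                "lambda": self.lam,
                "epsilon": self.epsilon,
                "intercept": self.intercept,
                "n_selected": self.n_selected,
                "n_sweeps": self.n_sweeps,
                "converged": self.converged,
                "kkt_violation": self.kkt_violation,
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=1)

    def summary(self, max_rows: int = 20) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        m = self.model
        head = [
            "BLASSO (weighted-L1 logistic regression)",
            "=" * 56,
            f"No. observations: {m.nobs:>10d}    lambda:    {self.lam:.6g}",
            f"No. features:     {m.nfeatures:>10d}    epsilon:   {self.epsilon:.4g}",
            f"Selected genes:   {self.n_selected:>10d}    converged: {self.converged}",
            f"Intercept:        {self.intercept:>10.4f}    KKT viol.: {self.kkt_violation:.2e}",
            "-" * 56,
            f"{'gene':<20}{'beta':>14}{'gamma':>12}",
        ]
        tab = self.to_frame()
        tab = tab[tab.beta != 0].reindex(
            tab[tab.beta != 0].beta.abs().sort_values(ascending=False).index
        )
        for _, row in tab.head(max_rows).iterrows():
            head.append(f"{row.gene_symbol:<20}{row.beta:>14.5f}{row.gamma:>12.4f}")
        if len(tab) > max_rows:
            head.append(f"... ({len(tab) - max_rows} more nonzero coefficients)")
        head.append("=" * 56)
        return "\n".join(head)


@dataclass
class RegularizationPath:
    """Warm-started fits along a strictly decreasing lambda sequence."""

    lambdas: np.ndarray
    fits: list[BlassoResults]

    def __len__(self) -> int:
        return len(self.fits)

    def __getitem__(self, i: int) -> BlassoResults:
        return self.fits[i]

    @property
    def n_selected(self) -> np.ndarray:
        return np.array([f.n_selected for f in self.fits])

    def predict(self, X) -> np.ndarray:
        """Class-1 probabilities, shape (n_lambdas, n_samples)."""
        return np.vstack([f.predict(X) for f in self.fits])
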