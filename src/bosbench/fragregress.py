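"""Second-order fragment-contribution regression with availability normalization.

Per-code classification accuracy R is modelled as

    R = beta0 + sum_i d_i F_i + sum_{i<j} f_ij F_i F_j + g(N),
    g(N) = gamma1 N + gamma2 N^2,

where F_i in {0, 1} marks fragment i's presence and N = sum_i F_i is the
fragment availability.  As printed, the model is not identifiable: on the
binary cube, N = sum_i F_i and N^2 = sum_i F_i + 2 sum_{i<j} F_i F_j are
exact linear combinations of the fragment columns, and the intercept
appears twice.  The default estimator therefore (a) keeps a single
intercept, and (b) fits in two stages — first the availability trend
``R ~ 1 + N + N^2`` (the normalization g), then the stage-1 residuals on
the fragment and interaction columns under sum-to-zero constraints
``sum_i d_i = 0`` and ``sum_{i<j} f_ij = 0``.  On the complete (balanced)
256-code design the constrained fragment space is orthogonal to
``(1, N, N^2)``, so the two-stage estimates coincide with the one-stage
constrained least-squares solution; both routes are available.

The module follows the statsmodels idiom: build a
:class:`FragmentRegression` model from data, call :meth:`fit`, and read
estimates, standard errors and a summary table off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from bosbench.errors import ValidationError
from bosbench.fragmentation import N_FRAGMENTS, FragmentCode

PAIRS: tuple[tuple[int, int], ...] = tuple(combinations(range(1, 9), 2))
N_PAIRS = len(PAIRS)  # 28

_SCHEME = "single-intercept, sum-to-zero d and f"


def _sum_zero_basis(k: int) -> np.ndarray:
    """Orthonormal (k, k-1) basis of the sum-to-zero subspace."""
    q, _ = np.linalg.qr(np.eye(k) - np.full((k, k), 1.0 / k))
    return q[:, :k - 1]


def build_design(codes: list[FragmentCode | str]) -> pd.DataFrame:
    """Full design matrix: const, F1..F8, 28 pair products, N, N^2.

    The matrix has 39 columns but numerical rank 37 on the complete code
    set, because N and N^2 are exact linear combinations of the F and
    F_iF_j columns.
    """
    codes = [c if isinstance(c, FragmentCode) else FragmentCode(str(c))
             for c in codes]
    F = np.stack([c.bits for c in codes]).astype(float)        # (n, 8)
    P = np.stack([F[:, i - 1] * F[:, j - 1] for i, j in PAIRS], axis=1)
    N = F.sum(axis=1)
    cols = {"const": np.ones(len(codes))}
    cols.update({f"F{i}": F[:, i - 1] for i in range(1, 9)})
    cols.update({f"F{i}F{j}": P[:, k] for k, (i, j) in enumerate(PAIRS)})
    cols["N"] = N
    cols["N2"] = N ** 2
    return pd.DataFrame(cols)


@dataclass
class FragmentRegressionResults:
    """Fitted coefficients, standard errors and diagnostics."""

    beta0: float
    gamma1: float
    gamma2: float
    d: np.ndarray                       # (8,) fragment effects, sum 0
    f: np.ndarray                       # (28,) pair interactions, sum 0
    bse_beta0: float
    bse_gamma: np.ndarray               # (2,)
    bse_d: np.ndarray                   # (8,)
    bse_f: np.ndarray                   # (28,)
    resid_std: float
    nobs: int
    method: str
    scheme: str = _SCHEME
    model: "FragmentRegression | None" = field(default=None, repr=False)

    @property
    def interaction_matrix(self) -> pd.DataFrame:
        """8x8 frame with f_ij in the upper triangle, NaN elsewhere."""
        m = np.full((N_FRAGMENTS, N_FRAGMENTS), np.nan)
        for k, (i, j) in enumerate(PAIRS):
            m[i - 1, j - 1] = self.f[k]
        idx = [f"F{i}" for i in range(1, 9)]
        return pd.DataFrame(m, index=idx, columns=idx)

    def g(self, n_avail: np.ndarray | float) -> np.ndarray | float:
        """Fitted availability curve beta0 + gamma1 N + gamma2 N^2."""
        n_avail = np.asarray(n_avail, dtype=float)
        return self.beta0 + self.gamma1 * n_avail + self.gamma2 * n_avail ** 2

    def predict(self, codes: list[FragmentCode | str]) -> np.ndarray:
        X = build_design(codes)
        F = X[[f"F{i}" for i in range(1, 9)]].to_numpy()
        P = X[[f"F{i}F{j}" for i, j in PAIRS]].to_numpy()
        return np.asarray(self.g(X["N"].to_numpy())) + F @ self.d + P @ self.f

    def to_frame(self) -> pd.DataFrame:
        """Long coefficient table (term, estimate, se)."""
        terms = (["beta0", "gamma1", "gamma2"]
                 + [f"d{i}" for i in range(1, 9)]
                 + [f"f{i}{j}" for i, j in PAIRS])
        est = np.concatenate([[self.beta0, self.gamma1, self.gamma2],
                              self.d, self.f])
        se = np.concatenate([[self.bse_beta0], self.bse_gamma,
                             self.bse_d, self.bse_f])
        return pd.DataFrame(dict(term=terms, estimate=est, se=se))

    def summary(self) -> str:
        lines = [
            "Fragment-contribution regression "
            f"({self.method}; {self.scheme})",
            f"nobs = {self.nobs}, residual std = {self.resid_std:.5f}",
            f"beta0  = {self.beta0: .5f} (se {self.bse_beta0:.5f})",
            f"gamma1 = {self.gamma1: .5f} (se {self.bse_gamma[0]:.5f})",
            f"gamma2 = {self.gamma2: .5f} (se {self.bse_gamma[1]:.5f})",
            "fragment effects d_i (sum to zero):",
        ]
        lines += [f"  d{i} = {v: .5f} (se {s:.5f})"
                  for i, (v, s) in enumerate(zip(self.d, self.bse_d), 1)]
        top = np.argsort(np.abs(self.f))[::-1][:6]
        lines.append("largest interactions f_ij:")
        lines += [f"  f{PAIRS[k][0]}{PAIRS[k][1]} = {self.f[k]: .5f} "
                  f"(se {self.bse_f[k]:.5f})" for k in top]
        return "\n".join(lines)


class FragmentRegression:
    """Model object: per-code accuracies regressed on fragment structure.

    Parameters
    ----------
    response : array-like
        Accuracy R in [0, 1], one value per code (the mean over that
        code's stimulus group).
    codes : list of FragmentCode or 8-digit strings, aligned with response.
    """

    MIN_CODES = 39  # need at least as many distinct codes as free params

    def __init__(self, response, codes):
        self.codes = [c if isinstance(c, FragmentCode) else
                      FragmentCode(str(c)) for c in codes]
        self.response = np.asarray(response, dtype=float)
        if self.response.ndim != 1 or len(self.response) != len(self.codes):
            raise ValidationError("response and codes must be aligned 1-D")
        if len(set(str(c) for c in self.codes)) < self.MIN_CODES:
            raise ValidationError(
                f"need >= {self.MIN_CODES} distinct codes; "
                f"got {len(set(str(c) for c in self.codes))}")
        self.design = build_design(self.codes)
        self._F = self.design[[f"F{i}" for i in range(1, 9)]].to_numpy()
        self._P = self.design[[f"F{i}F{j}" for i, j in PAIRS]].to_numpy()
        self._N = self.design["N"].to_numpy()

    @classmethod
    def from_accuracy_table(cls, table: pd.DataFrame,
                            code_col: str = "fragment_code",
                            acc_col: str = "accuracy") -> "FragmentRegression":
        return cls(table[acc_col].to_numpy(), list(table[code_col]))

    def fit(self, method: str = "two-stage") -> FragmentRegressionResults:
        """Estimate the model; ``method`` is ``two-stage`` or ``one-stage``.

        Both impose the same identification scheme (single intercept,
        sum-to-zero d and f); on a balanced complete design they agree to
        numerical precision.
        """
        if method not in ("two-stage", "one-stage"):
            raise ValidationError(f"unknown fit method {method!r}")
        R = self.response
        Cd = _sum_zero_basis(N_FRAGMENTS)
        Cf = _sum_zero_basis(N_PAIRS)
        X1 = np.column_stack([np.ones_like(self._N), self._N, self._N ** 2])
        X2 = np.column_stack([self._F @ Cd, self._P @ Cf])

        if method == "two-stage":
            st1 = sm.OLS(R, X1).fit()
            resid = R - X1 @ st1.params
            st2 = sm.OLS(resid, X2).fit()
            theta, cov2 = st2.params, st2.cov_params()
            b0, g1, g2 = st1.params
            bse1 = st1.bse
        else:
            X = np.column_stack([X1, X2])
            joint = sm.OLS(R, X).fit()
            b0, g1, g2 = joint.params[:3]
            theta = joint.params[3:]
            cov = joint.cov_params()
            bse1 = np.sqrt(np.diag(cov)[:3])
            cov2 = cov[3:, 3:]
        rank2 = np.linalg.matrix_rank(X2)
        if rank2 < X2.shape[1]:
            missing = sorted(
                {FragmentCode.from_int(v).digits for v in range(256)}
                - {c.digits for c in self.codes})
            raise ValidationError(
                "rank-deficient constrained design; missing codes include "
                + ", ".join(missing[:5]))
        d = Cd @ theta[:N_FRAGMENTS - 1]
        f = Cf @ theta[N_FRAGMENTS - 1:]
        cov_d = Cd @ cov2[:N_FRAGMENTS - 1, :N_FRAGMENTS - 1] @ Cd.T
        cov_f = Cf @ cov2[N_FRAGMENTS - 1:, N_FRAGMENTS - 1:] @ Cf.T
        pred = X1 @ np.array([b0, g1, g2]) + self._F @ d + self._P @ f
        resid_all = R - pred
        dof = max(1, len(R) - (3 + X2.shape[1]))
        return FragmentRegressionResults(
            beta0=float(b0), gamma1=float(g1), gamma2=float(g2),
            d=d, f=f, bse_beta0=float(bse1[0]), bse_gamma=np.asarray(bse1[1:]),
            bse_d=np.sqrt(np.diag(cov_d)), bse_f=np.sqrt(np.diag(cov_f)),
            resid_std=float(np.sqrt(resid_all @ resid_all / dof)),
            nobs=len(R), method=method, model=self)


def availability_curve(fit: FragmentRegressionResults,
                       stratify_f8: bool = True) -> dict:
    """Availability trend g(N) plus the per-code scatter.

    Returns the overall (beta0, gamma1, gamma2), the scatter of one
    (N, R) point per code, and — when ``stratify_f8`` — separate
    quadratic fits for the codes with fragment 8 present vs absent.
    """
    model = fit.model
    if model is None:
        raise ValidationError("results object lost its model reference")
    N, R = model._N, model.response
    out = dict(beta0=fit.beta0, gamma1=fit.gamma1, gamma2=fit.gamma2,
               scatter=pd.DataFrame(dict(
                   N=N, R=R, code=[str(c) for c in model.codes])))
    if stratify_f8:
        f8 = np.array([c.present(8) for c in model.codes])
        for name, sel in [("f8_present", f8), ("f8_absent", ~f8)]:
            if len(np.unique(N[sel])) < 3:
                raise ValidationError(
                    f"stratum {name} has < 3 distinct availability levels")
            X1 = np.column_stack([np.ones(sel.sum()), N[sel], N[sel] ** 2])
            b = sm.OLS(R[sel], X1).fit().params
            out[name] = dict(beta0=float(b[0]), gamma1=float(b[1]),
                             gamma2=float(b[2]))
    return out


def simulate_accuracies(truth: FragmentRegressionResults,
                        sigma: float,
                        rng: np.random.Generator | int = 0,
                        codes: list[FragmentCode] | None = None
                        ) -> np.ndarray:
    """Draw synthetic per-code accuracies from a known coefficient set.

    Gaussian noise of scale ``sigma`` is added to the model's mean
    surface and the result is clipped to [0, 1].
    """
    if sigma < 0:
        raise ValidationError("noise scale must be nonnegative")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    codes = FragmentCode.all_codes() if codes is None else codes
    mean = truth.predict(codes)
    return np.clip(mean + rng.normal(0.0, sigma, size=len(codes)), 0.0, 1.0)


def make_truth(beta0: float, gamma1: float, gamma2: float,
               d: np.ndarray, f: np.ndarray) -> FragmentRegressionResults:
    """Assemble a ground-truth coefficient set for simulation studies."""
    d, f = np.asarray(d, float), np.asarray(f, float)
    if d.shape != (N_FRAGMENTS,) or f.shape != (N_PAIRS,):
        raise ValidationError("d must have 8 entries and f 28")
    if abs(d.sum()) > 1e-9 or abs(f.sum()) > 1e-9:
        raise ValidationError("truth coefficients must satisfy sum-to-zero")
    z8, z28 = np.zeros(N_FRAGMENTS), np.zeros(N_PAIRS)
    return FragmentRegressionResults(
        beta0=beta0, gamma1=gamma1, gamma2=gamma2, d=d, f=f,
        bse_beta0=0.0, bse_gamma=np.zeros(2), bse_d=z8, bse_f=z28,
        resid_std=0.0, nobs=0, method="truth")
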