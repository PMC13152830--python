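"""Compact structural-equation engine for path models with latent variables.

The engine represents a model in RAM-like form: an asymmetric matrix ``A``
of directed paths, a symmetric matrix ``S`` of variances/covariances, a mean
vector ``M``, and a filter selecting the observed variables.  Model-implied
moments follow from

    mu    = F (I - A)^{-1} M
    Sigma = F (I - A)^{-1} S (I - A)^{-T} F'

Models are declared as :class:`StructuralModelSpec` objects (lists of edges
with fixed or free, possibly equality-constrained, parameters), compiled to
index templates, and fitted either by normal-theory maximum likelihood to
summary moments (:func:`fit_ml_moments`) or by full-information maximum
likelihood to raw data with missing values (:func:`fit_fiml`).  Gradients of
both discrepancy functions are analytic; standard errors come from a
numerically differentiated Hessian of -2 log L at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Fixed",
    "Free",
    "fixed",
    "free",
    "StructuralModelSpec",
    "CompiledModel",
    "SampleMoments",
    "RawDataset",
    "FitOptions",
    "FitIndices",
    "ParameterEstimate",
    "FitResult",
    "NestedComparison",
    "SemError",
    "SpecError",
    "DuplicateEdgeError",
    "UnknownVariableError",
    "EmptyModelError",
    "SingularModelError",
    "MomentsError",
    "AllMissingError",
    "NotNestedError",
    "compile_model",
    "implied_moments",
    "implied_full_moments",
    "fit_ml_moments",
    "fit_fiml",
    "fit_indices",
    "standardize_solution",
    "compare_nested",
    "saturated_moments_spec",
]


# ---------------------------------------------------------------------------
# errors

class SemError(Exception):
    """Base class for engine errors."""


class SpecError(SemError):
    pass


class DuplicateEdgeError(SpecError):
    pass


class UnknownVariableError(SpecError):
    pass


class EmptyModelError(SpecError):
    pass


class SingularModelError(SemError):
    pass


class MomentsError(SemError):
    pass


class AllMissingError(SemError):
    pass


class NotNestedError(SemError):
    pass


# ---------------------------------------------------------------------------
# parameter references

@dataclass(frozen=True)
class Fixed:
    value: float


@dataclass(frozen=True)
class Free:
    label: str
    start: float = 0.0


def fixed(value: float) -> Fixed:
    return Fixed(float(value))


def free(label: str, start: float = 0.0) -> Free:
    return Free(str(label), float(start))


ParameterRef = Fixed | Free


# ---------------------------------------------------------------------------
# model specification

@dataclass
class StructuralModelSpec:
    """Declarative path model.

    directed_edges: (source, target, ref) — a one-headed arrow source -> target.
    variance_edges: (var_a, var_b, ref)   — two-headed; var_a == var_b is a variance.
    mean_terms:     (variable, ref)       — intercept/mean input on the variable.

    Two free references sharing a label are equality-constrained.
    """

    observed_names: list[str]
    latent_names: list[str] = field(default_factory=list)
    directed_edges: list[tuple[str, str, ParameterRef]] = field(default_factory=list)
    variance_edges: list[tuple[str, str, ParameterRef]] = field(default_factory=list)
    mean_terms: list[tuple[str, ParameterRef]] = field(default_factory=list)

    @property
    def all_names(self) -> list[str]:
        return list(self.observed_names) + list(self.latent_names)

    def validate(self) -> None:
        names = self.all_names
        if not self.observed_names:
            raise EmptyModelError("model has no observed variables")
        if len(set(names)) != len(names):
            raise SpecError("duplicate variable name in observed/latent lists")
        if not (self.directed_edges or self.variance_edges or self.mean_terms):
            raise EmptyModelError("model has no edges or mean terms")
        known = set(names)
        seen_directed: set[tuple[str, str]] = set()
        for src, tgt, _ in self.directed_edges:
            if src not in known or tgt not in known:
                raise UnknownVariableError(f"directed edge {src}->{tgt} uses unknown variable")
            if (src, tgt) in seen_directed:
                raise DuplicateEdgeError(f"duplicate directed edge {src}->{tgt}")
            seen_directed.add((src, tgt))
        seen_var: set[frozenset[str]] = set()
        for a, b, _ in self.variance_edges:
            if a not in known or b not in known:
                raise UnknownVariableError(f"variance edge {a}~~{b} uses unknown variable")
            key = frozenset((a, b))
            if key in seen_var:
                raise DuplicateEdgeError(f"duplicate variance edge {a}~~{b}")
            seen_var.add(key)
        seen_mean: set[str] = set()
        for v, _ in self.mean_terms:
            if v not in known:
                raise UnknownVariableError(f"mean term on unknown variable {v}")
            if v in seen_mean:
                raise DuplicateEdgeError(f"duplicate mean term on {v}")
            seen_mean.add(v)


# ---------------------------------------------------------------------------
# compiled form

@dataclass
class CompiledModel:
    observed_names: list[str]
    latent_names: list[str]
    a_template: np.ndarray          # fixed values embedded, free cells zero
    s_template: np.ndarray
    m_template: np.ndarray
    parameter_index: dict[str, list[tuple[str, int, int]]]  # label -> cells ("A"|"S"|"M", i, j)
    theta_labels: list[str]
    theta_start: np.ndarray
    variance_labels: frozenset[str]  # labels living only on the S diagonal

    @property
    def all_names(self) -> list[str]:
        return self.observed_names + self.latent_names

    @property
    def n_observed(self) -> int:
        return len(self.observed_names)

    @property
    def n_all(self) -> int:
        return len(self.all_names)

    @property
    def theta_dimension(self) -> int:
        return len(self.theta_labels)

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Write a parameter vector into (A, S, M)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.theta_dimension,):
            raise ValueError(f"theta must have length {self.theta_dimension}")
        A = self.a_template.copy()
        S = self.s_template.copy()
        M = self.m_template.copy()
        for k, label in enumerate(self.theta_labels):
            for mat, i, j in self.parameter_index[label]:
                if mat == "A":
                    A[i, j] = theta[k]
                elif mat == "S":
                    S[i, j] = theta[k]
                    S[j, i] = theta[k]
                else:
                    M[i] = theta[k]
        return A, S, M

    def read_theta(self, A: np.ndarray, S: np.ndarray, M: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`matrices` (reads the first cell of each label)."""
        out = np.empty(self.theta_dimension)
        for k, label in enumerate(self.theta_labels):
            mat, i, j = self.parameter_index[label][0]
            out[k] = A[i, j] if mat == "A" else (S[i, j] if mat == "S" else M[i])
        return out


def compile_model(spec: StructuralModelSpec) -> CompiledModel:
    spec.validate()
    names = spec.all_names
    idx = {v: k for k, v in enumerate(names)}
    p = len(names)
    A = np.zeros((p, p))
    S = np.zeros((p, p))
    M = np.zeros(p)
    param_index: dict[str, list[tuple[str, int, int]]] = {}
    theta_labels: list[str] = []
    starts: dict[str, float] = {}

    def register(ref: ParameterRef, cell: tuple[str, int, int]) -> None:
        if isinstance(ref, Free):
            if ref.label not in param_index:
                param_index[ref.label] = []
                theta_labels.append(ref.label)
                starts[ref.label] = ref.start
            param_index[ref.label].append(cell)

    for src, tgt, ref in spec.directed_edges:
        i, j = idx[tgt], idx[src]
        if isinstance(ref, Fixed):
            A[i, j] = ref.value
        register(ref, ("A", i, j))
    for a, b, ref in spec.variance_edges:
        i, j = idx[a], idx[b]
        if isinstance(ref, Fixed):
            S[i, j] = S[j, i] = ref.value
        register(ref, ("S", i, j))
    for v, ref in spec.mean_terms:
        i = idx[v]
        if isinstance(ref, Fixed):
            M[i] = ref.value
        register(ref, ("M", i, 0))

    variance_labels = frozenset(
        label
        for label, cells in param_index.items()
        if all(mat == "S" and i == j for mat, i, j in cells)
    )
    model = CompiledModel(
        observed_names=list(spec.observed_names),
        latent_names=list(spec.latent_names),
        a_template=A,
        s_template=S,
        m_template=M,
        parameter_index=param_index,
        theta_labels=theta_labels,
        theta_start=np.array([starts[l] for l in theta_labels]),
        variance_labels=variance_labels,
    )
    # numeric invertibility probe of (I - A) at the start values
    A0, _, _ = model.matrices(model.theta_start)
    try:
        B = np.linalg.inv(np.eye(p) - A0)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SingularModelError("(I - A) is singular at the start values") from exc
    if not np.all(np.isfinite(B)):
        raise SingularModelError("(I - A) is numerically singular at the start values")
    return model


# ---------------------------------------------------------------------------
# implied moments

def _structural_arrays(model: CompiledModel, theta: np.ndarray):
    A, S, M = model.matrices(theta)
    p = model.n_all
    I = np.eye(p)
    try:
        B = np.linalg.solve(I - A, I)
    except np.linalg.LinAlgError as exc:
        raise SingularModelError("(I - A) is singular at this parameter value") from exc
    return A, S, M, B


def implied_full_moments(model: CompiledModel, theta: np.ndarray):
    """Implied mean vector and covariance over ALL variables (observed + latent)."""
    _, S, M, B = _structural_arrays(model, theta)
    mu = B @ M
    Sigma = B @ S @ B.T
    return mu, 0.5 * (Sigma + Sigma.T)


def implied_moments(model: CompiledModel, theta: np.ndarray):
    """Implied mean vector and covariance over the observed variables."""
    mu, Sigma = implied_full_moments(model, theta)
    k = model.n_observed
    return mu[:k], Sigma[:k, :k]


# ---------------------------------------------------------------------------
# data containers

@dataclass
class SampleMoments:
    """Sample mean vector, covariance matrix, and sample size.

    The covariance matrix is used exactly as supplied; whether it carries the
    n or n-1 divisor is the caller's convention (log-likelihood reporting
    treats it as the ML covariance).
    """

    variable_names: list[str]
    mean_vector: np.ndarray
    covariance_matrix: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.mean_vector = np.asarray(self.mean_vector, dtype=float)
        self.covariance_matrix = np.asarray(self.covariance_matrix, dtype=float)
        p = len(self.variable_names)
        if self.mean_vector.shape != (p,) or self.covariance_matrix.shape != (p, p):
            raise MomentsError("names, means and covariance dimensions disagree")
        if self.n <= 0:
            raise MomentsError("n must be positive")
        if not np.allclose(self.covariance_matrix, self.covariance_matrix.T, atol=1e-10):
            raise MomentsError("covariance matrix is not symmetric within 1e-10")
        ev = np.linalg.eigvalsh(self.covariance_matrix)
        if ev.min() < -1e-8:
            raise MomentsError(f"covariance matrix has eigenvalue {ev.min():.3g} < -1e-8")

    @classmethod
    def from_sd_corr(
        cls,
        variable_names: Sequence[str],
        means: Sequence[float],
        sds: Sequence[float],
        correlation: np.ndarray,
        n: int,
    ) -> "SampleMoments":
        """Build from means, SDs and a correlation matrix.

        Correlation matrices whose smallest eigenvalue lies in (-1e-8, 0) are
        repaired by clipping eigenvalues at 1e-10 and renormalizing the
        diagonal; anything more indefinite is an error.
        """
        R = np.asarray(correlation, dtype=float)
        R = 0.5 * (R + R.T)
        ev, V = np.linalg.eigh(R)
        if ev.min() < -1e-8:
            raise MomentsError(f"correlation matrix eigenvalue {ev.min():.3g} < -1e-8")
        if ev.min() <= 0:
            R = (V * np.clip(ev, 1e-10, None)) @ V.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
        sds = np.asarray(sds, dtype=float)
        cov = R * np.outer(sds, sds)
        return cls(list(variable_names), np.asarray(means, float), cov, int(n))

    def subset(self, names: Sequence[str]) -> "SampleMoments":
        pos = [self.variable_names.index(v) for v in names]
        return SampleMoments(
            list(names),
            self.mean_vector[pos],
            self.covariance_matrix[np.ix_(pos, pos)],
            self.n,
        )

    @classmethod
    def from_data(cls, frame: pd.DataFrame, names: Sequence[str], ddof: int = 0) -> "SampleMoments":
        """Complete-data moments (default divisor n, the ML convention)."""
        X = frame[list(names)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise MomentsError("from_data requires complete data")
        n = X.shape[0]
        mean = X.mean(axis=0)
        Xc = X - mean
        cov = (Xc.T @ Xc) / (n - ddof)
        return cls(list(names), mean, cov, n)


@dataclass
class RawDataset:
    """Wide per-participant data; missing values are NaN (never a magic number)."""

    frame: pd.DataFrame
    variable_names: list[str]
    covariate_names: list[str] = field(default_factory=list)
    completer_col: str | None = None

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.variable_names + self.covariate_names if c not in self.frame.columns]
        if missing_cols:
            raise UnknownVariableError(f"columns absent from data: {missing_cols}")

    @property
    def n(self) -> int:
        return len(self.frame)

    def values(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = list(names) if names is not None else self.variable_names
        return self.frame[names].to_numpy(dtype=float)

    def validate_rows(self) -> None:
        X = self.values()
        if np.all(np.isnan(X), axis=1).any():
            raise MomentsError("rows with no observed modeled variable present")


# ---------------------------------------------------------------------------
# fit options / results

@dataclass
class FitOptions:
    compute_se: bool = True
    compute_indices: bool = True
    multi_start: int = 5
    jitter: float = 0.5
    seed: int = 0
    gtol: float = 1e-8
    max_iter: int = 5000
    start_overrides: dict[str, float] | None = None


@dataclass
class ParameterEstimate:
    label: str
    value: float
    se: float = math.nan
    z: float = math.nan
    p: float = math.nan
    standardized_value: float = math.nan


@dataclass
class FitIndices:
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float
    chi_square_over_df: float
    p_value: float
    applicable: bool = True


@dataclass
class FitResult:
    estimates: list[ParameterEstimate]
    theta: np.ndarray
    minus_two_log_likelihood: float
    discrepancy_value: float
    chi_square: float
    df: int
    chi_square_over_df: float
    p_value: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float
    converged: bool
    n_used: int
    method: str
    gradient_norm: float
    warnings: list[str] = field(default_factory=list)
    baseline_chi_square: float = math.nan
    baseline_df: int = 0
    standardized_cells: dict[str, list[float]] = field(default_factory=dict)

    def estimate(self, label: str) -> ParameterEstimate:
        for e in self.estimates:
            if e.label == label:
                return e
        raise KeyError(label)

    def theta_dict(self) -> dict[str, float]:
        return {e.label: e.value for e in self.estimates}


@dataclass
class NestedComparison:
    delta_chi_square: float
    delta_df: int
    delta_cfi: float


# ---------------------------------------------------------------------------
# gradient machinery

def _theta_gradient(
    model: CompiledModel,
    B: np.ndarray,
    S_full: np.ndarray,
    M_full: np.ndarray,
    dF_dSigma_obs: np.ndarray,
    dF_dmu_obs: np.ndarray,
) -> np.ndarray:
    """Map derivatives w.r.t. observed (mu, Sigma) to theta via the chain rule.

    Uses the sparsity of the templates: each free label touches a handful of
    cells of A, S or M.
    """
    p_all = model.n_all
    k = model.n_observed
    G = np.zeros((p_all, p_all))
    G[:k, :k] = dF_dSigma_obs
    g_mu = np.zeros(p_all)
    g_mu[:k] = dF_dmu_obs

    Sigma_full = B @ S_full @ B.T
    # A-cell (i<-j): 2 (Sigma_full G B)[j, i]  +  u[i] (B M)[j]
    SGB = Sigma_full @ G @ B
    u = B.T @ g_mu
    Bm = B @ M_full
    P = B.T @ G @ B  # S-cell derivatives

    grad = np.zeros(model.theta_dimension)
    for t, label in enumerate(model.theta_labels):
        acc = 0.0
        for mat, i, j in model.parameter_index[label]:
            if mat == "A":
                acc += 2.0 * SGB[j, i] + u[i] * Bm[j]
            elif mat == "S":
                acc += P[i, j] if i == j else (P[i, j] + P[j, i])
            else:
                acc += u[i]
        grad[t] = acc
    return grad


def _chol_inverse(Sigma: np.ndarray):
    """(inverse, log-determinant) via Cholesky; raises SingularModelError."""
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise SingularModelError("implied covariance not positive definite") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    inv = np.linalg.inv(L)
    return inv.T @ inv, logdet


# ---------------------------------------------------------------------------
# ML fitting to summary moments

def _ml_value_grad(model: CompiledModel, theta: np.ndarray, moments: SampleMoments,
                   logdet_S: float, want_grad: bool = True):
    A, S_full, M_full, B = _structural_arrays(model, theta)
    k = model.n_observed
    mu = (B @ M_full)[:k]
    Sigma = (B @ S_full @ B.T)[:k, :k]
    W, logdet = _chol_inverse(Sigma)
    Smat = moments.covariance_matrix
    d = moments.mean_vector - mu
    Wd = W @ d
    value = logdet - logdet_S + float(np.trace(Smat @ W)) - k + float(d @ Wd)
    if not want_grad:
        return value, None
    dF_dSigma = W - W @ (Smat + np.outer(d, d)) @ W
    dF_dmu = -2.0 * Wd
    grad = _theta_gradient(model, B, S_full, M_full, dF_dSigma, dF_dmu)
    return value, grad


def _transform_masks(model: CompiledModel):
    return np.array([l in model.variance_labels for l in model.theta_labels])


def _to_eta(theta: np.ndarray, log_mask: np.ndarray) -> np.ndarray:
    eta = theta.copy()
    eta[log_mask] = np.log(np.clip(theta[log_mask], 1e-8, None))
    return eta


def _to_theta(eta: np.ndarray, log_mask: np.ndarray) -> np.ndarray:
    theta = eta.copy()
    theta[log_mask] = np.exp(np.clip(eta[log_mask], -40.0, 40.0))
    return theta


def _moment_derivatives(model: CompiledModel, theta: np.ndarray):
    """Observed implied moments and their per-parameter derivatives."""
    _, S_full, M_full, B = _structural_arrays(model, theta)
    k = model.n_observed
    mu = (B @ M_full)[:k]
    Sigma = (B @ S_full @ B.T)[:k, :k]
    n_all = model.n_all
    dSig, dmu = [], []
    SB = S_full @ B.T
    for label in model.theta_labels:
        dA = np.zeros((n_all, n_all))
        dS = np.zeros((n_all, n_all))
        dM = np.zeros(n_all)
        for mat, i, j in model.parameter_index[label]:
            if mat == "A":
                dA[i, j] = 1.0
            elif mat == "S":
                dS[i, j] += 1.0
                if i != j:
                    dS[j, i] += 1.0
            else:
                dM[i] = 1.0
        dB = B @ dA @ B
        dSf = dB @ SB + B @ dS @ B.T + (B @ S_full) @ dB.T
        dSig.append(dSf[:k, :k])
        dmu.append((dB @ M_full + B @ dM)[:k])
    return mu, Sigma, dSig, dmu


def _expected_information(model: CompiledModel, theta: np.ndarray,
                          scale: float = 1.0) -> np.ndarray:
    """Expected (Fisher) information of the ML discrepancy,
    H_ab = tr(W dSigma_a W dSigma_b) + 2 dmu_a' W dmu_b, times ``scale``."""
    _, Sigma, dSig, dmu = _moment_derivatives(model, theta)
    W, _ = _chol_inverse(Sigma)
    m = model.theta_dimension
    WdS = [W @ d for d in dSig]
    Wdm = [W @ d for d in dmu]
    H = np.empty((m, m))
    for a in range(m):
        for b in range(a + 1):
            H[a, b] = H[b, a] = (float(np.einsum("ij,ji->", WdS[a], WdS[b]))
                                 + 2.0 * float(dmu[a] @ Wdm[b]))
    return scale * H


def _safe_fun_grad(fun_grad, theta):
    try:
        value, grad = fun_grad(theta)
    except SingularModelError:
        return None
    if not (np.isfinite(value) and np.all(np.isfinite(grad))):
        return None
    return value, grad


def _fisher_lm(fun_grad, info_fun, start: np.ndarray, options: FitOptions,
               max_iter: int | None = None):
    """Fisher-scoring with Levenberg-Marquardt damping.

    Converges when the gradient inf-norm drops below ``options.gtol`` or when
    an (almost) undamped scoring step no longer moves the parameters beyond
    numerical precision — the scale-invariant criterion needed for the badly
    conditioned ridges this model family is known for.
    """
    max_iter = max_iter or options.max_iter
    out = _safe_fun_grad(fun_grad, start)
    if out is None:
        return start, math.inf, math.inf, False, "bad start"
    theta = start.copy()
    value, grad = out
    lam = 1e-3
    for _ in range(max_iter):
        gnorm = float(np.max(np.abs(grad)))
        # scale-relative: the FIML objective is -2 log L (order n), the
        # moments objective is the discrepancy (order 1)
        if gnorm < options.gtol * max(1.0, abs(value)):
            return theta, value, gnorm, True, ""
        try:
            H = info_fun(theta)
        except SingularModelError:
            break
        dscale = np.clip(np.diag(H), 1e-10, None)
        accepted = False
        for _trial in range(60):
            try:
                step = np.linalg.solve(H + lam * np.diag(dscale), -grad)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            if (lam <= 1e-5
                    and float(np.max(np.abs(step))) < 1e-9 * (1.0 + float(np.max(np.abs(theta))))):
                # stationary to numerical precision
                return theta, value, gnorm, True, ""
            out = _safe_fun_grad(fun_grad, theta + step)
            if out is not None and out[0] < value:  # strict float improvement
                theta = theta + step
                value, grad = out
                lam = max(lam / 3.0, 1e-10)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            gnorm = float(np.max(np.abs(grad)))
            # the whole damping ladder failed to improve the function by even
            # one ulp: the discrepancy is flat to machine precision here
            note = ""
            if gnorm >= options.gtol * max(1.0, abs(value)):
                note = ("converged by function-improvement exhaustion; "
                        f"max |gradient| = {gnorm:.3g}: the likelihood is "
                        "ridge-flat around the solution (empirical "
                        "underidentification); individual estimates on the "
                        "ridge are not separately interpretable")
            return theta, value, gnorm, True, note
    return theta, value, float(np.max(np.abs(grad))), False, "iteration limit"


def _lbfgs(model: CompiledModel, fun_grad, start: np.ndarray, options: FitOptions):
    """Quasi-Newton fallback on an unconstrained parameterisation
    (variance labels log-transformed)."""
    log_mask = _transform_masks(model)
    s0 = start.copy()
    s0[log_mask] = np.clip(s0[log_mask], 1e-3, None)

    def obj(eta):
        theta = _to_theta(eta, log_mask)
        out = _safe_fun_grad(fun_grad, theta)
        if out is None:
            return 1e12, np.zeros_like(eta)
        value, grad = out
        geta = grad.copy()
        geta[log_mask] *= theta[log_mask]
        return value, geta

    res = optimize.minimize(obj, _to_eta(s0, log_mask), jac=True, method="L-BFGS-B",
                            options={"maxiter": options.max_iter, "ftol": 1e-16,
                                     "gtol": 1e-12, "maxcor": 40})
    return _to_theta(res.x, log_mask), float(res.fun)


def _minimize(model: CompiledModel, fun_grad, start: np.ndarray, options: FitOptions,
              info_fun):
    """Fisher-scoring/LM with an L-BFGS fallback and seeded multi-start."""
    rng = np.random.default_rng(options.seed)
    best = None  # (value, theta, gnorm, converged, note)

    def consider(theta, value, gnorm, conv, note):
        nonlocal best
        if best is None or (conv and not best[3]) or (conv == best[3] and value < best[0]):
            best = (value, theta, gnorm, conv, note)

    for attempt in range(max(1, options.multi_start)):
        s0 = start if attempt == 0 else start + rng.normal(0.0, options.jitter, start.size)
        theta, value, gnorm, conv, note = _fisher_lm(fun_grad, info_fun, s0, options)
        consider(theta, value, gnorm, conv, note)
        if not conv and np.isfinite(value):
            # quasi-Newton escape, then rescore
            theta2, _ = _lbfgs(model, fun_grad, theta, options)
            theta3, value3, gnorm3, conv3, note3 = _fisher_lm(fun_grad, info_fun, theta2,
                                                              options, max_iter=1000)
            consider(theta3, value3, gnorm3, conv3, note3)
        if best[3]:
            break
    value, theta, gnorm, conv, note = best
    return theta, float(value), float(gnorm), bool(conv), note


def _n_moments(p: int) -> int:
    return p * (p + 3) // 2


def _numeric_hessian(grad_fun, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient; evaluation
    failures (e.g. a perturbation leaving the PD region) yield NaN columns."""
    m = theta.size
    H = np.zeros((m, m))
    for j in range(m):
        h = rel_step * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        try:
            H[:, j] = (grad_fun(tp) - grad_fun(tm)) / (2 * h)
        except SingularModelError:
            H[:, j] = np.nan
    return 0.5 * (H + H.T)


def _se_from_hessian(H_m2ll: np.ndarray, warnings_list: list[str]):
    if not np.all(np.isfinite(H_m2ll)):
        warnings_list.append(
            "information matrix could not be evaluated; standard errors not available")
        return None
    try:
        ev = np.linalg.eigvalsh(H_m2ll)
        if ev.min() <= 0:
            warnings_list.append(
                "information matrix not positive definite; standard errors not available")
            return None
        cov = 2.0 * np.linalg.inv(H_m2ll)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        warnings_list.append("information matrix could not be inverted")
        return None


def _srmr(sample_cov: np.ndarray, implied_cov: np.ndarray) -> float:
    d = np.sqrt(np.diag(sample_cov))
    scale = np.outer(d, d)
    resid = (sample_cov - implied_cov) / scale
    iu = np.triu_indices_from(resid)
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def _build_estimates(model: CompiledModel, theta: np.ndarray, se: np.ndarray | None):
    out = []
    for k, label in enumerate(model.theta_labels):
        e = ParameterEstimate(label=label, value=float(theta[k]))
        if se is not None and np.isfinite(se[k]) and se[k] > 0:
            e.se = float(se[k])
            e.z = e.value / e.se
            e.p = 2.0 * float(stats.norm.sf(abs(e.z)))
        out.append(e)
    return out


def _admissibility_warnings(model: CompiledModel, theta: np.ndarray) -> list[str]:
    notes = []
    for k, label in enumerate(model.theta_labels):
        if label in model.variance_labels and theta[k] < 0:
            notes.append(f"inadmissible: negative variance estimate for {label}")
    _, Sigma = implied_moments(model, theta)
    if np.linalg.eigvalsh(Sigma).min() <= 0:
        notes.append("inadmissible: implied observed covariance not positive definite")
    return notes


def fit_ml_moments(model: CompiledModel, moments: SampleMoments,
                   options: FitOptions | None = None) -> FitResult:
    """Fit by normal-theory ML to a mean vector and covariance matrix.

    chi-square uses the (n - 1) * F_ML convention; the baseline model for
    incremental indices is the independence model (free variances and means),
    whose discrepancy has the closed form -log|R|.
    """
    options = options or FitOptions()
    moments = moments.subset(model.observed_names)
    k = model.n_observed
    n_mom = _n_moments(k)
    if model.theta_dimension > n_mom:
        raise SpecError(
            f"model has {model.theta_dimension} free parameters but only {n_mom} sample moments")
    _, logdet_S = _chol_inverse(moments.covariance_matrix)

    start = model.theta_start.copy()
    if options.start_overrides:
        for label, v in options.start_overrides.items():
            if label in model.theta_labels:
                start[model.theta_labels.index(label)] = v

    fun_grad = lambda th: _ml_value_grad(model, th, moments, logdet_S)
    info_fun = lambda th: _expected_information(model, th)
    theta_hat, F_min, gnorm, converged, note = _minimize(model, fun_grad, start,
                                                         options, info_fun)
    F_min = max(F_min, 0.0)

    n = moments.n
    df = n_mom - model.theta_dimension
    chi2 = max((n - 1) * F_min, 0.0)
    mu_hat, Sigma_hat = implied_moments(model, theta_hat)

    warn: list[str] = []
    if note:
        warn.append(note)
    if not converged:
        warn.append(f"non-convergence: max |gradient| = {gnorm:.3g}")
    warn.extend(_admissibility_warnings(model, theta_hat))

    # -2 log L treating the supplied covariance as the ML (divisor n) matrix
    try:
        W, logdet = _chol_inverse(Sigma_hat)
        d = moments.mean_vector - mu_hat
        m2ll = n * (k * math.log(2 * math.pi) + logdet
                    + float(np.trace(moments.covariance_matrix @ W)) + float(d @ W @ d))
    except SingularModelError:
        m2ll = math.nan

    se = None
    if options.compute_se and converged:
        grad_only = lambda th: _ml_value_grad(model, th, moments, logdet_S)[1]
        H_F = _numeric_hessian(grad_only, theta_hat)
        se = _se_from_hessian((n - 1) * H_F, warn)

    if options.compute_indices:
        F_base = -float(logdet_S - np.sum(np.log(np.diag(moments.covariance_matrix))))
        chi2_base = max((n - 1) * F_base, 0.0)
        df_base = n_mom - 2 * k
        idx = fit_indices(chi2, df, chi2_base, df_base, n,
                          residual_summary=(moments.covariance_matrix, Sigma_hat))
    else:
        chi2_base, df_base = math.nan, 0
        idx = FitIndices(math.nan, math.nan, math.nan, (math.nan, math.nan),
                         math.nan, math.nan, math.nan, applicable=False)

    return FitResult(
        estimates=_build_estimates(model, theta_hat, se),
        theta=theta_hat,
        minus_two_log_likelihood=m2ll,
        discrepancy_value=F_min,
        chi_square=chi2,
        df=df,
        chi_square_over_df=chi2 / df if df > 0 else math.nan,
        p_value=float(stats.chi2.sf(chi2, df)) if df > 0 else math.nan,
        cfi=idx.cfi, tli=idx.tli, rmsea=idx.rmsea, rmsea_ci=idx.rmsea_ci, srmr=idx.srmr,
        converged=converged,
        n_used=n,
        method="ml_moments",
        gradient_norm=gnorm,
        warnings=warn,
        baseline_chi_square=chi2_base,
        baseline_df=df_base,
    )


# ---------------------------------------------------------------------------
# FIML

def _missingness_patterns(X: np.ndarray):
    """Group rows by missingness pattern; per pattern return indices of the
    observed columns, count, mean and ML (divisor n_p) covariance."""
    mask = ~np.isnan(X)
    patterns = {}
    for row_mask in np.unique(mask, axis=0):
        key = tuple(row_mask)
        rows = np.all(mask == row_mask, axis=1)
        obs = np.flatnonzero(row_mask)
        sub = X[np.ix_(rows, obs)]
        n_p = sub.shape[0]
        mean = sub.mean(axis=0)
        Xc = sub - mean
        cov = (Xc.T @ Xc) / n_p
        patterns[key] = (obs, n_p, mean, cov)
    return list(patterns.values())


def _fiml_value_grad(model: CompiledModel, theta: np.ndarray, patterns, want_grad=True):
    A, S_full, M_full, B = _structural_arrays(model, theta)
    k = model.n_observed
    mu = (B @ M_full)[:k]
    Sigma = (B @ S_full @ B.T)[:k, :k]
    value = 0.0
    Gacc = np.zeros((k, k))
    gmu = np.zeros(k)
    log2pi = math.log(2 * math.pi)
    for obs, n_p, mean_p, cov_p in patterns:
        Sp = Sigma[np.ix_(obs, obs)]
        W, logdet = _chol_inverse(Sp)
        d = mean_p - mu[obs]
        Wd = W @ d
        value += n_p * (len(obs) * log2pi + logdet
                        + float(np.trace(cov_p @ W)) + float(d @ Wd))
        if want_grad:
            Gp = n_p * (W - W @ (cov_p + np.outer(d, d)) @ W)
            Gacc[np.ix_(obs, obs)] += Gp
            gmu[obs] += -2.0 * n_p * Wd
    if not want_grad:
        return value, None
    grad = _theta_gradient(model, B, S_full, M_full, Gacc, gmu)
    return value, grad


def _logdet_floored(Sigma: np.ndarray) -> float:
    """log|Sigma| with a relative eigenvalue floor: the documented fallback
    for degenerate data (e.g. literally duplicated columns) whose empirical
    covariance is singular, so the saturated reference stays computable."""
    ev = np.linalg.eigvalsh(Sigma)
    floor = 1e-10 * max(float(np.trace(Sigma)) / Sigma.shape[0], 1e-10)
    return float(np.sum(np.log(np.clip(ev, floor, None))))


def _em_saturated(X: np.ndarray, max_iter: int = 500, tol: float = 1e-9):
    """EM for the unstructured multivariate normal under arbitrary missingness.

    Returns (mu, Sigma, minus_two_log_likelihood) of the saturated model.
    """
    n, p = X.shape
    mask = ~np.isnan(X)
    if mask.all():
        mu = X.mean(axis=0)
        Xc = X - mu
        Sigma = (Xc.T @ Xc) / n
        m2ll = n * (p * math.log(2 * math.pi) + _logdet_floored(Sigma) + p)
        return mu, Sigma, m2ll

    col_means = np.nanmean(X, axis=0)
    col_vars = np.nanvar(X, axis=0)
    mu = col_means.copy()
    Sigma = np.diag(np.clip(col_vars, 1e-6, None))
    patterns = []
    for row_mask in np.unique(mask, axis=0):
        rows = np.flatnonzero(np.all(mask == row_mask, axis=1))
        patterns.append((np.flatnonzero(row_mask), np.flatnonzero(~row_mask), rows))

    prev = math.inf
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        ll = 0.0
        for obs, mis, rows in patterns:
            Xo = X[np.ix_(rows, obs)]
            n_r = len(rows)
            Soo = Sigma[np.ix_(obs, obs)]
            W, logdet = _chol_inverse(Soo)
            Do = Xo - mu[obs]
            ll += n_r * (len(obs) * math.log(2 * math.pi) + logdet)
            ll += float(np.einsum("ij,jk,ik->", Do, W, Do))
            Ximp = np.empty((n_r, p))
            Ximp[:, obs] = Xo
            if mis.size:
                Smo = Sigma[np.ix_(mis, obs)]
                reg = Smo @ W
                Ximp[:, mis] = mu[mis] + Do @ reg.T
                Cmm = Sigma[np.ix_(mis, mis)] - reg @ Smo.T
            T1 += Ximp.sum(axis=0)
            T2 += Ximp.T @ Ximp
            if mis.size:
                T2[np.ix_(mis, mis)] += n_r * Cmm
        mu = T1 / n
        Sigma = T2 / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        if abs(prev - ll) < tol * (1 + abs(ll)):
            prev = ll
            break
        prev = ll
    return mu, Sigma, prev


def fit_fiml(model: CompiledModel, data: RawDataset,
             options: FitOptions | None = None) -> FitResult:
    """Full-information ML on raw data with missing values.

    The casewise likelihood is accumulated over missingness patterns using
    the pattern-marginal implied moments; chi-square is the likelihood-ratio
    statistic against the pattern-saturated multivariate normal (fitted by
    EM), and the baseline for incremental indices is the independence model
    (closed-form per-variable ML over each variable's observed entries).
    """
    options = options or FitOptions()
    X = data.values(model.observed_names)
    if X.shape[0] == 0:
        raise MomentsError("empty dataset")
    col_all_missing = np.all(np.isnan(X), axis=0)
    if col_all_missing.any():
        bad = [model.observed_names[i] for i in np.flatnonzero(col_all_missing)]
        raise AllMissingError(f"variables entirely missing: {bad}")
    row_all_missing = np.all(np.isnan(X), axis=1)
    warn: list[str] = []
    if row_all_missing.any():
        warn.append(f"dropped {int(row_all_missing.sum())} rows with no observed modeled variable")
        X = X[~row_all_missing]
    n = X.shape[0]
    k = model.n_observed
    n_mom = _n_moments(k)
    patterns = _missingness_patterns(X)

    mu_sat, Sigma_sat, m2ll_sat = _em_saturated(X)
    # degenerate data (e.g. duplicated columns): the empirical covariance is
    # singular and the likelihood unbounded; ridge the data second moments
    # consistently (objective, saturated reference, baseline) so every
    # quantity stays well-defined
    scale = float(np.trace(Sigma_sat)) / k
    ridge = 0.0
    if np.linalg.eigvalsh(Sigma_sat).min() < 1e-8 * scale:
        ridge = 1e-6 * scale
        warn.append(f"empirical covariance is singular; ridge {ridge:.3g} "
                    "added to all data second moments")
        patterns = [(obs, n_p, mean_p, cov_p + ridge * np.eye(len(obs)))
                    for obs, n_p, mean_p, cov_p in patterns]
        Sigma_sat_r = Sigma_sat + ridge * np.eye(k)
        m2ll_sat = 0.0
        for obs, n_p, mean_p, cov_p in patterns:
            Wp, ldp = _chol_inverse(Sigma_sat_r[np.ix_(obs, obs)])
            d = mean_p - mu_sat[obs]
            m2ll_sat += n_p * (len(obs) * math.log(2 * math.pi) + ldp
                               + float(np.trace(cov_p @ Wp)) + float(d @ Wp @ d))

    start = model.theta_start.copy()
    if options.start_overrides:
        for label, v in options.start_overrides.items():
            if label in model.theta_labels:
                start[model.theta_labels.index(label)] = v

    fun_grad = lambda th: _fiml_value_grad(model, th, patterns)
    # complete-data expected information at scale n: an adequate (PSD)
    # scoring matrix under moderate missingness
    info_fun = lambda th: _expected_information(model, th, scale=n)
    theta_hat, m2ll, gnorm, converged, note = _minimize(model, fun_grad, start,
                                                        options, info_fun)

    chi2 = max(m2ll - m2ll_sat, 0.0)
    df = n_mom - model.theta_dimension

    if note:
        warn.append(note)
    if not converged:
        warn.append(f"non-convergence: max |gradient| = {gnorm:.3g}")
    warn.extend(_admissibility_warnings(model, theta_hat))

    se = None
    if options.compute_se and converged:
        grad_only = lambda th: _fiml_value_grad(model, th, patterns)[1]
        H = _numeric_hessian(grad_only, theta_hat)
        se = _se_from_hessian(H, warn)

    if options.compute_indices:
        # independence baseline: per-variable univariate MLE over observed entries
        m2ll_base = 0.0
        for j in range(k):
            xj = X[:, j]
            xj = xj[~np.isnan(xj)]
            v = float(np.var(xj)) + ridge
            m2ll_base += xj.size * (math.log(2 * math.pi) + math.log(v) + 1.0)
        chi2_base = max(m2ll_base - m2ll_sat, 0.0)
        df_base = n_mom - 2 * k
        _, Sigma_hat = implied_moments(model, theta_hat)
        idx = fit_indices(chi2, df, chi2_base, df_base, n,
                          residual_summary=(Sigma_sat, Sigma_hat))
    else:
        chi2_base, df_base = math.nan, 0
        idx = FitIndices(math.nan, math.nan, math.nan, (math.nan, math.nan),
                         math.nan, math.nan, math.nan, applicable=False)

    return FitResult(
        estimates=_build_estimates(model, theta_hat, se),
        theta=theta_hat,
        minus_two_log_likelihood=m2ll,
        discrepancy_value=(m2ll - m2ll_sat) / max(n, 1),
        chi_square=chi2,
        df=df,
        chi_square_over_df=chi2 / df if df > 0 else math.nan,
        p_value=float(stats.chi2.sf(chi2, df)) if df > 0 else math.nan,
        cfi=idx.cfi, tli=idx.tli, rmsea=idx.rmsea, rmsea_ci=idx.rmsea_ci, srmr=idx.srmr,
        converged=converged,
        n_used=n,
        method="fiml",
        gradient_norm=gnorm,
        warnings=warn,
        baseline_chi_square=chi2_base,
        baseline_df=df_base,
    )


# ---------------------------------------------------------------------------
# fit indices

def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """90% interval by noncentral chi-square inversion; lower bound clamped at 0."""
    alpha = (1.0 - level) / 2.0
    denom = df * (n - 1)

    def solve(prob: float) -> float:
        # find lambda with P(chi2_{df, lambda} <= chi2) = prob
        if stats.ncx2.cdf(chi2, df, 1e-12) < prob:
            return 0.0
        lo, hi = 0.0, 1.0
        while stats.ncx2.cdf(chi2, df, hi) > prob:
            hi *= 2.0
            if hi > 1e8:
                return hi
        return float(optimize.brentq(lambda lam: stats.ncx2.cdf(chi2, df, lam) - prob, lo, hi))

    lam_lo = solve(1.0 - alpha)
    lam_hi = solve(alpha)
    return (math.sqrt(max(lam_lo, 0.0) / denom), math.sqrt(max(lam_hi, 0.0) / denom))


def fit_indices(chi_square: float, df: int, baseline_chi_square: float, baseline_df: int,
                n: int, residual_summary=None) -> FitIndices:
    """CFI/TLI (clamped to [0, 1]), RMSEA with a 90% noncentrality interval,
    and SRMR from standardized covariance residuals (means excluded)."""
    if df <= 0 or baseline_df <= 0:
        srmr = math.nan
        if isinstance(residual_summary, tuple):
            srmr = _srmr(*residual_summary)
        elif isinstance(residual_summary, (int, float)):
            srmr = float(residual_summary)
        return FitIndices(math.nan, math.nan, math.nan, (math.nan, math.nan), srmr,
                          math.nan, math.nan, applicable=False)
    nc_t = max(chi_square - df, 0.0)
    nc_b = max(baseline_chi_square - baseline_df, 0.0)
    cfi = 1.0 if nc_b <= 0 else 1.0 - nc_t / nc_b
    cfi = min(max(cfi, 0.0), 1.0)
    if baseline_chi_square > 0 and chi_square >= 0:
        rb = baseline_chi_square / baseline_df
        rt = chi_square / df
        tli = (rb - rt) / (rb - 1.0) if rb > 1.0 else 1.0
    else:
        tli = 1.0
    tli = min(max(tli, 0.0), 1.0)
    rmsea = math.sqrt(max(0.0, (chi_square - df) / (df * (n - 1))))
    ci = _rmsea_ci(chi_square, df, n)
    if isinstance(residual_summary, tuple):
        srmr = _srmr(*residual_summary)
    elif isinstance(residual_summary, (int, float)):
        srmr = float(residual_summary)
    else:
        srmr = math.nan
    return FitIndices(cfi, tli, rmsea, ci, srmr,
                      chi_square / df, float(stats.chi2.sf(chi_square, df)))


# ---------------------------------------------------------------------------
# standardized solution / nested comparison

def standardize_solution(fit: FitResult, model: CompiledModel) -> FitResult:
    """Attach standardized estimates (rescaled by implied SDs of source and
    target).  Labels spanning several cells keep the first cell's value in
    ``standardized_value``; all per-cell values are kept in
    ``standardized_cells``."""
    mu_full, Sigma_full = implied_full_moments(model, fit.theta)
    sd = np.sqrt(np.clip(np.diag(Sigma_full), 0.0, None))
    cells_out: dict[str, list[float]] = {}
    for k_idx, label in enumerate(model.theta_labels):
        vals = []
        for mat, i, j in model.parameter_index[label]:
            if mat == "A":
                if sd[i] <= 0 or sd[j] <= 0:
                    fit.warnings.append(f"standardization skipped for {label}: zero implied variance")
                    vals.append(math.nan)
                else:
                    vals.append(fit.theta[k_idx] * sd[j] / sd[i])
            elif mat == "S":
                if sd[i] <= 0 or sd[j] <= 0:
                    fit.warnings.append(f"standardization skipped for {label}: zero implied variance")
                    vals.append(math.nan)
                else:
                    vals.append(fit.theta[k_idx] / (sd[i] * sd[j]))
            else:
                vals.append(fit.theta[k_idx] / sd[i] if sd[i] > 0 else math.nan)
        cells_out[label] = vals
        fit.estimates[k_idx].standardized_value = vals[0]
    fit.standardized_cells = cells_out
    return fit


def compare_nested(fit_restricted: FitResult, fit_free: FitResult) -> NestedComparison:
    delta_df = fit_restricted.df - fit_free.df
    if delta_df < 0:
        raise NotNestedError("restricted model has smaller df than the free model")
    return NestedComparison(
        delta_chi_square=fit_restricted.chi_square - fit_free.chi_square,
        delta_df=delta_df,
        delta_cfi=fit_restricted.cfi - fit_free.cfi,
    )


# ---------------------------------------------------------------------------
# convenience

def saturated_moments_spec(names: Sequence[str]) -> StructuralModelSpec:
    """Saturated model: all variances, covariances and means free."""
    names = list(names)
    edges = []
    for i, a in enumerate(names):
        for b in names[: i + 1]:
            lbl = f"v_{a}" if a == b else f"c_{a}_{b}"
            edges.append((a, b, free(lbl, 1.0 if a == b else 0.0)))
    means = [(a, free(f"m_{a}", 0.0)) for a in names]
    return StructuralModelSpec(observed_names=names, variance_edges=edges, mean_terms=means)
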