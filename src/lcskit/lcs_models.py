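"""Builders for univariate and bivariate dual latent change score models.

The dual change score model represents each construct by latent true scores
x_1..x_T behind the observed wave scores, with successive differences
Delta x_t = x_t - x_{t-1} modeled as latent variables driven by

    Delta x_t = s_x  +  beta_x * x_{t-1}  (+ phi_x * Delta x_{t-1}, t >= 3)

and, in the bivariate form, cross-construct couplings: the other construct's
prior *level* (gamma) and prior *change* (xi).  The intercept factor i_x is
the wave-1 true score itself; loadings of observed scores on true scores and
all accumulation paths are fixed at 1.  Under the default options every
dynamic coefficient and the measurement error variances carry a single label
across waves (equality over time).

Naming: observed FF_T1..FF_T4 / EP_T1..EP_T4 by default; latents i_x, s_x,
x_2.., dx_2.. (and the y analogues).  Free-parameter labels are the field's
Greek names spelled out: beta_x, phi_x, gamma_xy, xi_xy, sigma2_ex, mu_ix,
mu_xs, var_ix, var_sx, cov_ix_sx, ...
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sem_core import (
    CompiledModel,
    Free,
    SampleMoments,
    SpecError,
    StructuralModelSpec,
    fixed,
    free,
)

__all__ = [
    "LcsParameters",
    "LcsModelOptions",
    "build_univariate_lcs",
    "build_bivariate_lcs",
    "expected_trajectory",
    "attach_covariates",
    "theta_from_labels",
    "start_values_from_moments",
    "STRUCTURAL_LABELS",
    "IS_BLOCK_LABELS",
]

#: the 14 structural labels of the default bivariate model
STRUCTURAL_LABELS = frozenset({
    "beta_x", "beta_y", "phi_x", "phi_y",
    "gamma_xy", "gamma_yx", "xi_xy", "xi_yx",
    "sigma2_ex", "sigma2_ey", "mu_ix", "mu_iy", "mu_xs", "mu_ys",
})

#: the 10 free (co)variances of the intercept/slope block
IS_BLOCK_LABELS = frozenset({
    "var_ix", "var_sx", "var_iy", "var_sy",
    "cov_ix_sx", "cov_ix_iy", "cov_ix_sy",
    "cov_sx_iy", "cov_sx_sy", "cov_iy_sy",
})


@dataclass
class LcsParameters:
    """Generative parameter set of the bivariate dual change score model.

    ``is_covariance`` is the 4x4 covariance of (i_x, s_x, i_y, s_y); the
    constant loadings alpha are structurally fixed at 1 and not fields.
    Units: intercept means in score units, slope means in score units per
    wave interval, beta/gamma per unit level, phi/xi per unit prior change.
    """

    n_waves: int = 4
    mu_ix: float = 0.0
    mu_iy: float = 0.0
    mu_xs: float = 0.0
    mu_ys: float = 0.0
    is_covariance: np.ndarray = field(default_factory=lambda: np.eye(4))
    beta_x: float = 0.0
    beta_y: float = 0.0
    phi_x: float = 0.0
    phi_y: float = 0.0
    gamma_xy: float = 0.0
    gamma_yx: float = 0.0
    xi_xy: float = 0.0
    xi_yx: float = 0.0
    sigma2_ex: float = 0.0
    sigma2_ey: float = 0.0

    def __post_init__(self) -> None:
        self.is_covariance = np.asarray(self.is_covariance, dtype=float)
        if self.n_waves < 2:
            raise SpecError("n_waves must be >= 2")
        if self.is_covariance.shape != (4, 4):
            raise SpecError("is_covariance must be 4x4 (i_x, s_x, i_y, s_y)")
        if not np.allclose(self.is_covariance, self.is_covariance.T, atol=1e-10):
            raise SpecError("is_covariance must be symmetric")
        if np.linalg.eigvalsh(self.is_covariance).min() < -1e-10:
            raise SpecError("is_covariance must be positive semidefinite")
        if self.sigma2_ex < 0 or self.sigma2_ey < 0:
            raise SpecError("measurement error variances must be nonnegative")

    def label_values(self) -> dict[str, float]:
        """True values keyed by the builder's free-parameter labels."""
        C = self.is_covariance
        out = {
            "beta_x": self.beta_x, "beta_y": self.beta_y,
            "phi_x": self.phi_x, "phi_y": self.phi_y,
            "gamma_xy": self.gamma_xy, "gamma_yx": self.gamma_yx,
            "xi_xy": self.xi_xy, "xi_yx": self.xi_yx,
            "sigma2_ex": self.sigma2_ex, "sigma2_ey": self.sigma2_ey,
            "mu_ix": self.mu_ix, "mu_iy": self.mu_iy,
            "mu_xs": self.mu_xs, "mu_ys": self.mu_ys,
            "var_ix": C[0, 0], "var_sx": C[1, 1], "var_iy": C[2, 2], "var_sy": C[3, 3],
            "cov_ix_sx": C[0, 1], "cov_ix_iy": C[0, 2], "cov_ix_sy": C[0, 3],
            "cov_sx_iy": C[1, 2], "cov_sx_sy": C[1, 3], "cov_iy_sy": C[2, 3],
        }
        return out


@dataclass
class LcsModelOptions:
    include_phi: bool = True
    include_level_coupling: bool = True
    include_change_coupling: bool = True
    covariates: list[str] = field(default_factory=list)
    equality_over_time: bool = True
    free_is_covariances: bool = True  # full 6-covariance i/s block


def _wave_label(base: str, t: int, equal: bool) -> str:
    return base if equal else f"{base}_w{t}"


def _univariate_edges(
    spec: StructuralModelSpec,
    n_waves: int,
    options: LcsModelOptions,
    observed: list[str],
    suffix: str,
) -> None:
    """Append one construct's LCS skeleton to a spec (in place)."""
    eq = options.equality_over_time
    i_name, s_name = f"i_{suffix}", f"s_{suffix}"
    true = [i_name] + [f"{suffix}_{t}" for t in range(2, n_waves + 1)]
    delta = [f"d{suffix}_{t}" for t in range(2, n_waves + 1)]
    spec.latent_names.extend(true + delta + [s_name])

    for t in range(n_waves):
        # constant loading fixed at 1; measurement error variance
        spec.directed_edges.append((true[t], observed[t], fixed(1.0)))
        spec.variance_edges.append(
            (observed[t], observed[t],
             free(_wave_label(f"sigma2_e{suffix}", t + 1, eq), 0.5)))
    for t in range(2, n_waves + 1):
        prev, cur, d = true[t - 2], true[t - 1], delta[t - 2]
        spec.directed_edges.append((prev, cur, fixed(1.0)))
        spec.directed_edges.append((d, cur, fixed(1.0)))
        spec.directed_edges.append((s_name, d, fixed(1.0)))
        spec.directed_edges.append((prev, d, free(_wave_label(f"beta_{suffix}", t, eq), 0.0)))
        if options.include_phi and t >= 3:
            spec.directed_edges.append(
                (delta[t - 3], d, free(_wave_label(f"phi_{suffix}", t, eq), 0.0)))

    spec.mean_terms.append((i_name, free(f"mu_i{suffix}", 0.0)))
    spec.mean_terms.append((s_name, free(f"mu_{suffix}s", 0.0)))
    spec.variance_edges.append((i_name, i_name, free(f"var_i{suffix}", 1.0)))
    spec.variance_edges.append((s_name, s_name, free(f"var_s{suffix}", 0.5)))
    spec.variance_edges.append((i_name, s_name, free(f"cov_i{suffix}_s{suffix}", 0.0)))


def build_univariate_lcs(
    n_waves: int,
    options: LcsModelOptions | None = None,
    observed_names: list[str] | None = None,
    suffix: str = "x",
) -> StructuralModelSpec:
    """Univariate dual change score model for one construct."""
    options = options or LcsModelOptions()
    if n_waves < 2:
        raise SpecError("a change score model needs at least 2 waves")
    if options.include_phi and n_waves < 3:
        raise SpecError("the change autoregression phi needs at least 3 waves")
    observed = observed_names or [f"X_T{t}" for t in range(1, n_waves + 1)]
    if len(observed) != n_waves:
        raise SpecError("observed_names length must equal n_waves")
    spec = StructuralModelSpec(observed_names=list(observed), latent_names=[])
    _univariate_edges(spec, n_waves, options, list(observed), suffix)
    if options.covariates:
        spec = attach_covariates(spec, options.covariates)
    return spec


def build_bivariate_lcs(
    n_waves: int = 4,
    options: LcsModelOptions | None = None,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> StructuralModelSpec:
    """Bivariate dual change score model with level-to-change (gamma) and
    change-to-change (xi) couplings; x = family functioning, y =
    externalizing problems in the study's reading."""
    options = options or LcsModelOptions()
    if n_waves < 2:
        raise SpecError("a change score model needs at least 2 waves")
    if (options.include_phi or options.include_change_coupling) and n_waves < 3:
        raise SpecError("phi / change-to-change coupling need at least 3 waves")
    eq = options.equality_over_time
    x_obs = x_names or [f"FF_T{t}" for t in range(1, n_waves + 1)]
    y_obs = y_names or [f"EP_T{t}" for t in range(1, n_waves + 1)]
    if len(x_obs) != n_waves or len(y_obs) != n_waves:
        raise SpecError("x_names / y_names length must equal n_waves")

    spec = StructuralModelSpec(observed_names=list(x_obs) + list(y_obs), latent_names=[])
    _univariate_edges(spec, n_waves, options, list(x_obs), "x")
    _univariate_edges(spec, n_waves, options, list(y_obs), "y")

    x_true = ["i_x"] + [f"x_{t}" for t in range(2, n_waves + 1)]
    y_true = ["i_y"] + [f"y_{t}" for t in range(2, n_waves + 1)]
    for t in range(2, n_waves + 1):
        dx, dy = f"dx_{t}", f"dy_{t}"
        if options.include_level_coupling:
            spec.directed_edges.append(
                (y_true[t - 2], dx, free(_wave_label("gamma_xy", t, eq), 0.0)))
            spec.directed_edges.append(
                (x_true[t - 2], dy, free(_wave_label("gamma_yx", t, eq), 0.0)))
        if options.include_change_coupling and t >= 3:
            spec.directed_edges.append(
                (f"dy_{t - 1}", dx, free(_wave_label("xi_xy", t, eq), 0.0)))
            spec.directed_edges.append(
                (f"dx_{t - 1}", dy, free(_wave_label("xi_yx", t, eq), 0.0)))

    if options.free_is_covariances:
        spec.variance_edges.append(("i_x", "i_y", free("cov_ix_iy", 0.0)))
        spec.variance_edges.append(("i_x", "s_y", free("cov_ix_sy", 0.0)))
        spec.variance_edges.append(("s_x", "i_y", free("cov_sx_iy", 0.0)))
        spec.variance_edges.append(("s_x", "s_y", free("cov_sx_sy", 0.0)))

    if options.covariates:
        spec = attach_covariates(spec, options.covariates)
    return spec


def expected_trajectory(params: LcsParameters) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form recursion for the per-wave expected means of X and Y.

    E[dx_t] = mu_xs + beta_x E[x_{t-1}] + gamma_xy E[y_{t-1}]
              + xi_xy E[dy_{t-1}] + phi_x E[dx_{t-1}]     (xi/phi terms t >= 3)
    E[x_t]  = E[x_{t-1}] + E[dx_t]; observed mean = true-score mean.

    Serves as the independent oracle for the builders' implied means.
    """
    T = params.n_waves
    ex = np.empty(T)
    ey = np.empty(T)
    ex[0], ey[0] = params.mu_ix, params.mu_iy
    dx_prev = dy_prev = 0.0
    for t in range(1, T):
        dx = params.mu_xs + params.beta_x * ex[t - 1] + params.gamma_xy * ey[t - 1]
        dy = params.mu_ys + params.beta_y * ey[t - 1] + params.gamma_yx * ex[t - 1]
        if t >= 2:
            dx += params.xi_xy * dy_prev + params.phi_x * dx_prev
            dy += params.xi_yx * dx_prev + params.phi_y * dy_prev
        ex[t] = ex[t - 1] + dx
        ey[t] = ey[t - 1] + dy
        dx_prev, dy_prev = dx, dy
    return ex, ey


def attach_covariates(spec: StructuralModelSpec, covariate_names: list[str]) -> StructuralModelSpec:
    """Regress the intercept and slope factors on observed exogenous covariates.

    Each covariate gains a free variance and mean; covariate-covariate
    covariances are free; one directed path runs from each covariate to each
    i/s factor present in the model.
    """
    if len(set(covariate_names)) != len(covariate_names):
        raise SpecError("duplicate covariate name")
    clash = set(covariate_names) & set(spec.all_names)
    if clash:
        raise SpecError(f"covariate names collide with model variables: {sorted(clash)}")
    targets = [v for v in spec.latent_names if v in ("i_x", "i_y", "s_x", "s_y")]
    if not targets:
        raise SpecError("no intercept/slope factors found to receive covariates")
    out = StructuralModelSpec(
        observed_names=list(spec.observed_names),
        latent_names=list(spec.latent_names),
        directed_edges=list(spec.directed_edges),
        variance_edges=list(spec.variance_edges),
        mean_terms=list(spec.mean_terms),
    )
    for c in covariate_names:
        out.observed_names.append(c)
        out.variance_edges.append((c, c, free(f"var_{c}", 1.0)))
        out.mean_terms.append((c, free(f"mu_{c}", 0.0)))
        for tgt in targets:
            out.directed_edges.append((c, tgt, free(f"b_{c}_{tgt}", 0.0)))
    for i, c1 in enumerate(covariate_names):
        for c2 in covariate_names[:i]:
            out.variance_edges.append((c2, c1, free(f"cov_{c2}_{c1}", 0.0)))
    return out


def theta_from_labels(model: CompiledModel, values: dict[str, float],
                      default: float = 0.0) -> np.ndarray:
    """Assemble a theta vector from a label->value mapping."""
    theta = np.full(model.theta_dimension, default, dtype=float)
    for k, label in enumerate(model.theta_labels):
        if label in values:
            theta[k] = values[label]
    return theta


def start_values_from_moments(moments: SampleMoments, x_names: list[str],
                              y_names: list[str]) -> dict[str, float]:
    """Crude data-driven start values for the bivariate builder's labels."""
    mom = moments.subset(list(x_names) + list(y_names))
    T = len(x_names)
    mx = mom.mean_vector[:T]
    my = mom.mean_vector[T:]
    vx = float(np.mean(np.diag(mom.covariance_matrix)[:T]))
    vy = float(np.mean(np.diag(mom.covariance_matrix)[T:]))
    return {
        "mu_ix": float(mx[0]), "mu_iy": float(my[0]),
        "mu_xs": float(np.mean(np.diff(mx))), "mu_ys": float(np.mean(np.diff(my))),
        "var_ix": 0.6 * vx, "var_iy": 0.6 * vy,
        "sigma2_ex": 0.35 * vx, "sigma2_ey": 0.35 * vy,
        "var_sx": 0.2 * vx, "var_sy": 0.2 * vy,
    }
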