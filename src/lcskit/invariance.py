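"""Longitudinal measurement invariance: configural -> metric -> scalar.

One factor per wave over the same items measured repeatedly, in a single
long model (waves as repeated factors) rather than literal multiple groups —
the estimable form for repeated measures on one sample.  Identification is
by marker item: the first item's loading is fixed to 1 and its intercept to
0 at every wave, factor means are free at every wave.  Residuals of the same
item are allowed to covary across all wave pairs.

The ladder equates loadings across waves (metric) and then intercepts
(scalar); each step is judged by the change in CFI, with a decrease larger
than the threshold (default 0.01) rejecting the step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .sem_core import (
    FitOptions,
    FitResult,
    RawDataset,
    SingularModelError,
    SpecError,
    StructuralModelSpec,
    compile_model,
    fit_fiml,
    fixed,
    free,
    implied_moments,
)

__all__ = [
    "LEVELS",
    "InvarianceConfig",
    "InvarianceResult",
    "build_longitudinal_cfa",
    "invariance_sequence",
    "decide_step",
]

LEVELS = ("configural", "metric", "scalar")


@dataclass
class InvarianceConfig:
    """Item layout for one construct: item_names_per_wave[w][j] is the j-th
    item at wave w; the first item is the marker at every wave."""

    construct: str
    item_names_per_wave: list[list[str]]
    threshold: float = 0.01


@dataclass
class InvarianceResult:
    construct: str
    fits: dict[str, FitResult]
    delta_cfi_metric: float
    delta_cfi_scalar: float
    decisions: dict[str, bool | None]
    threshold: float
    warnings: list[str] = field(default_factory=list)


def decide_step(delta_cfi: float, threshold: float) -> bool:
    """Accept unless the CFI *decrease* exceeds the threshold.

    delta_cfi is signed (later minus earlier); -0.02 with threshold 0.01
    rejects, +0.02 accepts.
    """
    if math.isnan(delta_cfi):
        return False
    return -delta_cfi <= threshold


def build_longitudinal_cfa(item_names_per_wave: list[list[str]],
                           level: str) -> StructuralModelSpec:
    """One-factor-per-wave longitudinal CFA at the requested invariance level."""
    if level not in LEVELS:
        raise SpecError(f"unknown invariance level {level!r}; expected one of {LEVELS}")
    T = len(item_names_per_wave)
    if T < 2:
        raise SpecError("need at least 2 waves")
    k = len(item_names_per_wave[0])
    if k < 3:
        raise SpecError("need at least 3 items per wave")
    if any(len(items) != k for items in item_names_per_wave):
        raise SpecError("every wave must have the same number of items")

    observed = [it for wave in item_names_per_wave for it in wave]
    if len(set(observed)) != len(observed):
        raise SpecError("item names must be unique across waves")
    factors = [f"f_{w + 1}" for w in range(T)]
    spec = StructuralModelSpec(observed_names=observed, latent_names=list(factors))

    equate_loadings = level in ("metric", "scalar")
    equate_intercepts = level == "scalar"
    for w, items in enumerate(item_names_per_wave):
        f = factors[w]
        for j, item in enumerate(items):
            if j == 0:
                spec.directed_edges.append((f, item, fixed(1.0)))
                spec.mean_terms.append((item, fixed(0.0)))
            else:
                lam = f"lambda_{j + 1}" if equate_loadings else f"lambda_{j + 1}_w{w + 1}"
                nu = f"nu_{j + 1}" if equate_intercepts else f"nu_{j + 1}_w{w + 1}"
                spec.directed_edges.append((f, item, free(lam, 1.0)))
                spec.mean_terms.append((item, free(nu, 0.0)))
            spec.variance_edges.append(
                (item, item, free(f"theta_{j + 1}_w{w + 1}", 0.3)))
        spec.variance_edges.append((f, f, free(f"psi_w{w + 1}", 0.3)))
        spec.mean_terms.append((f, free(f"kappa_w{w + 1}", 0.0)))
    for w1 in range(T):
        for w2 in range(w1 + 1, T):
            spec.variance_edges.append(
                (factors[w1], factors[w2], free(f"psi_w{w1 + 1}_w{w2 + 1}", 0.1)))
            # same-item residual covariances across waves
            for j in range(k):
                a = item_names_per_wave[w1][j]
                b = item_names_per_wave[w2][j]
                spec.variance_edges.append(
                    (a, b, free(f"rtheta_{j + 1}_w{w1 + 1}_w{w2 + 1}", 0.0)))
    return spec


_WAVE_SUFFIX = "_w"


def _expand_labels(labels: list[str], coarse: dict[str, float]) -> dict[str, float]:
    """Map a coarser (equated) solution onto a freer model's labels."""
    out = {}
    for lbl in labels:
        if lbl in coarse:
            out[lbl] = coarse[lbl]
        else:
            head, sep, tail = lbl.rpartition(_WAVE_SUFFIX)
            if sep and tail.isdigit() and head in coarse:
                out[lbl] = coarse[head]
    return out


def _contract_labels(labels: list[str], fine: dict[str, float]) -> dict[str, float]:
    """Map a freer solution onto an equated model's labels (per-wave values
    averaged into the shared label)."""
    out = {}
    pools: dict[str, list[float]] = {}
    for lbl, v in fine.items():
        head, sep, tail = lbl.rpartition(_WAVE_SUFFIX)
        if sep and tail.isdigit():
            pools.setdefault(head, []).append(v)
    for lbl in labels:
        if lbl in fine:
            out[lbl] = fine[lbl]
        elif lbl in pools:
            out[lbl] = sum(pools[lbl]) / len(pools[lbl])
    return out


def _usable_starts(model, warm: dict[str, float],
                   base: dict[str, float]) -> dict[str, float]:
    """Blend a warm start toward the data-driven start until the implied
    covariance is positive definite (a warm start expanded from a boundary
    solution can sit exactly on the singular edge)."""
    for alpha in (1.0, 0.98, 0.9, 0.7, 0.0):
        merged = dict(base)
        for lbl, v in warm.items():
            merged[lbl] = alpha * v + (1 - alpha) * base.get(lbl, v * 0.9)
        theta = model.theta_start.copy()
        for k, lbl in enumerate(model.theta_labels):
            if lbl in merged:
                theta[k] = merged[lbl]
        try:
            _, Sigma = implied_moments(model, theta)
            np.linalg.cholesky(Sigma)
            return merged
        except (SingularModelError, np.linalg.LinAlgError):
            continue
    return base


def _start_overrides(data: RawDataset, item_names_per_wave: list[list[str]],
                     level: str) -> dict[str, float]:
    """Data-driven starts: factor mean from the marker item, intercepts from
    item-mean offsets, uniquenesses from half the item variances."""
    frame = data.frame
    out: dict[str, float] = {}
    T = len(item_names_per_wave)
    k = len(item_names_per_wave[0])
    for w in range(T):
        items = item_names_per_wave[w]
        marker_mean = float(frame[items[0]].mean())
        marker_var = float(frame[items[0]].var())
        out[f"kappa_w{w + 1}"] = marker_mean
        out[f"psi_w{w + 1}"] = 0.5 * marker_var
        for j in range(k):
            v = float(frame[items[j]].var())
            out[f"theta_{j + 1}_w{w + 1}"] = max(0.5 * v, 0.05)
            if j > 0:
                key = f"nu_{j + 1}" if level == "scalar" else f"nu_{j + 1}_w{w + 1}"
                out.setdefault(key, float(frame[items[j]].mean()) - marker_mean)
    return out


def invariance_sequence(item_data: RawDataset, config: InvarianceConfig,
                        options: FitOptions | None = None) -> InvarianceResult:
    """Run the three-level ladder and apply the delta-CFI rule per step."""
    missing = [c for wave in config.item_names_per_wave for c in wave
               if c not in item_data.frame.columns]
    if missing:
        raise SpecError(f"item columns absent from data: {missing}")
    options = options or FitOptions(compute_se=False, multi_start=3)

    fits: dict[str, FitResult] = {}
    warn: list[str] = []
    # fit the most restricted level first and warm-start each freer level by
    # expanding the coarser solution (lambda_2 -> lambda_2_w3, ...): this
    # keeps the ladder discrepancies monotone even on degenerate data
    coarse: dict[str, float] = {}
    for level in reversed(LEVELS):
        spec = build_longitudinal_cfa(config.item_names_per_wave, level)
        model = compile_model(spec)
        base = _start_overrides(item_data, config.item_names_per_wave, level)
        starts = _usable_starts(model, _expand_labels(model.theta_labels, coarse), base)
        opts = FitOptions(
            compute_se=False,
            compute_indices=True,
            multi_start=options.multi_start,
            jitter=options.jitter,
            seed=options.seed,
            gtol=options.gtol,
            max_iter=options.max_iter,
            start_overrides=starts,
        )
        fit = fit_fiml(model, item_data, opts)
        fits[level] = fit
        coarse = fit.theta_dict()

    # upward pass: refit restricted levels warm-started by contracting the
    # freer neighbour's solution; keep whichever discrepancy is lower
    neighbour = {"metric": "configural", "scalar": "metric"}
    for level in ("metric", "scalar"):
        spec = build_longitudinal_cfa(config.item_names_per_wave, level)
        model = compile_model(spec)
        base = _start_overrides(item_data, config.item_names_per_wave, level)
        starts = _usable_starts(
            model, _contract_labels(model.theta_labels, fits[neighbour[level]].theta_dict()),
            base)
        refit = fit_fiml(model, item_data, FitOptions(
            compute_se=False, multi_start=1, seed=options.seed,
            gtol=options.gtol, max_iter=options.max_iter, start_overrides=starts))
        if refit.discrepancy_value < fits[level].discrepancy_value:
            fits[level] = refit

    for level in LEVELS:
        if not fits[level].converged:
            warn.append(f"{level} model did not converge; decision suppressed")

    d_metric = fits["metric"].cfi - fits["configural"].cfi
    d_scalar = fits["scalar"].cfi - fits["metric"].cfi
    decisions: dict[str, bool | None] = {
        "metric": (decide_step(d_metric, config.threshold)
                   if fits["metric"].converged and fits["configural"].converged else None),
        "scalar": (decide_step(d_scalar, config.threshold)
                   if fits["scalar"].converged and fits["metric"].converged else None),
    }
    return InvarianceResult(
        construct=config.construct,
        fits=fits,
        delta_cfi_metric=d_metric,
        delta_cfi_scalar=d_scalar,
        decisions=decisions,
        threshold=config.threshold,
        warnings=warn,
    )
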