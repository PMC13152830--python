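"""Readers and writers for the package's plain-text formats.

Moments file: a small CSV container with four blocks introduced by comment
lines (`# means`, `# sds`, `# correlations`, `# n`); correlations are stored
as lower-triangle triples and converted to a covariance matrix on read.
Raw data: wide CSV, one row per participant, with a declared missing-value
sentinel (empty cell by default).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .sem_core import MomentsError, RawDataset, SampleMoments

__all__ = ["read_moments_csv", "write_moments_csv", "read_wide_csv", "write_wide_csv"]


def write_moments_csv(moments: SampleMoments, path: str | Path) -> None:
    names = moments.variable_names
    sds = np.sqrt(np.diag(moments.covariance_matrix))
    R = moments.covariance_matrix / np.outer(sds, sds)
    lines = ["# means"]
    lines += [f"{v},{float(m):.17g}" for v, m in zip(names, moments.mean_vector)]
    lines.append("# sds")
    lines += [f"{v},{float(s):.17g}" for v, s in zip(names, sds)]
    lines.append("# correlations")
    for i in range(1, len(names)):
        for j in range(i):
            lines.append(f"{names[i]},{names[j]},{float(R[i, j]):.17g}")
    lines.append("# n")
    lines.append(str(moments.n))
    Path(path).write_text("\n".join(lines) + "\n")


def read_moments_csv(path: str | Path) -> SampleMoments:
    section = None
    names: list[str] = []
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    corr: list[tuple[str, str, float]] = []
    n = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            section = line.lstrip("# ").lower()
            continue
        parts = [p.strip() for p in line.split(",")]
        if section == "means":
            names.append(parts[0])
            means[parts[0]] = float(parts[1])
        elif section == "sds":
            sds[parts[0]] = float(parts[1])
        elif section == "correlations":
            corr.append((parts[0], parts[1], float(parts[2])))
        elif section == "n":
            n = int(parts[0])
        else:
            raise MomentsError(f"moments file line outside a known block: {line!r}")
    if n is None or not names or set(names) != set(sds):
        raise MomentsError("moments file is missing a block (means, sds or n)")
    p = len(names)
    idx = {v: i for i, v in enumerate(names)}
    R = np.eye(p)
    for a, b, r in corr:
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return SampleMoments.from_sd_corr(
        names, [means[v] for v in names], [sds[v] for v in names], R, n)


def read_wide_csv(path: str | Path, variable_names: list[str],
                  covariate_names: list[str] | None = None,
                  completer_col: str | None = None,
                  missing_sentinel: str | float | None = None) -> RawDataset:
    """Read wide per-participant data.  ``missing_sentinel`` (besides empty
    cells) is mapped to NaN at the reader layer; values are never imputed."""
    na = ["", "NA", "NaN"]
    if missing_sentinel is not None:
        na.append(str(missing_sentinel))
    frame = pd.read_csv(path, na_values=na, keep_default_na=True)
    if missing_sentinel is not None and not isinstance(missing_sentinel, str):
        frame = frame.replace(missing_sentinel, np.nan)
    return RawDataset(frame=frame, variable_names=list(variable_names),
                      covariate_names=list(covariate_names or []),
                      completer_col=completer_col)


def write_wide_csv(data: RawDataset, path: str | Path) -> None:
    data.frame.to_csv(path, index=False)
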