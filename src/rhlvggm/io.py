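"""File formats and run artifacts: CSV matrices in, CSV/JSON results out."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ObservedData
from .em import FitResult
from .metrics import MetricsReport, ZERO_TOL

logger = logging.getLogger(__name__)

__all__ = ["read_matrix", "write_results"]


def read_matrix(path: str | Path) -> ObservedData:
    """Read a samples-by-variables matrix from delimited text.

    The delimiter is sniffed (comma/tab/semicolon/whitespace); a header row
    and a leading non-numeric ID column are auto-detected.  Missing values
    are rejected with the offending cell named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None)
    except pd.errors.ParserError as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc

    def _numeric(v) -> bool:
        try:
            float(v)
            return True
        except (TypeError, ValueError):
            return False

    has_header = not all(_numeric(v) for v in df.iloc[0])
    if has_header:
        header = [str(v) for v in df.iloc[0]]
        df = df.iloc[1:].reset_index(drop=True)
    else:
        header = None
    # leading ID column: non-numeric below the header row
    if df.shape[1] >= 2 and not all(_numeric(v) for v in df.iloc[:, 0]):
        df = df.iloc[:, 1:]
        if header is not None:
            header = header[1:]
    names = header if header is not None else [f"V{j + 1}" for j in range(df.shape[1])]

    values = np.empty(df.shape, dtype=float)
    for j in range(df.shape[1]):
        col = pd.to_numeric(df.iloc[:, j], errors="coerce")
        if col.isna().any():
            i = int(col.isna().idxmax())
            raise ValueError(
                f"non-numeric or missing value at row {i + 1 + int(has_header)}, "
                f"column {names[j]!r} of {path}"
            )
        values[:, j] = col.to_numpy()
    if values.shape[0] < 3:
        raise ValueError(f"{path} has n={values.shape[0]} rows; need at least 3")
    return ObservedData(values, var_names=names)


def _frame(M: np.ndarray, names: list[str]) -> pd.DataFrame:
    return pd.DataFrame(M, columns=names)


def write_results(
    fit: FitResult,
    out_dir: str | Path,
    metrics: MetricsReport | None = None,
    var_names: list[str] | None = None,
    selection_table: list[dict] | None = None,
    manifest_extra: dict | None = None,
    overwrite: bool = False,
    edge_tol: float = ZERO_TOL,
) -> dict:
    """Write the standard result bundle to ``out_dir`` and return a manifest.

    Files: S_hat/L_hat/Theta_hat/means/proportions/labels/edges as CSV, an
    optional selection table and metrics row, plus ``manifest.json`` holding
    the configuration echo, convergence record and objective trace.
    Existing files are never overwritten unless ``overwrite`` is set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = fit.params.S.shape[0]
    names = var_names or [f"V{j + 1}" for j in range(p)]
    theta = fit.params.theta

    files: dict[str, str] = {}

    def target(fname: str) -> Path:
        f = out / fname
        if f.exists() and not overwrite:
            raise FileExistsError(f"{f} exists; pass overwrite to replace")
        files[fname.split(".")[0]] = str(f)
        return f

    _frame(fit.params.S, names).to_csv(target("S_hat.csv"), index=False)
    _frame(fit.params.L, names).to_csv(target("L_hat.csv"), index=False)
    _frame(theta, names).to_csv(target("Theta_hat.csv"), index=False)
    pd.DataFrame(fit.params.mu, columns=names).to_csv(target("means.csv"), index=False)
    pd.DataFrame(
        {"component": range(len(fit.params.pi)), "pi": fit.params.pi}
    ).to_csv(target("proportions.csv"), index=False)

    gamma_cols = {f"gamma_{k}": fit.gamma[:, k] for k in range(fit.gamma.shape[1])}
    pd.DataFrame(
        {"sample": range(len(fit.hard_labels)), "hard_label": fit.hard_labels, **gamma_cols}
    ).to_csv(target("labels.csv"), index=False)

    ii, jj = np.where(np.triu(np.abs(theta) > edge_tol, k=1))
    pd.DataFrame(
        {
            "i": ii, "j": jj,
            "name_i": [names[i] for i in ii],
            "name_j": [names[j] for j in jj],
            "theta_ij": theta[ii, jj],
        }
    ).to_csv(target("edges.csv"), index=False)

    if selection_table:
        pd.DataFrame(selection_table).to_csv(target("selection.csv"), index=False)
    if metrics is not None:
        pd.DataFrame([metrics.to_dict()]).to_csv(target("metrics.csv"), index=False)

    manifest = {
        "converged": fit.converged,
        "n_outer": fit.n_outer,
        "delta": fit.params.delta,
        "K": fit.params.K,
        "pi": fit.params.pi.tolist(),
        "objective_trace": [asdict(o) for o in fit.objective_trace],
        "inner_iterations": fit.inner_iterations,
        "files": files,
        **(manifest_extra or {}),
    }
    mpath = target("manifest.json")
    mpath.write_text(json.dumps(manifest, indent=2))
    (out / "run.log").write_text("\n".join(fit.log) + "\n")
    return manifest
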