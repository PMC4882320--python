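"""Delimited-text interchange for panels, matrices and results.

Tab-separated text with a header row is the interchange format for subject
panels and square matrices; JSON (sorted keys, fixed float formatting) for
metadata and result summaries, so repeated runs with the same seed produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ResidualPanel, SubjectPanel

_COVARIATE_COLUMNS = ["group", "age", "sex", "glucose"]


def write_panel(panel: SubjectPanel, values_path, covariates_path) -> None:
    """Write a panel as two TSVs: values (subjects x regions) and covariates."""
    panel.values.to_csv(values_path, sep="\t", index_label="subject_id")
    cov = panel.covariates.copy()
    cov.insert(0, "group", panel.group)
    cov.to_csv(covariates_path, sep="\t", index_label="subject_id")


def read_panel(values_path, covariates_path, group: str | None = None) -> SubjectPanel:
    values = pd.read_csv(values_path, sep="\t", index_col="subject_id")
    cov = pd.read_csv(covariates_path, sep="\t", index_col="subject_id")
    if group is None:
        groups = cov["group"].unique() if "group" in cov else [""]
        if len(groups) != 1:
            raise ValueError(f"covariate file mixes groups {list(groups)}; pass group=")
        group = str(groups[0])
    cov = cov.drop(columns=[c for c in ("group",) if c in cov.columns])
    return SubjectPanel(values=values, covariates=cov, group=group)


def write_matrix(matrix: np.ndarray, labels, path) -> None:
    """Square matrix as TSV with region labels on both axes."""
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(
        path, sep="\t", index_label="region"
    )


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="region")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path} is not a labeled square matrix")
    return df.to_numpy(dtype=float), list(df.columns)


def write_residual_panel(res: ResidualPanel, residuals_path, coefficients_path) -> None:
    res.residuals.to_csv(residuals_path, sep="\t", index_label="subject_id")
    payload = {
        "group": res.group,
        "covariates": list(res.covariate_names),
        "coefficients": {
            region: {c: res.coefficients.loc[region, c] for c in res.coefficients.columns}
            for region in res.coefficients.index
        },
    }
    write_json(payload, coefficients_path)


def read_residual_panel(residuals_path, coefficients_path) -> ResidualPanel:
    residuals = pd.read_csv(residuals_path, sep="\t", index_col="subject_id")
    meta = read_json(coefficients_path)
    coef = pd.DataFrame.from_dict(meta["coefficients"], orient="index")
    return ResidualPanel(
        residuals=residuals,
        coefficients=coef.loc[list(residuals.columns)],
        group=meta.get("group", ""),
        covariate_names=tuple(meta.get("covariates", ())),
    )


def _default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(payload: dict, path) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_default) + "\n"
    )


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
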