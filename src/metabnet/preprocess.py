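"""ROI-level preprocessing: global-mean normalization and covariate removal.

Two steps precede network construction.  First every subject's regional
profile is divided by that subject's whole-brain mean, which removes the
subject-specific global scaling that PET uptake values carry.  Second, for
each region, the normalized value is regressed (ordinary least squares, with
intercept) on the nuisance covariates — age, sex and fasting blood glucose —
and the residual replaces the value.  The across-subject Pearson correlation
of these residuals defines the group's covariance network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_COVARIATES = ("age", "sex", "glucose")


@dataclass
class SubjectPanel:
    """Subjects x regions table of regional metabolism plus covariates.

    ``values`` rows are subjects (index = subject ids), columns are region
    labels in canonical atlas order.  ``covariates`` is row-aligned with
    ``values`` and holds ``age`` (years), ``sex`` (0/1) and ``glucose``
    (mmol/L).  Values are strictly positive uptake-like quantities.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame
    group: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != len(self.covariates):
            raise ValueError("values and covariates have different numbers of subjects")
        if not self.values.index.equals(self.covariates.index):
            raise ValueError("values and covariates subject ids are not aligned")
        if self.values.isna().any().any() or self.covariates.isna().any().any():
            raise ValueError("missing entries are not allowed (complete-case design)")

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    @property
    def region_labels(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ResidualPanel:
    """OLS residuals of normalized regional values, plus fitted coefficients.

    ``coefficients`` has one row per region and one column per design term
    (``intercept`` plus the covariates used), so the fits can be inspected.
    """

    residuals: pd.DataFrame
    coefficients: pd.DataFrame
    group: str = ""
    covariate_names: tuple[str, ...] = field(default=DEFAULT_COVARIATES)

    @property
    def n_subjects(self) -> int:
        return len(self.residuals)

    @property
    def region_labels(self) -> list[str]:
        return list(self.residuals.columns)

    def matrix(self) -> np.ndarray:
        return self.residuals.to_numpy()


def global_normalize(panel: SubjectPanel) -> SubjectPanel:
    """Divide each subject's row by that subject's mean over all regions.

    Output rows have mean exactly 1 (up to floating point), so any
    per-subject multiplicative factor — scanner dose, global metabolism —
    is removed before correlation.
    """
    values = panel.values.to_numpy(dtype=float)
    if np.any(values <= 0):
        bad = panel.values.index[np.any(values <= 0, axis=1)][0]
        raise ValueError(f"non-positive metabolism value for subject {bad!r}")
    row_means = values.mean(axis=1, keepdims=True)
    normalized = pd.DataFrame(
        values / row_means, index=panel.values.index, columns=panel.values.columns
    )
    return SubjectPanel(values=normalized, covariates=panel.covariates.copy(), group=panel.group)


def design_matrix(covariates: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    """Intercept + selected covariate columns, with a rank check.

    Raises ``ValueError`` naming the offending column when a covariate is
    missing, constant, or collinear with the rest of the design.
    """
    cols = [np.ones(len(covariates))]
    for name in names:
        if name not in covariates.columns:
            raise ValueError(f"covariate {name!r} missing from panel")
        col = covariates[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            raise ValueError(f"covariate {name!r} is constant; design matrix is rank deficient")
        cols.append(col)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # locate the first column whose removal restores full rank
        for k, name in enumerate(names, start=1):
            reduced = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(reduced) == reduced.shape[1]:
                raise ValueError(f"covariate {name!r} is collinear with the remaining design")
        raise ValueError("design matrix is rank deficient")
    return X


def ols_residuals(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residuals and coefficients of Y (n x p_regions) on design X (n x k)."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta, beta


def residualize(
    panel: SubjectPanel, covariates: tuple[str, ...] = DEFAULT_COVARIATES
) -> ResidualPanel:
    """Per-region OLS residuals of the panel values on the covariate design.

    The panel should already be globally normalized.  Residuals have zero
    mean per region and are orthogonal to every design column.
    """
    X = design_matrix(panel.covariates, tuple(covariates))
    resid, beta = ols_residuals(panel.values.to_numpy(dtype=float), X)
    coef = pd.DataFrame(
        beta.T, index=panel.values.columns, columns=["intercept", *covariates]
    )
    residuals = pd.DataFrame(resid, index=panel.values.index, columns=panel.values.columns)
    return ResidualPanel(
        residuals=residuals, coefficients=coef, group=panel.group,
        covariate_names=tuple(covariates),
    )


def preprocess(
    panel: SubjectPanel, covariates: tuple[str, ...] = DEFAULT_COVARIATES
) -> ResidualPanel:
    """Convenience: global normalization followed by residualization."""
    return residualize(global_normalize(panel), covariates)
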