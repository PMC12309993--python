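"""Small design-matrix builders shared by the regression modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_design_matrix", "cell_means_design", "factorial_design"]


def _dummies(col: pd.Series, name: str, reference=None) -> pd.DataFrame:
    levels = sorted(col.unique().tolist())
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from {name!r}")
    out = {}
    for lv in levels:
        if lv == reference:
            continue
        out[f"{name}[{lv}]"] = (col == lv).astype(float)
    return pd.DataFrame(out, index=col.index)


def build_design_matrix(table: pd.DataFrame, terms,
                        reference_levels: dict | None = None) -> pd.DataFrame:
    """Treatment-coded design matrix with an intercept.

    ``terms`` are column names of ``table`` plus optional interactions
    written "a:b".  Categorical columns are dummy-coded against a
    reference level (the first sorted level unless overridden via
    ``reference_levels``); numeric columns pass through.
    """
    reference_levels = reference_levels or {}
    X = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)

    def expand(term: str) -> pd.DataFrame:
        col = table[term]
        if pd.api.types.is_numeric_dtype(col):
            return pd.DataFrame({term: col.astype(float)})
        return _dummies(col, term, reference_levels.get(term))

    for term in terms:
        if ":" in term:
            a, b = term.split(":", 1)
            A, B = expand(a), expand(b)
            for ca in A.columns:
                for cb in B.columns:
                    X[f"{ca}:{cb}"] = A[ca] * B[cb]
        else:
            for c, v in expand(term).items():
                X[c] = v
    return X


def cell_means_design(groups: pd.Series, baseline,
                      covariates: pd.DataFrame | None = None):
    """Cell-means coding ("~ 0 + group") plus optional covariate columns.

    Returns (X, contrasts) where contrasts maps each non-baseline group
    to the vector testing that group against the baseline group.
    """
    levels = sorted(groups.unique().tolist())
    if baseline not in levels:
        raise ValueError(f"baseline group {baseline!r} not among groups")
    X = pd.DataFrame(
        {f"group[{lv}]": (groups == lv).astype(float) for lv in levels},
        index=groups.index)
    if covariates is not None:
        cov = covariates.loc[groups.index]
        for c in cov.columns:
            X[str(c)] = cov[c].astype(float)
    contrasts = {}
    base_col = X.columns.get_loc(f"group[{baseline}]")
    for lv in levels:
        if lv == baseline:
            continue
        vec = np.zeros(X.shape[1])
        vec[X.columns.get_loc(f"group[{lv}]")] = 1.0
        vec[base_col] = -1.0
        contrasts[str(lv)] = vec
    return X, contrasts


def factorial_design(table: pd.DataFrame,
                     covariates: pd.DataFrame | None = None,
                     reference_levels: dict | None = None):
    """Genotype x treatment design with interaction, plus covariates.

    Returns (X, contrasts) with one unit contrast per non-intercept
    effect column (genotype, treatment, their interaction, covariates).
    """
    X = build_design_matrix(table, ["genotype", "treatment",
                                    "genotype:treatment"], reference_levels)
    if covariates is not None:
        cov = covariates.loc[table.index]
        for c in cov.columns:
            X[str(c)] = cov[c].astype(float)
    contrasts = {}
    for j, col in enumerate(X.columns):
        if col == "Intercept":
            continue
        vec = np.zeros(X.shape[1])
        vec[j] = 1.0
        contrasts[col] = vec
    return X, contrasts
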