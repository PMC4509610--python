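"""Fixed-effect pre-correction of repeated phenotype records.

Contemporary-group effects are removed before the genome scan: raw records
are adjusted for herd-year-season, parity, age-at-calving class and month of
calving by ordinary least squares on the *full* recorded population (not only
genotyped animals, so sparse contemporary groups are still well estimated),
and the OLS residuals of the genotyped animals become the scan response.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "PHENO_COLUMNS",
    "FACTOR_COLUMNS",
    "read_phenotypes",
    "bin_age",
    "fit_fixed_effects",
    "residualize",
]

PHENO_COLUMNS = ["animal", "value", "hys", "parity", "age_class", "month"]
FACTOR_COLUMNS = ["hys", "parity", "age_class", "month"]

_FORMULA = "value ~ C(hys) + C(parity) + C(age_class) + C(month)"


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype CSV with columns animal,value,hys,parity,age_class,month."""
    df = pd.read_csv(path, dtype={c: str for c in ["animal", *FACTOR_COLUMNS]})
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    df["value"] = df["value"].astype(float)
    return df[PHENO_COLUMNS].copy()


def bin_age(age_days: pd.Series, bin_days: int = 365) -> pd.Series:
    """Bin a continuous age-at-calving into yearly (default) factor classes."""
    return (np.floor(age_days / bin_days).astype(int)).astype(str)


def fit_fixed_effects(table: pd.DataFrame):
    """OLS of the trait on all fixed-effect factors, over the full record set.

    Returns a fitted statsmodels results object (level estimates, residual
    variance).  Raises on factors with a single level or on a rank-deficient
    design after reference-level constraints (confounded factors).
    """
    table = _validate(table)
    for col in FACTOR_COLUMNS:
        if table[col].nunique() < 2:
            raise ValueError(
                f"fixed-effect factor {col!r} has fewer than 2 levels"
            )
    model = smf.ols(_FORMULA, data=table)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        rank = {
            col: table[col].nunique() for col in FACTOR_COLUMNS
        }
        raise ValueError(
            "fixed-effect design is rank deficient after constraints; "
            f"check for confounded factors (levels: {rank})"
        )
    return model.fit()


def residualize(
    table: pd.DataFrame,
    model,
    genotyped_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Residual (observed - fitted) per record, restricted to genotyped animals.

    ``model`` must have been fitted on a superset of the factor levels in
    ``table``; an unseen level is a hard error.  Records of animals without
    genotypes are discarded when ``genotyped_ids`` is given.
    """
    table = _validate(table)
    if genotyped_ids is not None:
        table = table[table["animal"].isin(set(genotyped_ids))].copy()
    try:
        fitted = model.predict(table)
    except Exception as exc:  # patsy raises on unseen factor levels
        raise ValueError(
            f"phenotype table contains factor levels unseen at fit time: {exc}"
        ) from exc
    if fitted.isna().any():
        bad = table.loc[fitted.isna()].iloc[0]
        raise ValueError(
            f"could not predict record for animal {bad['animal']!r} "
            "(unseen factor level?)"
        )
    out = pd.DataFrame(
        {
            "animal": table["animal"].to_numpy(),
            "record_index": np.arange(len(table)),
            "residual": table["value"].to_numpy() - fitted.to_numpy(),
        }
    )
    return out


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENO_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    table = table.copy()
    for col in ["animal", *FACTOR_COLUMNS]:
        table[col] = table[col].astype(str)
    if table[PHENO_COLUMNS].isna().any().any():
        raise ValueError("phenotype table contains missing entries")
    return table
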