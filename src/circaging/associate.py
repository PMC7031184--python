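"""Inferential layers: qPCR normalization and the association models.

qPCR relative expression is global-mean normalized: technical replicates
are collapsed by median Ct, each sample's Cts are referenced to the
arithmetic mean Ct across assays (the geometric mean on the 2^-Ct
expression scale), expression is 2^-dCt, and each assay is finally
divided by its geometric mean across samples so that every assay has a
per-assay geometric mean of exactly 1.

Association models are ordinary least squares with listwise deletion.
Model orientation is configurable per outcome: for age and parental
longevity score the expression is the dependent variable; for grip
strength the phenotype is the dependent variable.  Significance against
multiplicity uses the unrounded Bonferroni threshold alpha / n_tests;
`bonferroni_threshold` additionally reports the rounded (half-up)
threshold used in text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QPCR_COLUMNS",
    "NormalizedQpcr",
    "AssociationResult",
    "SenescenceResult",
    "normalize_qpcr",
    "fit_phenotype_association",
    "bonferroni_threshold",
    "senescence_compare",
    "count_dysregulated",
    "mouse_lifespan_association",
    "MOUSE_REFERENCE_ASSAYS",
]

QPCR_COLUMNS = ["assay_id", "sample_id", "technical_replicate", "ct"]

#: Endogenous-control assays used for mouse tissue normalization.
MOUSE_REFERENCE_ASSAYS = ("Pol2ra", "Trfc", "Ipo8")

#: Default model orientation per outcome (which side is the dependent
#: variable); recorded in every result row.
DEFAULT_ORIENTATION = {
    "age": "expression_dependent",
    "PLS": "expression_dependent",
    "grip_cross_sectional": "outcome_dependent",
    "grip_longitudinal": "outcome_dependent",
    "lifespan": "expression_dependent",
}


class NormalizedQpcr(NamedTuple):
    expression: pd.DataFrame  # assays x samples relative expression
    dropped_samples: list[str]
    flagged_assays: list[str]


@dataclass(frozen=True)
class AssociationResult:
    circ_id: str
    outcome: str
    stratum: str
    beta: float
    se: float
    p: float
    ci_low: float
    ci_high: float
    n_used: int
    significant_adjusted: bool
    orientation: str = "expression_dependent"
    detected: bool = True


@dataclass(frozen=True)
class SenescenceResult:
    circ_id: str
    cell_type: str
    median_early: float
    median_late: float
    iqr_early: tuple[float, float]
    iqr_late: tuple[float, float]
    p: float
    expressed: bool


def _geomean(values: np.ndarray) -> float:
    values = values[~np.isnan(values)]
    return float(np.exp(np.mean(np.log(values))))


def normalize_qpcr(matrix: pd.DataFrame) -> NormalizedQpcr:
    """Global-mean normalize a long-format Ct matrix.

    ``matrix`` needs :data:`QPCR_COLUMNS`; "undetermined" wells are NaN
    Cts (never Ct=50).  Samples with no Ct at all are dropped with a
    warning; assays missing in more than half of the retained samples are
    flagged (but kept).  Returns relative expression with assays as rows
    and samples as columns; the geometric mean of each assay across its
    non-missing samples is 1.
    """
    missing_cols = [c for c in QPCR_COLUMNS if c not in matrix.columns]
    if missing_cols:
        raise ValueError(f"qPCR matrix missing columns: {missing_cols}")
    ct = matrix["ct"]
    if ((ct <= 0) | (ct > 50)).any():
        raise ValueError("Ct values must lie in (0, 50] or be missing")

    # (1) collapse technical replicates by median
    collapsed = (
        matrix.groupby(["assay_id", "sample_id"])["ct"].median().unstack("sample_id")
    )
    if collapsed.shape[0] < 2 or collapsed.shape[1] < 2:
        raise ValueError("need at least 2 assays and 2 samples")

    dropped = [s for s in collapsed.columns if collapsed[s].isna().all()]
    if dropped:
        warnings.warn(f"dropping sample(s) with no Ct data: {dropped}")
        collapsed = collapsed.drop(columns=dropped)
    if collapsed.shape[1] < 2:
        raise ValueError("fewer than 2 samples with data after dropping")

    # (2) delta Ct against the per-sample mean across assays
    dct = collapsed - collapsed.mean(axis=0, skipna=True)
    # (3) expression scale
    expr = np.power(2.0, -dct)
    # (4) per-assay global (geometric) mean scaling
    scale = expr.apply(lambda row: _geomean(row.values), axis=1)
    expr = expr.div(scale, axis=0)

    frac_missing = expr.isna().mean(axis=1)
    flagged = sorted(frac_missing[frac_missing > 0.5].index)
    return NormalizedQpcr(expression=expr, dropped_samples=dropped, flagged_assays=flagged)


def bonferroni_threshold(
    alpha: float, n_tests: int, decimals: int | None = None
) -> float:
    """Bonferroni significance threshold alpha / n_tests.

    ``decimals`` rounds half-up for reporting (e.g. 0.05/4 -> 0.013);
    significance flagging elsewhere always uses the unrounded value.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    threshold = alpha / n_tests
    if decimals is None:
        return threshold
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(threshold)).quantize(quantum, rounding=ROUND_HALF_UP))


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns from near-zero R diagonal of a pivoted QR
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        tol = max(arr.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
        bad = [X.columns[i] for i in range(min(len(diag), X.shape[1])) if diag[i] <= tol]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_phenotype_association(
    expression: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    circ_id: str = "circ",
    outcome_name: str = "PLS",
    orientation: str | None = None,
    stratum: str = "all",
    alpha: float = 0.05,
    n_tests: int = 1,
) -> AssociationResult:
    """OLS association between one circRNA's expression and a phenotype.

    Listwise deletion over expression, outcome and covariates; two-sided
    p from the t distribution with residual df; 95% CI.  ``orientation``
    defaults per outcome via :data:`DEFAULT_ORIENTATION`.
    """
    import statsmodels.api as sm

    if orientation is None:
        orientation = DEFAULT_ORIENTATION.get(outcome_name, "expression_dependent")
    if orientation not in ("expression_dependent", "outcome_dependent"):
        raise ValueError(f"unknown orientation {orientation!r}")

    frame = pd.concat(
        [expression.rename("_expr"), outcome.rename("_outcome"), covariates], axis=1
    ).dropna()
    if orientation == "expression_dependent":
        y = frame["_expr"]
        exposure = "_outcome"
    else:
        y = frame["_outcome"]
        exposure = "_expr"
    X = frame[[exposure] + list(covariates.columns)]
    n_used = len(frame)
    n_params = X.shape[1] + 1
    if n_used <= n_params + 1:
        raise ValueError(
            f"only {n_used} complete cases for {n_params} parameters"
        )
    X = sm.add_constant(X, has_constant="add")
    _check_rank(X)
    fit = sm.OLS(y.to_numpy(dtype=float), X.to_numpy(dtype=float)).fit()
    idx = list(X.columns).index(exposure)
    beta = float(fit.params[idx])
    se = float(fit.bse[idx])
    p = float(fit.pvalues[idx])
    ci = fit.conf_int(alpha=0.05)
    ci_low, ci_high = float(ci[idx][0]), float(ci[idx][1])
    return AssociationResult(
        circ_id=circ_id,
        outcome=outcome_name,
        stratum=stratum,
        beta=beta,
        se=se,
        p=p,
        ci_low=ci_low,
        ci_high=ci_high,
        n_used=n_used,
        significant_adjusted=bool(p < alpha / n_tests),
        orientation=orientation,
    )


def _two_group_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p, with the degenerate cases pinned down.

    Zero between-group variance gives F=0, p=1 (even when the within-
    group variance is also zero); zero within-group variance with a real
    group difference gives p=0.
    """
    k = len(groups)
    all_vals = np.concatenate(groups)
    n = all_vals.size
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    scale = float(np.sum(all_vals**2)) + 1e-300
    if ssb <= 0 or ssb < 1e-24 * scale:
        return 0.0, 1.0
    if ssw == 0:
        return float("inf"), 0.0
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p


def senescence_compare(
    matrix: pd.DataFrame,
    cell_type: str | None = None,
    early_label: str = "early",
    late_label: str = "late",
) -> list[SenescenceResult]:
    """Early- vs late-passage comparison for one cell type.

    ``matrix`` is long format with columns assay_id, passage,
    biological_replicate, technical_replicate, ct (optionally cell_type,
    used when ``cell_type`` is given).  Normalization runs across all
    samples of the cell type; each assay is then tested by one-way ANOVA
    (two groups) on the per-biological-replicate normalized expression.
    Assays with a passage group entirely missing are reported
    ``expressed=False`` and not tested.
    """
    sub = matrix
    if cell_type is not None:
        sub = matrix[matrix["cell_type"] == cell_type]
        if sub.empty:
            raise KeyError(f"cell type {cell_type!r} not in matrix")
    sub = sub.copy()
    sub["sample_id"] = (
        sub["passage"].astype(str) + "_b" + sub["biological_replicate"].astype(str)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-missing sample drops are expected here
        normalized = normalize_qpcr(sub[QPCR_COLUMNS])
    expr = normalized.expression

    sample_passage = (
        sub.drop_duplicates("sample_id").set_index("sample_id")["passage"].to_dict()
    )
    results = []
    for assay in expr.index:
        row = expr.loc[assay]
        early = row[[s for s in row.index if sample_passage[s] == early_label]].dropna()
        late = row[[s for s in row.index if sample_passage[s] == late_label]].dropna()
        expressed = len(early) > 0 and len(late) > 0

        def _summary(vals: pd.Series) -> tuple[float, tuple[float, float]]:
            if len(vals) == 0:
                return float("nan"), (float("nan"), float("nan"))
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            return float(med), (float(q1), float(q3))

        med_e, iqr_e = _summary(early)
        med_l, iqr_l = _summary(late)
        if expressed and len(early) >= 2 and len(late) >= 2:
            _, p = _two_group_anova([early.to_numpy(), late.to_numpy()])
        else:
            p = float("nan")
        results.append(
            SenescenceResult(
                circ_id=assay,
                cell_type=cell_type if cell_type is not None else "all",
                median_early=med_e,
                median_late=med_l,
                iqr_early=iqr_e,
                iqr_late=iqr_l,
                p=p,
                expressed=expressed,
            )
        )
    return results


def count_dysregulated(
    results: pd.DataFrame | Iterable[SenescenceResult], alpha: float = 0.05
) -> tuple[int, int, int]:
    """Count circRNAs dysregulated in at least one cell type.

    Accepts a DataFrame with columns circ_id, cell_type, p, expressed, or
    an iterable of :class:`SenescenceResult`.  Returns
    ``(n_dysregulated, n_expressed, percent)`` where percent is rounded
    half-up to a whole number.  Distinct-count semantics: a circRNA
    significant in several cell types counts once; duplicate rows and
    cell-type order do not matter.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(
            [
                {
                    "circ_id": r.circ_id,
                    "cell_type": r.cell_type,
                    "p": r.p,
                    "expressed": r.expressed,
                }
                for r in results
            ]
        )
    if results.empty:
        raise ValueError("no senescence results supplied")
    results = results.drop_duplicates(subset=["circ_id", "cell_type"])
    expressed_ids = set(results.loc[results["expressed"].astype(bool), "circ_id"])
    sig = results[
        results["expressed"].astype(bool) & (results["p"] < alpha)
    ]
    dysregulated_ids = set(sig["circ_id"]) & expressed_ids
    n_expressed = len(expressed_ids)
    n_dys = len(dysregulated_ids)
    if n_expressed == 0:
        return 0, 0, 0
    percent = int(
        Decimal(repr(100.0 * n_dys / n_expressed)).quantize(
            Decimal(1), rounding=ROUND_HALF_UP
        )
    )
    return n_dys, n_expressed, percent


def _normalize_mouse(
    panel: pd.DataFrame, tissue: str, reference_assays: Sequence[str]
) -> pd.DataFrame:
    """Reference-gene + global-mean normalization for one tissue.

    Technical replicates are collapsed by median; each animal's circRNA
    Ct is referenced to the arithmetic mean Ct of the reference assays
    (geometric mean on the expression scale); expression = 2^-dCt is then
    divided by the per-circRNA geometric mean across all animals of the
    tissue.  Returns a long frame (animal-level) of normalized
    expression with strain, lifespan and age_group carried along.
    """
    sub = panel[panel["tissue"] == tissue]
    if sub.empty:
        raise KeyError(f"tissue {tissue!r} not in panel")
    collapsed = (
        sub.groupby(["animal_id", "assay_id"])["ct"].median().unstack("assay_id")
    )
    refs = [a for a in reference_assays if a in collapsed.columns]
    if not refs:
        raise ValueError(f"no reference assays {reference_assays} in panel")
    ref_mean = collapsed[refs].mean(axis=1)
    meta = sub.drop_duplicates("animal_id").set_index("animal_id")[
        ["strain", "median_lifespan_months", "age_group"]
    ]
    records = []
    circ_assays = [a for a in collapsed.columns if a not in refs]
    for assay in circ_assays:
        dct = collapsed[assay] - ref_mean
        expr = np.power(2.0, -dct)
        valid = expr.dropna()
        if len(valid) > 0:
            expr = expr / _geomean(valid.to_numpy())
        for animal, value in expr.items():
            records.append(
                {
                    "assay_id": assay,
                    "animal_id": animal,
                    "expression": value,
                    "strain": meta.loc[animal, "strain"],
                    "median_lifespan_months": meta.loc[animal, "median_lifespan_months"],
                    "age_group": meta.loc[animal, "age_group"],
                }
            )
    return pd.DataFrame(records)


def mouse_lifespan_association(
    panel: pd.DataFrame,
    tissue: str,
    stratum: str = "all",
    reference_assays: Sequence[str] = MOUSE_REFERENCE_ASSAYS,
    alpha: float = 0.05,
    n_tests: int = 1,
) -> list[AssociationResult]:
    """Regress normalized mouse circRNA expression on median strain lifespan.

    ``panel`` is long format with columns strain, median_lifespan_months,
    age_group ('young'/'old'), tissue, animal_id, assay_id,
    technical_replicate, ct.  ``stratum`` is 'all', 'young' or 'old'.
    circRNAs with no detectable Ct in the tissue are reported with
    ``detected=False`` (the ND convention).
    """
    import statsmodels.api as sm

    if stratum not in ("all", "young", "old"):
        raise ValueError(f"unknown stratum {stratum!r}")
    normalized = _normalize_mouse(panel, tissue, reference_assays)
    results = []
    for assay in sorted(normalized["assay_id"].unique()):
        rows = normalized[normalized["assay_id"] == assay]
        if stratum != "all":
            rows = rows[rows["age_group"] == stratum]
        rows = rows.dropna(subset=["expression"])
        if rows.empty:
            results.append(
                AssociationResult(
                    circ_id=assay,
                    outcome="lifespan",
                    stratum=stratum,
                    beta=float("nan"),
                    se=float("nan"),
                    p=float("nan"),
                    ci_low=float("nan"),
                    ci_high=float("nan"),
                    n_used=0,
                    significant_adjusted=False,
                    detected=False,
                )
            )
            continue
        if rows["strain"].nunique() < 3:
            raise ValueError(
                f"assay {assay!r}: fewer than 3 distinct strains in stratum {stratum!r}"
            )
        if rows["median_lifespan_months"].nunique() < 2:
            raise ValueError("fewer than 2 distinct lifespan values")
        X = sm.add_constant(rows["median_lifespan_months"].to_numpy(dtype=float))
        fit = sm.OLS(rows["expression"].to_numpy(dtype=float), X).fit()
        ci = fit.conf_int(alpha=0.05)
        results.append(
            AssociationResult(
                circ_id=assay,
                outcome="lifespan",
                stratum=stratum,
                beta=float(fit.params[1]),
                se=float(fit.bse[1]),
                p=float(fit.pvalues[1]),
                ci_low=float(ci[1][0]),
                ci_high=float(ci[1][1]),
                n_used=len(rows),
                significant_adjusted=bool(fit.pvalues[1] < alpha / n_tests),
                orientation="expression_dependent",
            )
        )
    return results


def association_results_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Tabulate AssociationResult rows (beta, p, 95% CI, ND markers)."""
    rows = []
    for r in results:
        rows.append(
            {
                "circ_id": r.circ_id,
                "outcome": r.outcome,
                "stratum": r.stratum,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_used": r.n_used,
                "significant_adjusted": r.significant_adjusted,
                "orientation": r.orientation,
                "detected": r.detected,
            }
        )
    frame = pd.DataFrame(rows)
    return frame
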