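"""Selection-frequency and relative-expression statistics.

Two computations close the pipeline: (1) the mutant-selection
(transposition) frequency — mutant colonies over total CFU — with a
Wilson score 95% confidence interval, and (2) qPCR relative expression
by the Livak 2^-ddCt method: per-replicate dCt = Ct(target) -
Ct(reference), ddCt = mean dCt(condition) - mean dCt(control), fold
change = 2^-ddCt, with a two-sided two-sample t-test (Welch by
default) on the replicate dCt values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .transposition_sim import CountData

__all__ = [
    "FrequencyEstimate",
    "ExpressionResult",
    "transposition_frequency",
    "relative_expression",
    "stars_for",
]


@dataclass(frozen=True)
class FrequencyEstimate:
    """Point estimate and Wilson 95% CI of a selection frequency."""

    point: float
    ci95: tuple[float, float]
    n_selected: int
    cfu: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (0.0 <= lo <= self.point <= hi <= 1.0):
            raise ValueError("require 0 <= low <= point <= high <= 1")


@dataclass(frozen=True)
class ExpressionResult:
    """2^-ddCt fold change of one gene under one condition."""

    gene: str
    condition: str
    fold_change: float
    p_value: float | None  # None when not testable (single replicate)
    stars: str
    ddct: float = 0.0
    dct_sd: float = float("nan")
    dct_sem: float = float("nan")
    n_replicates: int = 0


def stars_for(p: float | None) -> str:
    """Significance stars at 0.05 / 0.01 / 0.001."""
    if p is None or np.isnan(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def transposition_frequency(data: CountData) -> FrequencyEstimate:
    """Frequency = mutant colonies / CFU, with a Wilson score 95% CI."""
    point = data.n_selected / data.cfu
    lo, hi = proportion_confint(data.n_selected, data.cfu, alpha=0.05, method="wilson")
    lo = min(float(lo), point)
    hi = max(float(hi), point)
    return FrequencyEstimate(point=point, ci95=(lo, hi), n_selected=data.n_selected, cfu=data.cfu)


def relative_expression(
    ct: pd.DataFrame,
    control_condition: str,
    reference_gene: str = "GAPDH",
    equal_var: bool = False,
) -> list[ExpressionResult]:
    """Livak 2^-ddCt fold changes with per-comparison t-tests.

    ``ct`` needs columns gene, condition, replicate, ct; the reference
    gene must be present in every condition, paired with targets by the
    replicate column.  The control condition's fold change is 1.0 by
    definition (its test is against itself and reported ``ns``).  With
    ``equal_var=False`` (default) the Welch t-test is used.  No
    multiple-testing correction is applied; results are
    per-comparison.
    """
    required = {"gene", "condition", "replicate", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    conditions = list(dict.fromkeys(ct["condition"]))
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} not in table")
    ref = ct[ct["gene"] == reference_gene]
    if set(conditions) - set(ref["condition"]):
        raise ValueError(f"reference gene {reference_gene!r} missing in some condition")
    if (ref.groupby("condition")["replicate"].count() < 2).any():
        raise ValueError("reference gene needs >= 2 replicates per condition")
    ref_ct = ref.set_index(["condition", "replicate"])["ct"]

    def dct_values(gene: str, condition: str) -> np.ndarray:
        sub = ct[(ct["gene"] == gene) & (ct["condition"] == condition)]
        vals = []
        for _, row in sub.iterrows():
            key = (condition, row["replicate"])
            if key not in ref_ct.index:
                raise ValueError(
                    f"no reference Ct for replicate {row['replicate']} in {condition}"
                )
            vals.append(row["ct"] - ref_ct.loc[key])
        return np.asarray(vals, dtype=float)

    results = []
    # the reference gene stays in the output as a self-test: its dCt is
    # identically zero, so its fold change must come out exactly 1.0
    genes = list(dict.fromkeys(ct["gene"]))
    for gene in genes:
        dct_control = dct_values(gene, control_condition)
        for cond in conditions:
            dct_cond = dct_values(gene, cond)
            if dct_cond.size == 0:
                continue
            ddct = float(dct_cond.mean() - dct_control.mean())
            fold = float(2.0 ** (-ddct))
            if cond == control_condition:
                fold = 1.0
                p = None
            elif dct_cond.size < 2 or dct_control.size < 2:
                p = None
            else:
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    p = float(
                        sps.ttest_ind(dct_control, dct_cond, equal_var=equal_var).pvalue
                    )
                if np.isnan(p):  # zero-variance degenerate comparison
                    p = None
            results.append(
                ExpressionResult(
                    gene=gene,
                    condition=cond,
                    fold_change=fold,
                    p_value=p,
                    stars=stars_for(p),
                    ddct=ddct,
                    dct_sd=float(dct_cond.std(ddof=1)) if dct_cond.size > 1 else float("nan"),
                    dct_sem=float(dct_cond.std(ddof=1) / np.sqrt(dct_cond.size))
                    if dct_cond.size > 1
                    else float("nan"),
                    n_replicates=int(dct_cond.size),
                )
            )
    return results
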