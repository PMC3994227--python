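"""2x2 association statistics: odds ratios, Woolf CIs, Wald p-values.

The 2x2 table splits individuals into model-positive / model-negative rows
and case / control columns.  The odds ratio is the cross-product
``a*d / (b*c)``; its 95% CI uses the Woolf standard error
``sqrt(1/a + 1/b + 1/c + 1/d)`` on the log scale and the p-value is the
two-sided normal tail of ``ln(OR)/SE``.  When any cell is zero, 1 is added
to *every* cell before computing OR/CI/p (the ``corrected`` flag is set);
the reported risk percentage always comes from the uncorrected counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

from .genotype_data import GenotypeDataset
from .model_space import SNPModel, _match_mask, fitness, is_valid_model

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "model_contingency",
    "odds_ratio_test",
    "single_snp_association",
    "summarize_best_models",
    "Z_975",
]

#: 0.975 normal quantile used for the 95% CI (full precision matters at
#: 3-decimal rounding of wide intervals).
Z_975 = float(norm.ppf(0.975))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = positive cases, b = positive controls,
    c = negative cases, d = negative controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def shifted(self, delta: int) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.a + delta, self.b + delta, self.c + delta, self.d + delta
        )


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool
    risk_pct: float
    table: ContingencyTable2x2

    def rounded(self) -> dict:
        """Report-layer rounding: OR/CI 3 d.p., p 3 d.p., percentages 2 d.p."""
        return {
            "odds_ratio": round(self.odds_ratio, 3),
            "ci_low": round(self.ci_low, 3),
            "ci_high": round(self.ci_high, 3),
            "p_value": round(self.p_value, 3),
            "risk_pct": round(self.risk_pct, 2),
            "corrected": self.corrected,
        }


def model_contingency(dataset: GenotypeDataset, model: SNPModel) -> ContingencyTable2x2:
    """Model-positive vs model-negative split by case/control status."""
    if not is_valid_model(model):
        raise ValueError(f"invalid model (repeated SNP): {model}")
    a = int(_match_mask(model, dataset.case_genotypes).sum())
    b = int(_match_mask(model, dataset.control_genotypes).sum())
    return ContingencyTable2x2(a, b, dataset.n_case - a, dataset.n_control - b)


def odds_ratio_test(table: ContingencyTable2x2) -> AssociationResult:
    """Odds ratio with Woolf 95% CI and two-sided Wald p-value.

    Zero-cell rule: if any cell is 0, add 1 to every cell first and flag
    the result as corrected.  Raises if an entire margin (row or column)
    of the original table is empty, since the OR is then undefined.
    """
    a, b, c, d = table.cells
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError(f"zero margin in table {table.cells}: OR undefined")
    risk_pct = 100.0 * a / (a + b)
    corrected = min(a, b, c, d) == 0
    work = table.shifted(1) if corrected else table
    a, b, c, d = work.cells
    oratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(oratio)
    ci_low = math.exp(log_or - Z_975 * se)
    ci_high = math.exp(log_or + Z_975 * se)
    p_value = 2.0 * norm.sf(abs(log_or) / se)
    return AssociationResult(
        odds_ratio=oratio,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p_value),
        corrected=corrected,
        risk_pct=risk_pct,
        table=table,
    )


def single_snp_association(dataset: GenotypeDataset, snp_index: int) -> pd.DataFrame:
    """Per-genotype association versus the reference genotype (code 1).

    For each non-reference genotype g the 2x2 table is (cases with g,
    controls with g, cases with reference, controls with reference).
    Returns one row per genotype including the reference row (which has no
    test statistics).
    """
    if not 0 <= snp_index < dataset.n_snps:
        raise IndexError(f"snp_index {snp_index} out of range")
    name = dataset.snp_names[snp_index]
    labels = (dataset.genotype_labels or {}).get(name, {})
    case_col = dataset.case_genotypes[:, snp_index]
    ctrl_col = dataset.control_genotypes[:, snp_index]
    ref_case = int((case_col == 1).sum())
    ref_ctrl = int((ctrl_col == 1).sum())
    if ref_case == 0 or ref_ctrl == 0:
        raise ValueError(
            f"reference genotype absent in a group for SNP {name!r}"
        )
    rows = []
    for g in range(1, dataset.n_genotypes + 1):
        n_case = int((case_col == g).sum())
        n_ctrl = int((ctrl_col == g).sum())
        row = {
            "snp": name,
            "genotype_code": g,
            "genotype": labels.get(g, str(g)),
            "case_n": n_case,
            "case_pct": round(100.0 * n_case / dataset.n_case, 2),
            "control_n": n_ctrl,
            "control_pct": round(100.0 * n_ctrl / dataset.n_control, 2),
            "odds_ratio": None,
            "ci_low": None,
            "ci_high": None,
            "p_value": None,
        }
        if g != 1:
            res = odds_ratio_test(
                ContingencyTable2x2(n_case, n_ctrl, ref_case, ref_ctrl)
            )
            row.update(
                odds_ratio=res.odds_ratio,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                p_value=res.p_value,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_best_models(
    dataset: GenotypeDataset, models_by_order: dict[int, SNPModel]
) -> pd.DataFrame:
    """Best-model summary: one model row plus an "Others" row per order.

    Columns mirror a per-order report of model notation, positive counts,
    case percentage among positives, fitness difference (%), odds ratio
    with 95% CI, p-value, and a significance flag at p < 0.05.  Numbers are
    rounded at this layer only (OR/CI/p to 3 d.p., percentages to 2 d.p.).
    """
    rows = []
    for order in sorted(models_by_order):
        model = models_by_order[order]
        if model.order != order:
            raise ValueError(
                f"model {model} has order {model.order}, expected {order}"
            )
        table = model_contingency(dataset, model)
        res = odds_ratio_test(table)
        fit = fitness(model, dataset)
        a, b, c, d = table.cells
        rows.append(
            {
                "order": order,
                "model": model.notation(),
                "case_n": a,
                "control_n": b,
                "cancer_pct": round(100.0 * a / (a + b), 2),
                "difference_pct": fit.percent,
                "odds_ratio": round(res.odds_ratio, 3),
                "ci_low": round(res.ci_low, 3),
                "ci_high": round(res.ci_high, 3),
                "p_value": round(res.p_value, 3),
                "significant": res.p_value < 0.05,
                "corrected": res.corrected,
            }
        )
        rows.append(
            {
                "order": order,
                "model": "Others",
                "case_n": c,
                "control_n": d,
                "cancer_pct": round(100.0 * c / (c + d), 2),
                "difference_pct": None,
                "odds_ratio": None,
                "ci_low": None,
                "ci_high": None,
                "p_value": None,
                "significant": None,
                "corrected": None,
            }
        )
    return pd.DataFrame(rows)
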