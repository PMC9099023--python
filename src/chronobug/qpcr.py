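"""Efficiency-corrected relative quantification of qPCR measurements.

Amplification efficiency E for each primer pair comes from a dilution-series
standard curve: Cq regressed on log10(relative concentration) has slope
``-1/log10(E)`` (a perfectly doubling reaction gives slope -3.3219 and
E = 2).  Relative expression uses the efficiency-corrected ratio

    ratio = E_target^(dCq_target) / E_ref^(dCq_ref)

with dCq = Cq(calibrator) - Cq(sample), referenced to a housekeeping gene
(rp49 in this workflow) and a calibrator sample.  A plain 2^(-ddCq) mode is
available for comparison (it is the special case E_target = E_ref = 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StandardCurve",
    "RelativeExpression",
    "fit_standard_curve",
    "relative_expression",
    "expression_table",
    "timecourse_summary",
]


@dataclass
class StandardCurve:
    gene: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    low_r2_warning: bool

    def predict_cq(self, log10_conc) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(log10_conc, dtype=float)


def fit_standard_curve(log10_dilutions, cq, gene: str = "") -> StandardCurve:
    """Least-squares standard curve of Cq on log10 concentration.

    Raises when fewer than 3 points are given or when the slope comes out
    non-negative (an inverted amplification curve).  ``r_squared`` below
    0.9 sets a warning flag rather than failing.
    """
    x = np.asarray(log10_dilutions, dtype=float)
    y = np.asarray(cq, dtype=float)
    if len(x) < 3:
        raise ValueError("standard curve needs >= 3 dilution points")
    res = sps.linregress(x, y)
    if res.slope >= 0:
        raise ValueError("amplification curve inverted (slope >= 0)")
    eff = 10.0 ** (-1.0 / res.slope)
    if not (1.0 < eff <= 2.2):
        raise ValueError(f"efficiency {eff:.3f} outside sanity bound (1, 2.2]")
    return StandardCurve(
        gene=gene,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(eff),
        low_r2_warning=bool(res.rvalue**2 < 0.9),
    )


@dataclass
class RelativeExpression:
    sample_id: str
    gene: str
    ratio: float
    dcq_target: float
    dcq_ref: float


def relative_expression(
    target_cq: float,
    ref_cq: float,
    calibrator_target_cq: float,
    calibrator_ref_cq: float,
    e_target: float = 2.0,
    e_ref: float = 2.0,
    sample_id: str = "",
    gene: str = "",
) -> RelativeExpression:
    """Efficiency-corrected expression ratio of one sample versus the
    calibrator (ratio 1 for the calibrator itself)."""
    for e in (e_target, e_ref):
        if not (1.0 < e <= 2.2):
            raise ValueError("efficiencies must lie in (1, 2.2]")
    dcq_t = calibrator_target_cq - target_cq
    dcq_r = calibrator_ref_cq - ref_cq
    ratio = e_target**dcq_t / e_ref**dcq_r
    return RelativeExpression(sample_id, gene, float(ratio), float(dcq_t), float(dcq_r))


def expression_table(
    cq_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_sample: str,
    e_target: float = 2.0,
    e_ref: float = 2.0,
) -> pd.DataFrame:
    """Per-sample efficiency-corrected ratios from a long-format Cq table
    (columns sample_id, gene, cq; technical replicates averaged first)."""
    means = (
        cq_table.groupby(["sample_id", "gene"])["cq"].mean().unstack("gene")
    )
    for g in (target_gene, reference_gene):
        if g not in means.columns:
            raise ValueError(f"gene {g!r} missing from Cq table")
    if calibrator_sample not in means.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} missing")
    if means[reference_gene].isna().any():
        missing = means.index[means[reference_gene].isna()].tolist()
        raise ValueError(f"missing reference-gene measurement for {missing}")
    cal_t = means.loc[calibrator_sample, target_gene]
    cal_r = means.loc[calibrator_sample, reference_gene]
    rows = []
    for sample, row in means.iterrows():
        r = relative_expression(
            row[target_gene], row[reference_gene], cal_t, cal_r,
            e_target, e_ref, sample_id=str(sample), gene=target_gene,
        )
        rows.append(
            {"sample_id": sample, "gene": target_gene, "ratio": r.ratio,
             "dcq_target": r.dcq_target, "dcq_ref": r.dcq_ref}
        )
    return pd.DataFrame(rows)


def timecourse_summary(
    expr: pd.DataFrame, by: list[str] = ("zt",), value: str = "ratio"
) -> pd.DataFrame:
    """Mean +- SEM per group cell (e.g. per ZT x genotype).

    Cells with a single replicate report SEM as NaN (flagged undefined);
    empty cells are simply absent from the output, never zero-filled.
    """
    g = expr.groupby(list(by))[value]
    out = g.agg(mean="mean", n="count", sd=lambda v: v.std(ddof=1)).reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "sem"] = math.nan
    return out.drop(columns="sd")
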