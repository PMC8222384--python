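"""Deterministic calculators for qPCR-based validation readouts.

ChIP-qPCR enrichment is expressed as percent of input with the fixed
1%-input correction (log2(100) = 6.64 cycles); relative expression uses
the delta-Ct method with a housekeeping gene and a Welch two-sided
t-test between groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

INPUT_CORRECTION_CT = 6.64  # log2(100): the input aliquot was 1% of the sample


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    group: str
    ct_target: float
    ct_reference: float  # housekeeping Ct (expression) or input Ct (ChIP)

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"Ct values must be positive finite, got {v}")


def chip_percent_input(ct_input: float, ct_sample: float) -> float:
    """ChIP enrichment as percent of input.

    100 * 2^(Ct_input - 6.64 - Ct_sample); the 6.64-cycle offset undoes
    the 100-fold dilution of the 1% input aliquot.  Strictly increasing
    in Ct_input and strictly decreasing in Ct_sample.
    """
    if not (math.isfinite(ct_input) and math.isfinite(ct_sample)):
        raise ValueError("Ct values must be finite")
    return 100.0 * 2.0 ** (ct_input - INPUT_CORRECTION_CT - ct_sample)


def delta_ct_expression(
    measurements: list[QpcrMeasurement],
    group1: str,
    group2: str,
) -> dict:
    """Relative expression by the delta-Ct method with a group test.

    Per sample: dCt = Ct_target - Ct_housekeeping, relative expression
    2^-dCt.  Reports per-group means +/- SEM of relative expression,
    the group2/group1 fold change of means, and the Welch (unequal
    variance) two-sided t-test p-value on the dCt values.
    """
    rows = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in measurements],
            "group": [m.group for m in measurements],
            "delta_ct": [m.ct_target - m.ct_reference for m in measurements],
        }
    )
    rows["rel_expr"] = 2.0 ** (-rows["delta_ct"])
    out: dict = {"per_sample": rows}
    stats_by_group = {}
    for g in (group1, group2):
        sub = rows[rows["group"] == g]["rel_expr"]
        if sub.empty:
            raise ValueError(f"no measurements in group {g!r}")
        stats_by_group[g] = {
            "n": int(len(sub)),
            "mean": float(sub.mean()),
            "sem": float(sub.sem()) if len(sub) > 1 else float("nan"),
        }
    out["groups"] = stats_by_group
    d1 = rows[rows["group"] == group1]["delta_ct"]
    d2 = rows[rows["group"] == group2]["delta_ct"]
    out["fold_change"] = float(2.0 ** (d1.mean() - d2.mean()))
    if len(d1) > 1 and len(d2) > 1:
        if d1.var() == 0 and d2.var() == 0:
            # degenerate zero-variance case: equal means are maximally
            # consistent with the null, unequal means are not
            equal = d1.mean() == d2.mean()
            out["t_statistic"] = 0.0 if equal else float("inf")
            out["pvalue"] = 1.0 if equal else 0.0
        else:
            t, p = stats.ttest_ind(d1, d2, equal_var=False)
            out["t_statistic"], out["pvalue"] = float(t), float(p)
    else:
        out["t_statistic"], out["pvalue"] = float("nan"), float("nan")
    return out


def read_qpcr_csv(path, ct_target_col="Ct_target", ct_reference_col="Ct_reference"):
    """CSV with columns sample, group, Ct_target, Ct_reference."""
    df = pd.read_csv(path)
    required = {"sample", "group", ct_target_col, ct_reference_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        QpcrMeasurement(
            sample_id=str(r["sample"]),
            group=str(r["group"]),
            ct_target=float(r[ct_target_col]),
            ct_reference=float(r[ct_reference_col]),
        )
        for _, r in df.iterrows()
    ]
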