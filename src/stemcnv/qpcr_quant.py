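"""qPCR quantification: replicate aggregation, the 2^-ddCt method, and
TaqMan-style copy-number estimation.

dCt = Ct_target - Ct_reference within a sample; ddCt = dCt_case - dCt_ctrl;
relative quantity RQ = 2^-ddCt (amplification efficiency fixed at 2).  Copy
number is RQ times the calibrator copy number (diploid 2 by default).
ddCt is invariant to a constant machine offset added to every Ct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "aggregate_replicates",
    "ddct",
    "copy_number",
    "analyze_ct_table",
    "DdctResult",
]


def aggregate_replicates(ct_values: Sequence[float]) -> Tuple[float, Optional[float]]:
    """Mean and SEM (sd/sqrt(n), ddof=1) of replicate Ct values.

    A single replicate has an undefined SEM, reported as None.
    """
    arr = np.asarray(list(ct_values), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicates")
    if not np.isfinite(arr).all():
        raise ValueError("Ct values must be finite")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else None
    return mean, sem


@dataclass
class DdctResult:
    dct_case: float
    dct_ctrl: float
    ddct: float
    rq: float
    sem: Optional[float] = None  # replicate-propagated


def ddct(
    target_case: Sequence[float],
    ref_case: Sequence[float],
    target_ctrl: Sequence[float],
    ref_ctrl: Sequence[float],
) -> DdctResult:
    """Relative quantity of the case sample vs the control by 2^-ddCt.

    Each argument is the replicate Ct vector of one (sample, assay) well
    group; missing arms are errors.  The propagated SEM combines the four
    replicate SEMs in quadrature (on the Ct scale).
    """
    parts = []
    for name, vals in (
        ("target_case", target_case),
        ("ref_case", ref_case),
        ("target_ctrl", target_ctrl),
        ("ref_ctrl", ref_ctrl),
    ):
        if vals is None or len(list(vals)) == 0:
            raise ValueError(f"missing arm: {name}")
        parts.append(aggregate_replicates(vals))
    (m_tc, s_tc), (m_rc, s_rc), (m_tt, s_tt), (m_rt, s_rt) = parts
    dct_case = m_tc - m_rc
    dct_ctrl = m_tt - m_rt
    dd = dct_case - dct_ctrl
    sems = [s for s in (s_tc, s_rc, s_tt, s_rt)]
    sem = (
        float(np.sqrt(sum(s**2 for s in sems))) if all(s is not None for s in sems) else None
    )
    return DdctResult(
        dct_case=dct_case, dct_ctrl=dct_ctrl, ddct=dd, rq=float(2.0 ** (-dd)), sem=sem
    )


def copy_number(rq: float, reference_cn: float = 2.0) -> float:
    """Estimated copies = calibrator copy number x RQ."""
    if rq <= 0:
        raise ValueError("RQ must be positive")
    return float(reference_cn * rq)


def analyze_ct_table(
    ct: pd.DataFrame, reference_cn: float = 2.0
) -> pd.DataFrame:
    """Run the ddCt workflow on a long Ct table.

    Expected columns: sample, group (control|case), assay, role
    (target|reference), context (copy_number|expression), replicate, ct.
    Every case sample is quantified against the control sample of the same
    context using the context's reference assay.  Returns one row per
    (context, case sample, target assay) with ddct, RQ, log2 fold change,
    propagated SEM, and estimated copy number (copy_number context only).
    """
    required = {"sample", "group", "assay", "role", "context", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    rows = []
    for context, sub in ct.groupby("context"):
        refs = sub[sub["role"] == "reference"]
        if refs.empty:
            raise ValueError(f"context {context!r} has no reference assay")
        ctrl = sub[sub["group"] == "control"]
        case = sub[sub["group"] == "case"]
        if ctrl.empty or case.empty:
            raise ValueError(f"context {context!r} missing a group")
        ctrl_sample = sorted(ctrl["sample"].unique())[0]
        for case_sample in sorted(case["sample"].unique()):
            for assay in sorted(case[case["role"] == "target"]["assay"].unique()):
                def cts(frame, sample, a):
                    vals = frame[(frame["sample"] == sample) & (frame["assay"] == a)]["ct"]
                    return list(vals)

                ref_assay = sorted(refs["assay"].unique())[0]
                res = ddct(
                    cts(case, case_sample, assay),
                    cts(case, case_sample, ref_assay),
                    cts(ctrl, ctrl_sample, assay),
                    cts(ctrl, ctrl_sample, ref_assay),
                )
                row = {
                    "context": context,
                    "sample": case_sample,
                    "assay": assay,
                    "ddct": res.ddct,
                    "rq": res.rq,
                    "log2fc": -res.ddct,
                    "sem": res.sem,
                }
                if context == "copy_number":
                    row["copy_number"] = copy_number(res.rq, reference_cn)
                rows.append(row)
    return pd.DataFrame(rows)
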