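"""Relative quantification by the 2^-ΔΔCt method and qPCR/RNA-seq concordance.

Technical replicates are averaged to one Ct per biological replicate before
any subtraction; ΔCt is taken against the reference gene within the same
(condition, biological replicate); ΔΔCt is the difference of condition-mean
ΔCt against the calibrator condition.  RQ = 2^-ΔΔCt, so the calibrator's RQ
is exactly 1, a constant plate offset cancels, and RQ(a→b)·RQ(b→a) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CtPanel:
    """Long-format Ct table.

    ``data`` columns: transcript, condition, bio_rep, tech_rep, ct.
    ``reference`` is the internal-control transcript (e.g. tubulin);
    ``calibrator`` is the condition all RQs are relative to.
    """

    data: pd.DataFrame
    reference: str
    calibrator: str

    def validate(self) -> None:
        required = {"transcript", "condition", "bio_rep", "tech_rep", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct panel missing columns {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if self.calibrator not in set(self.data["condition"]):
            raise ValueError(f"calibrator condition {self.calibrator!r} has no data")
        ref = self.data[self.data["transcript"] == self.reference]
        groups = set(zip(self.data["condition"], self.data["bio_rep"]))
        ref_groups = set(zip(ref["condition"], ref["bio_rep"]))
        if groups - ref_groups:
            missing_in = sorted(groups - ref_groups)[0]
            raise ValueError(
                f"reference {self.reference} missing in condition/replicate {missing_in}"
            )


def relative_quantity(panel: CtPanel) -> pd.DataFrame:
    """Per-transcript, per-condition RQ = 2^-ΔΔCt with per-replicate RQs.

    Returns a frame with columns transcript, condition, delta_ct_mean,
    ddct, rq, rq_replicates (list of per-biological-replicate RQs).
    """
    panel.validate()
    df = panel.data
    # average technical replicates -> one Ct per (transcript, condition, bio_rep)
    ct = (
        df.groupby(["transcript", "condition", "bio_rep"])["ct"].mean().rename("ct")
    ).reset_index()
    ref = ct[ct["transcript"] == panel.reference].rename(columns={"ct": "ct_ref"})
    merged = ct.merge(
        ref[["condition", "bio_rep", "ct_ref"]], on=["condition", "bio_rep"], how="left"
    )
    if merged["ct_ref"].isna().any():
        raise ValueError("missing reference Ct for some condition/replicate")
    merged["delta_ct"] = merged["ct"] - merged["ct_ref"]

    rows = []
    for transcript, sub in merged.groupby("transcript"):
        calib = sub[sub["condition"] == panel.calibrator]
        if calib.empty:
            raise ValueError(f"transcript {transcript} has no calibrator data")
        calib_mean = calib["delta_ct"].mean()
        for condition, csub in sub.groupby("condition"):
            ddct = csub["delta_ct"].mean() - calib_mean
            rq_reps = 2.0 ** -(csub["delta_ct"] - calib_mean)
            rows.append(
                {
                    "transcript": transcript,
                    "condition": condition,
                    "delta_ct_mean": csub["delta_ct"].mean(),
                    "ddct": ddct,
                    "rq": 2.0**-ddct,
                    "rq_replicates": list(np.round(rq_reps, 6)),
                }
            )
    return pd.DataFrame(rows).sort_values(["transcript", "condition"]).reset_index(drop=True)


def qpcr_log2_fold_changes(rq: pd.DataFrame, condition: str) -> pd.Series:
    """log2 RQ of the given condition per transcript (calibrator-relative)."""
    sub = rq[rq["condition"] == condition]
    return pd.Series(
        np.log2(sub["rq"].to_numpy()), index=sub["transcript"].to_numpy()
    ).sort_index()


def concordance(
    qpcr_log2fc: pd.Series, seq_log2fc: pd.Series
) -> tuple[float, float, float]:
    """OLS of qPCR log2 fold changes on sequencing log2 fold changes.

    Returns (slope, intercept, r_squared) over the paired transcripts.
    """
    common = qpcr_log2fc.index.intersection(seq_log2fc.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired fold changes")
    x = seq_log2fc.loc[common].to_numpy(dtype=float)
    y = qpcr_log2fc.loc[common].to_numpy(dtype=float)
    if np.allclose(x.var(), 0):
        raise ValueError("zero variance in sequencing fold changes")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
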