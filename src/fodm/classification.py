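"""IDR taxonomy built on the (RD_unit, RD_IDR) plane and the K ranges.

A disordered region is compared with its structural unit through two
micelle-likeness readouts.  The RD = 0.5 cut-off splits the unit square
into four quadrants:

  Group 1 (FOD-ordered):   both RD < 0.5 — core in both unit and IDR.
  Group 2 (FOD-unordered): both RD >= 0.5 — no core in either.
  Group 3 (FOD-unordered): unit < 0.5 <= IDR — ordered unit, disordered IDR.
  Group 4 (FOD-ordered):   IDR < 0.5 <= unit — ordered IDR in a
                           disordered unit.

The FOD-ordered/unordered flag follows the IDR's own RD.  The
environment coefficient K is binned into low (K <= 0.5, aqueous
micelle-like), mid (0.5 < K < 1.5, partially modified environment) and
high (K >= 1.5, strong external field, e.g. membrane), giving a 3x3
segmentation of cohorts.  Cohort-level structure is summarised by
splitting the scatter about the identity line RD_IDR = RD_unit and
fitting ordinary least-squares regression lines, with a deterministic
largest-residual elimination standing in for by-eye outlier removal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats

__all__ = [
    "GroupLabel",
    "CohortRow",
    "RegressionReport",
    "classify_group",
    "segment_by_k",
    "split_upper_lower",
    "fit_regression",
    "eliminate_to_target",
    "k_segmentation_matrix",
    "cohort_report",
]

K_LOW_MAX = 0.5   # K <= 0.5 is "low" (boundary included, as tabulated)
K_HIGH_MIN = 1.5  # K >= 1.5 is "high" (boundary included)


@dataclass(frozen=True)
class GroupLabel:
    group: int                       # 1..4
    fod_status: str                  # "FOD-ordered" | "FOD-unordered"
    k_cell: Optional[tuple[str, str]] = None  # (unit bin, IDR bin)

    def __post_init__(self):
        ordered = self.group in (1, 4)
        if ordered != (self.fod_status == "FOD-ordered"):
            raise ValueError(
                f"group {self.group} inconsistent with {self.fod_status}"
            )


@dataclass
class CohortRow:
    protein_id: str
    rd_unit: float
    rd_idr: float
    k_unit: float
    k_idr: float
    has_ss_bonds: bool = False

    def __post_init__(self):
        for name in ("rd_unit", "rd_idr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.k_unit < 0 or self.k_idr < 0:
            raise ValueError("K values must be nonnegative")


@dataclass
class RegressionReport:
    slope: float
    intercept: float
    pearson_r: float
    retained: list[str]
    eliminated: list[str] = field(default_factory=list)
    reached: bool = True

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "n_retained": len(self.retained),
            "retained": self.retained,
            "eliminated": self.eliminated,
            "reached": self.reached,
        }


def classify_group(rd_unit: float, rd_idr: float,
                   cutoff: float = 0.5) -> GroupLabel:
    """Assign the quadrant group and FOD-ordered/unordered flag.

    RD exactly at the cut-off counts as >= (no core): the core criterion
    is strictly RD < cut-off.
    """
    for name, v in (("rd_unit", rd_unit), ("rd_idr", rd_idr)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0,1]")
    unit_core = rd_unit < cutoff
    idr_core = rd_idr < cutoff
    if unit_core and idr_core:
        return GroupLabel(1, "FOD-ordered")
    if not unit_core and not idr_core:
        return GroupLabel(2, "FOD-unordered")
    if unit_core:  # ordered unit, disordered IDR
        return GroupLabel(3, "FOD-unordered")
    return GroupLabel(4, "FOD-ordered")


def _k_bin(k: float) -> str:
    if k < 0:
        raise ValueError(f"negative K: {k}")
    if k <= K_LOW_MAX:
        return "low"
    if k >= K_HIGH_MIN:
        return "high"
    return "mid"


def segment_by_k(k_unit: float, k_idr: float) -> tuple[str, str]:
    """Bin (K_unit, K_IDR) into the 3x3 environment-strength grid.

    low: 0 <= K <= 0.5; mid: 0.5 < K < 1.5; high: K >= 1.5.  Both
    boundaries belong to the outer bins, matching the tabulated ranges.
    """
    return (_k_bin(k_unit), _k_bin(k_idr))


def split_upper_lower(rows: Iterable[CohortRow]
                      ) -> tuple[list[CohortRow], list[CohortRow], list[CohortRow]]:
    """Split about the identity line RD_IDR = RD_unit.

    Returns (upper, lower, ties): upper has RD_IDR > RD_unit (IDR less
    micelle-like than its unit), lower the reverse; exact ties are
    reported separately.
    """
    upper, lower, ties = [], [], []
    for row in rows:
        if row.rd_idr > row.rd_unit:
            upper.append(row)
        elif row.rd_idr < row.rd_unit:
            lower.append(row)
        else:
            ties.append(row)
    return upper, lower, ties


def fit_regression(rows: list[CohortRow]) -> RegressionReport:
    """OLS of RD_IDR on RD_unit with the Pearson correlation."""
    if len(rows) < 2:
        raise ValueError("need at least 2 rows to fit a line")
    x = np.array([r.rd_unit for r in rows])
    y = np.array([r.rd_idr for r in rows])
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all rd_unit values equal")
    res = stats.linregress(x, y)
    return RegressionReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        retained=[r.protein_id for r in rows],
    )


def eliminate_to_target(
    rows: list[CohortRow],
    target_r: float = 0.8,
    max_removed: Optional[int] = None,
) -> RegressionReport:
    """Deterministic stand-in for by-eye outlier removal.

    Repeatedly drops the point with the largest absolute residual from
    the current OLS fit of RD_IDR on RD_unit, recomputing Pearson r,
    until r >= ``target_r`` or ``max_removed`` points are gone (default
    cap: len(rows) - 3, so at least three points survive).  Being
    residual-driven rather than visual, the retained set is reproducible
    but need not match any particular hand-curated selection.
    """
    if not 0.0 < target_r < 1.0:
        raise ValueError("target_r must be in (0, 1)")
    if len(rows) < 3:
        raise ValueError("need at least 3 rows")
    if max_removed is None:
        max_removed = len(rows) - 3
    kept = list(rows)
    eliminated: list[str] = []
    report = fit_regression(kept)
    while report.pearson_r < target_r and len(eliminated) < max_removed \
            and len(kept) > 3:
        x = np.array([r.rd_unit for r in kept])
        y = np.array([r.rd_idr for r in kept])
        resid = np.abs(y - (report.slope * x + report.intercept))
        worst = int(np.argmax(resid))
        eliminated.append(kept.pop(worst).protein_id)
        report = fit_regression(kept)
    report.eliminated = eliminated
    report.reached = report.pearson_r >= target_r
    return report


def k_segmentation_matrix(rows: Iterable[CohortRow]) -> dict:
    """3x3 counts of cohort rows by (unit K bin, IDR K bin).

    Each cell holds the protein count and, in a companion entry, how
    many of those carry disulfide bonds.
    """
    bins = ("low", "mid", "high")
    counts = {u: {i: 0 for i in bins} for u in bins}
    ss = {u: {i: 0 for i in bins} for u in bins}
    for row in rows:
        u, i = segment_by_k(row.k_unit, row.k_idr)
        counts[u][i] += 1
        if row.has_ss_bonds:
            ss[u][i] += 1
    return {"counts": counts, "with_ss_bonds": ss}


def cohort_report(rows: list[CohortRow], cutoff: float = 0.5,
                  target_r: float = 0.8) -> dict:
    """Full cohort summary: groups, K matrix, split and regressions."""
    labels = {}
    for row in rows:
        g = classify_group(row.rd_unit, row.rd_idr, cutoff)
        labels[row.protein_id] = {
            "group": g.group,
            "fod_status": g.fod_status,
            "k_cell": list(segment_by_k(row.k_unit, row.k_idr)),
        }
    upper, lower, ties = split_upper_lower(rows)
    out = {
        "n": len(rows),
        "labels": labels,
        "group_counts": {
            g: sum(1 for v in labels.values() if v["group"] == g)
            for g in (1, 2, 3, 4)
        },
        "k_matrix": k_segmentation_matrix(rows),
        "n_upper": len(upper),
        "n_lower": len(lower),
        "n_ties": len(ties),
    }
    if len(rows) >= 3:
        out["regression_all"] = eliminate_to_target(rows, target_r).to_dict()
    for name, subset in (("upper", upper), ("lower", lower)):
        if len(subset) >= 2 and len({r.rd_unit for r in subset}) > 1:
            out[f"regression_{name}"] = fit_regression(subset).to_dict()
    return out


def report_to_json(report: dict, **kw) -> str:
    return json.dumps(report, indent=2, **kw)
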