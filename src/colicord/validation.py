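"""Bench-side validation computations: ddCt qPCR fold changes, the
modified endoscopic colitis severity score, and animal weight statistics.

ddCt relative quantification normalizes each target-gene Ct to a
housekeeping gene within the same subject/condition (dCt), then to the
control condition within the same subject (ddCt); the per-subject fold
change is 2^(-ddCt).  The headline per-condition fold change is the
arithmetic mean of per-subject fold changes (the geometric variant
2^(-mean ddCt) is reported alongside).  Significance is a two-sided
paired t-test of dCt at the condition vs the control, which is
numerically identical to a one-sample t on the ddCt values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import log2fc_to_signed, student_t_test
from .io_core import ValidationError

__all__ = [
    "CtTable",
    "ddct_fold_change",
    "MeicsScore",
    "meics_total",
    "weight_stats",
    "WeightStats",
]


@dataclass
class CtTable:
    """qPCR Ct values: one row per (subject, condition, gene)."""

    table: pd.DataFrame  # columns subject, condition, gene, ct
    housekeeping: str

    REQUIRED = ("subject", "condition", "gene", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"Ct table missing columns {missing}")
        if (self.table["ct"] <= 0).any():
            raise ValidationError("Ct values must be positive")
        if self.housekeeping not in set(self.table["gene"]):
            raise ValidationError(
                f"housekeeping gene {self.housekeeping!r} absent from table"
            )


@dataclass
class DdctResult:
    """Per-condition relative expression vs the control condition."""

    condition: str
    mean_fc: float  # mean of per-subject 2^(-ddCt)
    geometric_fc: float  # 2^(-mean ddCt)
    signed_fc: float  # display convention of mean_fc
    p: float  # paired t on dCt, condition vs control
    n_subjects: int
    warnings: list[str] = field(default_factory=list)


def ddct_fold_change(
    ct: CtTable, target: str, control_condition: str
) -> dict[str, DdctResult]:
    """Relative expression of ``target`` per condition vs the control.

    Subjects missing the control condition (for either gene) are dropped
    with a warning; a condition with fewer than 2 complete subjects has
    an undefined p-value.
    """
    df = ct.table
    tgt = df[df["gene"] == target].set_index(["subject", "condition"])["ct"]
    hk = df[df["gene"] == ct.housekeeping].set_index(["subject", "condition"])["ct"]
    if tgt.empty:
        raise ValidationError(f"target gene {target!r} absent from table")
    dct = (tgt - hk).dropna()  # per (subject, condition)
    conditions = [c for c in dict.fromkeys(df["condition"]) if c != control_condition]
    results: dict[str, DdctResult] = {}
    for cond in conditions:
        warnings: list[str] = []
        pairs = []
        for subject in dict.fromkeys(df["subject"]):
            has_cond = (subject, cond) in dct.index
            has_ctrl = (subject, control_condition) in dct.index
            if has_cond and has_ctrl:
                pairs.append(
                    (dct.loc[(subject, cond)], dct.loc[(subject, control_condition)])
                )
            elif has_cond and not has_ctrl:
                warnings.append(f"subject {subject!r} missing control; dropped")
        if not pairs:
            continue
        d_cond = np.array([p[0] for p in pairs])
        d_ctrl = np.array([p[1] for p in pairs])
        ddct = d_cond - d_ctrl
        per_subject_fc = 2.0 ** (-ddct)
        mean_fc = float(per_subject_fc.mean())
        geometric_fc = float(2.0 ** (-ddct.mean()))
        if len(pairs) >= 2:
            p = student_t_test(d_cond, d_ctrl, paired=True).p
        else:
            p = math.nan
            warnings.append("fewer than 2 complete subjects; p undefined")
        signed = mean_fc if mean_fc >= 1 else -1.0 / mean_fc
        results[cond] = DdctResult(
            condition=cond,
            mean_fc=mean_fc,
            geometric_fc=geometric_fc,
            signed_fc=float(signed),
            p=float(p),
            n_subjects=len(pairs),
            warnings=warnings,
        )
    return results


@dataclass(frozen=True)
class MeicsScore:
    """Modified endoscopic colitis severity score: four 0-3 subscores
    (colon thickening is not considered), total range 0-12."""

    subscores: tuple[int, int, int, int]
    total: int


def meics_total(subscores) -> MeicsScore:
    subs = tuple(int(s) for s in subscores)
    if len(subs) != 4:
        raise ValidationError("the modified score has exactly four criteria")
    for s in subs:
        if not 0 <= s <= 3:
            raise ValidationError(f"subscore {s} outside the 0-3 range")
    return MeicsScore(subscores=subs, total=sum(subs))


@dataclass(frozen=True)
class WeightStats:
    mean_loss: float  # grams
    percent_loss: float  # one decimal
    p: float  # two-sided paired t


def weight_stats(w_baseline, w_followup) -> WeightStats:
    """Mean weight loss, percent of baseline (one decimal) and paired-t p."""
    a = np.asarray(w_baseline, dtype=float)
    b = np.asarray(w_followup, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("baseline and follow-up weights must pair up")
    if len(a) < 2:
        raise ValidationError("need >= 2 subjects")
    mean_loss = float((a - b).mean())
    percent = round(100.0 * mean_loss / a.mean(), 1)
    p = student_t_test(a, b, paired=True).p
    return WeightStats(mean_loss=mean_loss, percent_loss=percent, p=p)
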