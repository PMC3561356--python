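"""Per-contrast differential expression and time-course gene selection.

Group contrasts use a Student t-test (pooled-variance unpaired by
default, paired within subject by flag) with Benjamini-Hochberg FDR,
and express effect sizes both as log2 fold change and as the signed
linear fold change convention common in the microarray literature
(a ratio r < 1 is displayed as -1/r, so the magnitude is always >= 1).

Time-course selection scores each gene by its maximum moderated paired
t statistic over post-baseline timepoints and converts it to a p-value
by within-subject condition-label permutation.  This is a defined,
seeded stand-in for Bayesian time-course selection tools: the variance
moderation shrinks per-gene variances toward the median gene, which
stabilizes scores at small subject counts, and the permutation null
preserves the paired design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import AnalysisConfig, ExpressionMatrix, SampleDesign, ValidationError

__all__ = [
    "TTestResult",
    "student_t_test",
    "fold_changes",
    "log2fc_to_signed",
    "signed_to_log2fc",
    "bh_fdr",
    "differential_expression",
    "timecourse_select",
    "TimecourseSelection",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def student_t_test(
    group_a: np.ndarray, group_b: np.ndarray, paired: bool = False
) -> TTestResult:
    """Two-sided Student t-test.

    Unpaired uses the pooled-variance statistic with df = n_a + n_b - 2;
    paired is the one-sample t on subject-aligned differences with
    df = n - 1.  Zero-variance inputs are handled explicitly: equal
    means give (t=0, p=1); unequal means give p=0 flagged degenerate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValidationError("paired test requires equal-length groups")
        if len(a) < 2:
            raise ValidationError("paired test requires n >= 2")
        d = a - b
        n = len(d)
        sd = d.std(ddof=1)
        df = n - 1
        if sd == 0:
            if d[0] == 0:
                return TTestResult(t=0.0, df=df, p=1.0)
            return TTestResult(t=math.copysign(math.inf, d[0]), df=df, p=0.0, degenerate=True)
        t = d.mean() / (sd / math.sqrt(n))
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValidationError("unpaired test requires each group n >= 2")
        na, nb = len(a), len(b)
        df = na + nb - 2
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        delta = a.mean() - b.mean()
        if sp2 == 0:
            if delta == 0:
                return TTestResult(t=0.0, df=df, p=1.0)
            return TTestResult(
                t=math.copysign(math.inf, delta), df=df, p=0.0, degenerate=True
            )
        t = delta / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def log2fc_to_signed(log2fc: float | np.ndarray):
    """Map log2 fold change to the signed linear convention (|fc| >= 1)."""
    log2fc = np.asarray(log2fc, dtype=float)
    out = np.where(log2fc >= 0, 2.0**log2fc, -(2.0 ** (-log2fc)))
    return out if out.ndim else float(out)


def signed_to_log2fc(signed_fc: float | np.ndarray):
    """Inverse of :func:`log2fc_to_signed` on its range {x : |x| >= 1}."""
    fc = np.asarray(signed_fc, dtype=float)
    if np.any(np.abs(fc) < 1):
        raise ValidationError("signed fold changes have magnitude >= 1")
    out = np.where(fc >= 0, np.log2(np.abs(fc)), -np.log2(np.abs(fc)))
    return out if out.ndim else float(out)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_changes(
    m: ExpressionMatrix,
    design: SampleDesign,
    cond_a: str,
    cond_b: str,
) -> pd.DataFrame:
    """Per-gene group means and fold changes for cond_a vs cond_b.

    log2fc = mean(cond_a) - mean(cond_b) on the log2 scale.
    """
    if m.scale != "log2":
        raise ValidationError("fold changes are computed on the log2 scale")
    design.validate_against(m)
    cols_a = [s for s in design.samples_for(cond_a) if s in m.values.columns]
    cols_b = [s for s in design.samples_for(cond_b) if s in m.values.columns]
    if not cols_a:
        raise ValidationError(f"condition {cond_a!r} absent from matrix")
    if not cols_b:
        raise ValidationError(f"condition {cond_b!r} absent from matrix")
    mean_a = m.values[cols_a].mean(axis=1)
    mean_b = m.values[cols_b].mean(axis=1)
    log2fc = mean_a - mean_b
    return pd.DataFrame(
        {
            "gene": m.values.index,
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.to_numpy(),
            "log2fc": log2fc.to_numpy(),
            "signed_fc": log2fc_to_signed(log2fc.to_numpy()),
        }
    ).set_index("gene")


def differential_expression(
    m: ExpressionMatrix,
    design: SampleDesign,
    cond_a: str,
    cond_b: str,
    paired: bool = False,
) -> pd.DataFrame:
    """Full per-gene contrast table: means, fold changes, p and q.

    Columns: mean_a, mean_b, log2fc, signed_fc, p, q; attrs carries the
    contrast label "<cond_a>_vs_<cond_b>".
    """
    table = fold_changes(m, design, cond_a, cond_b)
    cols_a = [s for s in design.samples_for(cond_a) if s in m.values.columns]
    cols_b = [s for s in design.samples_for(cond_b) if s in m.values.columns]
    A = m.values[cols_a].to_numpy(dtype=float)
    B = m.values[cols_b].to_numpy(dtype=float)
    if paired:
        sub = design.table.set_index("sample_id")
        subj_a = {sub.loc[s, "subject_id"]: s for s in cols_a}
        subj_b = {sub.loc[s, "subject_id"]: s for s in cols_b}
        shared = [s for s in subj_a if s in subj_b]
        if len(shared) < 2:
            raise ValidationError("paired contrast needs >= 2 complete subjects")
        A = m.values[[subj_a[s] for s in shared]].to_numpy(dtype=float)
        B = m.values[[subj_b[s] for s in shared]].to_numpy(dtype=float)
        p = _vector_paired_t_p(A, B)
    else:
        p = _vector_unpaired_t_p(A, B)
    table["p"] = p
    table["q"] = bh_fdr(p)
    table.attrs["contrast"] = f"{cond_a}_vs_{cond_b}"
    table.attrs["paired"] = paired
    return table


def _vector_unpaired_t_p(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na, nb = A.shape[1], B.shape[1]
    df = na + nb - 2
    sp2 = ((na - 1) * A.var(axis=1, ddof=1) + (nb - 1) * B.var(axis=1, ddof=1)) / df
    delta = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(np.abs(t), df)
    p[(sp2 == 0) & (delta == 0)] = 1.0
    p[(sp2 == 0) & (delta != 0)] = 0.0
    return p


def _vector_paired_t_p(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    D = A - B
    n = D.shape[1]
    sd = D.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = D.mean(axis=1) / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), n - 1)
    zero_mean = D.mean(axis=1) == 0
    p[(sd == 0) & zero_mean] = 1.0
    p[(sd == 0) & ~zero_mean] = 0.0
    return p


@dataclass
class TimecourseSelection:
    """Per-gene time-course scores with permutation p, q and selection flag."""

    table: pd.DataFrame  # index gene; columns score, p, q, selected
    n_permutations: int
    warnings: list[str]

    @property
    def selected_genes(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def timecourse_select(
    m: ExpressionMatrix,
    design: SampleDesign,
    cfg: AnalysisConfig,
    baseline: str = "T0",
    method: str = "parametric",
) -> TimecourseSelection:
    """Select genes with sustained differential expression over time.

    Per gene the score is the maximum over post-baseline timepoints of
    the absolute moderated paired t statistic: the per-timepoint
    difference variance s^2 is shrunk as s*^2 = (d0*s0^2 + d*s^2)/(d0+d)
    with d0 = 3 prior degrees of freedom and s0^2 the median difference
    variance across genes at that timepoint.  A gene is selected when
    its BH-adjusted p-value is <= cfg.tc_alpha.

    With ``method="parametric"`` (default) the p-value is the Bonferroni
    bound over timepoints on the two-sided tail of a t distribution with
    d0 + (n_subjects - 1) degrees of freedom; slightly conservative
    because the per-timepoint statistics share the baseline sample.
    With ``method="permutation"`` the p-value is per-gene within-subject
    permutation of condition labels (seeded), p = (1 + #{permuted score
    >= observed}) / (1 + B).  The permutation null is exact but, at
    small subject counts, permutations that realign a gene's own planted
    signal put a floor under its attainable p (about 4^-n_subjects per
    timepoint pattern), which makes it very low-powered at n = 5; it is
    provided for calibration checks, not as the default.
    """
    if m.scale != "log2":
        raise ValidationError("time-course selection expects a log2 matrix")
    design.validate_against(m)
    conditions = design.conditions()
    if baseline not in conditions:
        raise ValidationError(f"baseline condition {baseline!r} absent from design")
    later = [c for c in conditions if c != baseline]
    if not later:
        raise ValidationError("need at least one post-baseline condition")
    subjects = design.subjects()
    if len(subjects) < 2:
        raise ValidationError("need >= 2 subjects for the paired design")
    warnings: list[str] = []
    B = cfg.tc_permutations
    if B < 100:
        warnings.append(f"only {B} permutations; p-value resolution is coarse")

    # genes x subjects x conditions cube, baseline first; subjects must be
    # complete across all conditions (paired design)
    sub = design.table.set_index(["subject_id", "condition"])["sample_id"]
    order = [baseline] + later
    cols = []
    for s in subjects:
        try:
            cols.append([sub.loc[(s, c)] for c in order])
        except KeyError as exc:
            raise ValidationError(f"subject {s!r} incomplete: missing {exc}") from exc
    X = np.stack(
        [m.values[[c for c in row]].to_numpy(dtype=float) for row in cols], axis=1
    )  # genes x subjects x conditions

    observed = _max_moderated_t(X)
    n_later = len(later)
    if method == "parametric":
        df = 3.0 + (len(subjects) - 1)
        p = np.minimum(1.0, n_later * 2 * stats.t.sf(observed, df))
    elif method == "permutation":
        rng = np.random.default_rng(cfg.rng_seed)
        n_cond = len(order)
        exceed = np.zeros(X.shape[0], dtype=int)
        for _ in range(B):
            perm = np.stack([rng.permutation(n_cond) for _ in subjects])
            Xp = np.take_along_axis(X, perm[None, :, :], axis=2)
            exceed += _max_moderated_t(Xp) >= observed
        p = (1 + exceed) / (1 + B)
    else:
        raise ValidationError(f"unknown timecourse method {method!r}")
    q = bh_fdr(p)
    table = pd.DataFrame(
        {"score": observed, "p": p, "q": q, "selected": q <= cfg.tc_alpha},
        index=m.values.index,
    )
    return TimecourseSelection(table=table, n_permutations=B, warnings=warnings)


def _max_moderated_t(X: np.ndarray, d0: float = 3.0) -> np.ndarray:
    """Max over timepoints of |moderated paired t| for a genes x subjects x
    conditions cube whose first condition is the baseline."""
    n = X.shape[1]
    D = X[:, :, 1:] - X[:, :, :1]  # differences vs baseline
    mean_d = D.mean(axis=1)
    var_d = D.var(axis=1, ddof=1)
    s0 = np.median(var_d, axis=0, keepdims=True)
    d = n - 1
    var_mod = (d0 * s0 + d * var_d) / (d0 + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / np.sqrt(var_mod / n)
    t = np.where(np.isfinite(t), t, 0.0)
    return np.abs(t).max(axis=1)
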