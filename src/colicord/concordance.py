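"""Cross-species concordance of differential expression.

Rat and human contrasts are joined through a 1:1 ortholog map and
compared at two levels:

* gene level — an ortholog pair is *concordant up* when both species
  show log2 fold change >= +threshold with p < the significance level,
  *concordant down* when both are <= -threshold with p < the level, and
  non-concordant otherwise; the overall association is Spearman's rho
  over the fold changes of **all** joined pairs (the scatterplot cloud,
  not just the significant genes);
* pathway level — per pathway the mean log2 fold change of member genes
  present in the contrast (pathways with fewer present members than a
  minimum size are excluded), correlated across species by Spearman's
  rho, with a sign-agreement concordance label per pathway.

Rat fold changes are translated to human gene ids through the ortholog
map before pathway mapping, so both species score identical pathway
memberships.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import AnalysisConfig, GeneSetCollection, OrthologMap, ValidationError

__all__ = [
    "SpearmanResult",
    "spearman",
    "join_orthologs",
    "classify_concordance",
    "ConcordanceSummary",
    "pathway_fold_changes",
    "pathway_concordance",
    "PathwayConcordance",
]

CONCORDANT_UP = "concordant_up"
CONCORDANT_DOWN = "concordant_down"
NONCONCORDANT = "nonconcordant"


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int
    undefined: bool = False


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of average ranks; the two-sided
    p-value uses the t approximation with n - 2 degrees of freedom
    (p = 0 when |rho| = 1).  Fewer than 3 points, or a constant input,
    yield an undefined result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman needs two equal-length 1-D vectors")
    n = len(x)
    if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(rho=math.nan, p=math.nan, n=n, undefined=True)
    rho, p = stats.spearmanr(x, y)
    if abs(rho) == 1.0:
        p = 0.0
    return SpearmanResult(rho=float(rho), p=float(p), n=n)


def join_orthologs(
    rat_de: pd.DataFrame, human_de: pd.DataFrame, omap: OrthologMap
) -> pd.DataFrame:
    """Inner-join two contrast tables through the ortholog map.

    Returns one row per ortholog pair present in both tables, with
    columns rat_gene, human_gene, rat_log2fc, rat_p, human_log2fc,
    human_p.  The join report lives in ``attrs['join_report']``.
    """
    rows = []
    for rat_gene, human_gene in omap.pairs:
        if rat_gene in rat_de.index and human_gene in human_de.index:
            rows.append(
                {
                    "rat_gene": rat_gene,
                    "human_gene": human_gene,
                    "rat_log2fc": float(rat_de.at[rat_gene, "log2fc"]),
                    "rat_p": float(rat_de.at[rat_gene, "p"]),
                    "human_log2fc": float(human_de.at[human_gene, "log2fc"]),
                    "human_p": float(human_de.at[human_gene, "p"]),
                }
            )
    joined = pd.DataFrame(
        rows,
        columns=[
            "rat_gene",
            "human_gene",
            "rat_log2fc",
            "rat_p",
            "human_log2fc",
            "human_p",
        ],
    )
    joined.attrs["join_report"] = {
        "n_map_pairs": len(omap),
        "n_joined": len(joined),
        "n_dropped": len(omap) - len(joined),
    }
    return joined


@dataclass
class ConcordanceSummary:
    rho: float
    rho_p: float
    n_pairs: int
    n_concordant_up: int
    n_concordant_down: int
    n_nonconcordant: int
    rho_undefined: bool = False


def classify_concordance(
    joined: pd.DataFrame, cfg: AnalysisConfig
) -> tuple[pd.DataFrame, ConcordanceSummary]:
    """Label each ortholog pair and summarize the joint fold-change cloud.

    The status rule is symmetric in the two species; rho is computed over
    all joined pairs' (rat log2fc, human log2fc).
    """
    lfc, alpha = cfg.lfc_threshold, cfg.p_threshold
    table = joined.copy()
    sig_r = (table["rat_p"] < alpha).to_numpy()
    sig_h = (table["human_p"] < alpha).to_numpy()
    r = table["rat_log2fc"].to_numpy()
    h = table["human_log2fc"].to_numpy()
    up = sig_r & sig_h & (r >= lfc) & (h >= lfc)
    down = sig_r & sig_h & (r <= -lfc) & (h <= -lfc)
    status = np.full(len(table), NONCONCORDANT, dtype=object)
    status[up] = CONCORDANT_UP
    status[down] = CONCORDANT_DOWN
    table["status"] = status
    if len(table) >= 3:
        res = spearman(r, h)
    else:
        res = SpearmanResult(rho=math.nan, p=math.nan, n=len(table), undefined=True)
    summary = ConcordanceSummary(
        rho=res.rho,
        rho_p=res.p,
        n_pairs=len(table),
        n_concordant_up=int(up.sum()),
        n_concordant_down=int(down.sum()),
        n_nonconcordant=int(len(table) - up.sum() - down.sum()),
        rho_undefined=res.undefined,
    )
    return table, summary


def pathway_fold_changes(
    de: pd.DataFrame, sets: GeneSetCollection, cfg: AnalysisConfig
) -> pd.DataFrame:
    """Mean log2 fold change per pathway over member genes present in ``de``.

    Pathways with fewer than ``cfg.pathway_min_size`` present members are
    flagged excluded and carry no score.  log2 fold changes (not signed
    linear ones) are averaged, since they are additive.
    """
    present = set(de.index)
    rows = []
    for gs in sets:
        members = [g for g in gs.members if g in present]
        n = len(members)
        if n < cfg.pathway_min_size:
            rows.append(
                {"pathway": gs.name, "n_mapped_genes": n, "mean_log2fc": np.nan, "excluded": True}
            )
        else:
            rows.append(
                {
                    "pathway": gs.name,
                    "n_mapped_genes": n,
                    "mean_log2fc": float(de.loc[members, "log2fc"].mean()),
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows, columns=["pathway", "n_mapped_genes", "mean_log2fc", "excluded"]).set_index("pathway")


def translate_to_human(de_rat: pd.DataFrame, omap: OrthologMap) -> pd.DataFrame:
    """Re-index a rat contrast table by human ortholog ids (unmapped dropped)."""
    a2b = omap.a_to_b()
    keep = [g for g in de_rat.index if g in a2b]
    out = de_rat.loc[keep].copy()
    out.index = pd.Index([a2b[g] for g in keep], name="gene")
    return out


@dataclass
class PathwayConcordance:
    table: pd.DataFrame  # pathway, rat mean fc, human mean fc, concordant flag
    rho: SpearmanResult
    n_concordant: int
    n_nonconcordant: int


def pathway_concordance(
    rat_pfc: pd.DataFrame, human_pfc: pd.DataFrame
) -> PathwayConcordance:
    """Correlate pathway-level fold changes across species.

    Only pathways scored (not excluded) in both species are compared.
    A pathway is labeled concordant when its two mean fold changes are
    both nonzero with the same sign — the minimal sign-agreement reading
    of scatterplot quadrants; this labeling rule is an explicit
    assumption recorded in output metadata.
    """
    shared = [
        p
        for p in rat_pfc.index
        if p in human_pfc.index
        and not rat_pfc.at[p, "excluded"]
        and not human_pfc.at[p, "excluded"]
    ]
    r = rat_pfc.loc[shared, "mean_log2fc"].to_numpy(dtype=float)
    h = human_pfc.loc[shared, "mean_log2fc"].to_numpy(dtype=float)
    concordant = (np.sign(r) == np.sign(h)) & (r != 0) & (h != 0)
    table = pd.DataFrame(
        {
            "rat_mean_log2fc": r,
            "human_mean_log2fc": h,
            "concordant": concordant,
        },
        index=pd.Index(shared, name="pathway"),
    )
    table.attrs["concordance_rule"] = "sign_agreement_of_mean_log2fc"
    if len(shared) >= 3:
        res = spearman(r, h)
    else:
        res = SpearmanResult(rho=math.nan, p=math.nan, n=len(shared), undefined=True)
    return PathwayConcordance(
        table=table,
        rho=res,
        n_concordant=int(concordant.sum()),
        n_nonconcordant=int(len(shared) - concordant.sum()),
    )
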