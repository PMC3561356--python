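"""Synthetic paired rat time-course and human case/control expression data
with planted, fully recorded ground truth.

The generator emulates the structure of the study design every stage of
the pipeline expects: a small cohort of rats sampled at a baseline and
three post-induction timepoints (paired within subject), unpaired human
ulcerative-colitis / Crohn's / control groups, a 1:1 ortholog map
covering a fraction of genes, GO-like gene sets aligned with planted
temporal archetypes, and pathway-like sets over human genes with a
controllable coherence of member effect signs.

Values are built on the log2 scale as baseline + planted effect +
i.i.d. Gaussian noise, then exported on the raw intensity scale
(2^value) so the normalization stage is genuinely exercised.  The same
configuration (including seed) always produces bit-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    HUMAN_CONDITIONS,
    OrthologMap,
    RAT_CONDITIONS,
    SampleDesign,
    ValidationError,
    write_expression_matrix,
    write_gene_sets,
    write_ortholog_map,
    write_sample_design,
)
from .validation import CtTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedStudy",
    "simulate_experiment",
    "simulate_ct_table",
    "ARCHETYPE_LIBRARY",
]

# Unit temporal shapes over (T3, T7, T12); max |value| = 1 so the planted
# effect magnitude is realized exactly at the designated timepoint.
ARCHETYPE_LIBRARY: tuple[tuple[float, float, float], ...] = (
    (1.0, 0.3, 0.0),  # early up, return
    (1.0, 1.0, 1.0),  # sustained up
    (0.0, 0.5, 1.0),  # late up
    (0.5, 1.0, 0.5),  # mid peak up
    (1.0, 0.6, 0.3),  # decaying up
    (-1.0, -0.3, 0.0),  # early down, return
    (-1.0, -1.0, -1.0),  # sustained down
    (0.0, -0.5, -1.0),  # late down
    (-0.5, -1.0, -0.5),  # mid trough
    (-1.0, -0.6, -0.3),  # decaying down
    (1.0, 0.0, -0.5),  # up then down
    (-1.0, 0.0, 0.5),  # down then up
    (0.3, 0.6, 1.0),  # ramp up
)

LABEL_CONCORDANT_UP = "concordant_up"
LABEL_CONCORDANT_DOWN = "concordant_down"
LABEL_DISCORDANT = "discordant"
LABEL_NULL = "null"


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic experiment.

    Group sizes default to the emulated design: 5 paired rat subjects
    over four timepoints and unpaired human groups of 25 ulcerative
    colitis, 11 Crohn's disease and 25 control samples; 13 temporal
    archetypes.  Effects are log2 units; magnitudes are clipped from
    below at ``min_effect`` so every regulated gene is regulated at
    least at the differential-expression threshold.
    """

    n_genes: int = 2000
    n_rat_subjects: int = 5
    rat_conditions: tuple[str, ...] = RAT_CONDITIONS
    n_uc: int = 25
    n_cd: int = 11
    n_control: int = 25
    fraction_regulated: float = 0.2
    fraction_concordant: float = 0.5
    effect_mean: float = 2.0
    effect_sd: float = 0.5
    min_effect: float = 1.1
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    n_cluster_archetypes: int = 13
    ortholog_fraction: float = 0.75
    human_effect_scope: str = "both"  # "both", "uc", "cd", or "random"
    n_go_sets: int = 30
    n_pathway_sets: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_regulated", "fraction_concordant", "ortholog_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in ("n_genes", "n_rat_subjects", "n_uc", "n_cd", "n_control"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        n_reg = round(self.fraction_regulated * self.n_genes)
        if self.fraction_regulated > 0 and n_reg < self.n_cluster_archetypes:
            raise ValidationError(
                f"{n_reg} regulated genes cannot populate "
                f"{self.n_cluster_archetypes} archetypes"
            )
        if self.human_effect_scope not in ("both", "uc", "cd", "random"):
            raise ValidationError(f"unknown human_effect_scope {self.human_effect_scope!r}")
        if self.rat_conditions[0] != "T0":
            raise ValidationError("first rat condition must be the baseline T0")


@dataclass
class SimTruth:
    """Planted ground truth recorded by the generator.

    ``rat_effects``/``human_effects`` hold the planted per-condition
    log2 effects (0 for null genes); ``pairs`` records for each ortholog
    pair its concordance label and, for regulated pairs, the designated
    rat condition where the full effect magnitude is realized.
    """

    rat_baseline: pd.Series
    human_baseline: pd.Series
    rat_effects: pd.DataFrame  # genes x rat conditions
    human_effects: pd.DataFrame  # genes x (UC, CD)
    pairs: pd.DataFrame  # rat_gene, human_gene, label, designated_condition
    archetype_id: pd.Series  # regulated rat gene -> archetype index (1-based)
    pathway_coherence: dict[str, float]
    noise_sd: float
    rng_seed: int

    def regulated_rat_genes(self) -> list[str]:
        mask = (self.rat_effects != 0).any(axis=1)
        return list(self.rat_effects.index[mask])


@dataclass
class SimulatedStudy:
    rat_expr: ExpressionMatrix  # raw scale
    rat_design: SampleDesign
    human_expr: ExpressionMatrix  # raw scale
    human_design: SampleDesign
    orthologs: OrthologMap
    go_sets: GeneSetCollection  # rat namespace, archetype-aligned
    pathway_sets: GeneSetCollection  # human namespace
    truth: SimTruth

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Export the five artifact families as TSV/GMT plus a truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "rat_expr": outdir / "rat_expression.tsv",
            "rat_design": outdir / "rat_design.tsv",
            "human_expr": outdir / "human_expression.tsv",
            "human_design": outdir / "human_design.tsv",
            "orthologs": outdir / "orthologs.tsv",
            "go_sets": outdir / "go_sets.gmt",
            "pathway_sets": outdir / "pathway_sets.gmt",
            "truth": outdir / "truth.json",
        }
        write_expression_matrix(self.rat_expr, paths["rat_expr"])
        write_sample_design(self.rat_design, paths["rat_design"])
        write_expression_matrix(self.human_expr, paths["human_expr"])
        write_sample_design(self.human_design, paths["human_design"])
        write_ortholog_map(self.orthologs, paths["orthologs"])
        write_gene_sets(self.go_sets, paths["go_sets"])
        write_gene_sets(self.pathway_sets, paths["pathway_sets"])
        truth = {
            "rng_seed": self.truth.rng_seed,
            "noise_sd": self.truth.noise_sd,
            "rat_effects": {
                g: {c: float(v) for c, v in row.items() if v != 0}
                for g, row in self.truth.rat_effects.iterrows()
                if (row != 0).any()
            },
            "human_effects": {
                g: {c: float(v) for c, v in row.items() if v != 0}
                for g, row in self.truth.human_effects.iterrows()
                if (row != 0).any()
            },
            "pairs": self.truth.pairs.to_dict(orient="records"),
            "archetype_id": {g: int(a) for g, a in self.truth.archetype_id.items()},
            "pathway_coherence": self.truth.pathway_coherence,
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return {k: str(v) for k, v in paths.items()}


def _archetype(i: int, n: int) -> tuple[float, float, float]:
    """i-th of n archetype shapes, cycling through the fixed library."""
    return ARCHETYPE_LIBRARY[i % len(ARCHETYPE_LIBRARY)]


def simulate_experiment(cfg: SimConfig) -> SimulatedStudy:
    """Generate the full synthetic study with recorded ground truth."""
    rng = np.random.default_rng(cfg.rng_seed)
    rat_genes = [f"RGENE{i:05d}" for i in range(cfg.n_genes)]
    human_genes = [f"HGENE{i:05d}" for i in range(cfg.n_genes)]
    later = list(cfg.rat_conditions[1:])

    # --- planted rat effects -------------------------------------------------
    n_reg = round(cfg.fraction_regulated * cfg.n_genes)
    reg_idx = np.sort(rng.choice(cfg.n_genes, size=n_reg, replace=False))
    magnitudes = np.maximum(
        rng.normal(cfg.effect_mean, cfg.effect_sd, size=n_reg), cfg.min_effect
    )
    archetype_ids = np.array(
        [1 + (j % cfg.n_cluster_archetypes) for j in range(n_reg)]
    )
    rat_effects = pd.DataFrame(
        0.0, index=rat_genes, columns=list(cfg.rat_conditions)
    )
    designated: dict[str, str] = {}
    for j, gi in enumerate(reg_idx):
        shape = np.array(_archetype(archetype_ids[j] - 1, cfg.n_cluster_archetypes))
        effects = magnitudes[j] * shape
        rat_effects.loc[rat_genes[gi], later] = effects
        designated[rat_genes[gi]] = later[int(np.argmax(np.abs(shape)))]

    # --- ortholog map and planted human effects -----------------------------
    n_pairs = round(cfg.ortholog_fraction * cfg.n_genes)
    pair_idx = np.sort(rng.choice(cfg.n_genes, size=n_pairs, replace=False))
    reg_set = set(reg_idx.tolist())
    human_effects = pd.DataFrame(0.0, index=human_genes, columns=["UC", "CD"])
    pair_rows = []
    for gi in pair_idx:
        rat_g, human_g = rat_genes[gi], human_genes[gi]
        if gi in reg_set:
            dcond = designated[rat_g]
            rat_eff = rat_effects.loc[rat_g, dcond]
            concordant = rng.random() < cfg.fraction_concordant
            human_eff = rat_eff if concordant else -rat_eff
            scope = cfg.human_effect_scope
            if scope == "random":
                scope = ("uc", "cd", "both")[rng.integers(3)]
            if scope in ("uc", "both"):
                human_effects.loc[human_g, "UC"] = human_eff
            if scope in ("cd", "both"):
                human_effects.loc[human_g, "CD"] = human_eff
            if concordant:
                label = LABEL_CONCORDANT_UP if rat_eff > 0 else LABEL_CONCORDANT_DOWN
            else:
                label = LABEL_DISCORDANT
        else:
            label, dcond = LABEL_NULL, ""
        pair_rows.append(
            {
                "rat_gene": rat_g,
                "human_gene": human_g,
                "label": label,
                "designated_condition": dcond,
            }
        )
    pairs = pd.DataFrame(
        pair_rows, columns=["rat_gene", "human_gene", "label", "designated_condition"]
    )
    orthologs = OrthologMap(
        pairs=tuple((r["rat_gene"], r["human_gene"]) for r in pair_rows),
        namespace_a="rat",
        namespace_b="human",
    )

    # --- expression matrices -------------------------------------------------
    rat_baseline = pd.Series(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes),
        index=rat_genes,
    )
    human_baseline = pd.Series(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes),
        index=human_genes,
    )

    rat_samples, rat_design_rows = [], []
    for s in range(1, cfg.n_rat_subjects + 1):
        for cond in cfg.rat_conditions:
            sid = f"rat{s}_{cond}"
            rat_samples.append((sid, f"rat{s}", cond))
            rat_design_rows.append(
                {"sample_id": sid, "subject_id": f"rat{s}", "condition": cond, "species": "rat"}
            )
    rat_log2 = np.empty((cfg.n_genes, len(rat_samples)))
    for j, (_, _, cond) in enumerate(rat_samples):
        rat_log2[:, j] = (
            rat_baseline.to_numpy()
            + rat_effects[cond].to_numpy()
            + rng.normal(0, cfg.noise_sd, size=cfg.n_genes)
        )
    rat_expr = ExpressionMatrix(
        values=pd.DataFrame(
            2.0**rat_log2, index=rat_genes, columns=[s[0] for s in rat_samples]
        ),
        scale="raw",
    )
    rat_design = SampleDesign(table=pd.DataFrame(rat_design_rows))

    human_samples, human_design_rows = [], []
    for cond, count in (("N", cfg.n_control), ("UC", cfg.n_uc), ("CD", cfg.n_cd)):
        for s in range(1, count + 1):
            sid = f"{cond.lower()}{s}"
            human_samples.append((sid, cond))
            human_design_rows.append(
                {"sample_id": sid, "subject_id": f"subj_{sid}", "condition": cond, "species": "human"}
            )
    human_cond_effect = {"N": np.zeros(cfg.n_genes)}
    human_cond_effect["UC"] = human_effects["UC"].to_numpy()
    human_cond_effect["CD"] = human_effects["CD"].to_numpy()
    human_log2 = np.empty((cfg.n_genes, len(human_samples)))
    for j, (_, cond) in enumerate(human_samples):
        human_log2[:, j] = (
            human_baseline.to_numpy()
            + human_cond_effect[cond]
            + rng.normal(0, cfg.noise_sd, size=cfg.n_genes)
        )
    human_expr = ExpressionMatrix(
        values=pd.DataFrame(
            2.0**human_log2, index=human_genes, columns=[s[0] for s in human_samples]
        ),
        scale="raw",
    )
    human_design = SampleDesign(table=pd.DataFrame(human_design_rows))

    # --- GO-like sets aligned with archetypes (rat namespace) ---------------
    go_sets: dict[str, GeneSet] = {}
    by_arch: dict[int, list[str]] = {}
    for j, gi in enumerate(reg_idx):
        by_arch.setdefault(int(archetype_ids[j]), []).append(rat_genes[gi])
    unregulated = [g for i, g in enumerate(rat_genes) if i not in reg_set]
    for arch, members in sorted(by_arch.items()):
        core = members[:40]
        n_bg = max(0, 5 - len(core)) + 3
        bg = list(rng.choice(unregulated, size=min(n_bg, len(unregulated)), replace=False))
        name = f"GOBP_ARCH{arch:02d}"
        go_sets[name] = GeneSet(name, f"archetype {arch} response", tuple(dict.fromkeys(core + bg)))
    i = 0
    while len(go_sets) < cfg.n_go_sets and len(rat_genes) >= 10:
        i += 1
        size = int(rng.integers(8, 40))
        members = tuple(
            dict.fromkeys(rng.choice(rat_genes, size=size, replace=False).tolist())
        )
        go_sets[f"GOBP_RAND{i:02d}"] = GeneSet(
            f"GOBP_RAND{i:02d}", "random background process", members
        )

    # --- pathway-like sets over human genes with coherent effect signs ------
    up_pool = list(human_effects.index[(human_effects > 0).any(axis=1)])
    down_pool = list(human_effects.index[(human_effects < 0).any(axis=1)])
    null_pool = list(human_effects.index[(human_effects == 0).all(axis=1)])
    pathway_sets: dict[str, GeneSet] = {}
    pathway_coherence: dict[str, float] = {}
    for i in range(1, cfg.n_pathway_sets + 1):
        size = int(rng.integers(8, 30))
        coherent = i % 2 == 1  # alternate coherent / incoherent sets
        if coherent and up_pool and down_pool:
            coherence = float(rng.uniform(0.6, 1.0))
            pool = up_pool if i % 4 == 1 else down_pool
            n_core = min(int(round(coherence * size)), len(pool))
            core = list(rng.choice(pool, size=n_core, replace=False))
            filler = list(
                rng.choice(null_pool, size=min(size - n_core, len(null_pool)), replace=False)
            )
            members = core + filler
        else:
            coherence = 0.0
            members = list(rng.choice(human_genes, size=size, replace=False))
        name = f"PATH{i:03d}"
        members = list(dict.fromkeys(members))
        if len(members) < 2:
            continue
        pathway_sets[name] = GeneSet(name, "synthetic pathway", tuple(members))
        pathway_coherence[name] = coherence

    truth = SimTruth(
        rat_baseline=rat_baseline,
        human_baseline=human_baseline,
        rat_effects=rat_effects,
        human_effects=human_effects,
        pairs=pairs,
        archetype_id=pd.Series(
            {rat_genes[gi]: int(archetype_ids[j]) for j, gi in enumerate(reg_idx)},
            dtype=int,
        ),
        pathway_coherence=pathway_coherence,
        noise_sd=cfg.noise_sd,
        rng_seed=cfg.rng_seed,
    )
    return SimulatedStudy(
        rat_expr=rat_expr,
        rat_design=rat_design,
        human_expr=human_expr,
        human_design=human_design,
        orthologs=orthologs,
        go_sets=GeneSetCollection(sets=go_sets),
        pathway_sets=GeneSetCollection(sets=pathway_sets),
        truth=truth,
    )


def simulate_ct_table(
    n_subjects: int,
    planted_ddct: dict[str, float],
    noise_sd: float,
    seed: int,
    target: str = "TARGET",
    housekeeping: str = "ACTB",
    control_condition: str = "T0",
) -> CtTable:
    """Synthetic qPCR Ct table with a planted ddCt per condition.

    The housekeeping gene cycles around 15, the target's baseline dCt is
    8; at condition c the target Ct is shifted by ``planted_ddct[c]`` so
    the recovered fold change at zero noise is exactly 2^(-ddCt).
    """
    if n_subjects < 2:
        raise ValidationError("need >= 2 subjects for a paired comparison")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    conditions = [control_condition] + [
        c for c in planted_ddct if c != control_condition
    ]
    rows = []
    base_dct = 8.0
    for s in range(1, n_subjects + 1):
        subject = f"subj{s}"
        for cond in conditions:
            hk = 15.0 + rng.normal(0, noise_sd)
            shift = planted_ddct.get(cond, 0.0) if cond != control_condition else 0.0
            tgt = hk + base_dct + shift + rng.normal(0, noise_sd)
            rows.append({"subject": subject, "condition": cond, "gene": housekeeping, "ct": hk})
            rows.append({"subject": subject, "condition": cond, "gene": target, "ct": tgt})
    return CtTable(table=pd.DataFrame(rows), housekeeping=housekeeping)
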