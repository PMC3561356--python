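"""Domain types and on-disk formats shared by every pipeline stage.

The pipeline exchanges four kinds of artifacts: expression matrices
(genes x samples, TSV), sample designs (TSV), gene-set collections
(GMT) and ortholog maps (two-column TSV).  All files are tab-separated
UTF-8 with ``#``-prefixed comment lines skipped and ``.`` as the decimal
separator, which fixes a bit-exact interchange dialect.

An :class:`ExpressionMatrix` is either on the raw intensity scale
(strictly positive values, as scanned off an array) or on the log2
scale (finite values, post-normalization); the flag prevents silent
double log-transforms downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

RAT_CONDITIONS = ("T0", "T3", "T7", "T12")
HUMAN_CONDITIONS = ("N", "UC", "CD")

__all__ = [
    "ParseError",
    "ValidationError",
    "ExpressionMatrix",
    "SampleDesign",
    "AnalysisConfig",
    "GeneSet",
    "GeneSetCollection",
    "OrthologMap",
    "LoadReport",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_design",
    "write_sample_design",
    "read_gene_sets",
    "write_gene_sets",
    "read_ortholog_map",
    "write_ortholog_map",
    "RAT_CONDITIONS",
    "HUMAN_CONDITIONS",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(ValueError):
    """Parsed content violates a domain-type invariant."""


@dataclass(frozen=True)
class LoadReport:
    """Counts retained/dropped by a reader, for the run report."""

    n_retained: int
    n_dropped: int
    details: Mapping[str, int] = field(default_factory=dict)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with an explicit scale flag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique gene ids, columns by unique sample ids.
    scale : {"raw", "log2"}
        ``raw`` requires all values strictly positive; ``log2`` requires
        all values finite.
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if self.scale == "raw" and not (arr > 0).all():
            raise ValidationError("raw-scale matrix must be strictly positive")
        if self.scale == "log2" and not np.isfinite(arr).all():
            raise ValidationError("log2-scale matrix must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SampleDesign:
    """Sample annotation: one row per sample with subject and condition.

    Within a subject there is at most one sample per condition, which is
    what makes paired (within-subject) contrasts well defined.
    """

    table: pd.DataFrame  # columns: sample_id, subject_id, condition, species

    REQUIRED = ("sample_id", "subject_id", "condition", "species")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"design missing columns {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id {dup!r} in design")
        dup_sc = self.table.duplicated(subset=["subject_id", "condition"])
        if dup_sc.any():
            row = self.table.loc[dup_sc].iloc[0]
            raise ValidationError(
                f"subject {row['subject_id']!r} has more than one sample "
                f"for condition {row['condition']!r}"
            )

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must appear exactly once in the design."""
        design_samples = set(self.table["sample_id"])
        missing = [s for s in matrix.sample_ids if s not in design_samples]
        if missing:
            raise ValidationError(f"samples missing from design: {missing[:5]}")

    def samples_for(self, condition: str) -> list[str]:
        sub = self.table[self.table["condition"] == condition]
        return list(sub["sample_id"])

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.table["subject_id"]))


@dataclass
class AnalysisConfig:
    """Pipeline-wide thresholds and algorithm settings.

    ``p_threshold``/``lfc_threshold`` define a differentially regulated
    gene (two-sided p < 0.05 and |log2 fold change| >= 1.1); the
    gene-set size window [``go_min_size``, ``go_max_size``] keeps
    enrichment terms specific; ``pathway_min_size`` excludes
    poorly-covered pathways from pathway-level fold changes;
    ``tc_alpha`` is the FDR level for time-course gene selection.
    """

    p_threshold: float = 0.05
    lfc_threshold: float = 1.1
    go_min_size: int = 5
    go_max_size: int = 1000
    pathway_min_size: int = 5
    tc_alpha: float = 0.01
    ap_damping: float = 0.9
    ap_max_iter: int = 1000
    ap_conv_iter: int = 50
    tc_permutations: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValidationError("p_threshold must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValidationError("lfc_threshold must be >= 0")
        if self.go_min_size > self.go_max_size:
            raise ValidationError("go_min_size must be <= go_max_size")
        if self.pathway_min_size < 1:
            raise ValidationError("pathway_min_size must be >= 1")
        if not 0 < self.tc_alpha < 1:
            raise ValidationError("tc_alpha must be in (0, 1)")
        if not 0.5 <= self.ap_damping < 1:
            raise ValidationError("ap_damping must be in [0.5, 1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Named gene sets (GO-BP terms or KEGG/Reactome-style pathways)."""

    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValidationError(f"set key {name!r} != set name {gs.name!r}")
            if len(gs.members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(gs.members)) != len(gs.members):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class OrthologMap:
    """One-to-one gene correspondence between two namespaces (e.g. rat/human)."""

    pairs: tuple[tuple[str, str], ...]
    namespace_a: str = "a"
    namespace_b: str = "b"

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValidationError("ortholog map is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def a_to_b(self) -> dict[str, str]:
        return {a: b for a, b in self.pairs}

    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv_lines(path: str | Path) -> list[tuple[int, str]]:
    """Return (1-based line number, line) pairs, comments/blank lines skipped."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            out.append((i, stripped))
    return out


def read_expression_matrix(path: str | Path, scale_hint: str = "raw") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header = sample ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error wrapping
        raise ParseError(f"cannot parse expression TSV {path}: {exc}") from exc
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"non-numeric value in {path} at gene {row!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise ParseError(f"missing values in expression TSV {path}")
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df, scale=scale_hint)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return SampleDesign(table=df)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_gene_sets(
    path: str | Path, min_size: int = 1, max_size: int = 10**9
) -> tuple[GeneSetCollection, LoadReport]:
    """Parse a GMT file, dropping sets outside [min_size, max_size].

    Sizes are counted after within-line member deduplication; the
    boundary is inclusive, so sets of exactly ``min_size`` or exactly
    ``max_size`` members are retained.
    """
    sets: dict[str, GeneSet] = {}
    n_dropped = 0
    for lineno, line in _read_tsv_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
        name, description = fields[0], fields[1]
        members = tuple(dict.fromkeys(m for m in fields[2:] if m))
        if name in sets:
            raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
        if not (min_size <= len(members) <= max_size):
            n_dropped += 1
            continue
        sets[name] = GeneSet(name=name, description=description, members=members)
    report = LoadReport(n_retained=len(sets), n_dropped=n_dropped)
    return GeneSetCollection(sets=sets), report


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_ortholog_map(
    path: str | Path,
    ambiguity_policy: str = "drop",
    namespace_a: str = "a",
    namespace_b: str = "b",
) -> tuple[OrthologMap, LoadReport]:
    """Read a two-column TSV of gene pairs and canonicalize to 1:1.

    With ``ambiguity_policy="drop"`` (default) any gene participating in
    more than one pair, on either side, is removed together with all its
    pairs; with ``"first"`` the first pair mentioning a gene wins.
    """
    if ambiguity_policy not in ("drop", "first"):
        raise ValidationError(f"unknown ambiguity policy {ambiguity_policy!r}")
    raw_pairs: list[tuple[str, str]] = []
    for lineno, line in _read_tsv_lines(path):
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}:{lineno}: expected two tab-separated gene ids")
        raw_pairs.append((fields[0], fields[1]))
    raw_pairs = list(dict.fromkeys(raw_pairs))  # exact duplicate pairs collapse
    if ambiguity_policy == "drop":
        from collections import Counter

        count_a = Counter(a for a, _ in raw_pairs)
        count_b = Counter(b for _, b in raw_pairs)
        kept = [
            (a, b) for a, b in raw_pairs if count_a[a] == 1 and count_b[b] == 1
        ]
    else:
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        kept = []
        for a, b in raw_pairs:
            if a in seen_a or b in seen_b:
                continue
            kept.append((a, b))
            seen_a.add(a)
            seen_b.add(b)
    report = LoadReport(n_retained=len(kept), n_dropped=len(raw_pairs) - len(kept))
    omap = OrthologMap(
        pairs=tuple(kept), namespace_a=namespace_a, namespace_b=namespace_b
    )
    return omap, report


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {omap.namespace_a}\t{omap.namespace_b}\n")
        for a, b in omap.pairs:
            fh.write(f"{a}\t{b}\n")


def write_json_report(report: Mapping, path: str | Path) -> None:
    """Machine-readable run report; keys sorted for byte-stable output."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
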