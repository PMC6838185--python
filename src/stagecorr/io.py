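"""Tabular I/O: expression tables, homolog maps, gene sets, result matrices.

All artifacts are tab-separated UTF-8 with a single header row.  Expression
sample columns are named ``<stage label>|<replicate id>`` where the stage
label starts with the time in hours post fertilization, e.g. ``"24 hpf
gastrula|r2"``.  Gene identifiers are opaque strings (the upstream data mixes
assembler contig ids, genome-model ids, and gene names).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix

_HPF_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*hpf\b", re.IGNORECASE)

_GENE_SET_CATEGORIES = frozenset(
    {"developmental", "housekeeping", "response", "metabolic", "lineage", "other"}
)


class FormatError(ValueError):
    """A tabular input violates the expected dialect or a content invariant."""


def parse_hpf(stage_label: str) -> float:
    """Extract the numeric hours-post-fertilization from a stage label."""
    m = _HPF_RE.match(stage_label)
    if m is None:
        raise FormatError(
            f"stage label {stage_label!r} has no parseable '<number> hpf' prefix"
        )
    return float(m.group(1))


@dataclass(frozen=True)
class Sample:
    """One sequenced sample: a developmental stage plus a replicate id."""

    stage_label: str
    hpf: float
    replicate_id: str


@dataclass
class ExpressionTable:
    """Gene x sample matrix of non-negative FPKM-scale expression values."""

    species_id: str
    gene_ids: tuple[str, ...]
    samples: tuple[Sample, ...]
    values: np.ndarray  # genes x samples

    def __post_init__(self) -> None:
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        self.samples = tuple(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise FormatError("value matrix shape does not match genes x samples")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise FormatError(f"duplicate gene id {dup!r} in {self.species_id} table")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative expression value {self.values[i, j]} at gene "
                f"{self.gene_ids[i]!r}, sample {self.samples[j].stage_label!r}/"
                f"{self.samples[j].replicate_id!r}"
            )
        if len({s.stage_label for s in self.samples}) < 2:
            raise FormatError("an expression table needs at least 2 stages")

    @property
    def stage_labels(self) -> tuple[str, ...]:
        """Distinct stage labels in column order of first appearance."""
        return tuple(dict.fromkeys(s.stage_label for s in self.samples))


def read_expression_table(path: str | Path, species_id: str) -> ExpressionTable:
    """Read a per-species expression TSV (first column: gene id).

    Hard errors (never silent drops): duplicate gene ids, negative or
    non-numeric cells, columns without a parseable stage annotation, empty
    files.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no records") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: no records")
    samples = []
    for col in df.columns:
        if "|" not in str(col):
            raise FormatError(
                f"{path}: column {col!r} missing stage annotation "
                "(expected '<stage label>|<replicate id>')"
            )
        stage_label, rep = str(col).split("|", 1)
        try:
            hpf = parse_hpf(stage_label)
        except FormatError as e:
            raise FormatError(f"{path}: column {col!r}: {e}") from None
        samples.append(Sample(stage_label=stage_label, hpf=hpf, replicate_id=rep))
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at gene "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at gene {df.index[i]!r}, column "
            f"{df.columns[j]!r} (encode absence as 0 upstream)"
        )
    return ExpressionTable(
        species_id=species_id,
        gene_ids=tuple(df.index.astype(str)),
        samples=tuple(samples),
        values=numeric.to_numpy(dtype=float),
    )


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    cols = [f"{s.stage_label}|{s.replicate_id}" for s in table.samples]
    df = pd.DataFrame(table.values, index=list(table.gene_ids), columns=cols)
    df.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class HomologMap:
    """Strict 1:1(:1) homolog records across 2 or 3 species."""

    records: tuple[tuple[str, ...], ...]
    species_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.species_order = tuple(str(s) for s in self.species_order)
        self.records = tuple(tuple(str(g) for g in r) for r in self.records)
        if len(self.species_order) not in (2, 3):
            raise FormatError("homolog map must cover 2 or 3 species")
        for r in self.records:
            if len(r) != len(self.species_order):
                raise FormatError(f"ragged homolog record {r!r}")
            if any(g == "" or g.lower() == "nan" for g in r):
                raise FormatError(f"empty field in homolog record {r!r}")
        for k, sp in enumerate(self.species_order):
            ids = [r[k] for r in self.records]
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(g for g in ids if g in seen or seen.add(g))
                raise FormatError(
                    f"gene id {dup!r} occurs in more than one record for "
                    f"species {sp!r} (violates 1:1 mapping)"
                )

    def __len__(self) -> int:
        return len(self.records)

    def column(self, species_id: str) -> tuple[str, ...]:
        k = self.species_order.index(species_id)
        return tuple(r[k] for r in self.records)

    def pairwise(self, species_a: str, species_b: str) -> "HomologMap":
        """Project onto two species, preserving record order."""
        ia = self.species_order.index(species_a)
        ib = self.species_order.index(species_b)
        return HomologMap(
            records=tuple((r[ia], r[ib]) for r in self.records),
            species_order=(species_a, species_b),
        )


def read_homolog_map(
    path: str | Path, species_order: Sequence[str] | None = None
) -> HomologMap:
    """Read a homolog table (header row names the species, one column each).

    If ``species_order`` is given, columns are reordered to match it.  A gene
    id appearing in two records for the same species is a hard error; so is a
    ragged line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no records") from None
    if df.isna().to_numpy().any():
        i = int(np.argwhere(df.isna().to_numpy())[0][0])
        raise FormatError(f"{path}: ragged or incomplete record at data line {i + 1}")
    cols = [str(c) for c in df.columns]
    if species_order is not None:
        missing = [s for s in species_order if s not in cols]
        if missing:
            raise FormatError(f"{path}: species {missing} not found in header {cols}")
        df = df[list(species_order)]
        cols = list(species_order)
    return HomologMap(
        records=tuple(tuple(r) for r in df.to_numpy(dtype=str)),
        species_order=tuple(cols),
    )


def write_homolog_map(homolog_map: HomologMap, path: str | Path) -> None:
    df = pd.DataFrame(list(homolog_map.records), columns=list(homolog_map.species_order))
    df.to_csv(path, sep="\t", index=False)


@dataclass
class GeneSet:
    """A named gene set (GO term, cell population, ...) in the reference
    species' identifier namespace."""

    name: str
    members: tuple[str, ...]
    category: str = "other"

    def __post_init__(self) -> None:
        self.members = tuple(str(m) for m in self.members)
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")
        if self.category not in _GENE_SET_CATEGORIES:
            raise FormatError(
                f"gene set {self.name!r}: unknown category {self.category!r}"
            )


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """Read gene sets from a two-column (set_name, gene_id) TSV.

    An optional third column assigns a category; the first non-empty category
    seen for a set wins.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no records") from None
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns (set_name, gene_id[, category])")
    out: dict[str, list[str]] = {}
    cats: dict[str, str] = {}
    for row in df.itertuples(index=False):
        name, gene = str(row[0]), str(row[1])
        out.setdefault(name, []).append(gene)
        if len(row) > 2 and isinstance(row[2], str) and row[2] and name not in cats:
            cats[name] = row[2]
    return {
        name: GeneSet(name=name, members=tuple(members), category=cats.get(name, "other"))
        for name, members in out.items()
    }


def write_gene_sets(sets: Mapping[str, GeneSet] | Iterable[GeneSet], path: str | Path) -> None:
    if isinstance(sets, Mapping):
        sets = sets.values()
    rows = [(s.name, m, s.category) for s in sets for m in s.members]
    pd.DataFrame(rows, columns=["set_name", "gene_id", "category"]).to_csv(
        path, sep="\t", index=False
    )


def write_matrix(
    matrix: CorrelationMatrix, path: str | Path, *, comments: Sequence[str] = ()
) -> None:
    """Write a correlation matrix as TSV, round-trippable at full precision.

    Provenance (species pair, gene count) is stored in ``#`` header comments.
    """
    path = Path(path)
    lines = [f"# {c}" for c in comments]
    lines.append(f"# species_a={matrix.species_a}")
    lines.append(f"# species_b={matrix.species_b}")
    lines.append(f"# n_genes={matrix.n_genes}")
    df = pd.DataFrame(
        matrix.values, index=list(matrix.row_labels), columns=list(matrix.col_labels)
    )
    # pandas str(float) serialization uses repr, which round-trips exactly
    body = df.to_csv(sep="\t", index_label="stage")
    path.write_text("\n".join(lines) + "\n" + body, encoding="utf-8")


def read_matrix(path: str | Path) -> CorrelationMatrix:
    path = Path(path)
    meta: dict[str, str] = {}
    data_lines = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            stripped = line[1:].strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta.setdefault(k.strip(), v.strip())
        elif line.strip():
            data_lines.append(line)
    if not data_lines:
        raise FormatError(f"{path}: no records")
    from io import StringIO

    df = pd.read_csv(
        StringIO("\n".join(data_lines)),
        sep="\t",
        index_col=0,
        float_precision="round_trip",
    )
    return CorrelationMatrix(
        values=df.to_numpy(dtype=float),
        row_labels=tuple(df.index.astype(str)),
        col_labels=tuple(df.columns.astype(str)),
        species_a=meta.get("species_a", "S1"),
        species_b=meta.get("species_b", "S2"),
        n_genes=int(meta.get("n_genes", 0)),
    )
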