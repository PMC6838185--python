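"""Replicate averaging, expression thresholds, homolog intersection, alignment.

The pipeline works on per-stage series: for every stage, the mean FPKM over
its replicates.  Correlations are computed on log10(FPKM + pseudocount) by
default, so that a handful of very high expressors cannot dominate the
Pearson r.  "Expressed" means exceeding an FPKM threshold (default 3, strict)
at one or more stages.  The presence partition classifies every homolog
record by which species express it - the Venn regions of a multi-species
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .io import ExpressionTable, GeneSet, HomologMap

DEFAULT_EXPRESSION_THRESHOLD = 3.0  # FPKM
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class StageSeries:
    """Per-species gene x stage matrix of replicate-averaged expression."""

    species_id: str
    gene_ids: tuple[str, ...]
    stage_labels: tuple[str, ...]
    hpf: np.ndarray
    values: np.ndarray  # genes x stages
    transform_tag: str = "raw"

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        self.stage_labels = tuple(self.stage_labels)
        self.hpf = np.asarray(self.hpf, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.stage_labels)):
            raise ValueError("values shape does not match genes x stages")
        if self.hpf.shape != (len(self.stage_labels),):
            raise ValueError("hpf vector does not match stage count")
        if np.any(np.diff(self.hpf) <= 0):
            raise ValueError("stages must be strictly increasing in hpf")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stage series values must be finite")
        if self.transform_tag == "raw" and np.any(self.values < 0):
            raise ValueError("raw stage series values must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(
                f"gene {gene_id!r} not present in {self.species_id} series"
            ) from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def stage_index(self, stage_label: str) -> int:
        try:
            return self.stage_labels.index(stage_label)
        except ValueError:
            raise KeyError(
                f"stage {stage_label!r} not present in {self.species_id} series"
            ) from None


def average_replicates(table: ExpressionTable) -> StageSeries:
    """Mean FPKM over all samples of each stage, stages ordered by hpf."""
    by_stage: dict[str, list[int]] = {}
    hpf_of: dict[str, float] = {}
    for j, s in enumerate(table.samples):
        by_stage.setdefault(s.stage_label, []).append(j)
        hpf_of.setdefault(s.stage_label, s.hpf)
        if hpf_of[s.stage_label] != s.hpf:
            raise ValueError(
                f"stage {s.stage_label!r} annotated with conflicting hpf values"
            )
    order = sorted(by_stage, key=lambda lab: hpf_of[lab])
    values = np.column_stack(
        [table.values[:, by_stage[lab]].mean(axis=1) for lab in order]
    )
    return StageSeries(
        species_id=table.species_id,
        gene_ids=table.gene_ids,
        stage_labels=tuple(order),
        hpf=np.array([hpf_of[lab] for lab in order]),
        values=values,
        transform_tag="raw",
    )


def is_expressed(
    series: StageSeries, gene_id: str, threshold: float = DEFAULT_EXPRESSION_THRESHOLD
) -> bool:
    """True iff the gene exceeds ``threshold`` (strictly) at >= 1 stage."""
    if series.transform_tag != "raw":
        raise ValueError("expression threshold applies to the raw FPKM scale")
    return bool(series.row(gene_id).max() > threshold)


@dataclass
class PresencePartition:
    """Disjoint classification of homolog records by expressing species.

    ``regions`` maps a sorted tuple of species ids (possibly empty = expressed
    in none) to the homolog records falling in that Venn region.
    """

    species_order: tuple[str, ...]
    regions: dict[tuple[str, ...], tuple[tuple[str, ...], ...]]

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def region_order(self) -> list[tuple[str, ...]]:
        """Canonical region order: all species, pairs, singles, none."""
        sp = self.species_order
        order: list[tuple[str, ...]] = []
        for size in range(len(sp), -1, -1):
            for combo in combinations(sp, size):
                order.append(combo)
        return order

    def counts_vector(self) -> tuple[int, ...]:
        return tuple(len(self.regions.get(r, ())) for r in self.region_order())


def presence_partition(
    series_list: Sequence[StageSeries],
    homolog_map: HomologMap,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> PresencePartition:
    """Assign every homolog record to exactly one presence region.

    A gene absent from a species' table counts as not expressed there.
    """
    ids = tuple(s.species_id for s in series_list)
    if set(ids) != set(homolog_map.species_order) or len(ids) != len(
        homolog_map.species_order
    ):
        raise ValueError(
            f"series species {ids} do not match homolog map species "
            f"{homolog_map.species_order}"
        )
    series_of = {s.species_id: s for s in series_list}
    ordered = [series_of[sp] for sp in homolog_map.species_order]
    expressed_sets = []
    for s in ordered:
        mask = s.values.max(axis=1) > threshold
        expressed_sets.append({g for g, m in zip(s.gene_ids, mask) if m})
    regions: dict[tuple[str, ...], list[tuple[str, ...]]] = {}
    for rec in homolog_map.records:
        present = tuple(
            sp
            for sp, gene, exp in zip(homolog_map.species_order, rec, expressed_sets)
            if gene in exp
        )
        regions.setdefault(present, []).append(rec)
    return PresencePartition(
        species_order=homolog_map.species_order,
        regions={k: tuple(v) for k, v in regions.items()},
    )


def log_transform(
    series: StageSeries, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> StageSeries:
    """log10(FPKM + pseudocount); pseudocount 1 keeps zeros at 0."""
    if series.transform_tag != "raw":
        raise ValueError("series already log-transformed")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return StageSeries(
        species_id=series.species_id,
        gene_ids=series.gene_ids,
        stage_labels=series.stage_labels,
        hpf=series.hpf,
        values=np.log10(series.values + pseudocount),
        transform_tag="log",
    )


@dataclass
class StageAlignment:
    """Declared pairing of morphologically equivalent stages.

    ``pairs`` lists (stage label in species 1, stage label in species 2) in
    developmental order; the alignment must be order-preserving in each
    species and never reuse a stage.
    """

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        self.pairs = tuple((str(a), str(b)) for a, b in self.pairs)
        if len(self.pairs) < 2:
            raise ValueError("an alignment needs at least 2 stage pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def identity(cls, stage_labels: Sequence[str]) -> "StageAlignment":
        return cls(pairs=tuple((l, l) for l in stage_labels))

    def resolve(
        self, series_a: StageSeries, series_b: StageSeries
    ) -> tuple[np.ndarray, np.ndarray]:
        """Translate labels to column indices and check order preservation."""
        ia = np.array([series_a.stage_index(a) for a, _ in self.pairs])
        ib = np.array([series_b.stage_index(b) for _, b in self.pairs])
        for name, idx in ((series_a.species_id, ia), (series_b.species_id, ib)):
            if np.any(np.diff(idx) <= 0):
                raise ValueError(
                    f"alignment is not order-preserving (or repeats a stage) "
                    f"for species {name!r}"
                )
        return ia, ib


@dataclass
class PairedMatrices:
    """Homolog-paired, stage-aligned gene x stage matrices for two species."""

    a: np.ndarray
    b: np.ndarray
    gene_ids_a: tuple[str, ...]
    gene_ids_b: tuple[str, ...]
    stage_labels_a: tuple[str, ...]
    stage_labels_b: tuple[str, ...]
    species_a: str
    species_b: str

    @property
    def n_genes(self) -> int:
        return self.a.shape[0]


def filter_map_to_series(
    homolog_map: HomologMap, series_list: Sequence[StageSeries]
) -> HomologMap:
    """Drop homolog records whose gene is absent from any of the tables."""
    series_of = {s.species_id: s for s in series_list}
    keep = []
    for rec in homolog_map.records:
        if all(
            gene in series_of[sp]
            for sp, gene in zip(homolog_map.species_order, rec)
            if sp in series_of
        ):
            keep.append(rec)
    return HomologMap(records=tuple(keep), species_order=homolog_map.species_order)


def restrict(
    series_a: StageSeries,
    series_b: StageSeries,
    homolog_map: HomologMap,
    gene_set: GeneSet | None = None,
    alignment: StageAlignment | None = None,
) -> PairedMatrices:
    """Pair the two series on homologs (optionally a gene set) and align stages.

    Gene-set members are interpreted in the namespace of the homolog map's
    first (reference) species.  Raises if the intersection is empty or if a
    mapped gene is missing from either series.
    """
    pm = homolog_map.pairwise(series_a.species_id, series_b.species_id)
    records = pm.records
    if gene_set is not None:
        ref_col = homolog_map.column(homolog_map.species_order[0])
        members = set(gene_set.members)
        records = tuple(
            rec for rec, ref in zip(pm.records, ref_col) if ref in members
        )
        if not records:
            raise ValueError(
                f"empty gene set after restriction: no member of "
                f"{gene_set.name!r} maps into the homolog set"
            )
    if alignment is None:
        if series_a.stage_labels != series_b.stage_labels:
            raise ValueError(
                "stage labels differ between species; an explicit alignment "
                "is required"
            )
        alignment = StageAlignment.identity(series_a.stage_labels)
    ia, ib = alignment.resolve(series_a, series_b)

    def _rows(series: StageSeries, genes: list[str]) -> np.ndarray:
        try:
            return np.array([series._gene_index[g] for g in genes])
        except KeyError as e:
            raise KeyError(
                f"homolog gene {e.args[0]!r} absent from {series.species_id} "
                "series (filter the map with filter_map_to_series first)"
            ) from None

    rows_a = _rows(series_a, [ga for ga, _ in records])
    rows_b = _rows(series_b, [gb for _, gb in records])
    return PairedMatrices(
        a=series_a.values[np.ix_(rows_a, ia)],
        b=series_b.values[np.ix_(rows_b, ib)],
        gene_ids_a=tuple(r[0] for r in records),
        gene_ids_b=tuple(r[1] for r in records),
        stage_labels_a=tuple(series_a.stage_labels[i] for i in ia),
        stage_labels_b=tuple(series_b.stage_labels[i] for i in ib),
        species_a=series_a.species_id,
        species_b=series_b.species_id,
    )
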