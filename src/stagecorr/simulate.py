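"""Synthetic paired-species developmental expression cohorts.

The generator emulates the processed product of a comparative RNA-seq time
course: two species' FPKM tables over a shared set of 1:1 homologs, with two
gene classes.

*Developmental* genes peak at one stage (a Gaussian bump of width one stage
on the log10 scale); the peak stages correspond between species, which is
what produces a diagonal interspecies correlation matrix.  A divergence
parameter delta in [0, 1] mixes the second species' profile toward an
independently drawn one - delta = 0 means identical regulation, delta = 1
fully independent - degrading the diagonal the way evolutionary distance
does.

*Housekeeping* genes share one monotone increasing temporal trend plus a
gene-specific constant offset, identical in both species: their interspecies
correlations are uniformly high regardless of stage matching, so they carry
no diagonality signal.

Replicate scatter is multiplicative log-normal noise on the FPKM values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .correlation import stage_correlation_matrix, summarize
from .diagonality import DiagonalityConfig, matrix_diagonality
from .io import (
    ExpressionTable,
    GeneSet,
    HomologMap,
    Sample,
    write_expression_table,
    write_gene_sets,
    write_homolog_map,
)
from .preprocess import (
    StageAlignment,
    average_replicates,
    log_transform,
    restrict,
)

PEAK_WIDTH_STAGES = 1.0  # sd of the Gaussian bump, in stage units


@dataclass
class SimulationConfig:
    """Generative parameters for a paired-species cohort.

    Defaults describe a mid-sized echinoderm-style time course: 500
    stage-peaked genes, 200 housekeeping genes, 7 stages x 3 replicates,
    moderate divergence (0.2) and replicate scatter (sd 0.1 on the log10
    scale, i.e. ~26% multiplicative noise).  ``baseline`` and ``amplitude``
    are log10-FPKM units: baseline 1 (10 FPKM) with amplitude 2 puts peak
    expression near 1000 FPKM, comfortably above the expressed threshold.
    ``peak_weights`` optionally concentrates developmental peaks at chosen
    stages (e.g. a phylotypic stage) instead of the uniform default.
    """

    n_genes_dev: int = 500
    n_genes_hk: int = 200
    n_stages: int = 7
    n_reps: int = 3
    divergence: float = 0.2
    noise_sd: float = 0.1
    baseline: float = 1.0
    amplitude: float = 2.0
    hk_offset_sd: float = 0.5
    peak_weights: tuple[float, ...] | None = None
    hk_divergence: bool = False
    species_ids: tuple[str, str] = ("spA", "spB")
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes_dev < 0 or self.n_genes_hk < 0:
            raise ValueError("gene counts must be non-negative")
        if self.n_genes_dev + self.n_genes_hk < 3:
            raise ValueError("need at least 3 genes in total")
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_stages < 2 or self.n_reps < 1:
            raise ValueError("need >= 2 stages and >= 1 replicate")
        if self.peak_weights is not None:
            w = np.asarray(self.peak_weights, dtype=float)
            if w.shape != (self.n_stages,) or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("peak_weights must be n_stages non-negative weights")


@dataclass
class SimulatedCohort:
    """Two expression tables, their homolog map, and the class gene sets."""

    tables: tuple[ExpressionTable, ExpressionTable]
    homolog_map: HomologMap
    gene_sets: dict[str, GeneSet]
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for t in self.tables:
            p = out_dir / f"expression_{t.species_id}.tsv"
            write_expression_table(t, p)
            paths[f"expression_{t.species_id}"] = p
        paths["homologs"] = out_dir / "homologs.tsv"
        write_homolog_map(self.homolog_map, paths["homologs"])
        paths["gene_sets"] = out_dir / "gene_sets.tsv"
        write_gene_sets(self.gene_sets, paths["gene_sets"])
        return paths


def _bump_profiles(
    peaks: np.ndarray, n_stages: int, baseline: float, amplitude: float
) -> np.ndarray:
    """Gene x stage log10 mean profiles: Gaussian bump at each gene's peak."""
    s = np.arange(n_stages)
    return baseline + amplitude * np.exp(
        -((s[None, :] - peaks[:, None]) ** 2) / (2 * PEAK_WIDTH_STAGES**2)
    )


def _draw_peaks(
    rng: np.random.Generator, n: int, cfg: SimulationConfig
) -> np.ndarray:
    if cfg.peak_weights is None:
        return rng.integers(0, cfg.n_stages, size=n)
    w = np.asarray(cfg.peak_weights, dtype=float)
    return rng.choice(cfg.n_stages, size=n, p=w / w.sum())


def simulate_pair(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedCohort:
    """Generate a paired-species cohort under the configured conditions."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_dev, n_hk = cfg.n_genes_dev, cfg.n_genes_hk
    n_genes = n_dev + n_hk
    n_st, n_rep = cfg.n_stages, cfg.n_reps

    mu = np.zeros((2, n_genes, n_st))
    if n_dev:
        peaks = _draw_peaks(rng, n_dev, cfg)
        mu1 = _bump_profiles(peaks, n_st, cfg.baseline, cfg.amplitude)
        peaks_ind = _draw_peaks(rng, n_dev, cfg)
        mu_ind = _bump_profiles(peaks_ind, n_st, cfg.baseline, cfg.amplitude)
        mu[0, :n_dev] = mu1
        mu[1, :n_dev] = (1 - cfg.divergence) * mu1 + cfg.divergence * mu_ind
    if n_hk:
        trend = cfg.baseline + cfg.amplitude * (np.arange(n_st) / n_st)
        offsets = rng.normal(0.0, cfg.hk_offset_sd, size=n_hk)
        hk = trend[None, :] + offsets[:, None]
        mu[0, n_dev:] = hk
        if cfg.hk_divergence:
            offsets_ind = rng.normal(0.0, cfg.hk_offset_sd, size=n_hk)
            hk_ind = trend[None, :] + offsets_ind[:, None]
            mu[1, n_dev:] = (1 - cfg.divergence) * hk + cfg.divergence * hk_ind
        else:
            mu[1, n_dev:] = hk

    hpf = 10.0 * (np.arange(n_st) + 1)
    stage_labels = [f"{int(h)} hpf" for h in hpf]
    samples = tuple(
        Sample(stage_label=lab, hpf=h, replicate_id=f"r{r + 1}")
        for lab, h in zip(stage_labels, hpf)
        for r in range(n_rep)
    )

    tables = []
    for k, sp in enumerate(cfg.species_ids):
        eps = rng.normal(0.0, cfg.noise_sd, size=(n_genes, n_st, n_rep))
        log_vals = mu[k][:, :, None] + eps
        fpkm = np.maximum(10.0**log_vals, 0.0)
        tables.append(
            ExpressionTable(
                species_id=sp,
                gene_ids=tuple(f"{sp}_g{i:05d}" for i in range(n_genes)),
                samples=samples,
                values=fpkm.reshape(n_genes, n_st * n_rep),
            )
        )

    homolog_map = HomologMap(
        records=tuple(
            (f"{cfg.species_ids[0]}_g{i:05d}", f"{cfg.species_ids[1]}_g{i:05d}")
            for i in range(n_genes)
        ),
        species_order=cfg.species_ids,
    )
    ref = cfg.species_ids[0]
    gene_sets: dict[str, GeneSet] = {}
    if n_dev:
        gene_sets["developmental"] = GeneSet(
            name="developmental",
            members=tuple(f"{ref}_g{i:05d}" for i in range(n_dev)),
            category="developmental",
        )
    if n_hk:
        gene_sets["housekeeping"] = GeneSet(
            name="housekeeping",
            members=tuple(f"{ref}_g{i:05d}" for i in range(n_dev, n_genes)),
            category="housekeeping",
        )
    return SimulatedCohort(
        tables=(tables[0], tables[1]),
        homolog_map=homolog_map,
        gene_sets=gene_sets,
        config=cfg,
    )


def sweep(
    cfg_grid: Sequence[SimulationConfig],
    diag_config: DiagonalityConfig | None = None,
    *,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Run the full pipeline on each config and tabulate (delta, sigma, set,
    n_genes, AC, AC_sd, peak_stage, MD)."""
    if not len(cfg_grid):
        raise ValueError("empty config grid")
    rows = []
    for cfg in cfg_grid:
        cohort = simulate_pair(cfg)
        series = [
            log_transform(average_replicates(t), pseudocount) for t in cohort.tables
        ]
        for name, gene_set in cohort.gene_sets.items():
            paired = restrict(
                series[0], series[1], cohort.homolog_map, gene_set=gene_set
            )
            cmat = stage_correlation_matrix(
                paired.a,
                paired.b,
                row_labels=paired.stage_labels_a,
                col_labels=paired.stage_labels_b,
                species=(paired.species_a, paired.species_b),
            )
            summ = summarize(cmat)
            dcfg = diag_config or DiagonalityConfig(seed=cfg.seed)
            md_res = matrix_diagonality(
                paired.a,
                paired.b,
                dcfg,
                allow_small=paired.n_genes < dcfg.n_g,
                set_name=name,
            )
            rows.append(
                {
                    "divergence": cfg.divergence,
                    "noise_sd": cfg.noise_sd,
                    "set": name,
                    "n_genes": paired.n_genes,
                    "AC": summ.ac,
                    "AC_sd": summ.ac_sd,
                    "peak_stage": summ.peak_stage,
                    "MD": md_res.md,
                }
            )
    return pd.DataFrame(rows)
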