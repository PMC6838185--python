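"""Matrix diagonality (MD): is the interspecies correlation pattern
significantly close to a diagonal matrix?

The test asks whether homologous genes of two species are most similar in
expression at *equivalent* developmental stages.  For a gene subsample the
stage correlation matrix C is compared to the ideal time-dependent matrix I
(1 on the diagonal, 0 elsewhere) through the squared Frobenius distance

    d = sum_ij (C_ij - I_ij)^2 .

A permutation test shuffles the stage-column order of one species - i.e.
relabels which stages count as equivalent, while preserving each species'
per-stage expression distributions exactly - and asks how often a random
relabelling is at least as close to I as the observed one.  Because column
permutation changes d only through the permuted diagonal trace
(d(pi) = ||C||^2 - 2 * sum_i C[i, pi(i)] + n), the null distribution is
computed from a single C per subsample.

MD is the count of subsamples (n_g genes drawn without replacement,
n_resamp times) whose permutation p-value falls below alpha: 100 is maximal
diagonality, 0 none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import permutations as _all_permutations
from math import factorial
from typing import Sequence

import numpy as np

from .correlation import cross_correlation

_EXHAUSTIVE_LIMIT = 8  # 8! = 40320 orders; beyond this use Monte Carlo


@dataclass
class DiagonalityConfig:
    """Parameters of the resampling/permutation diagonality test.

    ``stage_window`` selects which aligned stages enter the test: ``"all"``,
    ``"lastK"`` (e.g. the default ``"last5"``, the late embryonic stages), or
    an explicit sequence of stage indices.
    """

    n_g: int = 50
    n_resamp: int = 100
    n_perm: int = 1000
    alpha: float = 0.05
    stage_window: str | Sequence[int] = "last5"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_g < 3:
            raise ValueError("n_g must be >= 3")
        if self.n_resamp < 1 or self.n_perm < 1:
            raise ValueError("n_resamp and n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def resolve_window(self, n_stages: int) -> np.ndarray:
        if isinstance(self.stage_window, str):
            w = self.stage_window.lower()
            if w == "all":
                idx = np.arange(n_stages)
            elif w.startswith("last"):
                k = min(int(w[4:]), n_stages)
                idx = np.arange(n_stages - k, n_stages)
            else:
                raise ValueError(f"unrecognized stage window {self.stage_window!r}")
        else:
            idx = np.asarray(sorted(self.stage_window), dtype=int)
            if np.any(idx < 0) or np.any(idx >= n_stages) or len(set(idx.tolist())) != len(idx):
                raise ValueError("stage window indices out of range or repeated")
        if len(idx) < 2:
            raise ValueError("stage window must cover at least 2 stages")
        return idx


def ideal_matrix(n: int) -> np.ndarray:
    """The ideal time-dependent correlation matrix I: identity of size n."""
    return np.eye(n)


def diagonality_distance(c: np.ndarray) -> float:
    """Squared Frobenius distance of a square correlation matrix from I.

    Zero iff C equals I exactly.  The absolute value is implementation-defined
    (any strictly monotone transform yields the same permutation p-value).
    """
    c = np.asarray(getattr(c, "values", c), dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("diagonality distance requires a square matrix")
    return float(((c - ideal_matrix(c.shape[0])) ** 2).sum())


@dataclass
class PermutationTestResult:
    p_value: float
    d_observed: float
    n_perm: int
    exhaustive: bool = False


def _null_trace_sums(
    c: np.ndarray, n_perm: int, rng: np.random.Generator | None, exhaustive: bool
) -> np.ndarray:
    """Sum_i C[i, pi(i)] for each null column order pi."""
    n = c.shape[0]
    if exhaustive:
        perms = np.array(list(_all_permutations(range(n))))
    else:
        if rng is None:
            rng = np.random.default_rng()
        # uniform random permutations via argsort of iid uniforms
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
    return c[np.arange(n)[None, :], perms].sum(axis=1)


def permutation_test(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    *,
    exhaustive: bool = False,
) -> PermutationTestResult:
    """Permutation p-value for diagonality of the correlation of two matrices.

    ``mat_a`` and ``mat_b`` are homolog-paired gene x stage matrices over the
    same (aligned) stage window.  The null shuffles ``mat_b``'s stage columns
    uniformly.  The Monte-Carlo estimator is the add-one count

        p = (1 + #{d_null <= d_observed}) / (1 + n_perm),

    which can never report p = 0 and returns exactly 1 when the columns are
    exchangeable.  With ``exhaustive=True`` all n! column orders are
    enumerated instead and the exact full-group p-value

        p = #{d_null <= d_observed} / n!

    is returned (the identity order is in the group, so p >= 1/n!); the
    add-one Monte-Carlo estimate converges to this exact value.
    """
    mat_a = np.asarray(mat_a, dtype=float)
    mat_b = np.asarray(mat_b, dtype=float)
    if mat_a.shape[1] != mat_b.shape[1]:
        raise ValueError("stage windows of the two species differ in length")
    if mat_a.shape[1] < 2:
        raise ValueError("at least 2 stages required")
    n = mat_a.shape[1]
    if exhaustive:
        if n > _EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive enumeration of {n}! column orders is not tractable"
            )
        n_perm = factorial(n)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    c = cross_correlation(mat_a, mat_b)
    d_obs = diagonality_distance(c)
    # d(pi) <= d_obs  <=>  sum_i C[i, pi(i)] >= trace(C)
    s_obs = float(np.trace(c))
    s_null = _null_trace_sums(c, n_perm, rng, exhaustive)
    hits = int(np.count_nonzero(s_null >= s_obs))
    if exhaustive:
        p = hits / n_perm
    else:
        p = (1 + hits) / (1 + n_perm)
    return PermutationTestResult(
        p_value=p, d_observed=d_obs, n_perm=n_perm, exhaustive=exhaustive
    )


@dataclass
class DiagonalityResult:
    """MD score with its per-subsample audit trail."""

    md: int
    d_observed: np.ndarray
    p_values: np.ndarray
    config: DiagonalityConfig
    set_name: str = ""
    n_genes: int = 0

    def __post_init__(self) -> None:
        self.d_observed = np.asarray(self.d_observed, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if not 0 <= self.md <= self.config.n_resamp:
            raise ValueError("md out of [0, n_resamp]")

    @property
    def median_p(self) -> float:
        return float(np.median(self.p_values))

    @property
    def median_d(self) -> float:
        return float(np.median(self.d_observed))


def matrix_diagonality(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    config: DiagonalityConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
    allow_small: bool = False,
    set_name: str = "",
) -> DiagonalityResult:
    """MD: significant-permutation-test count over gene resamples.

    Draws ``n_g`` genes without replacement ``n_resamp`` times, runs the
    permutation test on each subsample restricted to the configured stage
    window, and counts p-values strictly below alpha.  If fewer than ``n_g``
    genes are available this is an error unless ``allow_small``, in which
    case every iteration uses all genes (resampling variance is suppressed).
    Reproducible: one generator seeded from ``config.seed`` drives the gene
    draws, and per-subsample permutation streams are split from it.
    """
    config = config or DiagonalityConfig()
    mat_a = np.asarray(mat_a, dtype=float)
    mat_b = np.asarray(mat_b, dtype=float)
    if mat_a.shape[0] != mat_b.shape[0]:
        raise ValueError("matrices must be row-paired (same gene count)")
    window = config.resolve_window(mat_a.shape[1])
    if mat_b.shape[1] != mat_a.shape[1]:
        raise ValueError("stage counts differ; align stages before the MD test")
    aw = mat_a[:, window]
    bw = mat_b[:, window]
    n_genes = aw.shape[0]
    if n_genes < config.n_g:
        if not allow_small:
            raise ValueError(
                f"only {n_genes} genes available but n_g={config.n_g}; pass "
                "allow_small=True to use all genes in every iteration"
            )
        warnings.warn(
            f"gene count {n_genes} < n_g={config.n_g}: using all genes every "
            "iteration; resampling variance is suppressed",
            UserWarning,
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    perm_streams = rng.spawn(config.n_resamp)
    d_list = np.empty(config.n_resamp)
    p_list = np.empty(config.n_resamp)
    for k in range(config.n_resamp):
        if n_genes < config.n_g:
            idx = np.arange(n_genes)
        else:
            idx = rng.choice(n_genes, size=config.n_g, replace=False)
        res = permutation_test(
            aw[idx], bw[idx], n_perm=config.n_perm, rng=perm_streams[k]
        )
        d_list[k] = res.d_observed
        p_list[k] = res.p_value
    md = int(np.count_nonzero(p_list < config.alpha))
    return DiagonalityResult(
        md=md,
        d_observed=d_list,
        p_values=p_list,
        config=config,
        set_name=set_name,
        n_genes=n_genes,
    )
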