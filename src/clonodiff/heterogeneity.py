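"""Repertoire-level heterogeneity summaries.

Clonality (one minus normalized Shannon–Wiener entropy after
downsampling to a fixed molecule count), pairwise clone-count
correlation, the expected clonotype overlap of two samples drawn from a
common repertoire, immunoglobulin isotype composition, and the
Mann–Whitney comparison of control versus experimental summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, log
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import ChainError, DepthError, ValidationError
from .repertoire_io import Repertoire, SamplePair

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# clonality
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClonalitySummary:
    """Downsampled clonality of one sample.

    ``clonality = 1 - H / ln S`` with Shannon entropy ``H`` and observed
    richness ``S``, computed after downsampling to ``target_umi``
    molecules and averaged over ``n_iterations`` independent draws.
    0 = perfectly even repertoire, 1 = monoclonal.
    """

    sample_id: str
    target_umi: int
    n_iterations: int
    clonality_mean: float
    clonality_sd: float
    seed: int


def _clonality_once(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    s = len(counts)
    if s <= 1:
        return 1.0  # monoclonal by convention
    f = counts / counts.sum()
    h = -np.sum(f * np.log(f))
    return float(1.0 - h / log(s))


def clonality(
    rep: Repertoire,
    target_umi: int = 500,
    n_iterations: int = 100,
    seed: int = 0,
) -> ClonalitySummary:
    """Clonality after repeated downsampling to ``target_umi`` molecules.

    Downsampling removes the dependence of entropy-based metrics on
    sequencing depth, so samples of unequal depth become comparable.
    Raises :class:`DepthError` when the sample is too shallow.
    """
    if rep.total_umi < target_umi:
        raise DepthError(
            f"{rep.sample_id}: total_umi {rep.total_umi} < target {target_umi}"
        )
    rng = np.random.default_rng(seed)
    counts = rep.counts()
    values = np.empty(n_iterations)
    for i in range(n_iterations):
        drawn = rng.multivariate_hypergeometric(counts, target_umi)
        values[i] = _clonality_once(drawn)
    return ClonalitySummary(
        sample_id=rep.sample_id,
        target_umi=target_umi,
        n_iterations=n_iterations,
        clonality_mean=float(values.mean()),
        clonality_sd=float(values.std(ddof=1)) if n_iterations > 1 else 0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# pairwise correlation
# ---------------------------------------------------------------------------


def pairwise_correlation(
    pair: SamplePair,
    scope: Literal["union", "intersection"] = "union",
    log_transform: bool = False,
    pseudocount: float = 0.5,
) -> float:
    """Pearson correlation of the two UMI-count vectors of a pair.

    Under the default ``union`` scope a clone absent from one sample
    contributes a zero, so presence/absence discordance lowers the
    correlation — the reading of r as a heterogeneity measure.  The
    ``intersection`` scope restricts to clones detected in both samples.
    """
    a, b = pair.counts()
    if scope == "intersection":
        keep = (a > 0) & (b > 0)
        a, b = a[keep], b[keep]
    elif scope != "union":
        raise ValidationError(f"unknown scope {scope!r}")
    if len(a) < 2:
        raise ValidationError("correlation needs >= 2 clones in scope")
    x = a.astype(float)
    y = b.astype(float)
    if log_transform:
        x = np.log(x + pseudocount)
        y = np.log(y + pseudocount)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined: a count vector has zero variance")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# expected overlap under two-sample sampling
# ---------------------------------------------------------------------------


def expected_overlap(
    n_a: int,
    n_b: int,
    repertoire: int | Sequence[int],
) -> float:
    """Expected number of clonotypes shared by two independent samples.

    Both samples are drawn without replacement from the *same* cell
    repertoire: ``n_a`` cells into sample A, independently ``n_b`` cells
    into sample B.  For clone sizes ``c_i`` (total ``T`` cells) the
    expectation is ``sum_i (1 - h(c_i, n_a, T)) (1 - h(c_i, n_b, T))``
    where ``h`` is the hypergeometric probability of drawing no member
    of clone ``i``.  When ``repertoire`` is an integer ``S`` the
    repertoire is ``S`` singleton clones and the expression collapses to
    ``n_a * n_b / S`` — e.g. 10-cell samples from 100 singletons share
    1 clonotype on average, 50-cell samples share 25.
    """
    if isinstance(repertoire, (int, np.integer)):
        s = int(repertoire)
        if n_a > s or n_b > s:
            raise ValidationError("sample size exceeds repertoire size")
        return n_a * n_b / s
    sizes = np.asarray(repertoire, dtype=np.int64)
    if np.any(sizes < 0):
        raise ValidationError("clone sizes must be non-negative")
    total = int(sizes.sum())
    if n_a > total or n_b > total:
        raise ValidationError("sample size exceeds total cells")
    # h(c, n, T) = C(T-c, n) / C(T, n), the chance a clone is missed entirely
    miss_a = stats.hypergeom.pmf(0, total, sizes, n_a)
    miss_b = stats.hypergeom.pmf(0, total, sizes, n_b)
    return float(np.sum((1.0 - miss_a) * (1.0 - miss_b)))


def overlap_monte_carlo(
    n_a: int,
    n_b: int,
    repertoire: int | Sequence[int],
    n_draws: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo mean and standard error of the shared-clonotype count.

    Each draw independently samples ``n_a`` and ``n_b`` cells without
    replacement from the clone-size vector and counts the clones present
    in both samples.  Used as the sampling cross-check for
    :func:`expected_overlap`.
    """
    if isinstance(repertoire, (int, np.integer)):
        sizes = np.ones(int(repertoire), dtype=np.int64)
    else:
        sizes = np.asarray(repertoire, dtype=np.int64)
    rng = np.random.default_rng(seed)
    shared = np.empty(n_draws)
    for i in range(n_draws):
        a = rng.multivariate_hypergeometric(sizes, n_a)
        b = rng.multivariate_hypergeometric(sizes, n_b)
        shared[i] = np.count_nonzero((a > 0) & (b > 0))
    return float(shared.mean()), float(shared.std(ddof=1) / np.sqrt(n_draws))


# ---------------------------------------------------------------------------
# isotype composition
# ---------------------------------------------------------------------------


def isotype_proportions(rep: Repertoire) -> dict[str, float]:
    """Fraction of total UMIs per immunoglobulin isotype.

    Computed on molecule counts (not clonotype counts), so transcript-
    rich plasma-cell clones dominate the composition as they do in
    RNA-based IGH libraries.  Unlabeled clonotypes are pooled under
    ``"unknown"``.
    """
    if rep.chain != "IGH":
        raise ChainError(f"isotype proportions require IGH, got {rep.chain}")
    labels = rep.table["isotype"].replace("", "unknown")
    totals = rep.table.groupby(labels)["umi_count"].sum().sort_index()
    fractions = (totals / rep.total_umi).to_dict()
    return {str(k): float(v) for k, v in fractions.items()}


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney U of x over y with 0.5 credit for ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def group_comparison(
    control_values: Sequence[float],
    experimental_values: Sequence[float],
    exact_max_n: int = 8,
) -> float:
    """Two-sided Mann–Whitney U p-value for two groups of summaries.

    For groups of at most ``exact_max_n`` values each, the p-value is
    exact: every assignment of the pooled values to the two groups is
    enumerated and ties contribute half counts to U, so identical groups
    give p = 1.  Larger groups use the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(control_values, dtype=float)
    y = np.asarray(experimental_values, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    if n1 <= exact_max_n and n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        mu = n1 * n2 / 2.0
        dev_obs = abs(_u_statistic(x, y) - mu)
        total = comb(n1 + n2, n1)
        hits = 0
        idx_all = np.arange(n1 + n2)
        for pick in combinations(idx_all, n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(pick)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)
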