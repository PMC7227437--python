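"""Beta-binomial noise model for differential clonal abundance.

Control replicates split from one homogenized single-cell suspension
differ only by technical noise: cell sampling, cell-to-cell variation in
receptor transcript expression, and molecule sampling during library
preparation.  That noise is overdispersed relative to a binomial split,
and the overdispersion depends on clone frequency.  This module fits a
frequency-dependent beta-binomial noise model on control replicate pairs
and uses it to call clonotypes whose frequency difference between two
samples exceeds what replicate noise allows at a chosen FDR.

Parametrization: a clone at frequency ``f`` observed at depth ``n``
contributes a count ``K ~ BetaBinomial(n, alpha, beta)`` with

    alpha = f (1 - rho) / rho,   beta = (1 - f)(1 - rho) / rho,

so the mean count is ``n f`` and ``rho = 1 / (alpha + beta + 1)`` is the
overdispersion: ``rho -> 0`` recovers the binomial split, ``rho -> 1``
maximal dispersion.  ``rho`` is fitted by maximum likelihood in bins of
log10 pooled clone frequency and interpolated piecewise-linearly between
bin centers (clamped at the ends).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import FitError, TrainingDataError, ValidationError
from .repertoire_io import SamplePair

logger = logging.getLogger(__name__)

#: Fraction of the marginal replicate overdispersion that remains in the
#: deviations of one margin around the pooled two-sample frequency: the
#: pooled estimate absorbs the shared half for pairs of comparable depth.
_POOLED_SHRINK = 0.5


# ---------------------------------------------------------------------------
# beta-binomial pmf in (mean frequency, overdispersion) parametrization
# ---------------------------------------------------------------------------


def _ab(mean_freq: float, rho: float) -> tuple[float, float]:
    s = (1.0 - rho) / rho
    return mean_freq * s, (1.0 - mean_freq) * s


def betabinom_logpmf(
    k: int | np.ndarray,
    n: int | np.ndarray,
    mean_freq: float,
    rho: float,
) -> float | np.ndarray:
    """Log pmf of the beta-binomial in mean/overdispersion form.

    ``rho = 0`` is the binomial limit.  Raises :class:`ValidationError`
    for out-of-range arguments.
    """
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    if not (0.0 < mean_freq < 1.0):
        raise ValidationError(f"mean_freq must be in (0,1), got {mean_freq}")
    if not (0.0 <= rho < 1.0):
        raise ValidationError(f"rho must be in [0,1), got {rho}")
    if np.any(k_arr < 0) or np.any(k_arr > n_arr):
        raise ValidationError("k must satisfy 0 <= k <= n")
    if rho < 1e-12:  # (1-rho)/rho overflows for denormal rho; binomial limit
        rho = 0.0
    if rho == 0.0:
        out = stats.binom.logpmf(k_arr, n_arr, mean_freq)
    else:
        a, b = _ab(mean_freq, rho)
        out = stats.betabinom.logpmf(k_arr, n_arr, a, b)
    return out if out.ndim else float(out)


def betabinom_two_sided_p(
    k: int, n: int, mean_freq: float, rho: float
) -> float:
    """Two-sided tail-doubled p-value for one margin.

    ``p = min(1, 2 min(P(K <= k), P(K >= k)))`` with
    ``K ~ BetaBinomial(n, mean_freq, rho)``.  Both tails include the
    observed point mass, so ``p`` is conservative and never below the
    pmf at ``k``.
    """
    if rho < 1e-12:
        lower = stats.binom.cdf(k, n, mean_freq)
        upper = stats.binom.sf(k - 1, n, mean_freq)
    else:
        a, b = _ab(mean_freq, rho)
        lower = stats.betabinom.cdf(k, n, a, b)
        upper = stats.betabinom.sf(k - 1, n, a, b)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _two_sided_p_vec(
    k: np.ndarray, n: int, mean_freq: np.ndarray, rho: np.ndarray
) -> np.ndarray:
    """Vectorized tail-doubled p over clones (per-clone frequency/rho)."""
    rho = np.maximum(rho, 1e-12)  # rho floor keeps us off the binomial branch
    s = (1.0 - rho) / rho
    a = mean_freq * s
    b = (1.0 - mean_freq) * s
    lower = stats.betabinom.cdf(k, n, a, b)
    upper = stats.betabinom.sf(k - 1, n, a, b)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Settings for the binned maximum-likelihood dispersion fit."""

    n_bins: int = 8
    min_clones_per_bin: int = 20
    min_total_clones: int = 100
    rho_floor: float = 1e-6
    rho_ceil: float = 1.0 - 1e-6
    xatol: float = 1e-4  # tolerance on log10(rho)
    max_iter: int = 200


@dataclass
class BetaBinomialNoiseModel:
    """Frequency-dependent overdispersion fitted on control replicates.

    ``log10_freq_nodes`` / ``rho_nodes`` define the piecewise-linear
    dispersion curve; outside the node range the curve is clamped to the
    end values.  ``train_depths`` records the UMI totals of the training
    pairs for the depth-compatibility guard.
    """

    log10_freq_nodes: np.ndarray
    rho_nodes: np.ndarray
    train_depths: list[tuple[int, int]]
    train_clone_count: int
    fit_loglik: float
    config: FitConfig = field(default_factory=FitConfig)
    #: Cell counts behind the training libraries, when known.
    train_cell_depths: list[tuple[int, int] | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.log10_freq_nodes = np.asarray(self.log10_freq_nodes, dtype=float)
        self.rho_nodes = np.asarray(self.rho_nodes, dtype=float)
        if len(self.log10_freq_nodes) != len(self.rho_nodes) or len(self.rho_nodes) == 0:
            raise ValidationError("dispersion curve needs >= 1 matching node pair")
        if not self.train_depths:
            raise ValidationError("train_depths must be non-empty")

    def rho(self, freq: float | np.ndarray) -> float | np.ndarray:
        """Overdispersion at clone frequency ``freq`` (clamped ends)."""
        out = np.interp(
            np.log10(np.asarray(freq, dtype=float)),
            self.log10_freq_nodes,
            self.rho_nodes,
        )
        return out if np.ndim(out) else float(out)

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "log10_freq_nodes": self.log10_freq_nodes.tolist(),
            "rho_nodes": self.rho_nodes.tolist(),
            "train_depths": [list(d) for d in self.train_depths],
            "train_cell_depths": [
                list(d) if d is not None else None for d in self.train_cell_depths
            ],
            "train_clone_count": self.train_clone_count,
            "fit_loglik": self.fit_loglik,
            "config": asdict(self.config),
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BetaBinomialNoiseModel":
        p = Path(source)
        doc = json.loads(p.read_text() if p.exists() else str(source))
        return cls(
            log10_freq_nodes=np.asarray(doc["log10_freq_nodes"]),
            rho_nodes=np.asarray(doc["rho_nodes"]),
            train_depths=[tuple(d) for d in doc["train_depths"]],
            train_clone_count=int(doc["train_clone_count"]),
            fit_loglik=float(doc["fit_loglik"]),
            config=FitConfig(**doc["config"]),
            train_cell_depths=[
                tuple(d) if d is not None else None
                for d in doc.get("train_cell_depths", [])
            ],
        )


def _bin_neg_loglik(
    log10_rho: float,
    k_a: np.ndarray,
    n_a: np.ndarray,
    k_b: np.ndarray,
    n_b: np.ndarray,
    f0: np.ndarray,
) -> float:
    """Negative symmetrized log-likelihood of one frequency bin.

    ``log10_rho`` parametrizes the *marginal* replicate overdispersion;
    each margin is scored against the pooled frequency, around which
    the null spread is half the marginal dispersion for replicates of
    comparable depth (the pooled estimate absorbs the shared half of
    the between-replicate variance), hence the factor ``_POOLED_SHRINK``.
    """
    rho = _POOLED_SHRINK * 10.0**log10_rho
    s = (1.0 - rho) / rho
    a = f0 * s
    b = (1.0 - f0) * s
    ll = stats.betabinom.logpmf(k_a, n_a, a, b) + stats.betabinom.logpmf(k_b, n_b, a, b)
    return -float(np.sum(ll))


def fit_noise_model(
    control_pairs: Sequence[SamplePair],
    config: FitConfig = FitConfig(),
) -> BetaBinomialNoiseModel:
    """Fit the dispersion curve on control replicate pairs.

    Each clone contributes the likelihood of both replicate counts given
    the pooled frequency (symmetrized training: the model is invariant
    to replicate ordering).  Clones are binned by log10 pooled frequency
    into ``config.n_bins`` equal-width bins; underpopulated bins are
    merged with neighbours; the per-bin marginal overdispersion ``rho``
    maximizes the bin likelihood
    over ``[rho_floor, rho_ceil]``.  Deterministic given inputs.
    """
    if not control_pairs:
        raise TrainingDataError("at least one control pair is required")
    ka, na, kb, nb = [], [], [], []
    depths: list[tuple[int, int]] = []
    cell_depths: list[tuple[int, int] | None] = []
    for pair in control_pairs:
        ca, cb = pair.counts()
        ka.append(ca)
        kb.append(cb)
        na.append(np.full(len(ca), pair.depth_a))
        nb.append(np.full(len(cb), pair.depth_b))
        depths.append((pair.depth_a, pair.depth_b))
        cells_a, cells_b = pair.rep_a.n_cells, pair.rep_b.n_cells
        cell_depths.append(
            (cells_a, cells_b) if cells_a is not None and cells_b is not None else None
        )
    k_a = np.concatenate(ka)
    k_b = np.concatenate(kb)
    n_a = np.concatenate(na)
    n_b = np.concatenate(nb)
    keep = (k_a + k_b) > 0
    k_a, k_b, n_a, n_b = k_a[keep], k_b[keep], n_a[keep], n_b[keep]
    n_clones = len(k_a)
    if n_clones < config.min_total_clones:
        raise TrainingDataError(
            f"{n_clones} clones after filtering; need >= {config.min_total_clones} to train"
        )
    f0 = (k_a + k_b) / (n_a + n_b)
    logf = np.log10(f0)

    # equal-width bins over the observed range, merged left-to-right so
    # that every group holds >= min_clones_per_bin clones
    lo, hi = float(logf.min()), float(logf.max())
    if hi - lo < 1e-12:
        edges = np.array([lo - 0.5, hi + 0.5])
    else:
        edges = np.linspace(lo, hi, config.n_bins + 1)
        edges[-1] = np.nextafter(edges[-1], np.inf)
    assignment = np.clip(np.searchsorted(edges, logf, side="right") - 1, 0, len(edges) - 2)
    groups: list[np.ndarray] = []
    current: list[int] = []
    for b in range(len(edges) - 1):
        current.append(b)
        idx = np.flatnonzero(np.isin(assignment, current))
        if len(idx) >= config.min_clones_per_bin:
            groups.append(idx)
            current = []
    if current:
        idx = np.flatnonzero(np.isin(assignment, current))
        if len(idx):
            if groups:
                groups[-1] = np.concatenate([groups[-1], idx])
            else:
                groups.append(idx)

    centers: list[float] = []
    rhos: list[float] = []
    total_ll = 0.0
    lb, ub = np.log10(config.rho_floor), np.log10(config.rho_ceil)
    for gi, idx in enumerate(groups):
        res = optimize.minimize_scalar(
            _bin_neg_loglik,
            bounds=(lb, ub),
            args=(k_a[idx], n_a[idx], k_b[idx], n_b[idx], f0[idx]),
            method="bounded",
            options={"xatol": config.xatol, "maxiter": config.max_iter},
        )
        if not res.success:
            raise FitError(f"dispersion optimizer failed to converge in bin {gi}: {res.message}")
        centers.append(float(np.mean(logf[idx])))
        rhos.append(float(10.0**res.x))
        total_ll += -float(res.fun)
    order = np.argsort(centers)
    model = BetaBinomialNoiseModel(
        log10_freq_nodes=np.asarray(centers)[order],
        rho_nodes=np.asarray(rhos)[order],
        train_depths=depths,
        train_clone_count=n_clones,
        fit_loglik=total_ll,
        config=config,
        train_cell_depths=cell_depths,
    )
    logger.info(
        "noise model fitted: clones=%d bins=%d loglik=%.1f rho=[%.2g..%.2g]",
        n_clones,
        len(groups),
        total_ll,
        model.rho_nodes.min(),
        model.rho_nodes.max(),
    )
    return model


# ---------------------------------------------------------------------------
# testing
# ---------------------------------------------------------------------------


def test_clone(
    k_a: int, n_a: int, k_b: int, n_b: int, model: BetaBinomialNoiseModel
) -> float:
    """Two-sided p-value for one clone against the replicate noise model.

    The null frequency is the pooled estimate
    ``f0 = (k_a + k_b) / (n_a + n_b)``; each margin is scored by the
    tail-doubled two-sided p at the conditional dispersion
    ``rho(f0) / 2`` (deviations around the pooled frequency carry half
    the marginal replicate dispersion) and the two margins are combined
    as their maximum, which makes the p-value invariant to swapping the
    two samples and conservative.
    """
    if k_a + k_b == 0:
        raise ValidationError("clone absent from both samples cannot be tested")
    f0 = (k_a + k_b) / (n_a + n_b)
    rho = _POOLED_SHRINK * model.rho(f0)
    p_a = betabinom_two_sided_p(k_a, n_a, f0, rho)
    p_b = betabinom_two_sided_p(k_b, n_b, f0, rho)
    return max(p_a, p_b)


@dataclass
class ExpansionCallSet:
    """Per-clone differential-abundance results for one sample pair.

    ``table`` has one row per tested clone with counts, depths,
    frequencies, ``p``, BH-adjusted ``q`` and the directional ``call``
    (``expanded_in_b`` / ``contracted_in_b`` / ``unchanged``).
    """

    pair_id: str
    table: pd.DataFrame
    fdr_threshold: float
    warnings: list[str] = field(default_factory=list)

    @property
    def n_expanded(self) -> int:
        return int((self.table["call"] == "expanded_in_b").sum())

    @property
    def n_contracted(self) -> int:
        return int((self.table["call"] == "contracted_in_b").sum())

    @property
    def n_called(self) -> int:
        return self.n_expanded + self.n_contracted

    def summary(self) -> dict:
        return {
            "pair_id": self.pair_id,
            "n_tested": int(len(self.table)),
            "n_expanded": self.n_expanded,
            "n_contracted": self.n_contracted,
            "fdr_threshold": self.fdr_threshold,
            "warnings": list(self.warnings),
        }

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def call_expansions(
    pair: SamplePair,
    model: BetaBinomialNoiseModel,
    fdr: float = 0.05,
) -> ExpansionCallSet:
    """Test every clone of a (filtered) pair and call directions at ``fdr``.

    p-values are Benjamini–Hochberg adjusted across all tested clones of
    the pair; a clone is called when ``q <= fdr``, with the direction
    taken from the sign of ``f_b - f_a`` (ties are never called).
    """
    warnings: list[str] = []
    check = depth_compatibility_check(model, pair)
    if not check.ok:
        warnings.append(check.message)
    k_a, k_b = pair.counts()
    tested = (k_a + k_b) > 0
    k_a, k_b = k_a[tested], k_b[tested]
    joint = pair.joint.loc[tested].reset_index(drop=True)
    if len(k_a) == 0:
        warnings.append(f"{pair.pair_id}: empty testable set")
        empty = joint.assign(p=[], q=[], call=[])
        return ExpansionCallSet(pair.pair_id, empty, fdr, warnings)
    n_a, n_b = pair.depth_a, pair.depth_b
    f0 = (k_a + k_b) / (n_a + n_b)
    rho = _POOLED_SHRINK * np.asarray(model.rho(f0))
    p = np.maximum(
        _two_sided_p_vec(k_a, n_a, f0, rho),
        _two_sided_p_vec(k_b, n_b, f0, rho),
    )
    _, q, _, _ = multipletests(p, method="fdr_bh")
    q = np.maximum(q, p)  # guard against float dips below the raw p
    f_a = k_a / n_a
    f_b = k_b / n_b
    call = np.where(
        (q <= fdr) & (f_b > f_a),
        "expanded_in_b",
        np.where((q <= fdr) & (f_b < f_a), "contracted_in_b", "unchanged"),
    )
    out = joint.copy()
    out["f_a"] = f_a
    out["f_b"] = f_b
    out["p"] = p
    out["q"] = q
    out["call"] = call
    return ExpansionCallSet(pair.pair_id, out, fdr, warnings)


# ---------------------------------------------------------------------------
# depth-compatibility guard
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepthCheckResult:
    ok: bool
    message: str
    ratio: float


def depth_compatibility_check(
    model: BetaBinomialNoiseModel,
    pair: SamplePair,
    max_ratio: float = 3.0,
) -> DepthCheckResult:
    """Warn when a pair's depth is incompatible with the training depth.

    A noise model trained on replicates of very different depth
    mis-estimates the dispersion of the pair under test and produces
    false-positive clonal expansions.  Depth is compared both in UMI
    totals and — when both the model and the pair carry them — in cell
    counts, since a library of ordinary molecule count can still rest
    on few cells and carry the full cell-sampling noise.  For each
    training pair the depths (sorted within the pair) are compared
    elementwise to the pair under test; the model is compatible if
    *some* training pair is within ``max_ratio`` in both elements.
    """

    def fold(x: float, y: float) -> float:
        return max(x, y) / min(x, y)

    def pairwise(train: list, probe: tuple) -> float:
        probe_sorted = sorted(probe)
        return min(
            max(fold(td[0], probe_sorted[0]), fold(td[1], probe_sorted[1]))
            for td in (sorted(d) for d in train)
        )

    umi_ratio = pairwise(model.train_depths, (pair.depth_a, pair.depth_b))
    worst, kind = umi_ratio, "UMI"
    cells_a, cells_b = pair.rep_a.n_cells, pair.rep_b.n_cells
    train_cells = [d for d in model.train_cell_depths if d is not None]
    if train_cells and cells_a is not None and cells_b is not None:
        cell_ratio = pairwise(train_cells, (cells_a, cells_b))
        if cell_ratio > worst:
            worst, kind = cell_ratio, "cell"
    if worst > max_ratio:
        return DepthCheckResult(
            ok=False,
            message=(
                f"{pair.pair_id}: {kind} depths differ from the model's "
                f"training depths by a factor of {worst:.1f} "
                f"(> {max_ratio:g}); dispersion estimates do not transfer "
                "across depth and the model may report false-positive "
                "clonal expansions"
            ),
            ratio=worst,
        )
    return DepthCheckResult(ok=True, message="", ratio=worst)
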