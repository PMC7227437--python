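"""Ground-truth repertoire simulator.

Emulates the noise cascade that separates a tissue's true clonal
composition from an observed clonotype table: heavy-tailed clone sizes,
cell sampling from the tissue, per-cell receptor-transcript expression
with log-normal dispersion (immunoglobulin output differs by roughly
2:5:500 between naive, memory and plasma B cells), and molecule (UMI)
sampling during library preparation.  Control replicates are produced by
partitioning a single cell suspension; experimental sections are
independent draws from tissue fragments that may carry spiked-in local
clonal expansions, recorded as ground truth for power evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DepthError, ValidationError
from .repertoire_io import IDENTITY_NT, Repertoire, _GENETIC_CODE

logger = logging.getLogger(__name__)

#: Relative receptor-transcript output per cell by lymphocyte subset.
#: B-cell subsets follow the ~2:5:500 naive:memory:plasma ratio; effector
#: T cells are the single-subset reference.
SUBSET_EXPRESSION: dict[str, float] = {
    "effector": 1.0,
    "naive": 2.0,
    "memory": 5.0,
    "plasma": 500.0,
}

#: Default isotype frequencies for synthetic IGH clones.
DEFAULT_ISOTYPE_MIX: dict[str, float] = {
    "IGHM": 0.30,
    "IGHG1": 0.25,
    "IGHG2": 0.10,
    "IGHG3": 0.05,
    "IGHG4": 0.02,
    "IGHA1": 0.20,
    "IGHA2": 0.05,
    "IGHE": 0.03,
}

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in _GENETIC_CODE.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
_INNER_AA = np.array(sorted(set(_GENETIC_CODE.values()) - {"*", "C", "F", "W"}))


@dataclass
class GroundTruthRepertoire:
    """True clonal composition of a synthetic tissue.

    ``cell_counts`` are per-clone cell numbers in the whole tissue;
    ``expression_rate`` is the expected receptor-transcript count per
    cell of each clone (before per-cell log-normal dispersion).
    ``section_spikes`` records, per generated experimental section, the
    clone indices whose cell counts were multiplied and by which fold.
    """

    chain: str
    cdr3_nt: np.ndarray
    cdr3_aa: np.ndarray
    v_gene: np.ndarray
    j_gene: np.ndarray
    isotype: np.ndarray
    subset: np.ndarray
    cell_counts: np.ndarray
    expression_rate: np.ndarray
    powerlaw_exponent: float
    section_spikes: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def n_clones(self) -> int:
        return len(self.cell_counts)

    @property
    def total_cells(self) -> int:
        return int(self.cell_counts.sum())

    def frequencies(self) -> np.ndarray:
        return self.cell_counts / self.total_cells

    def clone_key(self, i: int) -> tuple[str, ...]:
        """Identity tuple of clone ``i`` under the default nt identity."""
        return (str(self.cdr3_nt[i]), str(self.v_gene[i]), str(self.j_gene[i]))

    def spiked_keys(self, section_id: str) -> list[tuple[str, ...]]:
        return [self.clone_key(i) for i in self.section_spikes.get(section_id, {})]

    def to_repertoire(
        self, umi_counts: np.ndarray, sample_id: str, n_cells: int | None = None
    ) -> Repertoire:
        """Materialize observed UMI counts as a clonotype table."""
        keep = umi_counts > 0
        table = pd.DataFrame(
            {
                "cdr3_nt": self.cdr3_nt[keep],
                "cdr3_aa": self.cdr3_aa[keep],
                "v_gene": self.v_gene[keep],
                "j_gene": self.j_gene[keep],
                "isotype": self.isotype[keep],
                "umi_count": umi_counts[keep].astype(np.int64),
            }
        )
        return Repertoire(sample_id, self.chain, table, identity=IDENTITY_NT, n_cells=n_cells)


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------


def _random_cdr3(rng: np.random.Generator, chain: str) -> tuple[str, str]:
    """Random in-frame CDR3: C...F (TRB) / C...W-or-F (IGH) framing."""
    length = int(rng.integers(8, 17))
    last = "F" if chain == "TRB" else str(rng.choice(["W", "F"]))
    aa = "C" + "".join(rng.choice(_INNER_AA, size=length - 2)) + last
    nt = "".join(str(rng.choice(_CODONS_BY_AA[a])) for a in aa)
    return nt, aa


def _gene_calls(rng: np.random.Generator, chain: str, n: int) -> tuple[np.ndarray, np.ndarray]:
    if chain == "TRB":
        v = np.array([f"TRBV{i}" for i in rng.integers(1, 31, size=n)])
        j = np.array([f"TRBJ{i}-{k}" for i, k in zip(rng.integers(1, 3, size=n), rng.integers(1, 7, size=n))])
    else:
        v = np.array([f"IGHV{i}-{k}" for i, k in zip(rng.integers(1, 8, size=n), rng.integers(1, 70, size=n))])
        j = np.array([f"IGHJ{i}" for i in rng.integers(1, 7, size=n)])
    return v, j


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of ``total * weights / sum(weights)``.

    Deterministic, count-conserving; uniform weights with total == n
    give exactly one cell per clone.
    """
    quota = total * weights / weights.sum()
    counts = np.floor(quota).astype(np.int64)
    remainder = total - int(counts.sum())
    if remainder > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


# ---------------------------------------------------------------------------
# base repertoire
# ---------------------------------------------------------------------------


def generate_base_repertoire(
    n_clones: int,
    powerlaw_exponent: float,
    total_cells: int,
    subset_mix: Mapping[str, float],
    seed: int,
    chain: str = "TRB",
    base_expression: float = 1.0,
    isotype_mix: Mapping[str, float] | None = None,
    size_model: str = "zipf",
) -> GroundTruthRepertoire:
    """Draw a ground-truth tissue with power-law clone sizes.

    With ``size_model="zipf"`` clone sizes are drawn from a discrete
    power law (zeta distribution with the given exponent); with
    ``size_model="rank"`` they follow the deterministic rank-abundance
    law ``c_i ∝ i**(-1/(exponent-1))`` with the same size-distribution
    exponent but no sampling variance in the head of the distribution —
    useful when a preset must hit a target clonality reproducibly.
    Either way the sizes are renormalized to ``total_cells`` by
    largest-remainder rounding, so the tail shape is preserved and the
    total is exact.  Subsets are assigned independently per clone;
    expression rates are ``base_expression`` times the subset factor
    (2/5/500 for naive/memory/plasma B cells, 1 for effector T cells).
    """
    if powerlaw_exponent <= 1.0:
        raise ValidationError("powerlaw_exponent must be > 1")
    if total_cells <= 0:
        raise ValidationError("infeasible total_cells")
    mix_labels = list(subset_mix)
    mix_p = np.asarray([subset_mix[s] for s in mix_labels], dtype=float)
    if abs(mix_p.sum() - 1.0) > 1e-9 or np.any(mix_p < 0):
        raise ValidationError("subset_mix proportions must be non-negative and sum to 1")
    unknown = set(mix_labels) - set(SUBSET_EXPRESSION)
    if unknown:
        raise ValidationError(f"unknown subsets: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    if size_model == "zipf":
        # zeta sampling saturates at ~1 for large exponents -> all singletons
        raw = rng.zipf(min(powerlaw_exponent, 50.0), size=n_clones).astype(float)
    elif size_model == "rank":
        raw = np.arange(1, n_clones + 1, dtype=float) ** (-1.0 / (powerlaw_exponent - 1.0))
    else:
        raise ValidationError(f"unknown size_model {size_model!r}")
    cell_counts = _apportion(raw, total_cells)

    subset = rng.choice(mix_labels, size=n_clones, p=mix_p)
    rate = base_expression * np.array([SUBSET_EXPRESSION[s] for s in subset])

    seen: set[str] = set()
    nts, aas = [], []
    for _ in range(n_clones):
        nt, aa = _random_cdr3(rng, chain)
        while nt in seen:
            nt, aa = _random_cdr3(rng, chain)
        seen.add(nt)
        nts.append(nt)
        aas.append(aa)
    v, j = _gene_calls(rng, chain, n_clones)
    if chain == "IGH":
        mix = isotype_mix or DEFAULT_ISOTYPE_MIX
        iso_labels = list(mix)
        iso_p = np.asarray([mix[k] for k in iso_labels], dtype=float)
        iso_p = iso_p / iso_p.sum()
        isotype = rng.choice(iso_labels, size=n_clones, p=iso_p)
    else:
        isotype = np.full(n_clones, "")

    return GroundTruthRepertoire(
        chain=chain,
        cdr3_nt=np.array(nts),
        cdr3_aa=np.array(aas),
        v_gene=v,
        j_gene=j,
        isotype=isotype,
        subset=subset,
        cell_counts=cell_counts,
        expression_rate=rate,
        powerlaw_exponent=powerlaw_exponent,
    )


def singleton_preset(n_clones: int = 100, seed: int = 0, chain: str = "TRB") -> GroundTruthRepertoire:
    """Toy tissue of ``n_clones`` clones, one cell each.

    The textbook overlap example: two 10-cell samples from 100 singleton
    clones share one clonotype on average.
    """
    return generate_base_repertoire(
        n_clones=n_clones,
        powerlaw_exponent=100.0,
        total_cells=n_clones,
        subset_mix={"effector": 1.0},
        seed=seed,
        chain=chain,
    )


# ---------------------------------------------------------------------------
# two-stage sampling: cells -> per-cell transcripts -> UMIs
# ---------------------------------------------------------------------------


def _draw_cells(pool: np.ndarray, n_cells: int, rng: np.random.Generator) -> np.ndarray:
    if n_cells > int(pool.sum()):
        raise DepthError(f"cannot draw {n_cells} cells from a pool of {int(pool.sum())}")
    return rng.multivariate_hypergeometric(pool, n_cells, method="marginals")


def _transcript_pool(
    cells: np.ndarray,
    rates: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
    poisson: bool = True,
) -> np.ndarray:
    """Per-clone transcript totals from per-cell expression draws.

    Each cell of clone ``i`` emits ``Poisson(rate_i * L)`` molecules,
    ``L`` log-normal with unit mean and log-sd ``sigma`` (``sigma = 0``
    and ``poisson=False`` give the deterministic no-noise limit).
    """
    idx = np.repeat(np.arange(len(cells)), cells)
    lam = rates[idx]
    if sigma > 0:
        lam = lam * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(idx))
    per_cell = rng.poisson(lam) if poisson else np.round(lam).astype(np.int64)
    return np.bincount(idx, weights=per_cell, minlength=len(cells)).astype(np.int64)


def _draw_umis(pool: np.ndarray, n_umi: int, rng: np.random.Generator) -> np.ndarray:
    total = int(pool.sum())
    if n_umi > total:
        raise DepthError(f"cannot draw {n_umi} UMIs from a transcript pool of {total}")
    return rng.multivariate_hypergeometric(pool, n_umi, method="marginals")


def _sample_repertoire(
    gt: GroundTruthRepertoire,
    cells: np.ndarray,
    umis: int | None,
    sigma: float,
    rng: np.random.Generator,
    sample_id: str,
    poisson: bool = True,
) -> Repertoire:
    transcripts = _transcript_pool(cells, gt.expression_rate, sigma, rng, poisson=poisson)
    if umis is None:
        counts = transcripts
    else:
        counts = _draw_umis(transcripts, umis, rng)
    return gt.to_repertoire(counts, sample_id, n_cells=int(cells.sum()))


def split_control_replicates(
    gt: GroundTruthRepertoire,
    n_replicates: int,
    cells_per_replicate: int,
    umis_per_replicate: int | None,
    seed: int,
    sigma: float = 1.0,
    poisson: bool = True,
    sample_prefix: str = "ctrl",
) -> list[Repertoire]:
    """Split one cell suspension into technical replicates.

    Cells are partitioned without replacement (sequential multivariate
    hypergeometric draws from the shrinking pool), then each replicate's
    transcript pool is generated and subsampled to
    ``umis_per_replicate`` molecules.  Differences between the outputs
    are pure technical noise — the training material for the
    beta-binomial model.  ``umis_per_replicate=None`` keeps the full
    transcript pool.
    """
    if n_replicates * cells_per_replicate > gt.total_cells:
        raise DepthError(
            f"{n_replicates} x {cells_per_replicate} cells exceed the tissue's {gt.total_cells}"
        )
    rng = np.random.default_rng(seed)
    remaining = gt.cell_counts.copy()
    reps = []
    for r in range(n_replicates):
        cells = _draw_cells(remaining, cells_per_replicate, rng)
        remaining -= cells
        reps.append(
            _sample_repertoire(
                gt, cells, umis_per_replicate, sigma, rng, f"{sample_prefix}{r + 1}", poisson
            )
        )
    return reps


def generate_experimental_sections(
    gt: GroundTruthRepertoire,
    n_sections: int,
    n_spiked: int,
    fold_range: tuple[float, float],
    seed: int,
    cells_per_section: int = 15_000,
    umis_per_section: int | None = 13_000,
    sigma: float = 1.0,
    sample_prefix: str = "sec",
    spike_min_freq: float = 5e-4,
    spike_max_freq: float = 5e-3,
    poisson: bool = True,
) -> list[Repertoire]:
    """Sample tissue sections carrying local clonal expansions.

    Each section is an independent draw from the tissue in which
    ``n_spiked`` randomly chosen clones (distinct per section) have
    their cell counts multiplied by a uniform draw from ``fold_range``
    before cell sampling.  Spiked clones are drawn among clones whose
    ground-truth frequency lies in ``[spike_min_freq, spike_max_freq]``:
    an expansion of a clone below the sampling detection limit is
    unidentifiable at any significance level, while multiplying an
    already-dominant clone turns most of the section into that clone
    and dilutes every other frequency — the emulated local expansions
    start from modest, detectable baseline frequencies.  Spiked clone
    identities and folds are recorded in ``gt.section_spikes`` keyed by
    the emitted sample id.
    """
    lo, hi = fold_range
    if lo <= 0 or hi < lo:
        raise ValidationError("fold_range must satisfy 0 < low <= high")
    if n_spiked > gt.n_clones:
        raise ValidationError("n_spiked exceeds the number of clones")
    rng = np.random.default_rng(seed)
    freqs = gt.frequencies()
    present = np.flatnonzero((freqs >= spike_min_freq) & (freqs <= spike_max_freq))
    if len(present) < n_spiked:
        present = np.flatnonzero(gt.cell_counts > 0)
    sections = []
    for s in range(n_sections):
        sample_id = f"{sample_prefix}{s + 1}"
        pool = gt.cell_counts.copy()
        spikes: dict[int, float] = {}
        if n_spiked > 0:
            chosen = rng.choice(present, size=min(n_spiked, len(present)), replace=False)
            folds = rng.uniform(lo, hi, size=len(chosen))
            for i, f in zip(chosen, folds):
                spikes[int(i)] = float(f)
                pool[i] = max(1, int(round(pool[i] * f)))
        gt.section_spikes[sample_id] = spikes
        cells = _draw_cells(pool, cells_per_section, rng)
        sections.append(
            _sample_repertoire(gt, cells, umis_per_section, sigma, rng, sample_id,
                               poisson=poisson)
        )
    return sections


def depth_mismatch_scenario(
    gt: GroundTruthRepertoire,
    deep_cells: int,
    shallow_cells: int,
    seed: int,
    umis_per_replicate: int = 200_000,
    sigma: float = 1.0,
) -> tuple[list[Repertoire], list[Repertoire]]:
    """Two null replicate pairs at mismatched cell depths from one tissue.

    Returns ``(deep_pair, shallow_pair)``: both are suspension-split
    control pairs with no true heterogeneity, differing 10:1 (by
    default) in the number of cells behind each library while the
    sequenced molecule count stays the same — the situation in which a
    library looks deep by UMI count but its frequencies rest on few
    cells, so cell-sampling and per-cell expression noise dominate.
    Intended use: train the noise model on the deep pair and apply it
    to the shallow pair to reproduce depth-transfer false positives.
    """
    if deep_cells <= shallow_cells:
        raise ValidationError("deep_cells must exceed shallow_cells")
    rng = np.random.default_rng(seed)
    remaining = gt.cell_counts.copy()

    def draw_pair(n_cells: int, prefix: str) -> list[Repertoire]:
        nonlocal remaining
        out = []
        for r in (1, 2):
            cells = _draw_cells(remaining, n_cells, rng)
            remaining -= cells
            out.append(
                _sample_repertoire(
                    gt, cells, umis_per_replicate, sigma, rng, f"{prefix}{r}"
                )
            )
        return out

    deep = draw_pair(deep_cells, "deep")
    shallow = draw_pair(shallow_cells, "shallow")
    return deep, shallow


# ---------------------------------------------------------------------------
# study-scale presets
# ---------------------------------------------------------------------------


def tcell_paper_preset(seed: int, total_cells: int = 60_000) -> GroundTruthRepertoire:
    """Tumor-infiltrating CD8 T-cell tissue at study scale.

    Sized so that suspension-split replicates of ~15,000 cells yielding
    ~13,000 UMIs have a downsampled clonality around 0.25 — a strongly
    but not extremely expanded intratumoral CD8 repertoire.
    """
    return generate_base_repertoire(
        n_clones=2_500,
        powerlaw_exponent=1.8,
        total_cells=total_cells,
        subset_mix={"effector": 1.0},
        seed=seed,
        chain="TRB",
        size_model="rank",
    )


def bcell_paper_preset(seed: int, total_cells: int, n_clones: int = 3_000) -> GroundTruthRepertoire:
    """Tumor-section B-cell tissue with a large plasma-cell fraction.

    Roughly half of the B cells are antibody-secreting plasma cells
    whose per-cell immunoglobulin output is ~100x that of naive/memory
    cells, as in tertiary-lymphoid-structure-rich tumor sections.
    """
    return generate_base_repertoire(
        n_clones=n_clones,
        powerlaw_exponent=1.8,
        total_cells=total_cells,
        subset_mix={"naive": 0.25, "memory": 0.25, "plasma": 0.5},
        seed=seed,
        chain="IGH",
        base_expression=0.5,
        size_model="rank",
    )
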