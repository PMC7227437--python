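"""Reading, writing, filtering, joining and downsampling clonotype tables.

A *clonotype* is a unique receptor rearrangement keyed, by default, by its
CDR3 nucleotide sequence plus V and J gene calls (allele stripped).  Its
abundance is the number of unique UMI-labeled cDNA molecules assigned to
it.  A *repertoire* is one sample's clonotype table; a *sample pair* joins
two repertoires over the union of their clonotype keys so that every clone
has a count in both samples (0 when absent).

Supported input dialects:

``airr``
    AIRR-community rearrangement TSV (``junction``, ``junction_aa``,
    ``v_call``, ``j_call``, ``duplicate_count`` or ``consensus_count``,
    optional ``c_call``).
``mixcr``
    MiXCR clone-table export, both legacy (``cloneCount``, ``nSeqCDR3``,
    ``aaSeqCDR3``, ``allVHitsWithScore`` ...) and current
    (``uniqueMoleculeCount``, ``nSeqImputedCDR3`` ...) headers.
``canonical``
    This package's own output format (see :func:`write_clonotype_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ChainError,
    DepthError,
    EmptyRepertoireError,
    FormatError,
    PairingError,
    ValidationError,
)

Chain = Literal["TRB", "IGH"]

#: Default clonotype identity: nucleotide CDR3 + V/J gene (allele stripped).
IDENTITY_NT: tuple[str, ...] = ("cdr3_nt", "v_gene", "j_gene")
#: Alternative identity for cross-replicate matching of hypermutated IGH.
IDENTITY_AA: tuple[str, ...] = ("cdr3_aa", "v_gene")

_CANONICAL_COLUMNS = [
    "sample_id",
    "chain",
    "cdr3_nt",
    "cdr3_aa",
    "v_gene",
    "j_gene",
    "isotype",
    "umi_count",
    "freq",
]

_GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_nt(nt: str) -> str:
    """Translate an in-frame nucleotide sequence to amino acids."""
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise ValidationError(f"nucleotide sequence length {len(nt)} not a multiple of 3")
    return "".join(_GENETIC_CODE.get(nt[i : i + 3], "X") for i in range(0, len(nt), 3))


def strip_allele(gene: str) -> str:
    """Truncate a gene call at the first ``*`` (drop the allele suffix).

    Also drops MiXCR score annotations (``TRBV12-1*00(1234)`` -> ``TRBV12-1``)
    and keeps only the best hit of a comma-separated hit list.
    """
    gene = gene.split(",")[0].strip()
    gene = gene.split("(")[0]
    return gene.split("*")[0]


@dataclass(frozen=True)
class Clonotype:
    """One receptor rearrangement with its UMI-deduplicated molecule count."""

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    umi_count: int
    isotype: str = ""

    def __post_init__(self) -> None:
        if self.umi_count < 0:
            raise ValidationError(f"negative umi_count {self.umi_count}")

    def validate_translation(self) -> None:
        """Strict-mode check that cdr3_aa matches the translation of cdr3_nt."""
        if self.cdr3_nt and self.cdr3_aa:
            aa = translate_nt(self.cdr3_nt)
            if aa != self.cdr3_aa:
                raise ValidationError(
                    f"cdr3_aa {self.cdr3_aa!r} does not match translation {aa!r} of cdr3_nt"
                )


@dataclass
class Repertoire:
    """One sample's clonotype table.

    The table holds one row per clonotype (already collapsed under
    ``identity``) with columns ``cdr3_nt, cdr3_aa, v_gene, j_gene,
    isotype, umi_count``.
    """

    sample_id: str
    chain: Chain
    table: pd.DataFrame
    identity: tuple[str, ...] = IDENTITY_NT
    #: Number of cells behind the library (e.g. a flow-cytometry
    #: estimate), when known.  Used by the depth-compatibility guard:
    #: two libraries of equal molecule count can rest on very different
    #: cell numbers.
    n_cells: int | None = None

    def __post_init__(self) -> None:
        self.table = _collapse(self.table, self.identity)

    @property
    def total_umi(self) -> int:
        return int(self.table["umi_count"].sum())

    @property
    def n_clonotypes(self) -> int:
        return int(len(self.table))

    def keys(self) -> pd.Index:
        """Clonotype keys under the configured identity, as tuples."""
        return pd.MultiIndex.from_frame(self.table[list(self.identity)])

    def counts(self) -> np.ndarray:
        return self.table["umi_count"].to_numpy()

    def frequencies(self) -> np.ndarray:
        return self.counts() / self.total_umi

    @classmethod
    def from_clonotypes(
        cls,
        sample_id: str,
        chain: Chain,
        clonotypes: Iterable[Clonotype],
        identity: tuple[str, ...] = IDENTITY_NT,
    ) -> "Repertoire":
        rows = [
            {
                "cdr3_nt": c.cdr3_nt,
                "cdr3_aa": c.cdr3_aa,
                "v_gene": c.v_gene,
                "j_gene": c.j_gene,
                "isotype": c.isotype,
                "umi_count": c.umi_count,
            }
            for c in clonotypes
        ]
        return cls(sample_id, chain, pd.DataFrame(rows), identity=identity)


def _collapse(table: pd.DataFrame, identity: Sequence[str]) -> pd.DataFrame:
    """Sum counts of rows identical under the identity columns."""
    required = {"cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "isotype", "umi_count"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"repertoire table missing columns: {sorted(missing)}")
    agg = {
        "umi_count": "sum",
        # carry the first annotation for columns outside the identity
        **{
            c: "first"
            for c in ("cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "isotype")
            if c not in identity
        },
    }
    out = (
        table.groupby(list(identity), as_index=False, sort=True)
        .agg(agg)
        .reindex(columns=["cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "isotype", "umi_count"])
    )
    out["umi_count"] = out["umi_count"].astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_AIRR_ALIASES = {
    "cdr3_nt": ["junction", "cdr3"],
    "cdr3_aa": ["junction_aa", "cdr3_aa"],
    "v_gene": ["v_call"],
    "j_gene": ["j_call"],
    "isotype": ["c_call"],
    "umi_count": ["duplicate_count", "consensus_count"],
}

_MIXCR_ALIASES = {
    "cdr3_nt": ["nSeqCDR3", "nSeqImputedCDR3", "targetSequences"],
    "cdr3_aa": ["aaSeqCDR3", "aaSeqImputedCDR3"],
    "v_gene": ["allVHitsWithScore", "bestVHit", "allVHits"],
    "j_gene": ["allJHitsWithScore", "bestJHit", "allJHits"],
    "isotype": ["allCHitsWithScore", "bestCHit", "allCHits"],
    "umi_count": ["uniqueMoleculeCount", "uniqueUMICount", "cloneCount"],
}

_MIXCR_READ_COUNT = ["readCount", "cloneCount"]

_CANONICAL_ALIASES = {
    "cdr3_nt": ["cdr3_nt"],
    "cdr3_aa": ["cdr3_aa"],
    "v_gene": ["v_gene"],
    "j_gene": ["j_gene"],
    "isotype": ["isotype"],
    "umi_count": ["umi_count"],
}

_OPTIONAL = {"isotype", "cdr3_aa"}


def _resolve_columns(
    columns: Sequence[str], aliases: dict[str, list[str]], dialect: str
) -> dict[str, str]:
    resolved: dict[str, str] = {}
    for target, candidates in aliases.items():
        found = next((c for c in candidates if c in columns), None)
        if found is None:
            if target in _OPTIONAL:
                continue
            raise FormatError(
                f"{dialect} table is missing required column "
                f"{candidates[0]!r} (accepted aliases: {candidates})"
            )
        resolved[target] = found
    return resolved


def read_clonotype_table(
    path: str | Path,
    format: Literal["airr", "mixcr", "mixcr-tsv", "canonical"],
    chain: Chain,
    sample_id: str | None = None,
    identity: tuple[str, ...] = IDENTITY_NT,
    allow_read_counts: bool = False,
    strict: bool = False,
    n_cells: int | None = None,
) -> Repertoire:
    """Read a clonotype table into a :class:`Repertoire`.

    Parameters
    ----------
    path
        TSV file in one of the supported dialects.
    format
        ``"airr"``, ``"mixcr"`` or ``"canonical"``.
    chain
        ``"TRB"`` or ``"IGH"``; IGH rows keep their constant-region call
        as the isotype, TRB isotypes are blanked.
    sample_id
        Defaults to the file stem.
    allow_read_counts
        The statistics downstream assume UMI-deduplicated molecule counts.
        A MiXCR table whose only abundance column is ``readCount`` is
        rejected unless this flag is set.
    strict
        Verify that ``cdr3_aa`` matches the translation of ``cdr3_nt``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mixcr-tsv":
        format = "mixcr"
    if format == "mixcr":
        aliases = dict(_MIXCR_ALIASES)
    elif format == "airr":
        aliases = dict(_AIRR_ALIASES)
    elif format == "canonical":
        aliases = dict(_CANONICAL_ALIASES)
    else:
        raise FormatError(f"unknown format {format!r}")

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.empty:
        raise EmptyRepertoireError(f"{path}: no data rows")
    if format == "mixcr" and allow_read_counts:
        aliases["umi_count"] = aliases["umi_count"] + _MIXCR_READ_COUNT
    cols = _resolve_columns(list(raw.columns), aliases, format)
    if (
        format == "mixcr"
        and cols["umi_count"] == "cloneCount"
        and "readCount" in raw.columns
        and not allow_read_counts
    ):
        # a modern export carrying readCount uses cloneCount as a read
        # count too; the downstream statistics assume UMI molecules
        raise FormatError(
            f"{path}: no UMI molecule-count column found "
            "(pass allow_read_counts=True to accept read counts)"
        )

    table = pd.DataFrame(
        {
            target: raw[src]
            for target, src in cols.items()
        }
    )
    for optional in _OPTIONAL:
        if optional not in table.columns:
            table[optional] = ""

    # count validation with row numbers (1-based, excluding header)
    counts = pd.to_numeric(table["umi_count"], errors="coerce")
    bad = counts.isna() | (counts != counts.round()) | (counts < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(
            f"{path}: invalid count {table['umi_count'].iloc[row - 1]!r} at data row {row}"
        )
    table["umi_count"] = counts.astype(np.int64)

    if format == "mixcr":
        table["v_gene"] = table["v_gene"].map(strip_allele)
        table["j_gene"] = table["j_gene"].map(strip_allele)
        if "isotype" in cols:
            table["isotype"] = table["isotype"].map(strip_allele)
    else:
        table["v_gene"] = table["v_gene"].map(strip_allele)
        table["j_gene"] = table["j_gene"].map(strip_allele)

    if chain == "TRB":
        table["isotype"] = ""

    if strict:
        for i, r in table.iterrows():
            Clonotype(
                r["cdr3_nt"], r["cdr3_aa"], r["v_gene"], r["j_gene"], int(r["umi_count"]), r["isotype"]
            ).validate_translation()

    return Repertoire(
        sample_id=sample_id or path.stem,
        chain=chain,
        table=table,
        identity=identity,
        n_cells=n_cells,
    )


def write_clonotype_table(rep: Repertoire, path: str | Path) -> None:
    """Write the canonical clonotype TSV (one row per clonotype)."""
    out = rep.table.copy()
    out.insert(0, "sample_id", rep.sample_id)
    out.insert(1, "chain", rep.chain)
    out["freq"] = out["umi_count"] / rep.total_umi if rep.total_umi else 0.0
    out[_CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pairing, filtering, downsampling
# ---------------------------------------------------------------------------


@dataclass
class SamplePair:
    """Two repertoires joined over the union of their clonotype keys.

    ``joint`` has the identity columns plus ``count_a`` / ``count_b``
    (0 for a clone absent from one sample).  ``depth_a`` / ``depth_b``
    are the *pre-filter* library depths: they stay fixed when the pair
    is filtered, because downstream tests use the full sequencing depth
    as the binomial denominator.
    """

    rep_a: Repertoire
    rep_b: Repertoire
    role: Literal["control", "experimental"]
    joint: pd.DataFrame
    depth_a: int
    depth_b: int
    filtered: bool = False
    pair_id: str = ""

    def __post_init__(self) -> None:
        if not self.pair_id:
            self.pair_id = f"{self.rep_a.sample_id}__{self.rep_b.sample_id}"

    @property
    def n_union_clones(self) -> int:
        return int(len(self.joint))

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.joint["count_a"].to_numpy(),
            self.joint["count_b"].to_numpy(),
        )

    def swapped(self) -> "SamplePair":
        """The same pair with the roles of a and b exchanged."""
        joint = self.joint.rename(columns={"count_a": "count_b", "count_b": "count_a"})
        return SamplePair(
            rep_a=self.rep_b,
            rep_b=self.rep_a,
            role=self.role,
            joint=joint,
            depth_a=self.depth_b,
            depth_b=self.depth_a,
            filtered=self.filtered,
            pair_id=f"{self.rep_b.sample_id}__{self.rep_a.sample_id}",
        )


def make_pair(
    rep_a: Repertoire,
    rep_b: Repertoire,
    role: Literal["control", "experimental"],
    pair_id: str = "",
) -> SamplePair:
    """Join two repertoires over the union of their clonotype keys."""
    if rep_a.chain != rep_b.chain:
        raise PairingError(f"chain mismatch: {rep_a.chain} vs {rep_b.chain}")
    if rep_a.identity != rep_b.identity:
        raise PairingError("repertoires use different clonotype identities")
    identity = list(rep_a.identity)
    a = rep_a.table[identity + ["umi_count"]].rename(columns={"umi_count": "count_a"})
    b = rep_b.table[identity + ["umi_count"]].rename(columns={"umi_count": "count_b"})
    annot_cols = [c for c in ("cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "isotype") if c not in identity]
    joint = a.merge(b, on=identity, how="outer")
    joint[["count_a", "count_b"]] = joint[["count_a", "count_b"]].fillna(0).astype(np.int64)
    if annot_cols:
        annot = pd.concat(
            [rep_a.table[identity + annot_cols], rep_b.table[identity + annot_cols]]
        ).drop_duplicates(subset=identity)
        joint = joint.merge(annot, on=identity, how="left")
    joint = joint.sort_values(identity, kind="mergesort").reset_index(drop=True)
    assert int(joint["count_a"].sum()) == rep_a.total_umi
    assert int(joint["count_b"].sum()) == rep_b.total_umi
    return SamplePair(
        rep_a=rep_a,
        rep_b=rep_b,
        role=role,
        joint=joint,
        depth_a=rep_a.total_umi,
        depth_b=rep_b.total_umi,
        pair_id=pair_id,
    )


def filter_min_umi(pair: SamplePair, min_umi: int = 3) -> SamplePair:
    """Keep clonotypes with >= ``min_umi`` UMIs in at least one sample.

    Differential-expansion testing only considers clonotypes supported by
    at least ``min_umi`` molecules; the threshold is applied to the
    maximum of the pair because a genuinely expanded clone may be absent
    from the other section.  Depths are *not* recomputed: the binomial
    denominators remain the full pre-filter library depths.
    """
    if min_umi < 1:
        raise ValidationError(f"min_umi must be >= 1, got {min_umi}")
    keep = (
        np.maximum(pair.joint["count_a"].to_numpy(), pair.joint["count_b"].to_numpy())
        >= min_umi
    )
    return replace(
        pair,
        joint=pair.joint.loc[keep].reset_index(drop=True),
        filtered=True,
    )


def downsample(rep: Repertoire, target_umi: int, seed: int) -> Repertoire:
    """Draw ``target_umi`` molecules without replacement from the UMI pool.

    The retained counts follow the multivariate hypergeometric
    distribution; the result is deterministic given ``seed``.
    """
    if target_umi > rep.total_umi:
        raise DepthError(
            f"target_umi {target_umi} exceeds total_umi {rep.total_umi} for {rep.sample_id}"
        )
    rng = np.random.default_rng(seed)
    counts = rep.counts()
    drawn = rng.multivariate_hypergeometric(counts, target_umi)
    table = rep.table.copy()
    table["umi_count"] = drawn
    table = table[table["umi_count"] > 0].reset_index(drop=True)
    return Repertoire(rep.sample_id, rep.chain, table, identity=rep.identity, n_cells=rep.n_cells)
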