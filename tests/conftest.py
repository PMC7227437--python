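import numpy as np
import pandas as pd
import pytest

from clonodiff.repertoire_io import IDENTITY_NT, Repertoire, SamplePair


def make_repertoire(counts, sample_id="s", chain="TRB", isotypes=None, n_cells=None):
    """Repertoire with synthetic keys clone0, clone1, ... and given counts."""
    n = len(counts)
    table = pd.DataFrame(
        {
            "cdr3_nt": [f"TGTGCC{i:06d}TTT" for i in range(n)],
            "cdr3_aa": [f"CA{i}F" for i in range(n)],
            "v_gene": ["TRBV1" if chain == "TRB" else "IGHV1-1"] * n,
            "j_gene": ["TRBJ1-1" if chain == "TRB" else "IGHJ4"] * n,
            "isotype": isotypes if isotypes is not None else [""] * n,
            "umi_count": list(counts),
        }
    )
    return Repertoire(sample_id, chain, table, identity=IDENTITY_NT, n_cells=n_cells)


def pair_from_counts(k_a, k_b, depth_a=None, depth_b=None, role="control",
                     cells_a=None, cells_b=None):
    """SamplePair built directly from joint count vectors.

    Depths default to the column sums; passing larger depths emulates a
    pair whose low-count clones were filtered out.
    """
    k_a = np.asarray(k_a, dtype=np.int64)
    k_b = np.asarray(k_b, dtype=np.int64)
    rep_a = make_repertoire(np.maximum(k_a, 0), "a", n_cells=cells_a)
    rep_b = make_repertoire(np.maximum(k_b, 0), "b", n_cells=cells_b)
    n = len(k_a)
    joint = pd.DataFrame(
        {
            "cdr3_nt": [f"TGTGCC{i:06d}TTT" for i in range(n)],
            "v_gene": ["TRBV1"] * n,
            "j_gene": ["TRBJ1-1"] * n,
            "cdr3_aa": [f"CA{i}F" for i in range(n)],
            "isotype": [""] * n,
            "count_a": k_a,
            "count_b": k_b,
        }
    )
    return SamplePair(
        rep_a=rep_a,
        rep_b=rep_b,
        role=role,
        joint=joint,
        depth_a=int(depth_a if depth_a is not None else k_a.sum()),
        depth_b=int(depth_b if depth_b is not None else k_b.sum()),
        filtered=True,
    )


def betabinom_pair(n_clones, depth, rho, seed, freq_range=(1e-3, 1e-2)):
    """Null control pair whose counts are exact beta-binomial draws.

    Clones are independent draws at known per-clone frequencies (this is
    a statistical fixture, not a compositional repertoire), so the
    dispersion fitted from it can be compared to the generating ``rho``.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    f = 10 ** rng.uniform(np.log10(freq_range[0]), np.log10(freq_range[1]), n_clones)
    s = (1.0 - rho) / rho
    k_a = stats.betabinom.rvs(depth, f * s, (1 - f) * s, random_state=rng)
    k_b = stats.betabinom.rvs(depth, f * s, (1 - f) * s, random_state=rng)
    keep = (k_a + k_b) > 0
    return pair_from_counts(k_a[keep], k_b[keep], depth, depth), f


@pytest.fixture
def airr_file(tmp_path):
    """Minimal 3-row AIRR rearrangement TSV with counts 5, 3, 2."""
    path = tmp_path / "sample.airr.tsv"
    rows = [
        "junction\tjunction_aa\tv_call\tj_call\tduplicate_count",
        "TGTGCAAGCTTT\tCASF\tTRBV19*01\tTRBJ2-7*01\t5",
        "TGTGCAAGGTTT\tCARF\tTRBV12-1*01\tTRBJ1-1*01\t3",
        "TGTGCAAGTTTC\tCASF\tTRBV19*01\tTRBJ2-1*01\t2",
    ]
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def mixcr_file(tmp_path):
    """Legacy MiXCR clone table with two rows collapsing to one clonotype."""
    path = tmp_path / "sample.mixcr.tsv"
    rows = [
        "cloneCount\tnSeqCDR3\taaSeqCDR3\tallVHitsWithScore\tallJHitsWithScore",
        "4\tTGTGCAAGCTTT\tCASF\tTRBV19*01(1200)\tTRBJ2-7*01(800)",
        "6\tTGTGCAAGCTTT\tCASF\tTRBV19*02(1100)\tTRBJ2-7*01(790)",
    ]
    path.write_text("\n".join(rows) + "\n")
    return path
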