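"""End-to-end orchestration from a sample manifest.

A manifest declares the samples (paths, dialects, chains), the pairing
plan — which pairs are control (split from one cell suspension) and
which are experimental (independent tissue sections) — and the analysis
settings.  ``run`` reads everything, trains the noise model on the
declared control pairs, calls expansions on every pair, computes the
per-sample and per-pair heterogeneity metrics, compares control and
experimental summaries, and emits a reproducible report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DepthError, ValidationError
from .heterogeneity import clonality, group_comparison, pairwise_correlation
from .noise_model import (
    BetaBinomialNoiseModel,
    FitConfig,
    call_expansions,
    depth_compatibility_check,
    fit_noise_model,
)
from .repertoire_io import (
    IDENTITY_AA,
    IDENTITY_NT,
    Repertoire,
    SamplePair,
    filter_min_umi,
    make_pair,
    read_clonotype_table,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    path: str
    format: str = "canonical"
    chain: str = "TRB"
    group: str = ""
    replicate_of: str = ""


@dataclass(frozen=True)
class PairSpec:
    pair_id: str
    a: str
    b: str
    role: str  # control | experimental


@dataclass(frozen=True)
class Settings:
    min_umi: int = 3
    fdr: float = 0.05
    clonality_target: int = 500
    clonality_iterations: int = 100
    seed: int = 0
    max_depth_ratio: float = 3.0
    identity: str = "nt"  # nt | aa


@dataclass
class Manifest:
    """Validated experiment description."""

    samples: list[SampleSpec]
    pairs: list[PairSpec]
    settings: Settings = field(default_factory=Settings)
    model_path: str | None = None

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate sample_id in manifest")
        by_id = {s.sample_id: s for s in self.samples}
        pair_ids = [p.pair_id for p in self.pairs]
        if len(set(pair_ids)) != len(pair_ids):
            raise ConfigurationError("duplicate pair_id in manifest")
        for p in self.pairs:
            for sid in (p.a, p.b):
                if sid not in by_id:
                    raise ConfigurationError(f"pair {p.pair_id} references unknown sample {sid}")
            if p.role not in ("control", "experimental"):
                raise ConfigurationError(f"pair {p.pair_id}: role must be control or experimental")
            if p.role == "control":
                ra, rb = by_id[p.a].replicate_of, by_id[p.b].replicate_of
                if not ra or ra != rb:
                    raise ConfigurationError(
                        f"control pair {p.pair_id}: samples must share a replicate_of tag "
                        f"(got {ra!r} vs {rb!r})"
                    )
        has_control = any(p.role == "control" for p in self.pairs)
        if not has_control and self.model_path is None:
            raise ConfigurationError(
                "manifest declares no control pair and no pre-trained model_path"
            )

    @property
    def sample_map(self) -> dict[str, SampleSpec]:
        return {s.sample_id: s for s in self.samples}

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any], base_dir: Path | None = None) -> "Manifest":
        def resolve(p: str) -> str:
            path = Path(p)
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            return str(path)

        samples = [
            SampleSpec(
                sample_id=s["sample_id"],
                path=resolve(s["path"]),
                format=s.get("format", "canonical"),
                chain=s.get("chain", "TRB"),
                group=s.get("group", ""),
                replicate_of=s.get("replicate_of", ""),
            )
            for s in doc.get("samples", [])
        ]
        pairs = [
            PairSpec(
                pair_id=p.get("pair_id", f"{p['a']}__{p['b']}"),
                a=p["a"],
                b=p["b"],
                role=p["role"],
            )
            for p in doc.get("pairs", [])
        ]
        settings = Settings(**doc.get("settings", {}))
        model_path = doc.get("model_path")
        return cls(samples=samples, pairs=pairs, settings=settings,
                   model_path=resolve(model_path) if model_path else None)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Manifest":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        manifest = cls.from_dict(doc, base_dir=path.parent)
        for s in manifest.samples:
            if not Path(s.path).exists():
                raise ConfigurationError(f"sample {s.sample_id}: path {s.path} does not exist")
        return manifest

    def to_dict(self) -> dict:
        return {
            "samples": [asdict(s) for s in self.samples],
            "pairs": [asdict(p) for p in self.pairs],
            "settings": asdict(self.settings),
            "model_path": self.model_path,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class Report:
    """All run outputs plus metadata; serializable to a directory."""

    sample_metrics: pd.DataFrame
    pair_summary: pd.DataFrame
    call_tables: dict[str, pd.DataFrame]
    models: dict[str, BetaBinomialNoiseModel]
    group_tests: dict[str, float | None]
    warnings: list[str]
    metadata: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sample_metrics.to_csv(out / "sample_metrics.tsv", sep="\t", index=False)
        self.pair_summary.to_csv(out / "pair_summary.tsv", sep="\t", index=False)
        calls_dir = out / "calls"
        calls_dir.mkdir(exist_ok=True)
        for pair_id, table in self.call_tables.items():
            table.to_csv(calls_dir / f"{pair_id}.tsv", sep="\t", index=False)
        for chain, model in self.models.items():
            model.to_json(out / f"model_{chain}.json")
        summary = {
            "group_tests": self.group_tests,
            "warnings": self.warnings,
            "metadata": self.metadata,
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def plot_pair_scatter(pair: SamplePair, calls_table: pd.DataFrame, path: str | Path) -> None:
    """Scatter of clone frequencies in sample A vs B, called clones colored.

    Purely presentational: no numeric result depends on this function.
    Requires matplotlib (``pip install clonodiff[plots]``).
    """
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as err:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (install the 'plots' extra)") from err
    t = calls_table
    f_a = np.maximum(t["f_a"].to_numpy(), 0.5 / pair.depth_a)
    f_b = np.maximum(t["f_b"].to_numpy(), 0.5 / pair.depth_b)
    call = t["call"].to_numpy()
    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    for label, color in [("unchanged", "0.7"), ("expanded_in_b", "tab:orange"),
                         ("contracted_in_b", "tab:blue")]:
        sel = call == label
        ax.scatter(f_a[sel], f_b[sel], s=8, c=color, label=label, alpha=0.7,
                   edgecolors="none")
    lims = [min(f_a.min(), f_b.min()) / 2, 1.0]
    ax.plot(lims, lims, lw=0.8, c="k")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(f"clone frequency in {pair.rep_a.sample_id}")
    ax.set_ylabel(f"clone frequency in {pair.rep_b.sample_id}")
    ax.legend(fontsize=7, frameon=False)
    ax.set_title(pair.pair_id, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _load_samples(manifest: Manifest) -> dict[str, Repertoire]:
    identity = IDENTITY_NT if manifest.settings.identity == "nt" else IDENTITY_AA
    reps: dict[str, Repertoire] = {}
    for spec in manifest.samples:
        rep = read_clonotype_table(
            spec.path,
            format=spec.format,  # type: ignore[arg-type]
            chain=spec.chain,  # type: ignore[arg-type]
            sample_id=spec.sample_id,
            identity=identity,
        )
        logger.info("stage=read sample=%s clones=%d umi=%d", spec.sample_id, rep.n_clonotypes, rep.total_umi)
        reps[spec.sample_id] = rep
    return reps


def run(manifest: Manifest, plot_dir: str | Path | None = None) -> Report:
    """Execute the full pipeline for one manifest.

    read -> pair -> filter -> train on control pairs -> depth guard ->
    call expansions on every pair -> per-sample and per-pair metrics ->
    control-vs-experimental group comparisons -> report.  When
    ``plot_dir`` is given, a frequency scatterplot per pair (called
    clones highlighted) is written there; no numeric output depends on
    plotting.
    """
    settings = manifest.settings
    reps = _load_samples(manifest)
    warnings: list[str] = []

    pairs: dict[str, SamplePair] = {}
    for spec in manifest.pairs:
        pair = make_pair(reps[spec.a], reps[spec.b], role=spec.role, pair_id=spec.pair_id)  # type: ignore[arg-type]
        pairs[spec.pair_id] = filter_min_umi(pair, settings.min_umi)
        logger.info("stage=pair pair=%s role=%s union=%d", spec.pair_id, spec.role, pairs[spec.pair_id].n_union_clones)

    # one model per chain, pooled over that chain's control pairs
    models: dict[str, BetaBinomialNoiseModel] = {}
    if manifest.model_path:
        model = BetaBinomialNoiseModel.from_json(manifest.model_path)
        for chain in {s.chain for s in manifest.samples}:
            models[chain] = model
    else:
        by_chain: dict[str, list[SamplePair]] = {}
        for spec in manifest.pairs:
            if spec.role == "control":
                by_chain.setdefault(reps[spec.a].chain, []).append(pairs[spec.pair_id])
        for chain, control_pairs in by_chain.items():
            models[chain] = fit_noise_model(control_pairs)
            logger.info("stage=train chain=%s pairs=%d", chain, len(control_pairs))

    call_tables: dict[str, pd.DataFrame] = {}
    pair_rows = []
    for spec in manifest.pairs:
        pair = pairs[spec.pair_id]
        chain = pair.rep_a.chain
        model = models[chain]
        check = depth_compatibility_check(model, pair, settings.max_depth_ratio)
        if not check.ok:
            warnings.append(check.message)
        calls = call_expansions(pair, model, fdr=settings.fdr)
        warnings.extend(w for w in calls.warnings if w not in warnings)
        call_tables[spec.pair_id] = calls.table
        if plot_dir is not None:
            Path(plot_dir).mkdir(parents=True, exist_ok=True)
            plot_pair_scatter(pair, calls.table, Path(plot_dir) / f"{spec.pair_id}.png")
        try:
            r = pairwise_correlation(pair)
        except ValidationError:
            r = float("nan")
        pair_rows.append(
            {
                "pair_id": spec.pair_id,
                "role": spec.role,
                "pearson_r": r,
                "n_union_clones": pair.n_union_clones,
                "n_expanded": calls.n_expanded,
                "n_contracted": calls.n_contracted,
            }
        )
        logger.info(
            "stage=call pair=%s expanded=%d contracted=%d r=%.3f",
            spec.pair_id, calls.n_expanded, calls.n_contracted, r,
        )
    pair_summary = pd.DataFrame(pair_rows)

    sample_rows = []
    for i, spec in enumerate(manifest.samples):
        rep = reps[spec.sample_id]
        row = {
            "sample_id": spec.sample_id,
            "chain": spec.chain,
            "total_umi": rep.total_umi,
            "n_clonotypes": rep.n_clonotypes,
            "clonality_mean": float("nan"),
            "clonality_sd": float("nan"),
        }
        try:
            summary = clonality(
                rep,
                target_umi=settings.clonality_target,
                n_iterations=settings.clonality_iterations,
                seed=settings.seed + i,
            )
            row["clonality_mean"] = summary.clonality_mean
            row["clonality_sd"] = summary.clonality_sd
        except DepthError as err:
            logger.info("stage=clonality sample=%s skipped: %s", spec.sample_id, err)
            warnings.append(f"clonality skipped for {spec.sample_id}: {err}")
        sample_rows.append(row)
    sample_metrics = pd.DataFrame(sample_rows)

    group_tests: dict[str, float | None] = {"pearson_r": None, "n_called": None}
    ctrl = pair_summary[pair_summary["role"] == "control"]
    expt = pair_summary[pair_summary["role"] == "experimental"]
    if len(ctrl) and len(expt):
        r_ctrl = ctrl["pearson_r"].dropna().tolist()
        r_expt = expt["pearson_r"].dropna().tolist()
        if r_ctrl and r_expt:
            group_tests["pearson_r"] = group_comparison(r_ctrl, r_expt)
        calls_ctrl = (ctrl["n_expanded"] + ctrl["n_contracted"]).tolist()
        calls_expt = (expt["n_expanded"] + expt["n_contracted"]).tolist()
        group_tests["n_called"] = group_comparison(calls_ctrl, calls_expt)

    from . import __version__

    metadata = {
        "config_hash": manifest.config_hash(),
        "seed": settings.seed,
        "version": __version__,
        "n_samples": len(manifest.samples),
        "n_pairs": len(manifest.pairs),
    }
    return Report(
        sample_metrics=sample_metrics,
        pair_summary=pair_summary,
        call_tables=call_tables,
        models=models,
        group_tests=group_tests,
        warnings=warnings,
        metadata=metadata,
    )
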