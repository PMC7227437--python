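# clonodiff

Replicate-controlled measurement of clonal heterogeneity in T- and
B-cell receptor repertoires between tumor tissue sections.

Comparing the clonotype tables of two tissue sections never gives
identical frequencies, even for biologically identical material: cell
sampling, cell-to-cell variation in receptor transcript expression, and
cDNA/UMI sampling all inject noise. `clonodiff` quantifies that noise
from **control replicates** — aliquots split from one homogenized
single-cell suspension — by fitting a frequency-dependent beta-binomial
model, and then calls clonotypes whose frequency difference between two
samples exceeds the replicate noise at a chosen FDR. It is written for
AIRR-seq analysts working with UMI-based TCRβ or IGH clonotype tables
(AIRR-C rearrangement TSV or MiXCR clone exports).

## Model

A clone at frequency *f* observed at UMI depth *n* contributes a count

> K ~ BetaBinomial(n, α, β),  α = f(1−ρ)/ρ,  β = (1−f)(1−ρ)/ρ,

with overdispersion ρ = 1/(α+β+1) fitted by maximum likelihood in bins
of log₁₀ pooled clone frequency on the control pairs and interpolated
between bin centers. For each clone of a tested pair, both margins are
scored against the pooled frequency f₀ = (k_a+k_b)/(N_a+N_b) with a
tail-doubled two-sided p-value, combined symmetrically, and
Benjamini–Hochberg adjusted; calls require q ≤ FDR (default 0.05).
Only clonotypes with ≥ 3 UMIs in at least one sample are tested.

Supporting heterogeneity statistics: downsampled clonality
C = 1 − H/ln S (computed after drawing a fixed number of molecules,
default 500), pairwise Pearson correlation of clone counts, the
expected clonotype overlap of two samples under hypergeometric cell
sampling, immunoglobulin isotype composition, and exact Mann–Whitney
comparison of control vs experimental summaries. A depth-compatibility
guard warns when a model is applied to samples whose UMI *or cell*
depth differs from the training replicates by more than 3×, a situation
that produces false-positive expansion calls.

A full synthetic-data generator (power-law clone sizes, two-stage
cell→transcript→UMI sampling, 2:5:500 naive:memory:plasma expression
ratios, spike-in local expansions, deliberate depth mismatches) makes
every stage testable without external data; see `docs/methods.md`.

## Worked example

```python
import clonodiff as cd

# a study-scale synthetic CD8 T-cell tissue: 2,500 clones, 60,000 cells
gt = cd.tcell_paper_preset(seed=0)

# control design: split one suspension into two replicates
reps = cd.split_control_replicates(gt, 2, 15_000, 13_000, seed=1)
ctrl = cd.filter_min_umi(cd.make_pair(reps[0], reps[1], role="control"))
model = cd.fit_noise_model([ctrl])

# experimental design: two sections, ten spiked local expansions each
secs = cd.generate_experimental_sections(
    gt, 2, 10, (6.0, 12.0), seed=2,
    cells_per_section=15_000, umis_per_section=13_000,
)
pair = cd.filter_min_umi(cd.make_pair(secs[0], secs[1], role="experimental"))
calls = cd.call_expansions(pair, model, fdr=0.05)

print("control pair:  r =", round(cd.pairwise_correlation(ctrl), 3),
      "| calls:", cd.call_expansions(ctrl, model).n_called)
print("section pair:  r =", round(cd.pairwise_correlation(pair), 3),
      "| expanded:", calls.n_expanded, "contracted:", calls.n_contracted)
c = cd.clonality(reps[0], target_umi=500, seed=3)
print(f"clonality of replicate 1: {c.clonality_mean:.3f} +/- {c.clonality_sd:.3f}")
```

prints

```
control pair:  r = 0.997 | calls: 0
section pair:  r = 0.979 | expanded: 6 contracted: 8
clonality of replicate 1: 0.259 +/- 0.013
```

The control replicates correlate almost perfectly and yield **zero**
expansion calls — their differences are within the trained noise model.
The two tissue sections correlate visibly worse and yield 14
directional calls at FDR 0.05: the spiked clones recovered in both
directions (a clone spiked in section 1 is "contracted in section 2").
The clonality value ≈ 0.26 describes a strongly expanded intratumoral
repertoire (0 = perfectly even, 1 = monoclonal).

The same analysis is scriptable from a sample manifest via the CLI:

```bash
clonodiff simulate --config scenario.yaml --out-dir sim/ --seed 7
clonodiff fit      --manifest manifest.yaml --out model.json
clonodiff call     --model model.json --sample-a X1.tsv --sample-b Y1.tsv --out calls.tsv
clonodiff metrics  --manifest manifest.yaml --out metrics.tsv
clonodiff run      --manifest manifest.yaml --out-dir report/
```

`run` reads the manifest (samples, control/experimental pairing plan,
settings), trains one model per chain on the declared control pairs,
calls expansions on every declared pair, computes per-sample and
per-pair metrics, compares the control and experimental groups, and
writes a deterministic report directory (TSV tables, model JSON,
`report.json` with warnings and run metadata).

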