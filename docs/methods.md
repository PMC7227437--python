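# Methods

## Problem setting

Sequencing the T-cell receptor (TCR) or immunoglobulin heavy chain (IGH)
repertoires of two sections of the same tumor never yields identical
clonotype tables, even when the sections are biologically identical:
cell sampling, cell-to-cell variation in receptor transcript expression,
and molecule (cDNA/UMI) sampling during library preparation all inject
noise. The question this package answers is *which clonotype frequency
differences between two samples exceed that technical noise* — i.e.
which clones are genuinely locally expanded or contracted — and how
heterogeneous two repertoires are overall once sampling effects are
accounted for.

The experimental design it assumes has two kinds of sample pairs:

- **control replicates** — aliquots split from a single homogenized
  cell suspension; any difference between them is technical noise;
- **experimental sections** — physically distinct tissue fragments
  processed independently; differences reflect noise *plus* true
  spatial heterogeneity.

The control replicates are used to train a noise model, which is then
applied to the experimental pairs.

## Noise model

For a clone at frequency `f` observed at UMI depth `n`, the count is
modelled as beta-binomial:

    K ~ BetaBinomial(n, α, β),
    α = f(1−ρ)/ρ,  β = (1−f)(1−ρ)/ρ,

so `E[K] = n f` and `ρ = 1/(α+β+1)` is the overdispersion: `ρ → 0` is
the pure binomial split, larger `ρ` means more extra-binomial replicate
noise. Because dispersion depends on clone frequency (abundant clones
are measured relatively more precisely), `ρ` is fitted per bin of log10
pooled clone frequency (default 8 equal-width bins, bins with fewer
than 20 clones merged with neighbours) and interpolated
piecewise-linearly between bin centers, clamped at the ends. The fit is
a bounded 1-D maximum-likelihood search per bin on log10 ρ, with floor
`ρ_floor = 1e−6`; it is deterministic given the input pair(s).

**What ρ means here.** The curve stores the *marginal* replicate
overdispersion — the dispersion of one replicate's counts around the
pair's common truth. During both fitting and testing, each margin is
scored against the *pooled* two-sample frequency
`f₀ = (k_a+k_b)/(N_a+N_b)`; deviations around the pooled estimate carry
about half the marginal dispersion (the pooled mean absorbs the shared
half), so the likelihood and the test both use `ρ/2` internally. This
makes the stored ρ directly comparable to a generative simulation
parameter, while the test statistic sees exactly the dispersion it has
under the null. Training is symmetrized (both replicate orderings enter
the likelihood), so the model is invariant to the order of replicates.

## Testing for local expansions

For each clone of a pair, the two-sided p-value is a tail-doubled
beta-binomial test of each margin against the pooled frequency,

    p_x = min(1, 2·min(P(K ≤ k_x), P(K ≥ k_x))),   K ~ BB(N_x, f₀, ρ(f₀)/2),

combined as `p = max(p_a, p_b)`. The maximum is exchange-symmetric
(swapping the samples maps expanded ↔ contracted calls and leaves every
p-value unchanged) and conservative. Only clonotypes with at least
3 UMIs in one of the two samples are tested; the binomial denominators
remain the full pre-filter library depths, because clone frequencies
are fractions of the whole repertoire, not of the filtered subset.
p-values are Benjamini–Hochberg adjusted per pair and a clone is called
at `q ≤ FDR` (default 0.05; the threshold and correction are package
choices — configurable), with the direction from the sign of
`f_b − f_a` and ties never called.

### Depth-compatibility guard

Dispersion estimates do not transfer across sampling depth. A model
trained on replicates resting on many cells underestimates the noise of
a pair resting on few cells — *even at equal UMI counts* — and then
reports false-positive expansions. `depth_compatibility_check` compares
the pair under test to the training pairs both in UMI totals and, when
cell-count estimates are available (`Repertoire.n_cells`), in cells,
and warns when every training pair differs by more than `max_ratio`
(default 3) in either respect.

## Heterogeneity metrics

- **Clonality** `C = 1 − H/ln S` (Shannon entropy `H`, observed
  richness `S`), computed after downsampling each sample without
  replacement to a fixed molecule count (default 500 UMIs) and averaged
  over 100 independent draws (mean ± sd reported; the iteration count
  is a package choice). `C = 0` is a perfectly even repertoire, `C = 1`
  monoclonal (the `S = 1` case is defined as 1). Downsampling removes
  the depth dependence of entropy estimates; natural logs are used
  (the normalization cancels the base).
- **Pairwise correlation**: Pearson r of the two UMI-count vectors over
  the *union* of clonotypes (absent = 0), so presence/absence
  discordance lowers r; an intersection scope and a log-transformed
  mode (pseudocount 0.5) exist for sensitivity analysis. Raw counts are
  the default because no transform is canonical for this use.
- **Expected overlap** between two samples of `n_a` and `n_b` cells
  drawn from a common repertoire with clone sizes `c_i` (total `T`):
  `E = Σ_i (1 − h(c_i, n_a, T))(1 − h(c_i, n_b, T))` with `h` the
  hypergeometric probability of missing clone `i` entirely. For `S`
  singleton clones this collapses to `n_a·n_b/S` — the reason repertoire
  overlap is meaningless without depth normalization: 10-cell samples
  of 100 singletons share 1 clone, 50-cell samples 25.
- **Isotype proportions**: fraction of total UMIs per constant-region
  call (subclass level, IGHG1…4 distinct), so transcript-rich plasma
  cell clones dominate the composition as they do in RNA-based IGH
  libraries.
- **Group comparison**: two-sided Mann–Whitney U. For groups of ≤ 8
  values the p-value is exact by enumeration of all C(n₁+n₂, n₁)
  labelings with ties credited ½ to U (identical groups give p = 1);
  larger groups use the tie-corrected normal approximation.

## Synthetic data generator

The generator exists so every pipeline stage is testable without
external data. It reproduces the three noise stages the method is built
around, in order:

1. **Tissue composition**: clone cell counts from a discrete power law
   — either random zeta draws (`size_model="zipf"`) or the
   deterministic rank-abundance law `c_i ∝ i^(−1/(a−1))`
   (`size_model="rank"`) with the same size-law exponent `a` —
   renormalized to the requested cell total by largest-remainder
   rounding. Lymphocyte subsets are assigned per clone; per-cell
   receptor-transcript output scales 2:5:500 for naive:memory:plasma B
   cells (effector T cells are the single-subset reference).
2. **Cell sampling**: replicates are multivariate-hypergeometric
   partitions of one suspension (control design) or independent draws
   from per-section pools (experimental design).
3. **Expression and molecule sampling**: each cell emits
   `Poisson(rate·L)` transcripts with `L` log-normal of unit mean and
   log-sd σ (default 1.0; the study this emulates gives no quantitative
   per-cell dispersion estimate, so σ is a pragmatic default), and the
   transcript pool is subsampled without replacement to the requested
   UMI count. `σ = 0` with `poisson=False` gives the exact no-noise
   limit used by tests.

Because the generator's noise is *not* beta-binomial, the fitted model
is always tested against a (realistically) mis-specified truth.

**Spiked expansions.** Experimental sections multiply the cell counts
of `n_spiked` randomly chosen clones by a fold drawn from `fold_range`.
Spiked clones are drawn from the ground-truth frequency band
`[5e−4, 5e−3]`: below it an 8-fold change is statistically invisible at
desk-scale depths (one cell more or less), and above it the spike
dominates the section's composition, genuinely diluting every other
clone — the band emulates the mid-frequency local expansions the method
is designed to find while keeping "false positive" bookkeeping
meaningful in power simulations.

**Study-scale presets.** `tcell_paper_preset` (2,500 clones, rank
size-law exponent 1.8, 60,000 cells) is sized so that 15,000-cell /
13,000-UMI suspension-split replicates have downsampled clonality
≈ 0.25 — a strongly but not extremely expanded intratumoral CD8
repertoire. It uses the deterministic rank-abundance law because random
zeta draws make the realized clonality swing between ~0.07 and ~0.9
across seeds, which would make the preset's conditions irreproducible.
`bcell_paper_preset` carries 50% plasma cells (≈100× per-cell
immunoglobulin output), as in tertiary-lymphoid-structure-rich tumor
sections. The depth-mismatch scenario draws two null replicate pairs
from one B-cell tissue at a 10:1 cell ratio (defaults 500,000 vs
50,000) while holding the UMI count per replicate fixed (default
200,000) — the situation where a library looks deep by molecule count
but its frequencies rest on few cells.

**Sequences**: synthetic CDR3s are random in-frame nucleotide sequences
framed C…F/W with plausible V/J gene names and, for IGH, per-clone
isotype draws, so identity handling and I/O are exercised end to end.
All generators are bit-reproducible given (configuration, seed); no
global RNG state is used anywhere.

## What the synthetic tests do and do not show

Passing the simulation suites shows the statistics are correct *under
the generator's assumptions*: independent clones, exchangeable cells,
log-normal expression dispersion, no sequencing errors, no somatic
hypermutation, no spatial structure within a section. Real repertoires
add clone-correlated expression (activation state), UMI collision and
error artifacts, and hypermutated IGH lineages that fragment clonotype
identity (the `(cdr3_aa, v_gene)` identity mode is a partial remedy).
Conclusions about real tissue require the real control-replicate
design; the synthetic results demonstrate the machinery, not the
biology.

## Numerical choices and degenerate inputs

- Dispersion optimizer: bounded Brent search on log10 ρ, `xatol 1e−4`;
  non-convergence raises rather than silently flooring.
- ρ below 1e−12 is treated as exactly binomial (the α, β mapping
  overflows for denormal ρ).
- Clones absent from both samples are never tested; an empty testable
  set yields an empty call set with a warning, not an error.
- A monoclonal downsample draw has `ln S = 0`; its clonality is defined
  as 1.
- Correlation on fewer than 2 clones or zero-variance vectors raises a
  validation error instead of returning NaN.
- Samples too shallow for the clonality depth are skipped with a logged
  warning; the pipeline continues.
- Report regeneration from the same manifest and seed is byte-identical
  (no timestamps in any output).

## Scale of the shipped simulations

The test and acceptance simulations run at reduced but structurally
faithful sizes chosen as reasonable desk-scale study conditions:
100 null pairs at 15,000 cells / 13,000 UMIs for the zero-call
property; 50 power runs with 10 spiked 8-fold expansions among 3,000
clones at 20,000 UMIs; 50 depth-mismatch runs at 500,000 vs 50,000
cells with 200,000 UMIs per replicate.
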