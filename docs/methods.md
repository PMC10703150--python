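# Methods

This note documents the models, conventions and design choices behind
`hlaselect`, in the spirit of a statistical-software methods appendix.  It
states nothing the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate system and data model

All analyses run over the concatenated exon 2 + exon 3 protein alignment of
HLA class I: 183 columns, 1-based, exon 2 = positions 1–90, exon 3 =
91–183.  Allele names are IMGT/HLA style (`A*01:01`); the locus is the text
before `*`.  Sequences use the 20 amino-acid letters plus a single
gap/unknown symbol `X`; columns are analyzed over the observed non-`X`
symbols, and an allele contributes no indicator at a position where it
carries `X`.

Frequency tables map (population, allele) to a frequency in (0, 1].
Frequencies must be strictly positive because the regression target is
log₁₀ f; alleles present in the alignment but absent from a population's
table are simply absent from that population's rows (no pseudocount —
upstream registry-style frequencies are imputed positive values, and adding
mass would distort them).  Multi-locus haplotype tables are reduced to
single-locus tables by marginal summation, which conserves per-population
mass exactly (to float addition).

Region definitions (peptide-binding, Bw4, loop, helices, groove, exons,
excluded alleles) are user-editable YAML.  The shipped default uses the
canonical Bw4 epitope positions 77–83 and a classical pocket-residue list
for the peptide-binding set, plus a coarse structural partition of 1–183
into groove floor / helices / Bw4 / loops that is disjoint and exhaustive.
These are documented defaults from the structural literature, not a claim
about any particular study's exact lists; studies should supply their own
file.

## Frequency regression

Each (population, allele) row gets binary indicators, one per retained
(position, amino acid) pair; the target is log₁₀ frequency (base 10
throughout — switching bases only rescales β and cannot change rank
statistics).  A position is retained when at least 3 alleles differ from
its majority amino acid; below that, a coefficient would be determined by
one or two alleles and is meaningless.  In joint fits over loci a locus
indicator block is appended, and in joint fits over populations a
population indicator block after it.  The default pipeline mode is one
model per population over all loci jointly ("all-loci"), because a single
all-populations model mostly learns between-population frequency offsets
rather than sequence effects.

Model families: linear SVR (default), RBF SVR, ridge, lasso, OLS.  Library
default hyperparameters are the tuned values of the original study design:
linear SVR C = 0.01, ε = 2, no input normalization; RBF SVR C = 1, ε = 1
with z-scoring.  Those values were tuned on registry-scale data whose
log-frequencies span ~7 decades; on data with a narrower spread an ε of 2
swallows most of the variance, so `grid_search` offers a deliberately small
fixed grid (C ∈ {0.01, 0.1, 1} × ε ∈ {0.1, 0.5, 1, 2}) selected by
validation Spearman on an allele-level split.  No broader tuner is
included by design.

Train/test splits (80/20 by default) are made at the *allele* level: all of
an allele's rows land on one side, so joint fits cannot leak a given
allele's frequency profile across the split.  This is deliberately
stricter than row-level splitting.  Accuracy is the Spearman rank
correlation (average ranks on ties) between predicted and observed log
frequencies on the held-out alleles; constant predictions are reported as
ρ = 0 with a warning flag instead of NaN.

### The zero-sum gauge

Because each allele activates exactly one indicator per retained position,
adding a constant to all of a position's coefficients shifts every
prediction equally: per-position coefficient levels are a gauge freedom.
Reported β values are therefore mean-centered within each (population,
position) over the amino acids observed there, making them unique and
comparable across positions; the acceptance checks verify that this changes
no between-allele difference of the linear sequence score beyond 1e-9.

## Selection score Sβ and its permutation null

`Sβ(pos) = Σ_pop Σ_AA |β(pop, pos, AA)|`.  Two alternative aggregations are
available (mean of |β|, and frequency-weighted mean where each |β| is
weighted by its amino acid's frequency at the position); the sum is the
default and the one used for significance calls.  Sβ is mechanically larger
at positions with more amino acids and more populations — an acknowledged
bias toward diverse positions, which are also the positions the score is
meant to interrogate.

Significance comes from a scrambled-frequency null: allele→frequency
assignments are permuted (sequences fixed), the full per-population
regressions are refit with identical settings, and Sβ is recomputed; over
100 replicates a position is called significant when its observed Sβ
strictly exceeds the empirical 95th percentile of its null values.  No
multiple-testing correction is applied to the per-position calls — the
output states this.  Both the observed run and the replicates use
*full-data* fits (no train/test split): the null must differ from the
observed run only in the permutation.

Scramble scope.  Real (and generated) tables contain the same alleles in
several populations with strongly correlated frequencies.  Permuting each
population independently destroys that correlation, and under a no-effect
generator it measurably inflates the type-I rate of the percentile call
(observed Sβ is then a sum of nearly identical per-population |β| draws and
is heavier-tailed than the null).  The default scramble therefore draws one
random reassignment of alleles and applies it in every population, which
preserves the dependence structure while severing the sequence→frequency
link; per-population independent scrambling remains available via
`--scramble-scope within-population`.  Under the no-effect generator the
default null flags ~5% of positions; being a binomial fraction over ~60
positions, individual runs can land anywhere from 0 to ~0.12.

The amino-acid enrichment test sums |β| per amino acid over a chosen
position set (typically the significant non-peptide-binding positions),
builds the expectation by permuting the |β| values over the (position,
amino acid) cells, computes per amino acid `(obs − exp)²/exp` against a 1
df chi-square per mixing, and reports how often each amino acid attains
p < 0.05 across 100 mixings.  Permuting cells (rather than amino-acid
labels) is one of two defensible readings of "mixing all these values"; the
label-permutation alternative would hold each amino acid's cell count fixed
and is not implemented.

Region comparisons use Kruskal–Wallis across the regions of a partition
scheme plus two-sided Mann–Whitney U tests per region pair; a scheme with
fewer than two populated regions degenerates to a note instead of a test.

## Codon-level chi-square

Per codon column of an in-frame alignment: the consensus is the modal
nucleotide per column (ties broken alphabetically; ambiguity codes do not
vote); "mutants" are sequences whose codon differs from the consensus codon
(a codon differing at more than one nucleotide counts once, its translation
compared directly); `diff_aa_mutants` are mutants translating to a
different amino acid than the consensus.  The expected fraction of
amino-acid-changing mutants enumerates the 9 single-nucleotide changes of
the consensus codon, each weighted κ if a transition and 1 if a
transversion (κ = 1 reproduces the unweighted count exactly; κ ≠ 1 gives
the Kimura-style variant).  Then `expected = fraction × n_mutants`,
`χ² = (diff_aa − expected)² / expected`, p from χ² with 1 df (one observed
vs one expected count).  Columns with zero mutants report missing
statistics, not zeros.  Mutants whose translation is a stop are counted as
amino-acid changes by default (they certainly alter the protein);
`--stop-policy exclude` removes them from numerator and denominator.
Sequences containing non-ACGT codes are excluded before counting.  The
consensus is computed per input alignment; callers wanting a cross-locus
consensus should concatenate loci into one file.  This is deliberately a
counting statistic — no codon substitution model, no likelihood.

## Phylogenetic amino-acid depth

Trees are built per exon and per locus with deterministic neighbor joining
on per-site mismatch (p-) distances, rooted on the branch to an outgroup
allele from another locus; externally built trees (e.g. maximum parsimony)
can be imported as newick and bypass construction.  After rooting, the
outgroup is pruned and all reconstruction runs on the ingroup subtree —
this makes removal of the outgroup provably neutral for ingroup states and
levels, at the cost of not letting the outgroup vote in the root's Fitch
set.

Ancestral amino acids come from generalized (multi-child) Fitch parsimony:
bottom-up intersection-else-union over child state sets (`X` leaves act as
wildcards), one substitution counted per union; top-down, the root takes
the alphabetically first member of its set and every other node keeps its
parent's state when possible, else its own alphabetically first member —
deterministic and documented, though any tie-break is arbitrary.  The
implementation is checked exhaustively against brute-force enumeration of
all internal assignments for every rooted binary shape with ≤ 6 leaves and
≤ 3 states.

Node levels: leaves 0, internal node = max over children + 1.  The leaf-up
rule is ambiguous for unbalanced nodes ("child + 1" — which child?); the
height convention (max) is the default and `rule="min"` is available.
The depth matrix pools all nodes (leaves and internal):
p(i, k, j) = frequency of amino acid j among level-i nodes at position k,
and `H(k, j) = Σᵢ i·pᵢⱼ / Σᵢ pᵢⱼ` with level 0 included in the denominator,
so an amino acid occurring only in leaves has H exactly 0 rather than 0/0.
Exon-2 and exon-3 trees contribute their own position ranges and are
concatenated into one H over 1–183.

β–H association is the Spearman correlation over the (position, amino
acid) cells present on both sides, per population; fewer than 3 shared
cells or a constant vector is an error, never a silent 0.  The depth
models replace each one-hot indicator's 1 by H(position, amino acid) (0
where filtered or absent) — "depth-only" — or concatenate both blocks —
"both" — and delegate fitting and evaluation to the regression module.

## Synthetic data: what it emulates and what it does not

`generate_alleles` grows an allele set by random leaf duplication from a
root sequence, mutating 3 positions per branching event at designated
variable positions, each with a private alphabet of 2–5 amino acids; the
generating tree is returned.  This yields HLA-like hypervariable columns
(well-mixed states, pairwise differences in the tens) and genuine
phylogenetic correlation between sequence similarity and shared mutations.

`plant_effects` selects planted positions among those whose two most
common amino acids each occur in ≥ 10% of alleles — the diverse,
well-populated positions the selection score targets, which also makes a
±0.5 effect identifiable — and assigns +effect to the most common state,
−effect to the second, 0 to the rest (zero-sum per position, shared across
populations, matching the reported gauge).  `generate_frequencies` draws a
per-allele baseline log₁₀ frequency from Normal(−3, 0.5) *once*, shared
across populations, so alleles rather than populations dominate variance —
mirroring data where the same alleles recur across populations with
correlated frequencies — then adds the planted linear effect and
Normal(0, noise_sd) noise per population, exponentiates and renormalizes
per population.  Reference conditions used by the experiments module and
the reproduction script: 2,000 alleles, 60 variable positions, 5
populations, 10 planted positions of ±0.5, noise 0.1 — comparable to the
real per-locus scale (2,000–3,200 alleles) while fast on one CPU.

The generator does **not** emulate: linkage disequilibrium across loci,
recombination or gene conversion (excluded alleles are config input, no
detection), population-specific effect sizes, or realistic amino-acid
substitution chemistry.  Passing the recovery tests therefore demonstrates
that the pipeline's statistics behave as designed under their own model —
not that real HLA frequencies obey that model.

`generate_codon_alignment` derives sequences from a random sense-codon
ancestor with per-codon site classes: conserved sites accept only
synonymous single-nucleotide changes, neutral sites any non-stop change,
diversifying sites only amino-acid-changing ones (mutation probability
0.25 per sequence per codon by default).

All randomness flows from explicit integer seeds through named
`numpy.random.Generator` instances; no global state.

## Numerical conventions

* Percentiles: `numpy.percentile` (linear interpolation); the significance
  call uses strict `>`.
* Spearman: `scipy.stats.spearmanr`, average ranks on ties.
* LinearSVR: `max_iter` 20,000, fixed `random_state`, convergence warnings
  suppressed for the permutation-null refits.
* The RBF SVR's z-scoring is folded back into raw-feature space when
  coefficients are exported (linear kinds only; the RBF model exposes no
  per-feature coefficients and cannot feed Sβ).
* Frequency tables tolerate per-population sums up to 1 + 1e-6; generated
  tables renormalize to 1 within 1e-12.
* Determinism: the same config and seed reproduce result tables
  byte-for-byte; every run directory carries a manifest with the config
  hash and seed.

## Known limitations

* Sβ inherits the regression's identifiability limits: correlated
  (linked) positions share signal, and the score scales with amino-acid
  diversity.  It flags association, not causation.
* NJ on p-distances is a deterministic stand-in for full tree search;
  import externally built trees where topology fidelity matters.
* The permutation null refits on full data; calibration under
  registry-sized tables with heavy-tailed frequencies has only been
  verified under the synthetic generator's conditions.
* The codon statistic assumes a single consensus per alignment and equal
  mutability across codon positions (up to the κ weighting).
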