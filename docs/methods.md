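# Methods

## Equilibrium model of homodimerization on a two-half-site palindrome

A palindromic probe D carries two equivalent half-sites. Binding proceeds by
mass action: D + P ⇌ PD with per-half-site dissociation constant *K*d, and
PD + P ⇌ P₂D with the second event scaled by the cooperativity factor ω.
With free protein *p*, the probe species have relative abundances

    [D] : [PD] : [P₂D] = 1 : 2p/Kd : ω (p/Kd)²

The statistical factor 2 sits on the monomer term because the two
singly-bound configurations are indistinguishable on a gel — they
co-migrate as the single "monomer" band. ω = 1 means the half-sites fill
independently (the binomial limit); ω > 1 positive, ω < 1 negative
cooperativity; ω = 0 forbids the dimer species entirely.

**Free-protein solution.** At the assay's design point the probe (50 nM) is
comparable to the protein (25–800 nM), so protein depletion is material.
The conservation equation

    P_tot = p + D_tot · (2x + 2ωx²)/(1 + 2x + ωx²),  x = p/Kd

has a strictly increasing residual in *p*, so the root is bracketed on
[0, P_tot] and found by Brent's method, then polished with up to five
Newton steps (Brent's absolute tolerance can leave the residual above the
target when the residual slope is steep, i.e. tiny *p* at very large ω).
Convergence is enforced at |residual| < 1e-10·P_tot; the solver raises
rather than returning a stale root.

**Per-lane estimator.** From the relative abundances,
f_dim·f_free/f_mon² = ω/4 independently of *p* and *K*d, giving

    ω̂ = 4 · f_dim · f_free / f_mon²

The factor 4 is exposed as the documented constant
`OMEGA_STATISTICAL_FACTOR`. The estimator is validated in tests against the
forward solver (estimate ∘ solve = identity across a (Kd, ω, P_tot) grid),
not taken on faith. Lanes are included in the summary only when all three
band fractions are ≥ 0.05 (configurable within (0, 1/3]; beyond 1/3 no lane
could ever qualify): near-empty bands make the ratio numerically unstable
and the published convention uses the same cutoff. When no lane qualifies,
the estimate is the explicit sentinel `"ND"` — never NaN that would
propagate silently.

**Global fit.** `fit_titration` minimizes the summed squared deviation
between observed and model band fractions over all lanes, optimizing
(log *K*d, log ω) so positivity is structural, with a 3×3 multistart grid
(*K*d ∈ {10, 100, 1000} nM, ω ∈ {0.1, 1, 10}) to avoid local minima.
Standard errors come from the delta method on the residual Jacobian.
Degenerate series — all lanes > 99% free, or all < 1% free — raise an
`IdentifiabilityWarning` instead of silently returning arbitrary numbers.
Both the per-lane average and the global fit are provided because published
values could plausibly be either; they agree to within noise on simulated
data.

**Dual-probe preference.** The single-tube two-color comparison is reduced
to the per-concentration difference of dimer fractions,
index(c) = f_dim,A(c) − f_dim,B(c), positive when the protein prefers to
dimerize on probe A. The difference (rather than a ratio) is chosen so the
index stays defined when one probe shows no dimer at all.

## Spec-seq enrichment and energies

Fractional enrichment of variant *i* in a bound band is its band share over
its input share, with a symmetric pseudocount α (default 0.5, a
Jeffreys-style choice) on every count: E_i = ((b_i+α)/Σ(b+α)) /
((n_i+α)/Σ(n+α)). Enrichment is invariant to sequencing depth per band.
Relative binding energy follows the standard Spec-seq convention
ΔΔG_i = −ln(E_i/E_ref) in kT units, lower = tighter; the reference sequence
is user-specified (the convention pins ΔΔG(ref) = 0, and changing the
reference only shifts all energies by a constant). Methylated libraries are
handled as a condition label, not a fifth alphabet symbol: 5mC has the same
sequence identity as C for enumeration. Ranking ties break
lexicographically so outputs are deterministic.

## Motif scanning

PWMs store per-position probabilities over A/C/G/T with a strictly positive
background (uniform by default); scores are log₂ odds with a 1e-9
probability floor so zero cells stay finite but prohibitive. A window is a
hit when its score reaches `threshold_fraction × max_score` (default 0.85);
the fraction-of-maximum semantics make thresholds comparable across PWMs of
different lengths and information content. Palindromy is auto-detected from
the consensus (equal to its reverse complement) with a constructor
override; palindromic PWMs are scanned on the plus strand only so each
genomic site is reported exactly once, asymmetric PWMs on both strands with
the strand recorded. Windows containing N are skipped and counted in the
debug log. Coordinates are BED-style 0-based half-open everywhere;
conversions (e.g. 1-based cytosine reports) happen exactly once, at the
reader boundary.

The shipped consensus matrices — CpGpal `ATGCGCAT`, MORE `ATGCATATGCAT`,
Octamer `ATGCAAAT` — are near-deterministic reconstructions
(`pwm_from_consensus`, match probability 0.997), not experimentally
measured matrices.

Peak–motif occupancy uses hit centers within ±window/2 of the peak center
(summit offset when available, midpoint otherwise), window default 100 bp.
Motif co-occurrence reports both the fraction of a-sites with a b-site
center within 200 bp and the fraction with direct coordinate overlap.

## Methylation, trajectories, accessibility, conservation

The core CpG of a palindromic 2k-mer site [s, e) is the dinucleotide at
positions (center−1, center); a report row matching either position serves
as the core value. The window mean averages the per-CpG fractions (not the
pooled counts) of all CpGs within ±window/2, window default 100 bp. CpGs
below `min_coverage` (default 1 read — the loosest defensible choice, since
the upstream convention does not state one) are ignored; a site with
nothing left is undefined (NaN / `<NA>`), which is deliberately distinct
from unmethylated.

A site is *methylated* under the default `full` rule only when its core
fraction equals 1.0 within 1e-12 — 0.99 does not qualify. For motifs
without a core CpG (Octamer, MORE) the `threshold` rule on the window mean
(default 0.8) is offered as a documented reconstruction. Trajectories over
ordered timepoint labels (no interpolation): the cohort is sites methylated
at the first timepoint; the end state at the last timepoint is
`remains_methylated` or `demethylated`, with coverage loss giving
`undefined`. The classes partition the cohort by construction.

Accessibility is mean per-base coverage in the site window against a user
threshold (no published intensity threshold exists to adopt; the synthetic
generator plants unambiguous classes instead). Conservation profiles are
position-wise means over motif-centered windows of length motif + 2·flank,
minus-strand sites flipped into motif orientation, missing bases excluded
per-position with counts reported.

## Synthetic data

The generator exists so every stage is testable against planted truth with
no external downloads. One global seed fans out through
`SeedSequence.spawn` into fixed per-generator substreams, so runs are
byte-identical per (config, seed) and adding a generator never shifts the
others.

- **Genome**: i.i.d. bases at GC fraction 0.42 (a typical mammalian bulk
  value); motifs planted at non-overlapping uniform positions with a
  one-motif-width exclusion margin. No dinucleotide structure — adequate
  for planted-truth tests, but background hit rates will not match real
  genomic CpG depletion.
- **Methylome**: every cohort site starts fully methylated; the maintained
  class stays at 1.0, the demethylating class decays linearly to 0 across
  timepoints (the simplest monotone model of gradual loss; the shape is
  configurable). Counts are binomial at coverage 20. Defaults: 400 sites,
  60/40 maintained/demethylating over 4 timepoints.
- **Titration**: band fractions from the forward model at *K*d = 100 nM,
  ω = 5, probe 50 nM, protein 25–800 nM; intensities get multiplicative
  lognormal noise (CV 5%) per band, emulating gel quantification error.
- **Spec-seq**: input counts multinomial-uniform; bound counts multinomial
  with weights ∝ exp(−ΔΔG). No PCR bias or sequencing error model.
- **Accessibility/conservation**: piecewise-constant tracks planting
  unambiguous open/closed classes and a conservation dip at site centers.

Because the generators plant clean, well-separated classes, perfect
recovery in tests demonstrates the correctness of the estimators and
classifiers — not their robustness to the messier failure modes of real
data (partial methylation heterogeneity, copy-number effects, mappability
gaps, antibody efficiency differences between ChIP timepoints).

## Problem sizes and numerical choices

The default test and acceptance workloads use a 1-Mb single-chromosome
genome with 50 planted palindromic sites, 400-site methylation cohorts at
coverage 20, 10-seed titration replicates, and Spec-seq depths of 1e5–1e6 —
sizes at which every planted-truth check is exact while the whole suite
runs in seconds. Equilibrium solving is exact to |residual| < 1e-10·P_tot;
scanner score comparisons use a 1e-9 slack so threshold-equal windows are
kept regardless of floating-point rounding; Spearman concordance uses
average ranks on ties.

## Known limitations

- The dimer model assumes two *equivalent* half-sites and a single
  cooperative coupling; heterodimers and probes with unequal half-sites are
  out of scope.
- Per-lane ω̂ is unbiased only as band-fraction noise → 0; at 5% gel noise
  the lane average is slightly high-biased (the estimator is convex in the
  fractions), which is why the global fit is also provided.
- The scanner loads each chromosome as a Python string and the bedGraph
  reader densifies tracks; both are sized for synthetic or small genomes,
  not whole mammalian genomes.
- Enrichment→energy conversion assumes the bound band samples the
  equilibrium Boltzmann distribution (no kinetic partitioning during
  electrophoresis).
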