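# Methods

`ibptrace` reconstructs where in a species phylogeny a set of gene families
(the motivating case: the twelve enhancer-blocking insulator binding
proteins, IBPs, of *Drosophila melanogaster*) originated, from transcriptome
assemblies alone.  The pipeline chains six analyses: profile-HMM homology
screening of six-frame-translated transcripts, reciprocal-best-hit (RBH)
orthology calling, domain-architecture annotation, maximum-parsimony
ancestral gain/loss reconstruction on a fixed species tree, distance-based
gene trees for duplication and paralogy checks, and branch-model dN/dS
likelihood-ratio tests.  A synthetic-data generator reproduces the
statistical structure each stage assumes, with full ground truth, so every
stage is testable without any external download.

## Profile HMMs (`phmm`)

Profiles use a simplified Plan7-like architecture: a linear core of
match/insert/delete states flanked by background loop states, with uniform
local entry into any match state and uniform local exit (so partial-profile
matches — fragmented transcripts — score naturally).  The model is
single-hit; tandem domain copies are recovered by iterative masking rather
than multi-hit glue.  Scoring is log-odds against an i.i.d. background
null, computed by the forward algorithm in log space; scores are reported
in bits.  Design points:

- **Match-state selection**: columns with non-gap fraction ≥ 0.5
  (configurable), the usual seed-alignment rule of thumb.
- **Emission smoothing**: observed counts mixed with
  `pseudocount_weight × background` (default 20), normalized.  The
  background defaults to amino-acid frequencies pooled over the seed MSA.
- **Transitions**: bigram counts along each row's match/insert/delete state
  path with a +1 pseudocount.
- **Stops**: `'*'` has zero emission probability in match and insert
  states but passes freely through the flanks, which confines matches to
  stop-free stretches of a translated frame.  This reproduces the effect of
  screening six-frame translations without inventing an ORF caller.
- **E-values**: a Gumbel law is fitted (`scipy.stats.gumbel_r.fit`) to
  forward bit scores of n ≥ 200 background-random sequences, seed-pinned.
  E-value = `db_size × SF(score)` with `db_size` the number of frames
  actually scored.  This calibration is noisier than an analytic one, but
  the operating threshold (E ≤ 10⁻¹⁴) sits far from the decision boundary:
  planted orthologs score hundreds of bits above random sequences, so
  calibration noise does not move presence calls.
- Envelope and profile-coverage coordinates come from a Viterbi traceback;
  the forward score decides significance.

The forward recursion is verified against an exhaustive path-enumeration
oracle (profiles ≤ 3 match states, sequences ≤ 4 residues) to 10⁻⁶ bits.

## Orthology and completeness (`orthology`)

A transcript is called an ortholog of gene *g* only if (i) some frame
passes the E-value threshold (default 10⁻¹⁴) and (ii) the best-scoring
entry across all pooled reference proteomes — Smith–Waterman–Gotoh local
alignment, BLOSUM62, gap open −11 / extend −1, ties broken by reference
order then entry id — carries label *g*.  The reciprocal query is the full
stop-free ORF containing the hit envelope, not the envelope alone: the
surrounding protein context is what distinguishes a gene from a
shared-domain paralog (the Su(Kpn)/FLYWCH-style confounder).  Rejection of
such confounders presumes the decoy family is itself represented in the
reference database, as it is in any comprehensive nr-style collection.

Copy counts collapse transcripts that are mutually ≥ 97 % identical (local
alignment, identity over the shorter sequence); the threshold is a stated
convention, configurable.

Completeness is assessed BUSCO-style against conserved single-copy gene
profiles: *complete* if a significant hit (default E ≤ 10⁻⁶) covers
≥ 70 % of the profile's match states (`frag_fraction`), *fragmented* if
significant but shorter, *missing* otherwise.  BUSCO's sigma-based length
heuristics and gene-model refinement are deliberately not reproduced.
Summary quartiles use type-7 linear interpolation (the convention behind
the published summary table is unstated; ours is documented).

## Ancestral reconstruction (`phylo`)

Presence/absence characters are reconstructed under unordered (Fitch)
parsimony by a two-pass dynamic program over states {0, 1} that handles
multifurcating nodes natively (pruning a polytomous backbone to binary
would silently change parsimony lengths).  The program computes, per node,
the exact set of states realized across *all* most-parsimonious
resolutions; nodes whose set is not a singleton are reported *equivocal*,
mirroring how MP reconstructions are usually displayed.  Event lists
require an explicit resolution: DELTRAN (default; delays changes toward
the tips, root ties resolve to absent — conservative on gains) or ACCTRAN.
Both are dynamic-programming tracebacks, so the event count always equals
the parsimony length.

Dollo parsimony is provided alongside: exactly one gain at the MRCA of the
present leaves, losses minimized given that constraint.  Dollo length ≥
Fitch length always, with equality iff presence is compatible with a
single gain.

Gene trees are a documented stand-in for a full ML tree search: pairwise
maximum-likelihood distances under the WAG replacement model
(rate-homogeneous; the Γ rate-heterogeneity of the original analysis is
dropped), neighbor joining (scikit-bio), and a nonparametric
column-resampling bootstrap.  The downstream consumers — duplication
flags and the paralogous-family grouping test — need topology, not
branch-support fidelity.  Two gene copies in one species flag *recent*
duplication when they are sisters and *ancient* (pre-speciation) when not;
family A "groups inside" family B when no single edge separates the two
leaf sets.

## Selection tests (`selection`)

A Goldman–Yang-type codon model over the 61 sense codons: target-codon
frequency π_j times κ for transitions, times ω for nonsynonymous changes;
zero for multi-nucleotide changes; scaled to one expected substitution per
codon site at equilibrium.  Codon frequencies default to F1x4 estimated
from the alignment.  Likelihoods come from Felsenstein pruning with
per-node rescaling; transition matrices from eigendecomposition of the
π-symmetrized generator.  Site patterns are compressed; gap/ambiguous
codons are missing data.

The branch test follows the two-class description (not the PAML
branch-site Model A): the null fixes ω ≡ 1 everywhere and optimizes κ and
all branch lengths (L-BFGS-B on log-parameters); the alternative holds
branch lengths at the null optimum and re-optimizes (κ, ω_foreground) from
three seed-pinned starts, warm-started at the null solution — so
lnL₁ ≥ lnL₀ holds by construction and the LRT 2(lnL₁ − lnL₀) is compared
to χ²(1).  A deficit beyond 10⁻⁶ raises an error rather than being
silently absolute-valued (published tables occasionally contain such
rows; they indicate a non-converged fit, not a negative statistic).
Bonferroni control divides the family level (default 0.05) by the number
of tests actually run in the batch.

## Synthetic data (`synthio`)

The generator emulates what the real study consumed, at desk scale, and
keeps the truth:

- **Species trees**: Yule process, exponential waiting times, default
  birth rate 1; leaves are contemporaneous.
- **Gain/loss histories**: two-state Markov process down the tree
  (default gain 0.25, loss 0.15 per unit branch length, root absent unless
  forced present); recorded events are net per-branch changes, so Fitch
  length ≤ true event count by construction.
- **Protein families**: an ancestral protein concatenates shared domain
  motifs per the configured architecture (zinc-finger-like motifs of
  23 aa, BTB 40 aa, …) joined by fixed-length random linkers, then evolves
  by i.i.d. per-site substitution (default 0.08 substitutions/site per
  unit branch).  No indels — the family alignment is therefore gap-free
  and domain copy-number truth is exact.  Decoy paralogs recombine the
  same domain motifs into unrelated backbones.
- **Transcriptomes**: uniform synonymous back-translation, random UTR
  flanks, random strand, random noise transcripts; genes are kept
  full-length with the per-species completeness probability, else
  fragmented (25–60 % of length) or dropped.  Default per-species targets
  are drawn from [0.15, 0.81], bracketing the completeness range the
  method is expected to tolerate.
- **Codon alignments**: Gillespie simulation per site and branch under the
  scaled generator, with branch-class ω; every substitution event is
  recorded, so nonsynonymous/synonymous counts per branch are exact.
- The **default panel** is 12 species × 6 families (architectures
  mirroring the known IBP domain compositions), 20 conserved single-copy
  genes for completeness, 2 reference proteomes plus decoys, one family
  designated positively selected (ω_fg = 4) in its codon alignment.

What the generator does *not* emulate — alignment error, codon usage bias,
indels inside domains, chimeric or cross-contaminated assemblies,
rate-heterogeneity across sites — bounds what green tests show: they
validate the algorithms against the model's own assumptions, not the
pipeline's robustness to every artifact of real transcriptome data.

## Problem sizes and numerics

Simulation studies run at sizes chosen to make their statistical bands
meaningful while keeping the whole suite interactive: parsimony oracle
checks on 500 random trees of ≤ 12 leaves; forward-algorithm oracle checks
on all-toy instances; pruning-likelihood oracle checks on 50 three-taxon
instances (tolerance 10⁻⁸); selection type-I error on 100 neutral
datasets of 300 codons on a 5-taxon tree and power on 10 datasets of 500
codons with ω_fg = 4; completeness calibration over 10 seeds at the
published median operating point (57.9 % complete).  Optimizer settings:
L-BFGS-B with `ftol 10⁻⁹`, log-parameterization, branch lengths bounded in
[e⁻⁹, e^2.5]; eigendecomposition tolerance is machine precision with
probabilities clipped at 10⁻³⁰⁰.

## Known limitations

- E-value calibration is empirical; absolute E-values are not comparable
  to HMMER's, only the ≤ 10⁻¹⁴ decision is.
- Gene trees are NJ-based; deep, short internal edges may be unresolved
  where a full ML search might resolve them.
- The branch-model fit holds branch lengths at the null optimum in the
  alternative; this keeps the models nested and the test valid but can be
  mildly conservative relative to a full joint re-optimization.
- Dollo reconstruction assumes the character can only be invented once;
  it is reported alongside Fitch, and the package takes no stance on which
  is biologically right for a given family.
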