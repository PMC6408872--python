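# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind each module, in the order data flows through the
pipeline.

## Coordinates and formats

All internal coordinates are 0-based half-open; GFF3 output and
human-facing reports are 1-based inclusive. Sequence I/O goes through
Biopython for FASTA; relaxed *sequential* PHYLIP (whitespace-delimited
names of any length, rows possibly wrapped) has a small dedicated reader
because the common library dialects cover either relaxed names or
sequential layout but not both; interleaved PHYLIP is rejected with an
explicit message. Trees are dendropy objects at module boundaries and flat
indexed arrays internally. Unknown residues (N/X) are kept, never dropped.

## Assembly statistics

N50/N90 follow the "smallest length L such that contigs ≥ L cover ≥ x% of
the total" convention with ties resolved toward the larger contig, matching
common assembler reports. GC content excludes ambiguity codes from both
numerator and denominator. GC and GC-skew tracks are non-overlapping
windows exported as 4-column TSV (contig, start, end, value), a flat file a
Circos configuration can ingest; windows with zero G+C emit value 0 plus a
flag rather than NaN.

## MSDIN mining

The precursor grammar is leader (ending in the POPB-cleaved proline), core
(7–10 residues, ending in proline), follower. `extract_core` chooses among
admissible proline pairs the one whose leader length is closest to 9
(ties to the shorter leader): MSDIN-family leaders are ~9–10 residues and
the *Lepiota* variant is one residue shorter. The leader profile is a
Laplace-pseudocounted position weight matrix scored in bits against a
uniform background; its threshold defaults to the minimum training-set
score minus 1 bit, so the training precursors always pass and the margin is
explicit rather than hidden.

`scan_orfs` translates all ATG..stop candidates on both strands, optionally
re-assembled across one canonical GT..AG intron (default length 40–200 bp —
fungal introns are short). Splice variants of one locus necessarily share a
leader and therefore a profile score, so the scanner collapses them by a
deterministic preference: leader score, then whole-precursor identity to
the nearest training precursor (real MSDIN followers are family-conserved,
which is what makes this informative), then fewest introns, then shortest
span. Only coding-region introns are modeled; UTR exons would require
transcript evidence and are out of scope. Genetic code: standard table.

The homology search is a profile scan plus local alignment rather than a
wrapper around an external BLAST; the search front-end is interchangeable
and keeping it in-process makes the false-positive behavior testable (a
random-sequence contig at matched GC yields no hits at the default
threshold).

## Spliced alignment

`spliced_align` is a dynamic program over (genomic × CDS) positions with
match/mismatch (+2/−3), affine exon gaps (−8 open, −2 extend), and an
intron state that opens only at GT, closes only at AG, costs a flat −10,
and has no per-base cost. Genomic flanks are free (fit alignment of the
full CDS). The minimum intron length (default 40 bp) is enforced exactly by
a delay line; because introns are free per base, the upper bound is
advisory. Ties resolve to the leftmost intron start. A result scoring below
`0.5 · match · |CDS|` raises `NoModel`. The implementation is row-vectorized
NumPy with int8 backpointers; a 3.1-kb gene against a 2.2-kb CDS aligns in
about a second. Correctness is checked against exhaustive enumeration of
intron placements on small inputs.

## Peptide chemistry

Residue formulas are summed and one water added for a linear chain; a
head-to-tail cycle has one water fewer. Monoisotopic isotope masses: C 12
(exact), H 1.0078250319, N 14.0030740052, O 15.9949146221, S 31.97207069.
The amatoxin modification preset is −2H +5O — the tryptathionine Trp–Cys
bridge (−2H), four hydroxylations and one sulfoxide (+5O) — stated as a
preset, not inferred biochemistry; it maps cyclo(IWGIGCNP) onto the
α-amanitin formula C₃₉H₅₄N₁₀O₁₄S exactly. The default [M+H]⁺ convention
adds a hydrogen-*atom* mass (1.0078250); the stricter proton mass
(1.0072765) is available via an option, and the two differ by ~0.6 mDa.
Isoleucine and leucine share a formula and are reported as such. Peak
matching reports every (peak, candidate) pair within the ppm tolerance
(default 10 ppm); one peak may match several candidates.

## Likelihood machinery

GTR+I+Γ with exchangeabilities (GT fixed at 1), stationary frequencies,
4 discrete gamma categories by mean of equal-probability quantile bins, and
an optional zero-rate invariant class mixed in as
`(1−p_inv)·mean_cat + p_inv·I(constant site)`. The rate matrix is scaled to
mean rate 1 and decomposed via the symmetrized eigensystem, so P(t) costs
one 4×4 multiply per branch per category. Pruning runs over
pattern-compressed columns; gaps and ambiguity codes are missing data
(all-ones partials). Per-site log-likelihood vectors always sum to the
total (tested), and the likelihood is invariant under re-rooting
(reversibility) and leaf order.

Optimization is coordinate ascent: bounded Brent on each branch
(t ∈ [1e-9, 10]), then on α (log scale, [0.02, 50]), p_inv and the five free
exchangeabilities when requested; a proposed move is kept only if it does
not decrease the likelihood, so lnL is non-decreasing. Convergence at
ΔlnL < 1e-6 or 100 rounds. The Brent x-tolerance is a parameter: final fits
use 1e-6, the inner loop of tree search uses 1e-3.

Tree search is NJ (deterministic lexicographic tie-break on the Q matrix)
followed by NNI hill-climbing: every neighbor is screened at carried branch
lengths with a plain likelihood, the top three candidates are re-optimized,
and the first that improves is accepted; moves violating a clade constraint
are never taken. This is deliberately not an SPR/ML-grade search; on data
simulated from trees whose internal branches are resolvable (≥ ~0.05
substitutions/site) it recovers the generating topology reliably, but
random Yule trees can contain arbitrarily short internal branches that no
search could resolve at finite alignment length — recovery tests therefore
use a fixed resolvable topology. Bayesian inference is out of scope;
bootstrap support is available instead.

## AU topology test

Per-site log-likelihoods of each candidate topology (branch lengths re-fit
per fixed topology) are resampled B times at the ten canonical scales
0.5–1.4. BP is the fraction of replicates where a tree attains the maximum,
with exact ties split equally, so BP sums to 1 across trees at every scale.
The AU p-value comes from weighted least squares on
Φ⁻¹(1−BP_r) = d·√r + c/√r with delta-method weights from the binomial
variance of BP; AU = 1 − Φ(d − c). Degenerate cases (BP ≈ 0 or 1 at nearly
all scales) short-circuit to 0 or 1 — a dominated tree needs no fit. The
`obs` column reports lnL(best) − lnL(tree), with the best tree showing the
negated gap to the runner-up. Under a symmetric two-tree null with iid
equal-mean site contributions the rejection rate at α = 0.05 is calibrated
(checked at 1000 replicates). B defaults to 10,000; the test suite uses
1000–2000, which is enough for the decisive contrasts it checks.

## Reconciliation

DL uses the LCA mapping (optimal for duplication+loss): duplication where a
gene node maps to the same species node as one of its children, losses from
depth differences (one fewer along speciation edges). DTL is a dynamic
program over gene nodes × species nodes on an *undated* species tree:
speciation free, duplication δ, transfer τ with the recipient restricted to
branches incomparable to the donor, and one loss λ per species branch
skipped during a descent. Defaults δ=1.5, τ=3.0, λ=1.0 (Notung's weighting,
which reproduces event-score arithmetic such as 5·1.5 + 31·1.0 = 38.5 and
5·3.0 + 9·1.0 = 24.0). The DP also counts co-optimal solutions; traceback
reports one optimum with a deterministic preference (speciation >
duplication > transfer, then preorder species rank). Verified exhaustively
against an independent closed-form enumeration over species-node
assignments on small instances; DTL ≤ DL holds for every input because
transfers are optional. Dated (time-consistent) DTL is a non-goal.

## Rates

NG86 counting: synonymous-site fractions per codon position with changes to
stop codons counted as nonsynonymous — this keeps S+N = 3 per codon, which
is asserted; multi-position codons average differences over substitution
pathways, skipping stop-crossing pathways when any stop-free pathway
exists. Jukes–Cantor correction with p ≥ 3/4 flagged as saturated (distance
undefined rather than clamped). This counting estimator stands in for ML
(codeml-style) estimates: the claims built on it here are orderings and
fold-ratios (housekeeping vs toxin-locus divergence), which are robust to
the counting-vs-ML choice. Genus-level distance ratios use the mean
JC-corrected nucleotide distance over cross-genus pairs (pairwise gap
deletion), with the housekeeping locus (rpb2 by default) as numerator.

## Synthetic data

Every generator is a pure function of (parameters, seed).

* **Planted MSDIN contigs** — the canonical conserved leaders
  (MSDINATRLP / MFDTNATRLP / MDANATRLP) and a conserved proline-free
  follower reflect the real family's conservation pattern (leader and
  follower conserved, core hypervariable); a mutation-rate parameter
  (default 0) substitutes non-anchor residues. Reverse translation picks
  synonymous codons tilted toward the target GC — composition, not a real
  codon-usage table, is what the miner sees. Background DNA is iid at the
  stated GC: sufficient for false-positive testing, silent on repeats.
* **Trees** — Yule species trees (uniform random tip splitting, exponential
  waiting times, ultrametric). Gene trees evolve top-down with per-branch
  Poisson duplications, losses, and *replacing* transfers (the transferred
  copy displaces the recipient's resident copy — the single-copy POPB
  scenario); donors are uniform over contemporaneous incomparable branches.
  The truth records every event and flags transfers that are identifiable
  from topology: a transfer into the donor's live sister branch leaves the
  topology unchanged (only the node age moves) and is unrecoverable by any
  topology-based method, so recovery tests score against the identifiable
  count.
* **Sequences** — forward GTR+I+Γ simulation from stationarity;
  category-resolved transition matrices from the same eigensystem as the
  likelihood code uses (the simulator and the scorer share the model but
  not the algorithm — simulation draws states, scoring integrates them
  out).
* **Codon pairs** — single-nucleotide exchanges between sense codons at
  rate 1 (synonymous) or ω (nonsynonymous), uniform codon frequencies, no
  transition/transversion bias, scaled to one expected substitution per
  codon per unit time at ω=1; divergence split evenly around a uniform
  ancestor.
* **Peaks** — Gaussian ppm noise on true masses plus uniform decoys
  excluded from ±3σ windows around every true mass.

What passing on synthetic data does *not* show: robustness to repeats and
assembly error in real contigs, to alignment error in real alignments
(alignments are consumed, not computed), to rate heterogeneity beyond Γ+I,
or to incomplete lineage sorting (no coalescent simulation).

## Study-condition stand-ins used in the validation suite

The validation suite exercises the printed worked examples on synthetic
constructs built to the same geometry: a 571-bp contig with a 154-bp
single-intron MSDIN gene (99 bp coding, 55 bp intron, 32-aa precursor with
the core at residues 10–17); a 3118-bp POPB-scale gene with 18 exons,
17 introns and a 731-aa product; and a 31-taxon species tree vs 20-taxon
POP gene tree in which the POPB clade (Lepiota basal, Amanita terminal)
contradicts a species phylogeny with Amanita early-diverging and
Galerina+Lepiota sisters. These stand-ins are labelled synthetic in the
code; conclusions drawn from them are structural (counts, spans, DTL < DL,
transfer presence), not numerical reproductions of any particular dataset.

## Problem sizes in the default test run

Simulation-based checks use: 8 taxa × 5000 sites × 20 seeds for the AU
accept/reject contrast (B = 1500); 1000 replicates × 200 sites (B = 1000)
for the AU null calibration; 100 planted contigs of 1.5 kb for miner
recovery; 100 seeds of 800-site alignments for the distance-ratio property;
100 seeds of 10-taxon trees at transfer rate 0.1 for transfer-count
recovery. These sizes were chosen so each check is decisive at its stated
threshold while the whole suite stays a desk-scale run.
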