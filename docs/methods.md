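# Methods

`tifykit` re-implements, as a tested library plus CLI, the standard analysis
arc for a plant transcription-factor gene family — here the TIFY family,
whose subfamilies (JAZ, ZML, TIFY, PPD) are defined by domain architecture:
every member carries a TIFY domain with the TIF[F/Y]XG core hexamer; JAZ
proteins add a C-terminal Jas motif (SLX₂FX₂KRX₂RX₅PY), ZML proteins a CCT
motif and a C2C2-GATA zinc finger, PPD proteins an N-terminal PPD domain.
Because no genome or read archive ships with the package, a synthetic-data
generator produces every input with recorded ground truth; the tests measure
whether the analysis recovers what was planted.

## Motif scanning and subfamily classification

Profile-HMM search is replaced by degenerate-consensus scanning (an L×20
PSSM can be supplied instead).  A consensus is a string of literals, `X`
wildcards and `[FY]`-style classes; a window is a hit when all *anchor*
positions match, at most `max_mismatches` non-anchor positions mismatch, and
the summed BLOSUM62 score of the non-wildcard positions reaches the model
threshold.  Defaults: TIFY `TIF[FY]XG` (anchors at the [FY] and terminal G,
threshold 15 — low enough to accept the catalogued variants TLSFQG, IIFYDG,
TIIYGG, TLVYQG, TLLFQG, whose scores range 17–28), Jas
`SLXXFXXKRXXRXXXXXPY` with the KR..R..PY residues anchored, and stylized
CCT/GATA/PPD surrogates whose anchors are the field's canonical residues
(e.g. the C-X₂-C…C-X₂-C zinc-finger spacing).  Anchors and thresholds were
chosen analytically for low false-positive rates under a uniform amino-acid
background (expected spurious anchor matches ≪ 1 per family scan), not fit
to data.  Overlapping same-motif hits resolve to the highest score, ties to
the leftmost window.

Classification order: no TIFY domain → unassigned; PPD → PPD; GATA → ZML;
CCT without Jas → ZML; Jas → JAZ; TIFY alone → TIFY.  GATA outranks a
co-occurring Jas motif because the one catalogued protein carrying
TIFY+Jas+CCT+GATA is a ZML; a bare CCT call does not overturn a JAZ
architecture because the Jas motif resembles the CCT N-terminus.

## Homology

`smith_waterman` is a local affine-gap alignment (BLOSUM62, gap open −10,
extend −1) computed by Biopython's `PairwiseAligner`; identity and
"positives" (aligned pairs with positive substitution score) are computed
over aligned non-gap columns, the BLAST convention.  The first optimal
traceback the aligner enumerates is used, which is deterministic for fixed
inputs.  E-values use the Karlin–Altschul form E = K·m·n·e^(−λ·score) with
gapped-BLOSUM62 constants K = 0.041, λ = 0.267 — any monotone surrogate
preserves the threshold semantics, and the constants are configurable.
Orthologue calls are reciprocal best hits between genomes at E < 1e-10,
score > 200, positives > 70%; paralogue calls are within-genome RBH at the
stricter E < 1e-50, score > 200, positives > 80%.  Best-hit ties break to
the lexicographically smallest subject id.

## Phylogenetics

Distances are p-distance or Poisson-corrected (−ln(1−p)) with pairwise
deletion of gap columns; a pair with no comparable columns is an error, and
Poisson-saturated pairs are clamped to the largest resolvable distance and
flagged rather than stored as infinities.  The likelihood model the original
analysis used for its protein tree (JTT+Γ) is not re-implemented: it is
un-parameterized in the source and NJ topology at family-level divergence is
robust to the substitution; the nucleotide confirmation tree uses p-distance
in any case.  Neighbor-Joining uses the Q-criterion with Studier–Keppler
updates, joins tie-broken to the smallest (i, j) index pair, and negative
branch lengths clamped to zero (no length transfer) — deterministic, and
exact on additive matrices (verified against scikit-bio's implementation and
against path-distance additivity).  Bootstrap supports resample alignment
columns with replacement; each internal edge of the full-data tree is
annotated with the percentage of replicate trees containing the same
bipartition (no consensus tree is built), replicates with an incomparable
pair are redrawn and counted.  Default 1,000 replicates.

## Ka/Ks and dating

The estimator is NG86 (the named calculator tool bundles several estimators;
NG86 is the canonical, fully specifiable default and the method name is
recorded in the output).  Per sense codon, the synonymous site count s sums,
over the three positions, the fraction of single-base changes that are
synonymous, with changes to stop codons removed from numerator and
denominator; n = 3 − s, so s + n = 3 exactly.  For a codon pair differing at
k positions, difference counts average the synonymous/non-synonymous step
classifications over all k! single-step pathway orderings, excluding
pathways through stop codons; if every pathway is excluded the average falls
back to all pathways (stop-crossing steps counted non-synonymous) and the
result is flagged.  Gap- or stop-containing codon columns are dropped
pairwise.  With S the mean of the two sequences' site totals, ps = Sd/S and
Ks = −¾·ln(1 − 4ps/3) (undefined at ps ≥ 0.75, flagged, and excluded from
dating with a warning count); likewise Ka, and ω = Ka/Ks when Ks > 0.
Codon alignments are threaded from a global protein alignment back onto the
CDSs (trailing stop stripped; translation verified codon by codon).

Dating is the strict molecular clock T = K̄s/(2λ) with λ = 6.5×10⁻⁹
synonymous substitutions per site per year (the grass rate) as default:
K̄s = 0.51 → 39.2 MYA, 0.58 → 44.6 MYA.  ω classifies selection (< 1
purifying, = 1 neutral, > 1 positive, with an optional neutrality band,
default exact).

## The synthetic-data generator

The generator's defaults are the study conditions.  Family design: 24
focal-genome members (18 JAZ, 5 ZML, 1 TIFY) arising from 18 ancestors plus
6 within-genome duplications (5 JAZ, 1 ZML); three genomes on a star
phylogeny with branch Ks {0.22, 0.29, 0.29}, giving pairwise orthologue
divergences {0.51, 0.51, 0.58}; paralogue divergence Ks 0.22; ω = 0.5 on
every branch.  Members are 240-residue proteins (uniform background, motifs
planted non-overlapping, Jas near the C terminus) — a fixed length so the
simulated family is trivially alignable, since multiple-alignment
construction is deliberately out of scope (aligned FASTA is the pipeline
input).  CDSs are back-translations with uniform synonymous codon choice.

Codon evolution targets the *observed* divergence: the synonymous difference
budget is p_s·S with p_s the inverse Jukes–Cantor transform of the target
Ks, placed at distinct nucleotide positions with stop-creating proposals
rejected (likewise Ka against N).  Non-synonymous changes are placed first
and the synonymous budget is computed against the mean S of the final pair —
amino-acid replacement drifts codon composition toward higher-degeneracy
codons, and budgeting against the ancestor alone would bias estimator
recovery by ~−10% at Ks ≈ 0.5.  Replacements are restricted to
BLOSUM62-positive exchanges and motif codons accept only synonymous change,
both emulating purifying selection; this keeps alignment positives in the
range real homologs show (without it, random replacements give ~60%
positives and the 70% orthologue threshold rejects true pairs).  Estimator
recovery on single-branch pairs is unbiased to within ~2% across
Ks ∈ [0.1, 0.58].  Two caveats the tests document: composed two-branch
divergences estimate ~4–6% above the planted sums (within-branch
distinct-position placement has fewer multiple hits than the JC correction
assumes), so the default scenario dates at ~41/42/47 MYA against planted
39/39/45; and recent duplicates legitimately cross-match their parents'
expressed-sequence evidence (~85% nucleotide identity at Ks 0.22), so more
genes carry EST support than were directly planted — the same shared-EST
pattern the real catalog shows.

Expression: counts are negative binomial (gamma–Poisson, dispersion 0.05)
around length × library × RPKM/10⁹ with 2×10⁷ mapped reads per library, two
replicates, two stresses × two timepoints plus control.  13 genes are
cold-induced, the first 11 of them also dehydration-induced (the nested
design), 2 repressed, fold 4 (0.2 for repression) at both timepoints.
Baseline RPKM is log-uniform on (2, 64): the floor keeps control counts
large enough (≈24 reads/replicate at 720 bp) that fold-change calls are
statistically stable; the cost is that the low/absent expression bin is
under-populated relative to real leaf tissue.  qPCR Cq values are
Cq_base − log2(fold) + N(0, 0.1²) in triplicate against a constant reference
gene.  What passing tests do **not** show about real data: no indels, no
rate heterogeneity across sites or lineages, no codon-usage bias, no
mapping/counting noise beyond NB dispersion, and EST evidence without
3'-bias or fragmentation.

## Expression analysis

RPKM = counts·10⁹/(library size · gene length).  Level bins use control
log2 RPKM: > 4 high, [1, 4] moderate (both boundaries inside the moderate
bin, reading "between 1 and 4" inclusively), < 1 low/absent.  Response calls
average replicate RPKM, add a 0.01 pseudocount to both sides of the fold
ratio (folds stay defined at near-zero control expression), and call "up"
when any timepoint exceeds fold 2, "down" when any falls below ½ without an
up call.  Summary percentages round halves down (9/24 prints as 37%, the
convention the source tables use).  qPCR folds are 2^−ΔΔCt on triplicate
means against the reference gene, control normalized to 1.

## Pipeline and reproducibility

One YAML config holds every numeric setting; CLI flags override it.  Stages
write a fixed layout (inputs/, truth/, catalog/, phylo/, homology/, kaks/,
expression/, manifest.json) with floats at fixed precision, so a rerun with
the same config and seed is byte-identical apart from the manifest's
timings.  Every stochastic step (generator, bootstrap) derives from the
single config seed.  Errors carry their stage name and exit non-zero at the
CLI.

Problem sizes in the shipped tests are the package's own choices: the full
acceptance scenario is the 24-member/3-genome default with 1,000 bootstrap
replicates (~30 s end to end); module tests use a 6-member scenario.
Parameter-recovery properties use 300-codon pairs, 20 seeds per target.

## Known limitations

Consensus scanning is not a profile HMM: remote or heavily diverged domain
instances that HMMER would find below threshold will be missed, and the
CCT/GATA/PPD defaults are stylized surrogates, not Pfam models.  The
Karlin–Altschul constants are fixed rather than fit, so E-values are
filter-grade, not BLAST-comparable.  NG86 ignores transition/transversion
and codon-frequency biases (ML estimators are out of scope).  The clock
dating inherits every caveat of a strict clock with a single λ.  NJ with
p-distances can be inconsistent under strong rate heterogeneity — the regime
the generator does not simulate.
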