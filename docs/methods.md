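# Methods

This note records the models implemented in `norascan`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data used by the test suite does and does not establish about real data.

## Scope and data model

The package analyses exactly three coding genomes at a time (the
three-lineage comparison is the designed use case; nothing generalizes
automatically to more taxa). Coordinates are 1-based inclusive on the
forward strand, the GenBank convention for the viral genomes that
motivated the tool. Codon alignments are protein-guided, so gaps occur
only as whole codons; terminal stop codons are recorded but excluded
from codon lists, and internal stops are rejected at ORF extraction,
because the Li site classes are defined for sense codons only.

## Pairwise and codon alignment

Global alignment is Needleman–Wunsch with affine gaps (a gap of length k
costs `open + (k−1)·extend`), computed by Biopython's `PairwiseAligner`.
Nucleotide defaults are match +1 / mismatch −1 / open −8 / extend −1:
deliberately indel-averse, since "overall nucleotide identity" between
genomes of unequal length should be dominated by substitutions, with
indels penalized through gapped columns in the identity denominator.
Protein alignment uses BLOSUM62 with open −10 / extend −1. All scores
are configurable (`ScoringParams`). Identity is identical columns over
all columns; gap-containing columns count in the denominator only.

Three-way codon alignments are built centre-star on the translated
proteins: the centre is the protein with the highest summed pairwise
alignment score (ties to the smallest id), the two outer sequences are
merged through the centre's coordinates, and residues are replaced by
their source codons. With three sequences the centre-star merge is exact
in the sense that both pairwise alignments are preserved; no iterative
refinement is attempted.

Whole-genome nucleotide identity is computed on the full genome
sequences, untranslated regions included; whether published identity
figures for particular genomes included UTRs is generally ambiguous, so
the convention here is stated rather than guessed, and scoring is
overridable.

## Star-tree ancestor

The three lineages are tips of an unresolved star tree. Pairwise K2P
distances on gap-free nucleotide columns give branch lengths through the
three-point formula b₁ = (d₁₂ + d₁₃ − d₂₃)/2 (and rotations), clamped
at zero. Saturated pairwise distances (log argument ≤ 0) are an error
naming the pair — at that divergence the downstream correction would be
meaningless anyway.

Ancestral states are per-nucleotide marginal maximum likelihood under
K2P with uniform root frequencies: the state maximizing the product of
the three tip transition probabilities, ties broken A<C<G<T, support
reported as the normalized likelihood. This is the lightest defensible
stand-in for a full phylogenetic reconstruction: per-site independence
makes every column exactly verifiable by brute force, which the test
suite exploits. Columns where two or more tips are gapped become gaps
(star-tree parsimony on indels); a single gapped or ambiguous tip simply
drops out of the product. Reconstructed stop codons are flagged and
treated like gaps by the divergence counting.

The choice of a nucleotide model rather than a codon model, and of the
star tree rather than a resolved topology, are deliberate
simplifications; with three taxa and one internal node the star tree is
the only unrooted shape, and branch-specific divergence relative to the
single internal node is exactly what the scan needs.

## The Li-method estimator

Site classes: each position of a sense codon is nondegenerate (0-fold),
twofold or fourfold according to whether 0, 1–2, or 3 of its three
single-nucleotide alternatives are synonymous (changes to stops count as
nonsynonymous). The threefold isoleucine third position falls in the
twofold class — the standard convention of this estimator family.

For an aligned codon pair, the site count of a position is split half
and half between the two codons' classes when they disagree, keeping
L₀+L₂+L₄ = 3 per compared pair exactly. Differences are classified as
transitions or transversions; for codons differing at k > 1 positions
the per-step classifications are averaged over all k! orderings of the
single changes, excluding orderings that pass through a stop codon.
Because the site classes and the substitution type of each changed
position depend only on the two end-point codons, all stop-free
orderings contribute identical increments; the enumeration decides only
whether a pair is countable at all. Pairs whose every ordering is
blocked would be skipped and tallied; enumeration over all 61×61 sense
pairs shows the standard code has no such pair, so the tally is a
safeguard.

Per class, P_i and Q_i are corrected with the K2P formulas (A_i, B_i)
and combined as

    Ka = A₀ + (L₀B₀ + L₂B₂)/(L₀ + L₂)
    Ks = (L₂A₂ + L₄A₄)/(L₂ + L₄) + B₄

(the Li-1993/Pamilo–Bianchi-1993 weighting; the 1985 variant weights
differently, and which of the two a given legacy pipeline used is often
unstated — the formulas above are this package's contract, validated
against an internal brute-force oracle). Estimates are invalid — NA,
never clipped — when a required log saturates or a required site-count
denominator is zero; silent clipping would bias the randomization null
that consumes window Ka values.

A known property of this estimator family, inherited deliberately:
transversions at twofold sites are booked as nonsynonymous even in the
few codon pairs where they are synonymous (arginine CGA↔AGA, CGG↔AGG).
Purely synonymous evolution therefore yields a small positive estimated
Ka (of order 0.005 at the divergences used in the tests), although the
realized nonsynonymous change is exactly zero. The simulator's event
record, not the estimator, is the arbiter of exactness in such tests.

## Window scan

Windows (default 50 codons wide, placed every 30 — the classic scan
geometry for genomes of this size) are laid within each gene
independently and never span gene boundaries: the viral ORFs overlap
slightly, so a single concatenated frame is ill-defined at junctions.
Genome-wide coordinates are reported as gene offsets plus gene-local
positions. A branch reports NA in a window when fewer than half its
codon pairs are comparable (threshold configurable), preventing
windows dominated by gaps from generating spurious peaks.

## Randomization null and peak calling

The null distribution of the peak statistic is obtained by shuffling
codon-column order jointly across the three tips and the ancestor,
within each gene, re-running the scan, and recording the per-lineage
maximum window Ka per replicate (default R = 1000). The threshold is the
empirical 95% quantile (type-7, i.e. numpy's default linear
interpolation — stated because R is finite) of those maxima. Using the
maximum gives family-wise control over all windows: a window crossing
the threshold is unlikely to occur anywhere in the genome by chance,
given that lineage's total divergence.

Design points:

- The ancestor is *not* re-inferred per replicate. Column statistics are
  therefore permutation-invariant and only their arrangement changes;
  this both matches the logic of the test (is the observed clustering of
  divergence special?) and makes replicates cheap, since per-column
  counts are precomputed once.
- Thresholds are per lineage, never pooled. Consequently the calibrated
  error rate is per lineage (≈ α per lineage under a uniform-ω null,
  measured ≈ 0.04–0.07 at α = 0.05 in the calibration tests); the
  probability that *some* lineage shows a false peak is correspondingly
  larger (≈ 3α for three lineages). Interpret multi-lineage peak tables
  accordingly.
- Column shuffling is genome-wide within genes (not within windows):
  the null preserves each gene's column multiset exactly and randomizes
  only spatial arrangement.
- A master seed spawns one RNG stream per replicate
  (`numpy.random.SeedSequence.spawn`), so results are bit-reproducible
  and independent of evaluation order. Replicates in which a lineage has
  no assessable window are dropped for that lineage; more than 10%
  dropped aborts.

Peaks are windows with Ka strictly above their lineage's threshold,
merged when overlapping within a gene, reported with their span and
maximum window.

## Synthetic data generator

The simulator emulates the study conditions the pipeline targets: three
coding sequences descending independently from a common ancestor on a
star tree. The root is i.i.d. uniform over the 61 sense codons. Per
branch of length t (expected *neutral* substitutions per nucleotide
site), each site receives Poisson(t) proposals, ordered by uniform event
times; a proposal is a transition with probability κ/(κ+2), otherwise a
uniform transversion. Selection is acceptance-thinning per codon:
proposals creating stops are rejected outright; synonymous proposals are
accepted with probability min(1, 1/ω) and nonsynonymous with
min(1, ω). For ω ≤ 1 this is the natural "purifying selection thins
amino-acid change" rule; the ω > 1 extension thins synonymous changes
instead so that realized dN/dS equals ω on both sides of 1, which the
planted-region recovery tests rely on (ω_high = 1.5). Every accepted
event is recorded, so tips replay exactly from the root and ground-truth
counts (e.g. nonsynonymous events in a region) are available to tests.

Defaults are the conditions of the motivating comparison: background
ω = 0.076 (strong purifying constraint typical of these viral
proteomes), κ = 2, branch lengths 0.3, 1200 codons (a viral-ORF-scale
genome); the planted region used throughout testing is 60 codons of
ω = 1.5 on one branch, emulating a lineage-specific divergence peak in a
suppressor-of-RNAi gene.

What the simulator does not model — and hence what passing tests do not
establish about real data: indels (gap handling is exercised with
hand-built fixtures instead, keeping truth replay exact), recombination
(an alternative explanation for localized divergence that the scan
cannot distinguish from selection), among-site rate heterogeneity, codon
usage bias, and alignment error (simulated alignments are known and
gap-free; real alignments contribute their own uncertainty upstream of
everything here). Stop-rejection slightly deflates realized rates
relative to nominal t (~4%), which the branch-length recovery tolerance
absorbs.

## Calibration and test-scale choices

The statistical tests in the suite and the quantities recomputed by
`scripts/acceptance.py` run at these problem sizes, chosen so each check
has clear power at interactive runtimes on one core:

- neutral calibration: ω = 1, t = 0.3, 2000 codons, 3 seeds; pooled
  Ka/Ks expected in [0.8, 1.25] (observed ≈ 0.95 — the mild downward
  pull is the stop-rejection asymmetry, which removes slightly more
  nonsynonymous than synonymous proposals);
- strict purifying exactness: ω = 0, zero realized nonsynonymous events
  and identical tip/root proteins;
- null calibration: 200 genomes, uniform ω = 0.1, 1200 codons, R = 200
  (scaled down from the default 1000), per-lineage false-peak rate in
  [0.01, 0.12];
- peak recovery: 50 replicates of the planted-region condition, R = 200,
  success = a peak on the correct lineage overlapping the true region,
  required in ≥ 80% (observed 100%);
- recovery: t = 0.2, 5000 codons, neutral (branch lengths are defined in
  neutral substitutions per site, so only ω = 1 simulations identify
  them); branch lengths within 15% relative error, true root matched at
  ≥ 99% of *unsaturated* sites, defined from simulator truth as sites
  hit on at most one branch. Sites hit on two or more branches are
  frequently unrecoverable in principle (two tips changed to the same
  state always mislead the reconstruction; three distinct states tie),
  which caps all-site accuracy near 95% at this divergence — a property
  of the inference problem, not of the implementation.

## Known limitations

- Exactly three taxa; no generalization to larger trees.
- The estimator-family Ka bias under purely synonymous evolution
  (arginine twofold transversions), documented above.
- Nucleotide-level ancestor: no codon-model likelihood, no rate
  heterogeneity, no joint reconstruction.
- The scan reports alignment-codon coordinates; mapping peaks back to a
  particular genome's nucleotide coordinates must account for that
  genome's gaps.
- Identity percentages depend on alignment scoring; defaults are stated
  and overridable, and whole-genome values should be quoted with the
  scoring convention.
- The whole-genome pairwise alignment is quadratic in sequence length;
  for genomes beyond a few tens of kilobases compute identity on coding
  regions or skip it (`--skip-nt-identity`).
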