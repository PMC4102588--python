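# norascan

Branch-specific nonsynonymous divergence scans for small RNA-virus
genomes.

## The problem

When three related viral genomes are compared — here motivated by the
Nora-like picorna-like viruses of *Drosophila*, whose VP1 protein
suppresses the host's antiviral RNAi machinery — the interesting signal
is rarely the overall divergence but *where along the genome one lineage
has changed its protein sequence far more than its own background rate*.
Such localized bursts of amino-acid divergence on a single branch are the
molecular footprint of host-specific selection (or recombination) and
point at the genes mediating host–virus arms races.

`norascan` answers that question for a trio of genomes:

1. build protein-guided codon alignments of the annotated ORFs;
2. infer the common ancestor of the three lineages on a star tree by
   per-site maximum likelihood under the Kimura two-parameter (K2P)
   model;
3. estimate the nonsynonymous divergence K_A of each tip from that
   ancestor with the counting method of Li (1993) / Pamilo–Bianchi
   (1993) in sliding windows (50 codons, every 30, by default);
4. judge window peaks against genome-wide per-lineage significance
   thresholds obtained by randomizing codon-column order (1000
   replicates by default): the threshold is the 95% quantile of the
   per-replicate *maximum* window K_A, so a peak crossing it is unlikely
   anywhere in the genome by chance, given that lineage's overall
   divergence.

A codon-evolution simulator with known ancestry, transition/transversion
bias, purifying selection and a plantable region of elevated dN/dS makes
every stage testable without any sequence downloads.

## The statistic

For two aligned codon sequences each codon position is classified by its
degeneracy (nondegenerate L₀, twofold L₂, fourfold L₄ sites, averaged
over the two codons), and observed differences are split into transition
and transversion proportions P_i, Q_i per class. Kimura's two-parameter
correction

    A_i = ½ ln 1/(1−2P_i−Q_i) − ¼ ln 1/(1−2Q_i),   B_i = ½ ln 1/(1−2Q_i)

yields the divergence estimates

    K_A = A₀ + (L₀B₀ + L₂B₂)/(L₀ + L₂)
    K_S = (L₂A₂ + L₄A₄)/(L₂ + L₄) + B₄

Codons differing at several positions are counted by averaging over all
orderings of the single changes, excluding orderings that pass through a
stop codon. Saturated windows are reported as NA, never clipped.

## Worked example

Simulate three lineages (1200 codons, branch length 0.3, strong
purifying background ω = 0.1) with a planted 60-codon region of ω = 1.5
on the first branch, then scan:

```python
from norascan import DivergenceScanModel
from norascan.simulate import SimConfig, RegionSpec, simulate

cfg = SimConfig(
    n_codons=1200, branch_lengths=(0.3, 0.3, 0.3), kappa=2.0,
    omega_background=0.1, region=RegionSpec(0, 601, 60, 1.5), seed=42,
)
sim = simulate(cfg)
res = DivergenceScanModel.from_simulation(sim).fit(n_permutations=1000, seed=1)
print(res.summary())
```

```
Nonsynonymous Divergence Scan
================================================================
Genes: gene1   codon columns: 1200
Window: 50 codons every 30   permutations: 1000   alpha: 0.05   seed: 1
K2P kappa: 2.0
----------------------------------------------------------------
branch        length       Ka       Ks    Ka/Ks   95% thr
tip1          0.0865   0.0349   0.2248   0.1550    0.1027
tip2          0.0844   0.0298   0.2235   0.1331    0.0951
tip3          0.0989   0.0380   0.2898   0.1310    0.1074
----------------------------------------------------------------
Peaks above the genome-wide threshold:
  tip1       gene1    codons 601-680  max Ka = 0.2118  (threshold 0.1027)
  tip3       gene1    codons 451-500  max Ka = 0.1121  (threshold 0.1074)
```

Reading the output: genome-wide K_A/K_S ≈ 0.13–0.16 reflects the
purifying background; the planted region (codons 601–660 on `tip1`) is
recovered as a peak whose windows span codons 601–680 with maximum
window K_A more than twice that lineage's genome-wide threshold. The
marginal `tip3` call at codons 451–500 sits just above threshold — the
kind of borderline peak the nominal 5% per-lineage error rate allows.
`res.windows_frame`, `res.peaks_frame` and `res.plot()` expose the scan
table, the peak table and a per-branch K_A trace with dashed threshold
lines.

The same analysis runs from the shell on real genomes:

```
norascan scan --genomes genomes.fasta --orfs orfs.tsv --out results/ \
    --permutations 1000 --seed 1
norascan identities --genomes genomes.fasta --orfs orfs.tsv
norascan motif --genomes genomes.fasta            # 5' UTR CCTGGGSGGGGGTTA
norascan simulate --out simdir --region 0,601,60,1.5
```

`orfs.tsv` is a 4-column table (genome id, ORF name, 1-based start, end)
or a GFF3 with CDS features; every ORF must be annotated in all three
genomes.

## Layout

- `norascan.io` — FASTA / ORF-table / GFF3 reading, ORF extraction,
  translation, IUPAC motif scans
- `norascan.align` — affine-gap global alignment, centre-star
  protein-guided codon alignment, identity statistics
- `norascan.ancestral` — K2P distances, star-tree branch lengths,
  marginal-ML ancestor
- `norascan.li` — the Li-method site classification, pathway-averaged
  counting and K_A/K_S estimates
- `norascan.windows`, `norascan.null` — the sliding-window scan and the
  codon-randomization null
- `norascan.simulate` — the synthetic-data generator
- `norascan.model`, `norascan.pipeline`, `norascan.cli` — the
  Model/Results interface, the persisted end-to-end pipeline and the
  command line

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
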