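# Methods

## Depth model and confirmation statistic

Per-base depth counts primary alignments only (secondary and supplementary
records excluded, duplicates counted — the upstream pipeline does not mark
them) with mapping quality strictly greater than an exclusive threshold that
defaults to 0, i.e. MAPQ-0 reads are dropped. Aligned blocks define coverage,
so deletions within a read (CIGAR `D`/`N`) and soft-clipped bases contribute
nothing, and uncovered positions report depth 0.

Region ratios are region mean depths divided by the mean of the analysis
controls' mean depths; the control ratios therefore average to 1 by
construction, which the suite checks to 1e-9. Confirmation cutoffs are
`mean ± m·SD` of a reference ratio set with `m = 3` by default; SD is the
*sample* standard deviation (n−1 denominator) over region-level ratios. With
five controls the reference set is small, so the estimator choice matters and
n−1 is the conventional default at that size. Two candidate cutoffs are
computed: from the five control ratios, and from the seven controls+pads
ratios renormalized by the controls+pads mean. The effective cutoff is the
stricter candidate — the larger for deletions, the smaller for duplications
— and the comparison against the control-normalized CNV ratio is inclusive
("at least" three SDs). When every control ratio is identical the SD is 0
and the cutoff degenerates to the mean; this is permitted (it keeps trivial
inputs usable) but logged as unreliable.

Copy number is the nearest rung of a ratio ladder: step 0.5 per copy on
autosomes, the female X, and pseudoautosomal regions (PARs), step 1 per copy
on the male X/Y outside the PARs. Midpoint ties resolve to the lower copy
number. PAR intervals default to the GRCh37 PAR1/PAR2 coordinates and are
overridable; resolving a sex-chromosome region with unknown sample sex is an
error rather than a guess.

The male sex-chromosome ladder deserves a note: it treats a single-copy male
X region as having expected ratio 1 against diploid autosomal controls, and a
one-copy gain as ratio 2. The simulator uses the matching generative rate —
on male non-PAR sex chromosomes the per-copy read rate is twice the
autosomal per-copy rate — so generator and estimator are self-consistent on
that ladder; this is the assay's interpretation convention, not a physical
claim about molarity.

## Target design

The sequencer BED contains nine 500-kb control regions (4.5 Mb total) plus
the suspected CNV with 500-kb pads abutting it exactly, truncated at
chromosome ends. Pads and CNV are merged into one interval for the BED
handed to the sequencer while the analysis manifest preserves roles. The CNV
overlapping a control is an error (controls must stay copy-number-neutral);
a *pad* overlapping a control only demotes that control from the analysis
subset with a warning. The packaged default panel is a synthetic stand-in:
its coordinates are placeholders on GRCh37-sized chromosomes that reproduce
the panel's structure (nine 500-kb regions; two sex-chromosome and two
low-coverage regions excluded from normalization, leaving five analysis
controls; two nearby chr17 regions merged for identity matching, giving four
match regions). Real deployments should supply their own panel file; every
routine accepts one.

## Identity matching

Candidate loci are biallelic SNVs with population AF in the closed band
[0.4, 0.6], chosen deterministically (first 150 by position per control
region) for reproducibility. Genotypes come from pileup allele counts:
`no_call` below the platform depth minimum (10 reads short-read, 1 read
long-read), homozygous when the allele fraction strictly exceeds 0.95,
otherwise `other`. Only loci homozygous in *both* panels enter the
comparison — loci homozygous in one panel only are excluded from numerator
and denominator — and a match region passes at strictly greater than 90%
agreement. A region with zero shared homozygous loci is reported as no-data,
which counts against the matched-region fraction but is distinguishable in
the per-region output. "Identity confirmed" requires all match regions to
agree; the pairwise matrix reports the fraction of regions matched (values
in {0, 0.25, 0.5, 0.75, 1} with four regions). For unrelated individuals,
independent homozygous genotypes at AF-0.5 loci agree with probability ~1/2,
far below the 0.9 bar, which the suite verifies both analytically
(constructed panels) and on simulated BAMs.

## Methylation phasing

Reads intersecting the imprinted island (defaults: SNRPN promoter CpG island
chr15:25,200,035–25,201,054 and phasing SNV chr15:25,199,992 C/G, GRCh37,
converted to 0-based internally) are assigned hap1/hap2 from their base at
the SNV; no coverage, a third allele, or a deletion at the site leaves the
read unassigned. 5mC calls are read from standard MM/ML tags (ML bin
midpoint `(ml+0.5)/256` as the probability). A CpG site counts as modified
at probability ≥ 0.5 and a read is methylated when the modified fraction of
its island CpGs exceeds 0.5; both thresholds are explicit config because the
underlying visual-classification convention has no published rule. The
module reports haplotype labels only — parent-of-origin interpretation is
the user's.

## Simulator

The generator emulates the coverage structure of an adaptive-sampling run:
within target regions, read starts follow a Poisson process at rate
`on_target_depth × copies/2 / mean_read_length` per bp (with the male
sex-chromosome convention above), with exponential read lengths of mean
4,805 bp; outside targets, short rejected reads (mean 603 bp) at 1.13X.
Defaults (9.5X on-target, 1.13X genome-wide, the two length means) are the
assay's observed operating point. Reads are emitted as perfect single-block
alignments at MAPQ 60 (optionally a configured fraction at MAPQ 0 to
exercise the filter), with genotype alleles substituted into sequences (het
alleles ride a per-read haplotype), optional uniform substitution error
(default 0), and MM/ML tags written per a per-haplotype per-site
modification probability over the island. The reference is deterministic
pseudo-random sequence generated in seekable 1-Mb blocks, so fixtures at
real GRCh37-scale coordinates need no stored FASTA. Truth manifests record
realized per-region mean depths (computed independently of the depth module,
which the suite cross-checks for exact agreement) and realized allele
counts.

What the simulator does *not* emulate: alignment ambiguity and mapping
error, basecalling error structure beyond uniform substitutions, GC and
pore-occupancy coverage biases, adaptive-sampling rejection kinetics, and
inter-run variability. Passing tests therefore demonstrate the correctness
and calibration of the analysis given the stated coverage model, not
robustness to every artifact of real flow cells.

## Experiment and test problem sizes

Simulation experiments use a compact layout — five 500-kb controls on one
chromosome, a padded test region on another, genome just large enough to
hold them — so a full simulate+confirm cycle runs in well under a second.
The reproduction script measures each ladder point (copies 0/1/3/5
autosomal, two-copy male X, copy-neutral) as the mean CNV ratio over 20
replicate simulations at 10X, and cohort concordance over 20 samples with
CNV sizes log-uniform in 40 kb–2 Mb at 9.5X. The test suite runs the
copy-neutral specificity property at 200 simulations (observed false-positive
rate ≤ 5% with one hypothesized direction per replicate, alternating), the
copy-number recovery property at 40 simulations (10 per copy state), and the
per-read methylation-classification property at 25 seeds × 40 reads; these
sizes were chosen to keep the default suite fast while leaving binomial
noise well inside the asserted margins.

## Numerical and degenerate-input choices

Windowed depth uses `floor(region_length × fraction)`-bp windows (default
fraction 1%), the final window absorbing the remainder rather than creating
an extra short window, so the length-weighted mean of window means equals
the region mean exactly. Downsampling retains whole reads by independent
Bernoulli draws at `target/full` control depth; replicate j at depth index i
uses seed `base + i·reps + j`, making the titration table reproducible.
Fold enrichment is reported to one decimal. Zero-depth control panels,
zero-length regions, sub-minimum window fractions, missing BAM indexes, and
chromosomes absent from the header are all rejected with actionable
messages rather than propagating NaNs.
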