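# Methods

## Scope and data model

riboplast analyses chloroplast ribosome-profiling data reduced to genomic
intervals: a plastid genome (FASTA), plastid protein-coding ORFs (GFF3, one
pre-spliced CDS interval per gene) and one BED6 file of footprints per
sample, with a TSV sample sheet (`sample_id  genotype  replicate  path`).
All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted exactly once, at the I/O boundary. The plastid
genome is treated as linear — an ORF running past the sequence end (i.e.
wrapping the circular molecule's origin) is rejected rather than silently
mishandled, since every profile operation assumes a contiguous interval.

Each footprint is reduced to its 5′ end (`start` on +, `end − 1` on −),
the single coordinate used for ORF assignment, frame QC and profiles. One
rule everywhere avoids boundary-case inconsistencies between stages. The
footprint length filter defaults to 20–40 nt, the sequenced insert-size
range of the libraries this design emulates; filtered counts are reported,
never silently discarded.

## Quantification: cpRPKM

A footprint is assigned to the ORF containing its 5′ end on the matching
strand. Plastid operons occasionally overlap; when a 5′ end falls in two
ORFs it goes to the one whose start codon is nearest upstream in gene
orientation (ties: lexicographic gene id), and the number of such
multi-candidate assignments is logged. This tie-break is a package decision
— any deterministic rule would do at the frequencies involved, but it must
be auditable.

cpRPKM is reads per kilobase of ORF per million reads mapped to total
chloroplast ORFs:

    cpRPKM_g = n_g / ((L_g/1000) · (N_total/10⁶)),

with `N_total` the sum of ORF-assigned counts in the sample. "Mapped to
total chloroplast ORFs" is taken literally: unassigned (intergenic,
antisense, upstream-of-start) reads do not enter the denominator. The
definition telescopes to the identity Σ_g cpRPKM_g·L_g(kb) = 10⁶, which the
test suite asserts to 1e-6 relative — a free end-to-end check on the whole
assignment/quantification chain.

Mutant/WT ratios: the WT reference is the mean cpRPKM over WT replicates
(`ratio_mode: mean_ref`); each mutant replicate contributes
log₂(cpRPKM_mut,r / WT_ref), summarised as mean ± sample SD (n−1; three
biological replicates is the designed case). A replicate-paired mode
(`paired`) is available but not the default, since the experimental design
implies no pairing between mutant and WT replicates. Genes with fewer than
`min_reads` (default 200) raw assigned counts in any sample are flagged
excluded with a reason string — the low-count exclusion threshold mirrors
the rule used for the weakest PSII gene in the emulated study — as is any
gene with a zero WT reference.

## QC

Length histogram: mode reported per sample; ties resolve to the smaller
length; an empty sample has no mode. 3-nt periodicity: for footprints whose
5′ end lies inside a triplet-length ORF, frame = (rel5 + psite_offset) mod 3
with rel5 the ORF-relative 5′ position measured from the gene's own start
codon in its own orientation — minus-strand genes are scored in their own
reading frame, not the genome frame, so the statistic is invariant to where
an ORF sits in the genome. The canonical 5′-to-P-site offset is not a
universal constant across libraries, so it is an explicit, reported
parameter; the default 12 nt is conventional for ~31-nt plant chloroplast
footprints.

## Profiles, peak calling and the relative-height ratio

Per-ORF coverage piles up assigned 5′ ends (optionally shifted by a P-site
offset, default 12 nt in the pipeline so positions read as P-site codons)
along the gene 5′→3′; each profile is normalised by its own total. With a
12-nt offset, footprints whose P-site codon lies within the first four
codons have 5′ ends upstream of the ORF and are unassignable — a genuine
property of 5′-end assignment, which is why the synthetic initiation pause
sits at codon 6 rather than codon 1.

Peak calling runs at codon resolution (nucleotide-level maxima are 3-nt
frame artifacts): density summed per codon, smoothed by a centred moving
average (`smooth_codons = 3`, truncated at ORF ends so edge codons average
over what exists), then:

1. local maxima (plateaus → 5′-most codon; terminal codons eligible — a
   missing side imposes no prominence constraint);
2. keep maxima with topographic prominence ≥ `min_prominence_frac` (0.25)
   of the global smoothed maximum;
3. merge maxima closer than `min_sep_codons` (9), keeping the higher
   (ties: 5′-most), greedily from the highest;
4. keep the `top_k` (6) by height; relabel with roman numerals in 5′→3′
   positional order.

"Major peak" has no agreed quantitative definition in the field; these four
parameters are declared defaults, chosen so that the synthetic CP47-like
fixture with five injected pauses yields exactly five major peaks, and all
are config keys stamped into output metadata. The window-sum inside the
moving average accumulates 5′→3′ in a fixed order, so results are
bit-reproducible and exactly match a naive reference implementation —
near-ties at the top-k cutoff must not depend on summation order.

The relative-height statistic: peaks are defined once, on the pooled-WT
normalised profile (the statistic compares "the fifth peak" across
genotypes, which presupposes a common peak set); each sample's height is the
maximum smoothed codon density within ±`match_window` (1) codons of the
peak, absorbing sub-codon jitter; WT reference = mean of WT replicate
heights; ratio_r = h_mut,r / WT_ref, reported as mean ± sample SD over
mutant replicates. Heights live in normalised (per-gene density) space —
that is what makes the statistic depth-invariant and distinguishes a ~1.3×
local stall from a 2× change in overall footprint abundance. No
significance test is attached: the design with three biological replicates
supports a mean ± SD summary, not a calibrated p-value.

The genome-wide scan applies the same machinery to every triplet-length ORF
passing `min_reads` in all samples, and sorts by mean ratio within genotype;
excluded genes are listed with reasons.

Exit-tunnel mapping: `emerging_residue = peak codon − tunnel_len_codons`.
The tunnel holds roughly 30–40 extended residues; 33 is a configurable
placeholder, not a measured constant. With a user TMD table (1-based
inclusive residue intervals, validated non-overlapping), the emerging
residue is annotated as a TMD or loop.

## Synthetic data generator

The generator emulates the structure of the emulated study's design —
3 genotypes × 3 biological replicates — with, per gene and sample:

* footprint count ~ Poisson(`depth_per_gene`), optionally scaled per
  genotype and gene (`genotype_depth_effects`) to model overall occupancy
  changes, which codon-level weights cannot produce;
* P-site codon ~ weights = baseline (uniform) × `pause_map` ×
  `genotype_effects`, each multiplier perturbed once per replicate by
  mean-1 lognormal noise with CV `replicate_noise_cv` (0.05 — producing
  ratio SDs of the few-percent magnitude real replicate triplets show).
  Multiplicative noise on multipliers, not additive noise on counts, is
  what spreads replicate *ratios*, the quantity the mean ± SD summarises;
* 5′ end = codon start − 12 nt, shifted ±1 nt with probability
  1 − `frame_fidelity` (default 0.9: strong but imperfect periodicity, as
  in real libraries);
* length ~ discrete distribution with mode 32 nt, support 28–36,
  most mass on 31–33.

Because pause multipliers act on sampling weights *before* normalisation,
an injected stall slightly depresses normalised density elsewhere — the
same shrinkage per-gene normalisation imposes on real data. The expected
observed ratio for a multiplier m at a codon with baseline density share d₀
is m/(1 + (m−1)·d₀) (further diluted by smoothing if the measurement window
exceeds the stalled window); `expected_peak_height_ratio` computes it, and
`calibrate_stall_effect` / `calibrate_depth_effect` invert it analytically.
The bundled `psbB_like_study` uses these inversions to set mutant effect
sizes whose *expected* psbB-V height ratios are 1.310 (fpb1) and 1.420
(pam68) and whose expected psbB cpRPKM abundance ratio is ~2 — calibration
against the closed form, never against a measured test outcome.

RNG streams are derived from (seed, CRC32(genotype), replicate) through
numpy's SeedSequence: identical configurations are byte-identical across
runs and platforms, with no dependence on process hashing or dict order.

What the generator does *not* emulate: sequencing error, rRNA/tRNA
contamination, nuclease sequence bias, codon-specific dwell-time variation,
UTR and intergenic coverage, or overlapping operonic transcripts. Passing
recovery tests on this generator therefore demonstrates that the estimator
chain is correct and calibrated for the modelled effects, not that real
libraries are free of those artifacts.

## Numerical and edge-case conventions

* Flat profile → zero peaks (not an error); zero-coverage profile →
  explicit error on normalisation.
* Sample SD uses ddof = 1 and is undefined (None/NaN) below two replicates.
* Footprints out of profile range after the P-site shift are dropped and
  counted; assignment conserves reads (assigned + unassigned = input).
* Non-triplet ORFs load with a flag; codon-level operations refuse them.
* Output TSVs carry '#' metadata (version + full parameter set, no
  timestamps and no paths), so identical analyses are byte-identical.

## Problem sizes used in validation

The validation suite runs at desk scale, chosen so the whole suite
completes in about a minute: oracle equivalence on 200 randomized instances
each for assignment and peak calling; stall recovery for m ∈ {1.5, 2, 3} at
depth 50 000 footprints on a single 508-codon gene over 20 seeds (recovered
mean within 15% of the renormalisation-corrected truth, measured without
smoothing since the stalled window is one codon); WT-vs-WT null scans at
the same depth (all ratios in [0.7, 1.4] in ≥95% of seeds); periodicity and
length-mode recovery at 100k/50k reads. `scripts/acceptance.py` uses a
depth of 20 000 footprints per gene per sample — deep enough that replicate
statistics are dominated by the modelled biological noise rather than
Poisson error, while emulating libraries that are three orders of magnitude
deeper.

## Known limitations

* 5′-end assignment loses footprints whose P-site codon is within
  `psite_offset`/3 codons of the start; initiation-proximal pauses are
  visible only from that codon onwards.
* Overlapping ORFs share no reads (hard assignment); a systematic operonic
  overlap would need fractional assignment, out of scope here.
* The max-within-window height measurement carries a small upward
  noise bias; with unequal WT/mutant depths this biases ratios a few
  percent toward the deeper genotype's favour at low coverage. It vanishes
  as depth grows and is symmetric under the null (covered by the WT-vs-WT
  calibration test).
* Peak labels are positional within genotype-shared (pooled-WT) peak sets;
  comparing labels across independently analysed datasets requires
  re-anchoring by codon position, not numeral.
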