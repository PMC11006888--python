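# riboplast

Chloroplast ribosome-profiling (Ribo-seq) analysis of translational pausing
on plastid ORFs — built around the question of where, and how much harder,
ribosomes stall on a transcript such as *psbB* (encoding the photosystem II
antenna protein CP47) when a biogenesis factor is missing.

Ribosome footprints report where ribosomes sit on an mRNA at codon
resolution. For a multi-spanning thylakoid membrane protein like CP47,
ribosomes pause at reproducible positions — typically ~30–40 codons
downstream of each transmembrane domain (TMD), the point at which that
segment emerges from the ribosomal exit tunnel and must be handed to the
membrane-insertion machinery. Comparing the *relative* height of such a
pause between a mutant and the wild type, on per-gene normalised profiles,
isolates changes in local dwell time from changes in overall ribosome load.

## What the package computes

Given a plastid genome (FASTA), a plastid ORF annotation (GFF3) and
ribosome-footprint intervals (BED6, one record per footprint, length-filtered
to the sequenced insert range of 20–40 nt), riboplast produces:

* **QC** — footprint-length histogram (expected mode 31–33 nt) and 3-nt
  periodicity: the fraction *f₀* of 5′ ends in the canonical reading frame,
  computed gene-relatively on both strands with an explicit P-site offset
  (default 12 nt).
* **cpRPKM quantification** — footprints are assigned to the ORF containing
  their 5′ end on the matching strand, and each gene gets

  ```
  cpRPKM_g = n_g / ( (L_g / 1000) · (N_total / 10⁶) )
  ```

  where `n_g` is the gene's assigned count, `L_g` its ORF length in nt and
  `N_total` the sample's total ORF-assigned count (so
  Σ_g cpRPKM_g·L_g(kb) = 10⁶ identically). Mutant/WT log₂ ratios are
  reported per gene with replicate mean ± SD; genes under 200 raw reads in
  any sample are flagged, not dropped.
* **Pause-site analysis** — per-ORF 5′-end coverage profiles in the gene's
  own orientation, normalised by the gene's total reads; major peaks called
  at codon resolution on the pooled wild-type profile (moving-average
  smoothing, topographic-prominence threshold, minimum peak separation,
  top-k cap) and labelled with roman numerals 5′→3′ (`psbB-V` = fifth peak
  of *psbB*); each peak's height re-measured in every sample and summarised
  as the mutant/WT relative-height ratio, mean ± SD over replicates.
* **Genome-wide scan** — the same peak-ratio statistic for every eligible
  plastid ORF and genotype, sorted by effect size.
* **Exit-tunnel mapping** — peak codon minus the tunnel length (default 33
  codons) gives the nascent-chain residue emerging at the stall; an optional
  TMD table translates that into "TMD VI", "loop", etc.
* **Synthetic data** — a generator with explicit pause architecture,
  genotype effects, replicate noise, footprint-length distribution and frame
  fidelity, emulating a 3-genotype × 3-replicate chloroplast Ribo-seq design,
  so every stage is testable against known ground truth.

## Worked example

The bundled synthetic study (`psbB_like_study`) is a 12-gene toy plastid
genome whose 508-codon `psbB` carries five intrinsic pause sites — one near
the start codon and four at TMD-emergence positions — and two mutant
genotypes (*fpb1*, *pam68*) that stall harder at the fifth pause and carry
roughly doubled *psbB* ribosome occupancy:

```python
import riboplast as rp
from riboplast.pausing import pool_profiles

config, genotypes = rp.psbB_like_study(seed=1, depth_per_gene=20_000)
footprints, sheet = rp.simulate_experiment(config, genotypes, n_replicates=3)

orf = next(o for o in config.orfs if o.gene_id == "psbB")
wt_ids = sheet.loc[sheet.genotype == "WT", "sample_id"]
profiles = {
    sid: rp.build_profile(footprints[footprints.sample_id == sid], orf,
                          offset_nt=config.psite_offset, sample_id=sid)
    for sid in sheet.sample_id
}
pooled_wt = rp.normalize_profile(pool_profiles([profiles[s] for s in wt_ids]))
peaks = rp.call_major_peaks(pooled_wt)
for p in peaks:
    print(f"{p.label:<10} codon {p.codon_index:>3}  height {p.height:.4f}  rank {p.rank}")

wt_norm = [rp.normalize_profile(profiles[s]) for s in wt_ids]
fifth = peaks[4]
for genotype in ("fpb1", "pam68"):
    mut = [rp.normalize_profile(profiles[s])
           for s in sheet.loc[sheet.genotype == genotype, "sample_id"]]
    pr = rp.peak_ratio(wt_norm, mut, fifth, genotype)
    print(f"{fifth.label} ratio in {genotype}: {pr.mean:.3f} +/- {pr.sd:.3f} (n={pr.n_replicates})")
```

prints

```
psbB-I     codon   6  height 0.0064  rank 1
psbB-II    codon 149  height 0.0048  rank 4
psbB-III   codon 254  height 0.0049  rank 3
psbB-IV    codon 291  height 0.0047  rank 5
psbB-V     codon 455  height 0.0054  rank 2
psbB-V ratio in fpb1: 1.261 +/- 0.075 (n=3)
psbB-V ratio in pam68: 1.330 +/- 0.102 (n=3)
```

Five major peaks are detected on the pooled wild-type *psbB* profile; the
fifth (psbB-V, P-site codon 455, i.e. residue ~422 emerging from a 33-codon
tunnel — inside TMD VI of CP47) is specifically elevated in both mutants.
The ratios are the per-gene *normalised* height ratios: they stay near the
calibrated 1.31/1.42 even though the mutants carry ~2× the absolute *psbB*
footprint load, which is exactly what separates a local stall from a global
occupancy change.

The same analysis runs from the shell:

```sh
riboplast simulate --out ds --seed 1
riboplast run --genome ds/genome.fasta --gff ds/annotation.gff3 \
              --sample-sheet ds/samples.tsv --out results
```

writing `length_hist.tsv`, `frame_fractions.tsv`, `gene_counts.tsv`,
`cp_rpkm.tsv`, `log2_ratios.tsv`, `peaks.tsv`, `peak_ratios.tsv`,
`tunnel_map.tsv`, per-gene profiles and a JSON run manifest, all stamped
with the full parameter set and byte-identical across re-runs.

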