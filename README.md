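# hornscan

Population-genetic analyses of the ovine polled-insertion system: a 1.78-kb
insertion in the 3′-UTR of *RXFP2* on sheep chromosome 10 is the leading
candidate variant for polledness (genetic hornlessness), but horn status is
*sex-influenced* — the horned allele acts dominant in rams and recessive in
ewes — and in many southern European and African breeds the insertion does not
segregate with the phenotype at all. `hornscan` packages the computational
toolchain needed to study this system:

* **Selection scan** (`hornscan.scan`): a case/control windowed F_ST scan.
  Sites are filtered to informative SNPs (pooled minor allele frequency
  > 0.05), the major allele among the polled cases is identified per site,
  both groups' frequencies of that allele are averaged over 20-kb sliding
  windows, and a Nei-style G_ST is computed from the window means:
  with p̄ = (p̄_case + p̄_control)/2,

      F_ST = (H_T − H_S) / H_T,   H_T = 2p̄(1−p̄),
      H_S = [2p̄_c(1−p̄_c) + 2p̄_h(1−p̄_h)] / 2.

  The identical-by-descent (IBD) region shared by the cases is called as the
  maximal run of windows with F_ST above mean + k·SD (default k = 1).
* **Segregation analysis** (`hornscan.segregation`): the sex-influenced
  dominance model (male horned ⇔ carries ≥1 `anc` allele; female horned ⇔
  `anc/anc`), genotype/phenotype concordance tables with a configurable policy
  for intermediate phenotypes (scurs/horn rudiments), genotype-frequency
  tables, and the packaged transcriptions of the study's four genotype tables.
* **Linkage disequilibrium** (`hornscan.ld`): two-locus haplotype frequencies
  from unphased diploid genotypes by EM (only the double heterozygote is
  phase-ambiguous), and D, D′, r² from the converged frequencies.
* **In-silico genotyping** (`hornscan.assay`): exact-match PCR amplicon
  prediction, multiplex presence/absence genotype calls (`anc/anc` → 506 bp;
  `der/der` → 2286 + 389 + 676 bp; `anc/der` → union), IUPAC restriction
  digestion (Hpy188I, TCN^GA) and RFLP fragment-pattern calls.
* **Synthetic data** (`hornscan.simulate`): generators that emulate the study
  conditions — a 246-kb region where 12 polled cases share a fixed ~40-kb
  haplotype against 12 horned controls, allele templates reproducing the
  published multiplex and RFLP fragment geometry, and breed panels with
  controllable genotype–phenotype discordance.

## Worked example

```python
import hornscan as hs

# 1. simulate the mapping design and scan it
matrix = hs.simulate_scan_data(hs.ScanSimParams(seed=1))
result = hs.run_scan(matrix)           # MAF filter -> profile -> F_ST -> IBD
print(result.threshold)                # 0.12082498574717648
print(result.ibd_intervals)            # [(29436000, 29480999)]

# 2. in-silico multiplex PCR on generated allele templates
templates, primers = hs.synth_allele_sequences()
call = hs.multiplex([templates["anc"], templates["der"]], primers)
print(call.fragments, call.genotype)   # (2286, 676, 506, 389) anc/der

# 3. headline aggregates of the packaged genotype tables
print(hs.headline_counts())
# {'set1_polled_total': 208, 'set1_horned_total': 84, 'set1_polled_derder': 204,
#  'gg_males_sex_dependent_breeds': 110, 'ag_males_completely_polled_breeds': 17,
#  'ag_females_completely_horned_breeds': 6, 'rambouillet_male_gg_percent': 98.7,
#  'ethiopian_menz_ag_frequency': 0.12, 'tibetan_ag_frequency': 0.11}
```

The scan threshold is the mean-plus-one-SD F_ST cutoff over non-empty windows;
the called interval brackets the simulated 29,436,000–29,476,000 bp shared
segment to within one window step. The multiplex fragments are the four
expected products of a heterozygote; the headline dictionary re-derives the
sample-set checksums (208 polled-breed and 84 horned-breed animals), the SNP
genotype counts by breed category and sex, and the rounded heterozygote
frequencies from the packaged tables.

The same stages are available from a shell:

```
hornscan simulate scan --seed 1 --out matrix.tsv
hornscan scan --matrix matrix.tsv --out scan1 --plot
hornscan report --out report1
```

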