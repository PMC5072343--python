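# Methods

## The system

Horn status in domestic sheep is controlled largely by a locus at the proximal
end of chromosome 10, where a 1.78-kb retrotransposed insertion in the 3′-UTR
of *RXFP2* (the derived allele, `der`) is associated with polledness.  The
trait is sex-influenced: the horned (`anc`) allele behaves as dominant in
males and recessive in females, so `anc/der` rams are horned and `anc/der`
ewes are polled.  In breeds with variable or sex-dependent horn status the
association breaks down, which is what the segregation and LD machinery here
is built to quantify.  Coordinates are 1-based inclusive on NC_019467.2
(Oar_v4.0) throughout.

## Selection scan

**Model.** Twelve polled cases and twelve horned controls are compared over a
246-kb region.  Per site, the major allele among case calls (frequency ≥ 0.5;
an exact tie resolves deterministically to the reference allele) is
identified, and the frequencies of that same allele in cases and controls are
averaged over sliding windows (default 20 kb, step 5 kb, grid anchored at the
region start).  F_ST per window is a Nei-style G_ST on the two window-mean
frequencies with equal group weights — a frequency-level estimator, chosen
because the procedure it reproduces works from group allele frequencies per
window, not from genotype-level variance components.  It is undefined when
total heterozygosity is zero and is set to 0 there (both groups fixed for the
same allele carry no differentiation signal).

**Filtering.** Sites with pooled-sample MAF ≤ 0.05 are uninformative and
removed; sites with call rate < 0.8 are dropped first.  Both removals are
logged with counts.

**IBD calling.** The threshold is mean + k·SD of F_ST over non-empty windows
(default k = 1, population SD with the n divisor — the published cutoff value
cannot adjudicate the divisor, so the simpler estimator is used and exposed).
Intervals are maximal unions of overlapping/adjacent windows strictly above
threshold, reported 1-based inclusive internally and 0-based half-open in BED
output.

**What the simulator emulates.** `simulate_scan_data` draws per-site
population frequencies from Beta(0.8, 0.8) — a U-shaped folded spectrum that
keeps a few percent of sites under the MAF filter so the filter path is
exercised — and Binomial(2, p) dosages for all samples, except that inside
the ~40-kb IBD interval every case is homozygous for a single shared
haplotype (its allele drawn once per site from Bernoulli(p)).  SNP density is
2/kb.  Sites are independent given p: there is no background LD, no mutation
or genealogy model, and no sequencing error.  Passing the recovery test
therefore shows that the scan localises a fully penetrant shared segment
under sampling noise; it does not establish performance under background LD
or partial haplotype sharing.  With these defaults the inflation of baseline
F_ST from re-using the case sample to pick the allele (winner's-curse bias)
is small relative to the inside-segment signal, giving clean recovery; at
much smaller sample sizes that bias would matter.

## Segregation analysis

`predict_phenotype` implements the two-allele sex-influenced rule; the
historical multi-allele proposals for horn inheritance (separate alleles for
strictly horned vs sex-dependent horns, or a linked modifier) are documented
history, not implemented models.  Concordance classifies each animal as
concordant/discordant against the rule; scurred animals and those with horn
rudiments form a separate *intermediate* class by default, because the
literature is split on whether such animals count as horned or polled — the
`scur_policy` switch reclassifies them either way.  Genotype frequencies are
rounded half-up (two decimals by default) so that printed-table comparisons
are exact.

**Packaged tables.** The four genotype tables are transcribed per stratum
(breed × phenotype × sex × genotype → count) and expanded to pseudo-animal
records on demand.  Strata that do not record individual sex alternate
male/female deterministically during expansion; this affects no aggregate
keyed on sex (those tables record sex explicitly).  Rows whose genotype-column
assignment is ambiguous in the source rendering carry an `uncertain` flag, are
excluded from all headline aggregates, and can be excluded from expansion.
A SHA-256 manifest guards the fixtures against silent edits; the `report`
command verifies it before computing anything.

## Linkage disequilibrium

Haplotype frequencies for two biallelic markers are estimated from the 3×3
joint dosage table by EM.  All classes except the double heterozygote are
phase-unambiguous; the E-step splits the double heterozygotes between cis and
trans in proportion to p_AB·p_ab / (p_AB·p_ab + p_Ab·p_aB), and the M-step
renormalises haplotype counts.  Every step preserves the observed allele
margins, so the iteration moves along the single free haplotype dimension;
convergence is declared when the largest frequency change falls below 1e-10
(cap 1000 iterations), and the log-likelihood is non-decreasing.
Initialisation is at linkage equilibrium (products of observed allele
frequencies) rather than a uniform simplex point: with unequal allele
frequencies a uniform start is inconsistent with the fixed margins, while the
equilibrium start is always feasible.  Degenerate data consisting solely of
double heterozygotes leave the equilibrium a stationary point; such tables
carry no phase information beyond symmetry and are not meaningful LD inputs.
Monomorphic loci raise an error (LD undefined).  Group-wise r² with a
between-group ratio (two-decimal rounding, denominator floored at 1e-12 with
a warning) reproduces the fixed-status vs variable-status comparison design;
the published group r² values themselves are not recoverable (the underlying
75-animal genotypes are unpublished), so only the ratio arithmetic is checked
against print.

## In-silico assays

Primer matching is exact on both strands with no mismatch or thermodynamic
model.  This is deliberate: the ACRS assay's reverse primer carries an
engineered template mismatch, and because amplicon fixtures embed the primer
sequence as written, exact matching reproduces the assay without modelling
annealing.  PCR reports every forward-site/downstream-reverse-site product up
to `max_len` (default 10 kb), lengths inclusive of both primer footprints, as
on a gel.  Digestion cuts at every IUPAC match of the recognition pattern; a
site found only as the reverse-complement of the pattern cuts at
`len − offset` from its start, and self-reverse-complement patterns such as
Hpy188I's TCNGA are counted once per location.  Fragments partition the
template (asserted property) and the engine is cross-checked against an
independent enzyme-registry implementation in the tests.

**Fixture geometry.** The allele templates are generated sequences carrying
the published size relationships: the ancestral F1–R1 amplicon is 506 bp, the
derived allele adds a 1780-bp insertion (F1/R1 = 2286 bp) containing the R2
and F2 sites so that F1/R2 = 389 bp and F2/R1 = 676 bp.  The published primer
sequences are not available in the main text, so primers are random 20-mers
verified unique per template and orientation — the fixtures validate the
engine and the geometry, not the actual oligos.  The derived haplotype's
83-bp absence and its point substitutions are available behind an off-by-
default flag: their position relative to the 506-bp amplicon is not
determined by the published sizes (2286 = 506 + 1780 exactly, leaving no room
for the deletion inside the amplicon), so the default geometry omits them.
RFLP fixtures plant Hpy188I sites to yield 726+28 (allele A) or 429+297+28
(allele G) over the 754-bp exon-14 amplicon — 754 bp, not the 765 bp reported
in earlier work, following the genome-sequence-based correction — and the
104-bp ACRS amplicon digests to 82+22 only when allele G completes the
engineered site.  Random fill is rejection-scrubbed so no spurious TCNGA
occurs on either strand.

## Synthetic breed panels

`synth_breed_panel` draws Hardy–Weinberg genotypes at a per-category derived-
allele frequency (completely polled 0.99, matching the observed near-fixation
with a few heterozygous ewes; completely horned 0.0; mixed categories 0.5),
assigns phenotypes by the inheritance rule, and flips a `discordance_rate`
fraction to emulate breeds where the insertion does not track horn status.
Zero discordance closes the loop with the concordance machinery exactly; the
binomial bound on observed discordance is checked at n = 200.

## Numerical and interface choices

* Dosage matrices are int8 with −1 as the missing code; all frequency
  computations use non-missing denominators.
* All generators take integer seeds and are reproducible bit-for-bit;
  pipeline runs write a JSON manifest with inputs, parameters and seed.
* Problem sizes in the test suite: scan recovery uses the full default design
  (≈490 sites × 24 samples) over 20 seeds; EM-vs-grid agreement uses 50
  random tables of n ≤ 30 with a 1e-4 likelihood grid; oracle equivalence for
  F_ST uses matrices of ≤ 50 sites.
* Known limitations: no background LD or genealogy in the scan simulator; no
  primer-mismatch tolerance (a single-base variant under a primer abolishes
  the site rather than weakening it); VCF support is minimal (biallelic GT
  only); the inheritance model is strictly two-allele and does not attempt
  penetrance estimation.
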