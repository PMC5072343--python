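"""Synthetic inputs with the structural properties the analyses assume.

Three generators stand in for data that cannot be redistributed:

* :func:`simulate_scan_data` — a 246-kb region of independent biallelic SNPs in
  which the 12 polled cases share a fixed homozygous haplotype across a ~40-kb
  interval, against a neutral background shared with the 12 horned controls.
* :func:`synth_allele_sequences` — ancestral/derived allele templates whose
  primer geometry reproduces the published multiplex-PCR fragment sizes
  (anc F1/R1 = 506 bp; der F1/R1 = 506 + 1780 = 2286 bp, F1/R2 = 389 bp,
  F2/R1 = 676 bp).  The published primer sequences are not available, so the
  primers are generated 20-mers; the geometry is what the fixtures validate.
* :func:`synth_rflp_fixture` / :func:`synth_acrs_fixture` — amplicon templates
  carrying Hpy188I (TCNGA) site layouts that digest to the published fragment
  patterns (exon-14 SNP: A → 726+28, G → 429+297+28 over 754 bp; 3'-UTR ACRS:
  A → 104, G → 82+22).

All generators are deterministic given their seed.  Sites are independent given
their population frequency — there is no background LD model and no read-level
error; see the methods note for what this does and does not exercise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    INSERTION_MARKER,
    AnimalRecord,
    BreedCategory,
    Genotype,
    Phenotype,
    Sex,
    SiteMatrix,
    logger,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Case/control scan matrix
# ---------------------------------------------------------------------------

@dataclass
class ScanSimParams:
    """Study conditions for the selection-scan simulator.

    Defaults mirror the mapping design: 12 polled cases vs 12 horned controls
    over NC_019467.2:29,331,000-29,577,000 (~246 kb), with the shared
    identical-by-descent segment spanning 29,436,000-29,476,000 (~40 kb).
    Per-site population allele frequencies follow Beta(0.8, 0.8): a U-shaped
    folded spectrum that leaves a few percent of sites under the MAF filter.
    """

    n_case: int = 12
    n_control: int = 12
    region: tuple[int, int] = (29_331_000, 29_577_000)
    snp_density: float = 2.0  # expected SNPs per kb
    ibd_interval: tuple[int, int] = (29_436_000, 29_476_000)
    background_freq_alpha: float = 0.8
    background_freq_beta: float = 0.8
    contig: str = "NC_019467.2"
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least two cases and two controls")
        lo, hi = self.region
        ilo, ihi = self.ibd_interval
        if not (lo <= ilo <= ihi <= hi):
            raise ValueError("ibd_interval must lie within region")


def simulate_scan_data(params: ScanSimParams) -> SiteMatrix:
    """Simulate a biallelic dosage matrix with a case-fixed IBD segment.

    Outside ``ibd_interval`` both groups draw Binomial(2, p) dosages from the
    same per-site frequency p ~ Beta(alpha, beta).  Inside it, every case is
    homozygous for one shared haplotype allele (drawn once per site from
    Bernoulli(p)) while controls keep following the background.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.region
    span = hi - lo + 1
    n_sites = rng.poisson(params.snp_density * span / 1000.0)
    positions = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_sites, replace=False))

    p = rng.beta(params.background_freq_alpha, params.background_freq_beta, size=n_sites)
    n = params.n_case + params.n_control
    calls = rng.binomial(2, p[:, None], size=(n_sites, n)).astype(np.int8)

    ilo, ihi = params.ibd_interval
    inside = (positions >= ilo) & (positions <= ihi)
    hap_allele = rng.binomial(1, p[inside])  # the shared case haplotype, per site
    calls[inside, : params.n_case] = (2 * hap_allele[:, None]).astype(np.int8)

    samples = [f"case_{i+1}" for i in range(params.n_case)] + [
        f"ctrl_{i+1}" for i in range(params.n_control)
    ]
    is_case = np.array([True] * params.n_case + [False] * params.n_control)
    logger.info("simulate_scan_data: %d sites, %d samples, seed=%d",
                n_sites, n, params.seed)
    return SiteMatrix(params.contig, positions, [("A", "G")] * n_sites,
                      calls, is_case, samples, region=params.region)


# ---------------------------------------------------------------------------
# Multiplex-PCR allele templates
# ---------------------------------------------------------------------------

@dataclass
class AssayFixtureParams:
    """Geometry of the multiplex-PCR fixture (defaults are the published sizes)."""

    insertion_length: int = 1780
    anc_amplicon_f1r1: int = 506
    f1r2_product: int = 389
    f2r1_product: int = 676
    primer_length: int = 20
    include_83bp_deletion: bool = False
    seed: int = 0

    def validate(self) -> None:
        k = self.primer_length
        if k < 10:
            raise ValueError("primers must be at least 10 bp")
        if self.anc_amplicon_f1r1 < 2 * k + 1:
            raise ValueError("anc amplicon too short for two primer footprints")
        der_len = self.anc_amplicon_f1r1 + self.insertion_length
        if self.insertion_length and not (
            self.f1r2_product >= 2 * k and self.f2r1_product >= 2 * k
            and self.f1r2_product < der_len and self.f2r1_product < der_len
        ):
            raise ValueError("internal products do not fit inside the derived amplicon")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _plant_unique(template: str, primers: dict[str, str]) -> bool:
    """True iff every primer occurs exactly at its planted site(s), no strays."""
    for seq in primers.values():
        for probe in (seq, revcomp(seq)):
            if template.count(probe) > 1:
                return False
    return True


def synth_allele_sequences(
    params: AssayFixtureParams | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Generate anc/der allele templates plus primers F1, F2, R1, R2.

    The ancestral template is the F1..R1 amplicon (506 bp by default).  The
    derived template carries ``insertion_length`` extra bases at the variable
    site, with the R2 and F2 binding sites wholly inside the insertion, placed
    so that F1/R2 and F2/R1 span the published 389- and 676-bp products.  With
    ``include_83bp_deletion`` the derived allele additionally lacks an 83-bp
    stretch downstream of the insertion (the derived-haplotype deletion seen in
    resequencing); it is off by default because its position relative to the
    506-bp amplicon is not determined by the published sizes.
    """
    params = params or AssayFixtureParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    k = params.primer_length
    anc_len = params.anc_amplicon_f1r1
    ins = params.insertion_length
    der_len = anc_len + ins

    # Insertion point x in anc coordinates: R2 must fit inside the insertion
    # upstream of f1r2_product, F2 inside it upstream of the R1-anchored span.
    if ins:
        x_max = min(params.f1r2_product - k, anc_len - k, der_len - params.f2r1_product)
        x_min = k
        if x_max < x_min:
            raise ValueError("no feasible insertion point for the requested geometry")
        x = (x_min + x_max) // 2
    else:
        x = anc_len // 2

    for _ in range(100):  # rejection-sample until primer sites are unique
        f1 = _random_seq(rng, k)
        f2 = _random_seq(rng, k)
        r1 = _random_seq(rng, k)
        r2 = _random_seq(rng, k)
        der = list(_random_seq(rng, der_len))
        der[0:k] = f1
        der[der_len - k:der_len] = revcomp(r1)
        if ins:
            der[params.f1r2_product - k:params.f1r2_product] = revcomp(r2)
            f2_start = der_len - params.f2r1_product
            der[f2_start:f2_start + k] = f2
        der_seq = "".join(der)
        anc_seq = der_seq[:x] + der_seq[x + ins:]
        primers = {"F1": f1, "F2": f2, "R1": r1, "R2": r2}
        if _plant_unique(der_seq, primers) and _plant_unique(anc_seq, primers):
            break
    else:  # pragma: no cover - 20-mer collisions are vanishingly rare
        raise RuntimeError("could not generate unique primer sites")

    if params.include_83bp_deletion:
        # drop 83 bp from the anc-shared segment downstream of the insertion,
        # clear of the R1 footprint
        del_at = x + ins + 10
        if del_at + 83 > der_len - k:
            raise ValueError("83-bp deletion does not fit the derived template")
        der_seq = der_seq[:del_at] + der_seq[del_at + 83:]

    return {"anc": anc_seq, "der": der_seq}, primers


# ---------------------------------------------------------------------------
# RFLP / ACRS amplicon fixtures
# ---------------------------------------------------------------------------

_HPY188I = re.compile(r"TC.GA")


def _scrub_motif(seq: list[str], protected: list[tuple[int, int]],
                 rng: np.random.Generator) -> None:
    """Remove spurious TCNGA motifs in place, never touching protected ranges."""
    def is_protected(i: int) -> bool:
        return any(a <= i < b for a, b in protected)

    for _ in range(200):
        s = "".join(seq)
        dirty = False
        for m in _HPY188I.finditer(s):
            span = range(m.start(), m.end())
            if all(is_protected(i) for i in span):
                continue  # a planted site
            # only positions with a specific pattern base can break the match
            # (index 2 of TCNGA is N and matches anything)
            editable = [i for i in span
                        if not is_protected(i) and i - m.start() != 2]
            if not editable:
                continue
            i = editable[len(editable) // 2]
            old = seq[i]
            choices = [b for b in "ACGT" if b != old]
            seq[i] = choices[int(rng.integers(0, 3))]
            dirty = True
        if not dirty:
            return
    raise RuntimeError("could not scrub spurious restriction sites")


def _plant_site(seq: list[str], cut_at: int, allele_base: str | None = None) -> None:
    """Plant TCNGA so the cut (offset 3, TCN^GA) falls after ``cut_at`` bases."""
    start = cut_at - 3
    seq[start:start + 5] = ["T", "C", "A", "G", "A"]
    if allele_base is not None:
        seq[start + 3] = allele_base  # the allele-dependent base ('G' keeps the site)


def synth_rflp_fixture(allele: str, length: int = 754, seed: int = 0,
                       primer_length: int = 20) -> tuple[str, tuple[str, str]]:
    """Exon-14 amplicon fixture for the Hpy188I RFLP assay.

    The A-allele template carries one constitutive site cutting 726+28; the
    G-allele template carries an additional allele-created site splitting the
    726-bp piece into 429+297.  No spurious TCNGA motif occurs elsewhere on
    either strand (the pattern is its own reverse complement).
    """
    if allele not in ("A", "G"):
        raise ValueError("allele must be 'A' or 'G'")
    rng = np.random.default_rng(seed)
    k = primer_length
    seq = list(_random_seq(rng, length))
    protected: list[tuple[int, int]] = []
    _plant_site(seq, cut_at=length - 28)          # constitutive: 726 + 28
    protected.append((length - 28 - 3, length - 28 + 2))
    _plant_site(seq, cut_at=429, allele_base=allele)  # SNP site: 429 + 297 (G only)
    protected.append((429 - 3, 429 + 2))
    _scrub_motif(seq, protected, rng)
    template = "".join(seq)
    fwd = template[:k]
    rev = revcomp(template[-k:])
    return template, (fwd, rev)


#: Published ACRS primers for the 3'-UTR SNP rs421908034.  The reverse primer
#: carries a deliberate template mismatch that creates a Hpy188I site when
#: allele G is present.
ACRS_FORWARD = "CAAGCCAAAAAGGTGAATGG"
ACRS_REVERSE = "GTGGAGCAGCAGCTTTGAAAT"


def synth_acrs_fixture(allele: str, seed: int = 0) -> tuple[str, tuple[str, str]]:
    """104-bp 3'-UTR ACRS amplicon: allele A → uncut 104; allele G → 82 + 22.

    The engineered site straddles the reverse-primer footprint: its terminal
    'A' comes from the primer and the allele base G completes TCNGA.
    """
    if allele not in ("A", "G"):
        raise ValueError("allele must be 'A' or 'G'")
    rng = np.random.default_rng(seed)
    length = 104
    rev_rc = revcomp(ACRS_REVERSE)  # occupies the final 21 bases; starts with 'A'
    seq = list(_random_seq(rng, length))
    seq[:len(ACRS_FORWARD)] = ACRS_FORWARD
    seq[length - len(rev_rc):] = rev_rc
    # cut after 82 bases: pattern at [79, 84); position 83 is the primer's 'A'
    seq[79], seq[80], seq[81], seq[82] = "T", "C", "A", allele
    protected = [(0, len(ACRS_FORWARD)), (79, 84), (length - len(rev_rc), length)]
    _scrub_motif(seq, protected, rng)
    return "".join(seq), (ACRS_FORWARD, ACRS_REVERSE)


# ---------------------------------------------------------------------------
# Breed panels
# ---------------------------------------------------------------------------

#: Frequency of the derived (insertion) allele used per breed category.  The
#: completely polled value matches the observed near-fixation (204/208 der/der);
#: mixed-status categories segregate at intermediate frequency.
CATEGORY_DER_FREQ: dict[BreedCategory, float] = {
    BreedCategory.completely_polled: 0.99,
    BreedCategory.completely_horned: 0.0,
    BreedCategory.sex_dependent: 0.5,
    BreedCategory.variable: 0.5,
    BreedCategory.unknown: 0.5,
}


def synth_breed_panel(category: BreedCategory, n_male: int, n_female: int,
                      discordance_rate: float = 0.0, seed: int = 0,
                      breed: str | None = None) -> list[AnimalRecord]:
    """Generate pseudo-animals of one breed category.

    Insertion genotypes are Hardy-Weinberg draws at the category's derived-
    allele frequency; phenotypes follow the sex-influenced dominance rule
    (horned allele ``anc`` dominant in males, recessive in females) except that
    a ``discordance_rate`` fraction of animals has its binary phenotype flipped.
    """
    from .segregation import predict_phenotype  # closure with the model

    if not 0.0 <= discordance_rate <= 1.0:
        raise ValueError("discordance_rate must be in [0, 1]")
    category = BreedCategory(category)
    rng = np.random.default_rng(seed)
    p_der = CATEGORY_DER_FREQ[category]
    breed = breed or f"synthetic_{category.value}"
    records: list[AnimalRecord] = []
    sexes = [Sex.male] * n_male + [Sex.female] * n_female
    for i, sex in enumerate(sexes):
        n_der = rng.binomial(2, p_der)
        alleles = tuple(sorted(["der"] * n_der + ["anc"] * (2 - n_der)))
        geno = Genotype(INSERTION_MARKER.name, alleles)
        pheno = predict_phenotype(geno, sex)
        if rng.random() < discordance_rate:
            pheno = Phenotype.polled if pheno == Phenotype.horned else Phenotype.horned
        records.append(AnimalRecord(f"{breed}_{i+1:03d}", breed, sex, pheno,
                                    {geno.marker: geno}))
    return records
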