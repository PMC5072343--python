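"""Two-locus linkage disequilibrium from unphased diploid genotypes.

Haplotype frequencies for two biallelic loci are estimated from a 3×3 joint
genotype-count table by expectation-maximization: only the double-heterozygote
class is phase-ambiguous, and the E-step splits it between the cis (AB/ab) and
trans (Ab/aB) configurations in proportion to
p_AB·p_ab / (p_AB·p_ab + p_Ab·p_aB).  From the converged frequencies the usual
pairwise statistics follow:

    D  = p_AB − p_A·p_B
    D′ = D / D_max          (D_max the sign-dependent bound)
    r² = D² / (p_A(1−p_A)·p_B(1−p_B))

EM is initialized at linkage equilibrium (products of the observed allele
frequencies), which the data's allele margins fix exactly: every EM step
preserves the observed allele frequencies, so the estimate moves only along
the one free haplotype dimension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import AnimalRecord, BreedCategory, InputError, logger

#: Haplotype order used throughout: AB, Ab, aB, ab where "A"/"B" are the
#: first (reference-like) alleles at locus 1 and 2.
HAPLOTYPES = ("AB", "Ab", "aB", "ab")


@dataclass
class TwoLocusCounts:
    """3×3 joint genotype counts; index = dosage of the second allele (0/1/2)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (3, 3):
            raise InputError("joint genotype table must be 3x3")
        if (self.counts < 0).any() or self.counts.sum() < 1:
            raise InputError("counts must be non-negative with total >= 1")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    def allele_freqs(self) -> tuple[float, float]:
        """Observed frequencies of the *second* allele (a at locus 1, b at 2)."""
        n = self.n
        dos1 = self.counts.sum(axis=1) @ np.array([0, 1, 2])
        dos2 = self.counts.sum(axis=0) @ np.array([0, 1, 2])
        return dos1 / (2 * n), dos2 / (2 * n)

    @classmethod
    def from_dosages(cls, d1: Sequence[int], d2: Sequence[int]) -> "TwoLocusCounts":
        tab = np.zeros((3, 3))
        for a, b in zip(d1, d2, strict=True):
            if a in (0, 1, 2) and b in (0, 1, 2):
                tab[a, b] += 1
        return cls(tab)


@dataclass
class HaplotypeFreqs:
    freqs: dict[str, float]
    log_likelihood: float
    iterations: int

    def __getitem__(self, hap: str) -> float:
        return self.freqs[hap]


@dataclass
class LDStats:
    D: float
    D_prime: float
    r2: float
    pA: float
    pB: float


def _class_probs(h: np.ndarray) -> np.ndarray:
    """P(joint dosage class) for haplotype freqs h = (pAB, pAb, paB, pab)."""
    pAB, pAb, paB, pab = h
    # dosage of second allele at locus1 = #a haplotypes, locus2 = #b haplotypes
    hap_dos = {"AB": (0, 0), "Ab": (0, 1), "aB": (1, 0), "ab": (1, 1)}
    P = np.zeros((3, 3))
    haps = list(hap_dos)
    for i, h1 in enumerate(haps):
        for j, h2 in enumerate(haps):
            d1 = hap_dos[h1][0] + hap_dos[h2][0]
            d2 = hap_dos[h1][1] + hap_dos[h2][1]
            P[d1, d2] += h[i] * h[j]
    return P


def log_likelihood(counts: TwoLocusCounts, h: np.ndarray) -> float:
    P = _class_probs(np.asarray(h, dtype=float))
    mask = counts.counts > 0
    with np.errstate(divide="ignore"):
        ll = np.where(mask, counts.counts * np.log(np.where(mask, P, 1.0)), 0.0)
    return float(ll.sum())


def em_haplotypes(counts: TwoLocusCounts, tol: float = 1e-10,
                  max_iter: int = 1000) -> HaplotypeFreqs:
    """EM haplotype-frequency estimation from a 3×3 joint genotype table.

    Iterates until the largest absolute frequency change is below ``tol``.
    The log-likelihood is non-decreasing across iterations.  Raises if either
    locus is monomorphic (LD undefined).
    """
    pa, pb = counts.allele_freqs()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise InputError("LD undefined: a locus is monomorphic in the sample")
    pA, pB = 1.0 - pa, 1.0 - pb
    h = np.array([pA * pB, pA * pb, pa * pB, pa * pb])  # linkage equilibrium

    c = counts.counts
    two_n = 2.0 * counts.n
    # haplotype counts contributed by phase-unambiguous classes
    base = np.array([
        2 * c[0, 0] + c[0, 1] + c[1, 0],  # AB
        2 * c[0, 2] + c[0, 1] + c[1, 2],  # Ab
        2 * c[2, 0] + c[2, 1] + c[1, 0],  # aB
        2 * c[2, 2] + c[2, 1] + c[1, 2],  # ab
    ], dtype=float)
    n_dh = c[1, 1]  # double heterozygotes: AB/ab or Ab/aB

    for it in range(1, max_iter + 1):
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        denom = cis + trans
        w = 0.5 if denom == 0 else cis / denom
        new = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new /= two_n
        delta = np.max(np.abs(new - h))
        h = new
        if delta < tol:
            break
    return HaplotypeFreqs(dict(zip(HAPLOTYPES, h.tolist())),
                          log_likelihood(counts, h), it)


def ld_stats(h: HaplotypeFreqs) -> LDStats:
    """D, D′ and r² from haplotype frequencies."""
    pAB = h["AB"]
    pA = h["AB"] + h["Ab"]
    pB = h["AB"] + h["aB"]
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise InputError("LD undefined: an allele is fixed")
    D = pAB - pA * pB
    if D >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if d_max == 0 else D / d_max
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LDStats(D, d_prime, r2, pA, pB)


# ---------------------------------------------------------------------------
# Panel-level grouped r²
# ---------------------------------------------------------------------------

def _dosage(rec: AnimalRecord, marker: str, second_allele: str) -> int | None:
    g = rec.genotypes.get(marker)
    if g is None or g.missing:
        return None
    return g.count(second_allele)


def counts_from_panel(panel: Sequence[AnimalRecord], marker1: str, marker2: str,
                      allele1: str, allele2: str) -> TwoLocusCounts:
    """Cross-tabulate two markers' dosages (of the named alleles) over a panel."""
    tab = np.zeros((3, 3))
    for rec in panel:
        d1 = _dosage(rec, marker1, allele1)
        d2 = _dosage(rec, marker2, allele2)
        if d1 is not None and d2 is not None:
            tab[d1, d2] += 1
    return TwoLocusCounts(tab)


def grouped_r2(panel: Sequence[AnimalRecord], marker1: str, marker2: str,
               grouping: dict[str, list[str]], *, allele1: str, allele2: str,
               ratio_groups: tuple[str, str] | None = None,
               eps: float = 1e-12) -> tuple[dict[str, LDStats], float | None]:
    """Per-group LD statistics plus an optional r² ratio between two groups.

    ``grouping`` maps group name → breed list.  Groups in which either locus is
    monomorphic are skipped with a warning.  The ratio (rounded to 2 decimals)
    uses a denominator floor ``eps``; a floored denominator is warned about.
    """
    stats: dict[str, LDStats] = {}
    for name, breeds in grouping.items():
        sub = [r for r in panel if r.breed in set(breeds)]
        try:
            counts = counts_from_panel(sub, marker1, marker2, allele1, allele2)
            stats[name] = ld_stats(em_haplotypes(counts))
        except InputError as exc:
            logger.warning("grouped_r2: group %r skipped (%s)", name, exc)
    ratio = None
    if ratio_groups is not None:
        num_g, den_g = ratio_groups
        if num_g in stats and den_g in stats:
            den = stats[den_g].r2
            if den < eps:
                logger.warning("grouped_r2: denominator r2 below %g, floored", eps)
                den = eps
            ratio = round(stats[num_g].r2 / den, 2)
    return stats, ratio


def r2_ratio(r2_num: float, r2_den: float, eps: float = 1e-12) -> float:
    """Ratio of two reported r² values, rounded to 2 decimals."""
    if r2_den < eps:
        logger.warning("r2_ratio: denominator below %g, floored", eps)
        r2_den = eps
    return round(r2_num / r2_den, 2)


def category_grouping(cfg, panel: Sequence[AnimalRecord]) -> dict[str, list[str]]:
    """Standard grouping: fixed-status breeds vs variable-status breeds."""
    fixed, variable = [], []
    for breed in sorted({r.breed for r in panel}):
        cat = cfg.category(breed)
        if cat in (BreedCategory.completely_polled, BreedCategory.completely_horned):
            fixed.append(breed)
        elif cat in (BreedCategory.variable, BreedCategory.sex_dependent):
            variable.append(breed)
    return {"fixed_status": fixed, "variable_status": variable}
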