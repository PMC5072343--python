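"""In-silico PCR (single and multiplex) and restriction digestion.

Reproduces the study's three genotyping assays on sequence templates:

* multiplex PCR with primers F1/F2/R1/R2 distinguishing the ancestral and
  derived (insertion-bearing) alleles by fragment pattern — anc/anc → {506},
  der/der → {2286, 389, 676}, anc/der → the union;
* Hpy188I (TCNGA, cut TCN^GA) digestion of the exon-14 amplicon —
  A → 726+28, G → 429+297+28 over 754 bp;
* the amplification-created restriction site (ACRS) assay on the 3'-UTR SNP —
  A → 104, G → 82+22.

Primer matching is exact (no mismatch or thermodynamic model): the deliberate
template mismatch of the ACRS reverse primer is embedded in the fixtures
as-is, so exact matching reproduces the assay.  Restriction enzymes are
user-definable records (IUPAC pattern + top-strand cut offset), not a bundled
database.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .datamodel import InputError
from .simulate import revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str  # 5'->3' over A/C/G/T

    def __post_init__(self) -> None:
        if len(self.sequence) < 10:
            raise InputError(f"primer {self.name} shorter than 10 bp")
        if set(self.sequence) - set("ACGT"):
            raise InputError(f"primer {self.name} contains non-ACGT characters")


@dataclass(frozen=True)
class Amplicon:
    template: str
    forward: str
    reverse: str
    start: int  # 1-based inclusive on template
    end: int    # 1-based inclusive

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RestrictionEnzyme:
    """IUPAC recognition pattern with the top-strand cut offset.

    ``offset`` counts bases of the pattern left of the cut: Hpy188I is
    TCNGA with offset 3 (TCN^GA).
    """

    name: str
    pattern: str
    offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.offset <= len(self.pattern):
            raise InputError("cut offset must lie within the pattern")
        if set(self.pattern) - set(IUPAC):
            raise InputError(f"pattern {self.pattern!r} is not IUPAC")

    def regex(self) -> re.Pattern:
        return re.compile("".join(IUPAC[b] for b in self.pattern))

    def revcomp_pattern(self) -> str:
        return self.pattern.translate(_IUPAC_COMPLEMENT)[::-1]


HPY188I = RestrictionEnzyme("Hpy188I", "TCNGA", 3)


@dataclass(frozen=True)
class MultiplexCall:
    fragments: tuple[int, ...]
    genotype: str  # anc/anc, anc/der, der/der or uncallable


# ---------------------------------------------------------------------------
# Primer-site search and PCR
# ---------------------------------------------------------------------------

def find_sites(template: str, primer: Primer | str) -> list[tuple[int, str]]:
    """Exact primer binding sites as (1-based position of the site's first
    template base, strand).

    Plus-strand sites are matches of the primer itself; minus-strand sites are
    matches of its reverse complement (the primer anneals to the plus strand
    and extends leftward).
    """
    seq = primer.sequence if isinstance(primer, Primer) else primer
    template = template.upper()
    out: list[tuple[int, str]] = []
    for probe, strand in ((seq, "+"), (revcomp(seq), "-")):
        start = 0
        while True:
            i = template.find(probe, start)
            if i < 0:
                break
            out.append((i + 1, strand))
            start = i + 1
    return sorted(out)


def pcr(template: str, forward: Primer | str, reverse: Primer | str,
        max_len: int = 10_000) -> list[Amplicon]:
    """Predict amplicons: every (plus-strand forward site, downstream
    minus-strand reverse site) pair with product length ≤ ``max_len``.

    Lengths include both primer footprints, matching gel interpretation.
    """
    fwd_name = forward.name if isinstance(forward, Primer) else "F"
    rev_name = reverse.name if isinstance(reverse, Primer) else "R"
    fwd_seq = forward.sequence if isinstance(forward, Primer) else forward
    rev_seq = reverse.sequence if isinstance(reverse, Primer) else reverse
    fwd_sites = [p for p, s in find_sites(template, fwd_seq) if s == "+"]
    rev_sites = [p for p, s in find_sites(template, rev_seq) if s == "-"]
    out = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev_seq) - 1
            if end <= f + len(fwd_seq) - 1:
                continue  # reverse site must lie downstream of the forward site
            length = end - f + 1
            if length <= max_len:
                out.append(Amplicon("", fwd_name, rev_name, f, end))
    return sorted(out, key=lambda a: (a.start, a.length))


def multiplex(templates: Iterable[str], primers: Mapping[str, str | Primer],
              *, max_len: int = 10_000,
              anc_product: int = 506,
              insertion_products: tuple[int, int] = (389, 676)) -> MultiplexCall:
    """Run the four-primer multiplex on the allele templates present and call
    the insertion genotype from the fragment-length pattern.

    Call rule: insertion-internal products present and the short anc product
    absent → der/der; the reverse → anc/anc; both → anc/der; anything else is
    uncallable.
    """
    def as_seq(p):
        return p.sequence if isinstance(p, Primer) else p

    pairs = (("F1", "R1"), ("F1", "R2"), ("F2", "R1"))
    fragments: list[int] = []
    for template in templates:
        for fname, rname in pairs:
            for amp in pcr(template, as_seq(primers[fname]), as_seq(primers[rname]),
                           max_len=max_len):
                fragments.append(amp.length)
    observed = tuple(sorted(fragments, reverse=True))
    uniq = set(observed)
    has_anc = anc_product in uniq
    has_ins = all(p in uniq for p in insertion_products)
    if has_ins and not has_anc:
        genotype = "der/der"
    elif has_anc and not has_ins and not any(p in uniq for p in insertion_products):
        genotype = "anc/anc"
    elif has_anc and has_ins:
        genotype = "anc/der"
    else:
        genotype = "uncallable"
    return MultiplexCall(observed, genotype)


# ---------------------------------------------------------------------------
# Restriction digestion and RFLP calls
# ---------------------------------------------------------------------------

def digest(sequence: str, enzyme: RestrictionEnzyme = HPY188I) -> list[int]:
    """Fragment lengths (descending) after digesting a linear sequence.

    Sites are every IUPAC match of the recognition pattern on either strand;
    each double-stranded cut event is placed at its top-strand cut point
    (pattern offset for plus-strand sites, ``len − offset`` for sites found
    only as the reverse-complement pattern).  Fragments partition the sequence.
    """
    seq = sequence.upper()
    fwd = {m.start() for m in enzyme.regex().finditer(seq)}
    cuts = {i + enzyme.offset for i in fwd}
    rc = enzyme.revcomp_pattern()
    if rc != enzyme.pattern:
        rc_re = re.compile("".join(IUPAC[b] for b in rc))
        for m in rc_re.finditer(seq):
            if m.start() not in fwd:
                cuts.add(m.start() + len(enzyme.pattern) - enzyme.offset)
    bounds = [0] + sorted(c for c in cuts if 0 < c < len(seq)) + [len(seq)]
    frags = [b - a for a, b in zip(bounds, bounds[1:])]
    return sorted(frags, reverse=True)


def rflp_call(fragments: Sequence[int], allele_patterns: Mapping[str, Sequence[int]],
              detection_floor: int | None = None) -> str:
    """Call a genotype from observed fragment lengths.

    ``allele_patterns`` maps allele name → expected fragment multiset.  The
    call is homozygous when fragments match one allele's pattern, heterozygous
    when they match the union of both, otherwise ``uncallable``.  With a
    ``detection_floor`` (gel resolution), fragments below the floor are masked
    from both observation and expectation before comparison.
    """
    if len(allele_patterns) != 2:
        raise InputError("need exactly two allele patterns")

    def mask(lengths: Iterable[int]) -> frozenset[int]:
        keep = [x for x in lengths
                if detection_floor is None or x >= detection_floor]
        return frozenset(keep)

    observed = mask(fragments)
    (a1, p1), (a2, p2) = sorted(allele_patterns.items())
    if observed == mask(p1):
        return f"{a1}/{a1}"
    if observed == mask(p2):
        return f"{a2}/{a2}"
    if observed == mask(list(p1) + list(p2)):
        return f"{a1}/{a2}"
    return "uncallable"


#: Published fragment patterns for the two Hpy188I assays.
EXON14_PATTERNS = {"A": (726, 28), "G": (429, 297, 28)}
ACRS_PATTERNS = {"A": (104,), "G": (82, 22)}
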