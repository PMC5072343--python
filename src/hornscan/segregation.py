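"""Sex-influenced dominance model for horn status and table aggregates.

The model under test: the ancestral allele (``anc``, no insertion) acts as the
horned allele, dominant in males and recessive in females.  A heterozygous
male is therefore horned while a heterozygous female is polled.  This module
evaluates genotype/phenotype concordance of animal panels under that rule,
computes genotype-frequency tables per breed (or breed × sex), and exposes the
packaged transcriptions of the study's genotype tables (three multiplex-PCR
panels and one intron-11 SNP panel) as pseudo-animal records.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Callable, Iterable, Sequence

import pandas as pd

from .datamodel import (
    DEFAULT_MARKERS,
    INSERTION_MARKER,
    AnimalRecord,
    BreedCategory,
    BreedCategoryConfig,
    Genotype,
    InputError,
    Phenotype,
    Sex,
    logger,
)

#: Intermediate horn phenotypes (small/irregular or skin-covered growths).
INTERMEDIATE_PHENOTYPES = frozenset({Phenotype.scurred, Phenotype.rudiments})


@dataclass(frozen=True)
class InheritanceModel:
    """Two-allele sex-influenced dominance: horned dominant in males,
    recessive in females."""

    marker: str = INSERTION_MARKER.name
    horned_allele: str = "anc"

    def predict(self, genotype: Genotype, sex: Sex) -> Phenotype:
        if genotype.missing:
            raise ValueError(f"cannot predict from missing genotype at {genotype.marker}")
        n_horned = genotype.count(self.horned_allele)
        if sex == Sex.male:
            return Phenotype.horned if n_horned >= 1 else Phenotype.polled
        return Phenotype.horned if n_horned == 2 else Phenotype.polled


DEFAULT_MODEL = InheritanceModel()

#: The same rule applied to the intron-11 SNP, whose A allele tracks ``anc``.
INTRON11_MODEL = InheritanceModel(marker="OAR10_29511510.1", horned_allele="A")


def predict_phenotype(genotype: Genotype, sex: Sex,
                      model: InheritanceModel = DEFAULT_MODEL) -> Phenotype:
    """Predicted binary horn status for one genotype and sex."""
    return model.predict(genotype, sex)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceCounts:
    concordant: int = 0
    discordant: int = 0
    intermediate: int = 0
    missing: int = 0

    @property
    def total(self) -> int:
        return self.concordant + self.discordant + self.intermediate + self.missing


@dataclass
class ConcordanceTable:
    per_breed: dict[str, ConcordanceCounts]
    pooled: ConcordanceCounts
    scur_policy: str

    def to_frame(self) -> pd.DataFrame:
        rows = {b: vars(c) | {"total": c.total} for b, c in self.per_breed.items()}
        rows["(pooled)"] = vars(self.pooled) | {"total": self.pooled.total}
        return pd.DataFrame.from_dict(rows, orient="index")


def concordance(panel: Sequence[AnimalRecord],
                model: InheritanceModel = DEFAULT_MODEL,
                scur_policy: str = "intermediate") -> ConcordanceTable:
    """Tabulate predicted-vs-observed horn status per breed and pooled.

    ``scur_policy`` decides how scurred/rudiments animals enter the comparison:
    ``intermediate`` (default) counts them in a separate class, ``horned`` or
    ``polled`` treats the observed phenotype as that binary class.  Animals with
    a missing genotype or unknown phenotype fall into ``missing``.
    """
    if not panel:
        raise InputError("panel is empty")
    if scur_policy not in ("intermediate", "horned", "polled"):
        raise InputError(f"unknown scur_policy {scur_policy!r}")
    per_breed: dict[str, ConcordanceCounts] = {}
    pooled = ConcordanceCounts()
    for rec in panel:
        counts = per_breed.setdefault(rec.breed, ConcordanceCounts())
        geno = rec.genotypes.get(model.marker)
        observed = rec.phenotype
        if observed in INTERMEDIATE_PHENOTYPES:
            if scur_policy == "intermediate":
                counts.intermediate += 1
                pooled.intermediate += 1
                continue
            observed = Phenotype(scur_policy)
        if geno is None or geno.missing or observed == Phenotype.unknown:
            counts.missing += 1
            pooled.missing += 1
            continue
        predicted = model.predict(geno, rec.sex)
        if predicted == observed:
            counts.concordant += 1
            pooled.concordant += 1
        else:
            counts.discordant += 1
            pooled.discordant += 1
    return ConcordanceTable(per_breed, pooled, scur_policy)


# ---------------------------------------------------------------------------
# Frequency tables and predicate counts
# ---------------------------------------------------------------------------

def _round_half_up(x: float, decimals: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(1).scaleb(-decimals),
                                           rounding=ROUND_HALF_UP))


def genotype_frequency_table(panel: Sequence[AnimalRecord], marker: str,
                             by: str = "breed", decimals: int = 2) -> pd.DataFrame:
    """Counts and rounded frequencies of the three genotype classes per stratum.

    ``by`` is ``breed`` or ``breed_sex``.  Frequencies are computed over
    non-missing calls and rounded half-up to ``decimals``.
    """
    if by not in ("breed", "breed_sex"):
        raise InputError(f"unknown stratification {by!r}")
    rows = []
    for rec in panel:
        geno = rec.genotypes.get(marker)
        if geno is None:
            raise InputError(f"marker {marker!r} absent from animal {rec.animal_id}")
        if geno.missing:
            continue
        key = (rec.breed,) if by == "breed" else (rec.breed, rec.sex.value)
        rows.append(key + (str(geno),))
    if not rows:
        raise InputError(f"no non-missing calls at {marker!r}")
    cols = ["breed"] if by == "breed" else ["breed", "sex"]
    df = pd.DataFrame(rows, columns=cols + ["genotype"])
    counts = df.groupby(cols + ["genotype"], sort=True).size().rename("count").reset_index()
    totals = counts.groupby(cols)["count"].transform("sum")
    counts["frequency"] = [
        _round_half_up(c / t, decimals) for c, t in zip(counts["count"], totals)
    ]
    return counts


def count_where(panel: Iterable[AnimalRecord],
                predicate: Callable[[AnimalRecord], bool]) -> int:
    """Exact count of records for which the predicate holds."""
    return sum(1 for rec in panel if predicate(rec))


# ---------------------------------------------------------------------------
# Packaged table fixtures
# ---------------------------------------------------------------------------

TABLE_NAMES = ("table1", "table2", "table3", "table4")


def _table_path(name: str):
    return resources.files("hornscan") / "tables" / f"{name}.csv"


def table_sha256(name: str) -> str:
    return hashlib.sha256(_table_path(name).read_bytes()).hexdigest()


def verify_table_checksums() -> None:
    """Raise if any packaged table deviates from its recorded integrity hash."""
    with (resources.files("hornscan") / "tables" / "checksums.json").open() as fh:
        expected = json.load(fh)
    for name, digest in expected.items():
        actual = table_sha256(name)
        if actual != digest:
            raise InputError(f"fixture {name}.csv integrity hash mismatch "
                             f"(expected {digest[:12]}…, found {actual[:12]}…)")


def load_table(name: str) -> pd.DataFrame:
    """Load one packaged per-stratum count table (``table1`` … ``table4``)."""
    if name not in TABLE_NAMES:
        raise InputError(f"unknown packaged table {name!r}")
    path = _table_path(name)
    if not path.is_file():
        raise InputError(f"packaged fixture {name}.csv is missing")
    with path.open() as fh:
        return pd.read_csv(fh)


def expand_table(name: str, include_uncertain: bool = True) -> list[AnimalRecord]:
    """Expand a per-stratum count table into pseudo-animal records.

    Each stratum row of ``count`` animals becomes that many records with ids
    ``<table>-<row>-<k>``.  Rows whose genotype-column assignment was ambiguous
    in the source rendering carry ``uncertain=True`` and can be excluded.
    """
    df = load_table(name)
    records: list[AnimalRecord] = []
    for i, row in df.iterrows():
        uncertain = bool(row.get("uncertain", 0))
        if uncertain and not include_uncertain:
            continue
        marker = DEFAULT_MARKERS[row["marker"]]
        alleles = tuple(sorted(row["genotype"].split("/")))
        sex_token = row["sex"]
        for k in range(int(row["count"])):
            # strata without individual sex alternate deterministically
            sex = (Sex.male if k % 2 == 0 else Sex.female) \
                if sex_token == "unknown" else Sex(sex_token)
            records.append(AnimalRecord(
                animal_id=f"{name}-r{i:02d}-{k + 1:03d}",
                breed=row["breed"],
                sex=sex,
                phenotype=Phenotype(row["phenotype"]),
                genotypes={marker.name: Genotype(marker.name, alleles)},
                uncertain=uncertain,
            ))
    logger.info("expand_table: %s -> %d pseudo-animals", name, len(records))
    return records


def table_breed_categories(names: Sequence[str] = TABLE_NAMES) -> BreedCategoryConfig:
    cfg = BreedCategoryConfig()
    for name in names:
        for _, row in load_table(name).iterrows():
            cfg.categories.setdefault(row["breed"], BreedCategory(row["category"]))
    return cfg


# ---------------------------------------------------------------------------
# Headline aggregates over the packaged tables
# ---------------------------------------------------------------------------

def headline_counts() -> dict[str, float]:
    """Recompute the headline aggregates of the packaged tables.

    Returns sample-set checksums (polled/horned totals of the multiplex panel),
    the intron-11 SNP counts for heterozygous and reference-homozygous animals
    by breed category and sex, and the derived percentages/frequencies.
    """
    cfg = table_breed_categories(("table4",))
    t1 = expand_table("table1")
    t4 = expand_table("table4")

    def cat(rec: AnimalRecord) -> BreedCategory:
        return cfg.category(rec.breed)

    def gt(rec: AnimalRecord, marker: str) -> str:
        return str(rec.genotypes[marker])

    snp = "OAR10_29511510.1"
    t1_cfg = table_breed_categories(("table1",))
    set1_polled = count_where(
        t1, lambda r: t1_cfg.category(r.breed) == BreedCategory.completely_polled)
    set1_horned = count_where(
        t1, lambda r: t1_cfg.category(r.breed) == BreedCategory.completely_horned)
    set1_derder = count_where(
        t1, lambda r: t1_cfg.category(r.breed) == BreedCategory.completely_polled
        and gt(r, "ins1780") == "der/der")

    gg_males_sexdep = count_where(
        t4, lambda r: cat(r) == BreedCategory.sex_dependent
        and r.sex == Sex.male and gt(r, snp) == "G/G")
    ag_males_polled = count_where(
        t4, lambda r: cat(r) == BreedCategory.completely_polled
        and r.sex == Sex.male and gt(r, snp) == "A/G")
    ag_females_horned = count_where(
        t4, lambda r: cat(r) == BreedCategory.completely_horned
        and r.sex == Sex.female and gt(r, snp) == "A/G")

    ramb_males = [r for r in t4 if r.breed == "Rambouillet" and r.sex == Sex.male]
    ramb_gg = count_where(ramb_males, lambda r: gt(r, snp) == "G/G")
    ramb_gg_pct = _round_half_up(100.0 * ramb_gg / len(ramb_males), 1)

    freqs = genotype_frequency_table(t4, snp, by="breed")

    def ag_freq(breed: str) -> float:
        sub = freqs[(freqs["breed"] == breed) & (freqs["genotype"] == "A/G")]
        return float(sub["frequency"].iloc[0]) if len(sub) else 0.0

    return {
        "set1_polled_total": set1_polled,
        "set1_horned_total": set1_horned,
        "set1_polled_derder": set1_derder,
        "gg_males_sex_dependent_breeds": gg_males_sexdep,
        "ag_males_completely_polled_breeds": ag_males_polled,
        "ag_females_completely_horned_breeds": ag_females_horned,
        "rambouillet_male_gg_percent": ramb_gg_pct,
        "ethiopian_menz_ag_frequency": ag_freq("Ethiopian Menz"),
        "tibetan_ag_frequency": ag_freq("Tibetan"),
    }
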