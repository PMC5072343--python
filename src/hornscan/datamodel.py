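"""Domain types and file I/O shared by all pipeline stages.

The pipeline studies presence/absence of a 1.78-kb insertion in the 3'-UTR of
ovine *RXFP2* (alleles ``anc``/``der``) and nearby SNPs, against horn-status
phenotypes.  This module owns the in-memory containers (animal panels, biallelic
site-by-sample matrices, marker definitions, breed-category configuration) and
the readers/writers for the plain-text formats the tool exchanges: CSV/TSV
panels, TSV or minimal-VCF site matrices, FASTA sequences and YAML configs.

Coordinates are 1-based inclusive throughout, following the GenBank convention
used for the *RXFP2* region (NC_019467.2).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("hornscan")

MISSING = -1  # dosage code for a missing diploid call

PANEL_FIXED_COLUMNS = ("animal_id", "breed", "sex", "phenotype")


class InputError(ValueError):
    """Malformed or contract-violating user input."""


class Sex(str, Enum):
    male = "male"
    female = "female"


class Phenotype(str, Enum):
    horned = "horned"
    polled = "polled"
    scurred = "scurred"
    rudiments = "rudiments"
    unknown = "unknown"


class BreedCategory(str, Enum):
    completely_polled = "completely_polled"
    completely_horned = "completely_horned"
    sex_dependent = "sex_dependent"
    variable = "variable"
    unknown = "unknown"


class MarkerKind(str, Enum):
    presence_absence = "presence_absence"
    snp = "snp"


@dataclass(frozen=True)
class MarkerDef:
    """A biallelic marker; ``alleles`` is ordered, reference-like allele first."""

    name: str
    alleles: tuple[str, str]
    kind: MarkerKind = MarkerKind.snp
    contig: str | None = None
    position: int | None = None  # 1-based

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != 2:
            raise ValueError(f"marker {self.name!r} needs two distinct alleles")


#: The insertion presence/absence marker: ``anc`` = no insertion (reference-like),
#: ``der`` = carries the 1.78-kb insertion associated with polledness.
INSERTION_MARKER = MarkerDef(
    name="ins1780",
    alleles=("anc", "der"),
    kind=MarkerKind.presence_absence,
    contig="NC_019467.2",
    position=29_433_060,
)

#: SNP markers genotyped alongside the insertion.
SNP_3UTR = MarkerDef("rs421908034", ("G", "A"), MarkerKind.snp, "NC_019467.2", 29_432_846)
SNP_EXON14 = MarkerDef("rs414104606", ("G", "A"), MarkerKind.snp)
SNP_INTRON11 = MarkerDef("OAR10_29511510.1", ("A", "G"), MarkerKind.snp)

DEFAULT_MARKERS: dict[str, MarkerDef] = {
    m.name: m for m in (INSERTION_MARKER, SNP_3UTR, SNP_EXON14, SNP_INTRON11)
}


@dataclass(frozen=True)
class Genotype:
    """An unordered diploid genotype at one marker; ``alleles`` is None when missing."""

    marker: str
    alleles: tuple[str, str] | None

    @property
    def missing(self) -> bool:
        return self.alleles is None

    def count(self, allele: str) -> int:
        if self.alleles is None:
            raise ValueError(f"genotype at {self.marker} is missing")
        return sum(a == allele for a in self.alleles)

    def __str__(self) -> str:
        return "./." if self.alleles is None else "/".join(self.alleles)


def parse_genotype(marker: MarkerDef, token: str) -> Genotype:
    """Parse an ``allele1/allele2`` token, order-insensitive; '' or './.' → missing."""
    token = token.strip()
    if token in ("", "./.", "NA", "na", "-"):
        return Genotype(marker.name, None)
    parts = token.split("/")
    if len(parts) != 2 or any(p not in marker.alleles for p in parts):
        return Genotype(marker.name, None)  # unparseable → missing (caller logs)
    return Genotype(marker.name, (min(parts), max(parts)))


@dataclass
class AnimalRecord:
    """One genotyped and phenotyped sheep."""

    animal_id: str
    breed: str
    sex: Sex
    phenotype: Phenotype
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    uncertain: bool = False  # source-table cell ambiguity flag

    def genotype(self, marker: str) -> Genotype:
        try:
            return self.genotypes[marker]
        except KeyError:
            raise KeyError(f"animal {self.animal_id} has no genotype at {marker}")


@dataclass
class BreedCategoryConfig:
    """Map breed name → horn-status category; unmapped breeds report ``unknown``."""

    categories: dict[str, BreedCategory] = field(default_factory=dict)

    def category(self, breed: str) -> BreedCategory:
        return self.categories.get(breed, BreedCategory.unknown)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BreedCategoryConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls({b: BreedCategory(c) for b, c in raw.items()})

    @classmethod
    def from_panel(cls, records: Iterable[AnimalRecord],
                   mapping: Mapping[str, str]) -> "BreedCategoryConfig":
        cfg = cls({b: BreedCategory(c) for b, c in mapping.items()})
        for rec in records:
            cfg.categories.setdefault(rec.breed, BreedCategory.unknown)
        return cfg


# ---------------------------------------------------------------------------
# Panels (CSV/TSV with header: animal_id, breed, sex, phenotype, marker ...)
# ---------------------------------------------------------------------------

def read_panel(path: str | Path,
               markers: Mapping[str, MarkerDef] | None = None) -> list[AnimalRecord]:
    """Read a delimiter-separated animal panel.

    The header must declare ``animal_id, breed, sex, phenotype`` followed by one
    column per marker with slash-separated alleles.  Unparseable genotype cells
    become missing calls (with a logged warning count); unknown sex/phenotype
    tokens and duplicated animal ids are hard errors.
    """
    markers = dict(markers or DEFAULT_MARKERS)
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in PANEL_FIXED_COLUMNS:
        if col not in df.columns:
            raise InputError(f"panel {path} is missing mandatory column {col!r}")
    marker_cols = [c for c in df.columns if c not in PANEL_FIXED_COLUMNS]
    for col in marker_cols:
        if col not in markers:
            raise InputError(f"panel column {col!r} references an undeclared marker")

    dup = df["animal_id"][df["animal_id"].duplicated()].unique()
    if len(dup):
        raise InputError(f"duplicated animal_id(s): {', '.join(dup)}")

    records: list[AnimalRecord] = []
    n_unparseable = 0
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        try:
            sex = Sex(row["sex"].strip().lower())
        except ValueError:
            raise InputError(f"unknown sex token {row['sex']!r} at row {rownum}")
        try:
            phenotype = Phenotype(row["phenotype"].strip().lower())
        except ValueError:
            raise InputError(f"unknown phenotype token {row['phenotype']!r} at row {rownum}")
        if not row["breed"].strip():
            raise InputError(f"empty breed at row {rownum}")
        genos: dict[str, Genotype] = {}
        for col in marker_cols:
            g = parse_genotype(markers[col], row[col])
            if g.missing and row[col].strip() not in ("", "./.", "NA", "na", "-"):
                n_unparseable += 1
            genos[col] = g
        records.append(AnimalRecord(row["animal_id"], row["breed"], sex, phenotype, genos))
    if n_unparseable:
        logger.warning("read_panel: %d unparseable genotype cell(s) set to missing",
                       n_unparseable)
    logger.info("read_panel: %d records from %s", len(records), path)
    return records


def write_panel(records: Sequence[AnimalRecord], path: str | Path) -> None:
    """Write a panel in the :func:`read_panel` format (round-trip identity)."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    marker_cols = sorted({m for r in records for m in r.genotypes})
    rows = []
    for r in records:
        row = {"animal_id": r.animal_id, "breed": r.breed,
               "sex": r.sex.value, "phenotype": r.phenotype.value}
        for m in marker_cols:
            g = r.genotypes.get(m)
            row[m] = "" if g is None or g.missing else str(g)
        rows.append(row)
    pd.DataFrame(rows, columns=list(PANEL_FIXED_COLUMNS) + marker_cols).to_csv(
        path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Site matrices (biallelic sites x samples, dosage-coded)
# ---------------------------------------------------------------------------

@dataclass
class SiteMatrix:
    """Biallelic sites × samples allele-dosage matrix with case/control labels.

    ``calls[i, j]`` is the count of the alternate allele (0/1/2) carried by
    sample ``j`` at site ``i``, or ``MISSING``.  ``is_case[j]`` marks polled
    cases.  Positions are 1-based and strictly increasing on ``contig``.
    """

    contig: str
    positions: np.ndarray            # (n_sites,) int64
    alleles: list[tuple[str, str]]   # per-site (ref, alt)
    calls: np.ndarray                # (n_sites, n_samples) int8, MISSING = -1
    is_case: np.ndarray              # (n_samples,) bool
    samples: list[str]
    region: tuple[int, int] | None = None  # 1-based inclusive scan bounds

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if self.positions.ndim != 1 or np.any(np.diff(self.positions) <= 0):
            raise InputError("site positions must be strictly increasing")
        if self.calls.shape != (len(self.positions), len(self.samples)):
            raise InputError("calls shape does not match sites x samples")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise InputError("dosages must be 0, 1, 2 or missing")
        if self.is_case.sum() < 1 or (~self.is_case).sum() < 1:
            raise InputError("need at least one case and one control sample")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_sites(self, keep: np.ndarray) -> "SiteMatrix":
        keep = np.asarray(keep)
        return SiteMatrix(
            contig=self.contig,
            positions=self.positions[keep],
            alleles=[a for a, k in zip(self.alleles, keep)
                     if k] if keep.dtype == bool else [self.alleles[i] for i in keep],
            calls=self.calls[keep],
            is_case=self.is_case,
            samples=self.samples,
            region=self.region,
        )


def _parse_gt(token: str) -> int:
    token = token.split(":")[0].replace("|", "/")
    if token in (".", "./.", ""):
        return MISSING
    try:
        a, b = token.split("/")
        if a == "." or b == ".":
            return MISSING
        return int(a) + int(b)
    except ValueError:
        return MISSING


def read_site_matrix(path: str | Path,
                     case_samples: Sequence[str] | None = None) -> SiteMatrix:
    """Read a site matrix from TSV or a minimal VCF subset.

    TSV columns: ``contig, pos, ref, alt`` then one dosage column per sample;
    a sample named ``case_*`` is a case unless ``case_samples`` is given.
    VCF: plain-text, GT fields only; multi-allelic sites are dropped with a
    logged count.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        rows, samples = _read_vcf_rows(path)
    else:
        rows, samples = _read_tsv_rows(path)
    if not samples:
        raise InputError(f"{path}: no sample columns")

    n_multi = sum(1 for r in rows if r is None)
    kept = [r for r in rows if r is not None]
    if n_multi:
        logger.warning("read_site_matrix: dropped %d non-biallelic site(s)", n_multi)
    if not kept:
        raise InputError(f"{path}: no biallelic sites")

    contig = kept[0][0]
    positions = np.array([r[1] for r in kept], dtype=np.int64)
    if np.any(np.diff(positions) <= 0):
        raise InputError(f"{path}: positions are not strictly increasing")
    alleles = [(r[2], r[3]) for r in kept]
    calls = np.array([r[4] for r in kept], dtype=np.int8)

    if case_samples is not None:
        case_set = set(case_samples)
        is_case = np.array([s in case_set for s in samples])
    else:
        is_case = np.array([s.startswith("case") for s in samples])
    return SiteMatrix(contig, positions, alleles, calls, is_case, list(samples))


def _read_tsv_rows(path: Path):
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
    for col in ("contig", "pos", "ref", "alt"):
        if col not in df.columns:
            raise InputError(f"{path} is missing column {col!r}")
    samples = [c for c in df.columns if c not in ("contig", "pos", "ref", "alt")]
    rows = []
    for _, row in df.iterrows():
        if "," in str(row["alt"]):
            rows.append(None)
            continue
        dosages = [MISSING if pd.isna(row[s]) else int(row[s]) for s in samples]
        rows.append((row["contig"], int(row["pos"]), row["ref"], row["alt"], dosages))
    return rows, samples


def _read_vcf_rows(path: Path):
    import pysam

    rows, samples = [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                rows.append(None)
                continue
            dosages = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    dosages.append(MISSING)
                else:
                    dosages.append(int(sum(gt)))
            rows.append((rec.chrom, rec.pos, rec.ref, rec.alts[0], dosages))
    return rows, samples


def write_site_matrix(matrix: SiteMatrix, path: str | Path) -> None:
    """Write the TSV form read back by :func:`read_site_matrix`."""
    df = pd.DataFrame({
        "contig": matrix.contig,
        "pos": matrix.positions,
        "ref": [a for a, _ in matrix.alleles],
        "alt": [b for _, b in matrix.alleles],
    })
    for j, name in enumerate(matrix.samples):
        df[name] = matrix.calls[:, j]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}; duplicate names are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise InputError(f"duplicate FASTA record name {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq.upper()), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, *, command: str,
                   inputs: Mapping[str, object] | None = None,
                   params: Mapping[str, object] | None = None,
                   seed: int | None = None) -> None:
    """Write a JSON run manifest (inputs, parameters, seed) alongside outputs."""
    manifest = {
        "tool": "hornscan",
        "command": command,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": dict(inputs or {}),
        "params": dict(params or {}),
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
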