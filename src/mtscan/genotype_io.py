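"""Reading, validation, and haplotype collapsing of haploid mtDNA genotypes.

Genotypes are haploid calls at a panel of biallelic mitochondrial SNPs mapped
to the revised Cambridge Reference Sequence (rCRS, NC_012920, 16 569 bp).
Calls are stored as a compact int8 matrix with codes ``REF=0``, ``ALT=1``,
``MISSING=-1``.  Heteroplasmy is out of model: diploid-style heterozygous VCF
genotypes are treated as missing.

Two on-disk dialects are supported: a tab-delimited genotype table (header of
rCRS positions, one row per individual with nucleotide characters) and a
haploid single-contig VCF read/written through :mod:`pysam`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("mtscan")

REF: int = 0
ALT: int = 1
MISSING: int = -1

RCRS_LENGTH = 16569
REGION_CLASSES = ("noncoding", "protein", "rRNA", "tRNA", "termination")


class GenotypeError(ValueError):
    """Raised on malformed or inconsistent genotype input."""


@dataclass(frozen=True)
class VariantDef:
    """One biallelic mtDNA site of the genotyping panel."""

    site_index: int
    rcrs_position: int
    ref_allele: str
    alt_allele: str
    region_class: str = "protein"

    def __post_init__(self) -> None:
        if not (1 <= self.rcrs_position <= RCRS_LENGTH):
            raise GenotypeError(
                f"rCRS position {self.rcrs_position} outside 1..{RCRS_LENGTH}"
            )
        if self.ref_allele == self.alt_allele:
            raise GenotypeError(
                f"site {self.rcrs_position}: ref and alt alleles are equal"
            )
        if self.region_class not in REGION_CLASSES:
            raise GenotypeError(
                f"site {self.rcrs_position}: unknown region class "
                f"{self.region_class!r}"
            )

    @property
    def label(self) -> str:
        """Standard ``m.<pos><REF>><ALT>`` variant notation."""
        return f"m.{self.rcrs_position}{self.ref_allele}>{self.alt_allele}"


@dataclass
class GenotypeMatrix:
    """Haploid calls for N individuals at L panel sites."""

    individual_ids: list[str]
    variants: list[VariantDef]
    calls: np.ndarray  # int8, N x L, values in {REF, ALT, MISSING}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, l = self.calls.shape
        if n != len(self.individual_ids):
            raise GenotypeError(
                f"{len(self.individual_ids)} ids but {n} call rows"
            )
        if l != len(self.variants):
            raise GenotypeError(f"{len(self.variants)} variants but {l} call columns")
        if len(set(self.individual_ids)) != n:
            raise GenotypeError("duplicate individual ids")
        positions = [v.rcrs_position for v in self.variants]
        if len(set(positions)) != len(positions):
            raise GenotypeError("duplicate rCRS positions in panel")
        bad = ~np.isin(self.calls, (REF, ALT, MISSING))
        if bad.any():
            raise GenotypeError("call codes outside {REF, ALT, MISSING}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_sites(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class Haplotype:
    """A distinct allele vector and the individuals carrying it."""

    haplotype_id: str
    alleles: tuple[int, ...]  # 0 = REF, 1 = ALT
    members: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class MappingResult:
    variants: list[VariantDef]
    unmapped: list[int] = field(default_factory=list)


@dataclass
class MissingReport:
    dropped_ids: list[str]
    n_imputed: int
    imputed_cells: list[tuple[str, int]]  # (individual_id, rcrs_position)


# ---------------------------------------------------------------------------
# site map
# ---------------------------------------------------------------------------

def read_site_map(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited site map.

    Expected columns: ``array_position``, ``rcrs_position``, ``ref``, ``alt``,
    ``region_class``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    required = {"array_position", "rcrs_position", "ref", "alt", "region_class"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeError(f"site map {path} lacks columns {sorted(missing)}")
    return df


def write_site_map(variants: Sequence[VariantDef], path: str | Path) -> None:
    rows = [
        {
            "array_position": v.site_index,
            "rcrs_position": v.rcrs_position,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
            "region_class": v.region_class,
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def map_positions(
    array_positions: Sequence[int],
    mapping_table: pd.DataFrame,
) -> MappingResult:
    """Translate array positions to rCRS-anchored :class:`VariantDef` entries.

    Output is sorted by rCRS position.  Array positions absent from the
    mapping table are excluded and listed in :attr:`MappingResult.unmapped`.
    """
    table = mapping_table.set_index("array_position")
    rcrs_seen: dict[int, int] = {}
    variants: list[VariantDef] = []
    unmapped: list[int] = []
    for pos in array_positions:
        if pos not in table.index:
            unmapped.append(pos)
            continue
        row = table.loc[pos]
        rcrs = int(row["rcrs_position"])
        if rcrs in rcrs_seen:
            raise GenotypeError(
                f"array positions {rcrs_seen[rcrs]} and {pos} both map to "
                f"rCRS {rcrs}"
            )
        rcrs_seen[rcrs] = pos
        variants.append(
            VariantDef(
                site_index=len(variants),
                rcrs_position=rcrs,
                ref_allele=str(row["ref"]),
                alt_allele=str(row["alt"]),
                region_class=str(row["region_class"]),
            )
        )
    variants.sort(key=lambda v: v.rcrs_position)
    variants = [
        VariantDef(
            site_index=i,
            rcrs_position=v.rcrs_position,
            ref_allele=v.ref_allele,
            alt_allele=v.alt_allele,
            region_class=v.region_class,
        )
        for i, v in enumerate(variants)
    ]
    if unmapped:
        logger.warning("%d array positions had no rCRS mapping", len(unmapped))
    return MappingResult(variants=variants, unmapped=unmapped)


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path, site_map: pd.DataFrame) -> GenotypeMatrix:
    """Read the tab-delimited genotype table dialect.

    The header row is ``individual_id`` followed by rCRS positions; each data
    row carries one nucleotide character per site.  Characters matching
    neither the site's REF nor ALT allele (e.g. ``N``) become MISSING, and
    the total number of such fallbacks is logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "individual_id":
        raise GenotypeError(f"{path}: first column must be 'individual_id'")
    mapped = map_positions(
        sorted(site_map["array_position"].astype(int)), site_map
    )
    variants = mapped.variants
    positions = [int(c) for c in df.columns[1:]]
    expected = [v.rcrs_position for v in variants]
    if positions != expected:
        raise GenotypeError(
            f"{path}: column count/order ({len(positions)}) does not match "
            f"site map ({len(expected)} sites sorted by rCRS position)"
        )
    ids = df["individual_id"].tolist()
    if len(set(ids)) != len(ids):
        raise GenotypeError(f"{path}: duplicate individual ids")
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    n_unknown = 0
    for j, v in enumerate(variants):
        col = raw[:, j].astype(str)
        calls[col == v.ref_allele, j] = REF
        calls[col == v.alt_allele, j] = ALT
        n_unknown += int(((col != v.ref_allele) & (col != v.alt_allele)).sum())
    if n_unknown:
        logger.warning(
            "%s: %d allele codes not matching REF/ALT set to MISSING",
            path,
            n_unknown,
        )
    return GenotypeMatrix(individual_ids=ids, variants=variants, calls=calls)


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the tabular dialect (MISSING rendered as ``N``)."""
    header = ["individual_id"] + [str(v.rcrs_position) for v in matrix.variants]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, ind in enumerate(matrix.individual_ids):
            chars = []
            for j, v in enumerate(matrix.variants):
                c = matrix.calls[i, j]
                chars.append(
                    v.ref_allele if c == REF else v.alt_allele if c == ALT else "N"
                )
            fh.write(ind + "\t" + "\t".join(chars) + "\n")


# ---------------------------------------------------------------------------
# VCF dialect
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a haploid (or homozygous-diploid) single-contig mtDNA VCF.

    GT mapping: ``0``/``0/0`` -> REF, ``1``/``1/1`` -> ALT, ``.`` -> MISSING.
    Heterozygous diploid genotypes become MISSING with a heteroplasmy warning.
    Multiallelic records are rejected; indel records are skipped with a
    warning.
    """
    vf = pysam.VariantFile(str(path))
    ids = list(vf.header.samples)
    if not ids:
        raise GenotypeError(f"{path}: VCF has no samples")
    variants: list[VariantDef] = []
    rows: list[np.ndarray] = []
    n_het = 0
    for rec in vf:
        if "GT" not in rec.format:
            raise GenotypeError(f"{path}: record at {rec.pos} lacks GT field")
        alts = rec.alts or ()
        if len(alts) != 1:
            raise GenotypeError(
                f"{path}: multiallelic record at position {rec.pos} "
                f"(ALT={','.join(alts) or '.'}); only biallelic sites are supported"
            )
        if len(rec.ref) != 1 or len(alts[0]) != 1:
            logger.warning("%s: skipping non-SNP record at %d", path, rec.pos)
            continue
        try:
            region = rec.info.get("RC", "protein")
        except (KeyError, ValueError):  # RC absent from the header
            region = "protein"
        variants.append(
            VariantDef(
                site_index=len(variants),
                rcrs_position=rec.pos,
                ref_allele=rec.ref,
                alt_allele=alts[0],
                region_class=str(region),
            )
        )
        col = np.full(len(ids), MISSING, dtype=np.int8)
        for k, sample in enumerate(ids):
            gt = rec.samples[sample]["GT"]
            alleles = tuple(a for a in gt if a is not None)
            if not alleles:
                continue
            if len(set(alleles)) > 1:
                n_het += 1
                continue
            col[k] = ALT if alleles[0] == 1 else REF
        rows.append(col)
    if n_het:
        logger.warning(
            "%s: %d heterozygous genotypes set to MISSING (heteroplasmy is "
            "not modeled)",
            path,
            n_het,
        )
    order = np.argsort([v.rcrs_position for v in variants], kind="stable")
    variants = [
        VariantDef(
            site_index=i,
            rcrs_position=variants[j].rcrs_position,
            ref_allele=variants[j].ref_allele,
            alt_allele=variants[j].alt_allele,
            region_class=variants[j].region_class,
        )
        for i, j in enumerate(order)
    ]
    calls = (
        np.stack([rows[j] for j in order], axis=1)
        if rows
        else np.empty((len(ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(individual_ids=ids, variants=variants, calls=calls)


def write_vcf(matrix: GenotypeMatrix, path: str | Path, contig: str = "chrM") -> None:
    """Write the matrix as an uncompressed haploid VCF."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={RCRS_LENGTH}>")
    header.add_line(
        '##INFO=<ID=RC,Number=1,Type=String,Description="Region class">'
    )
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    for ind in matrix.individual_ids:
        header.add_sample(ind)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, v in enumerate(matrix.variants):
            rec = out.new_record(
                contig=contig,
                start=v.rcrs_position - 1,
                stop=v.rcrs_position,
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.info["RC"] = v.region_class
            for k, ind in enumerate(matrix.individual_ids):
                c = matrix.calls[k, j]
                rec.samples[ind]["GT"] = (None,) if c == MISSING else (int(c),)
            out.write(rec)


# ---------------------------------------------------------------------------
# missingness policy and collapsing
# ---------------------------------------------------------------------------

def handle_missing(
    matrix: GenotypeMatrix, max_missing_rate: float = 0.05
) -> tuple[GenotypeMatrix, MissingReport]:
    """Drop high-missingness individuals, then impute the major allele.

    Individuals whose fraction of MISSING calls exceeds ``max_missing_rate``
    are removed; remaining MISSING cells take the panel-wide major allele at
    that site (ties go to REF).  A site MISSING in every retained individual
    is uninformative and raises an error.
    """
    if not 0 <= max_missing_rate <= 1:
        raise GenotypeError("max_missing_rate must lie in [0, 1]")
    calls = matrix.calls
    miss = calls == MISSING
    rate = miss.mean(axis=1) if matrix.n_sites else np.zeros(matrix.n_individuals)
    keep = rate <= max_missing_rate
    dropped = [i for i, k in zip(matrix.individual_ids, keep) if not k]
    kept_ids = [i for i, k in zip(matrix.individual_ids, keep) if k]
    sub = calls[keep].copy()
    imputed_cells: list[tuple[str, int]] = []
    for j, v in enumerate(matrix.variants):
        col = sub[:, j]
        hole = col == MISSING
        if not hole.any():
            continue
        if hole.all():
            raise GenotypeError(
                f"site {v.label} is missing in every retained individual"
            )
        n_alt = int((col == ALT).sum())
        n_ref = int((col == REF).sum())
        major = ALT if n_alt > n_ref else REF
        col[hole] = major
        imputed_cells.extend(
            (kept_ids[i], v.rcrs_position) for i in np.flatnonzero(hole)
        )
    report = MissingReport(
        dropped_ids=dropped,
        n_imputed=len(imputed_cells),
        imputed_cells=imputed_cells,
    )
    if dropped or imputed_cells:
        logger.info(
            "missingness policy: dropped %d individuals, imputed %d calls",
            len(dropped),
            len(imputed_cells),
        )
    out = GenotypeMatrix(individual_ids=kept_ids, variants=matrix.variants, calls=sub)
    return out, report


def collapse_haplotypes(matrix: GenotypeMatrix) -> list[Haplotype]:
    """Collapse individuals into distinct haplotypes.

    Haplotypes are ordered (and numbered) lexicographically by allele vector,
    so the output is deterministic for a given matrix.  The matrix must be
    complete; run :func:`handle_missing` first.
    """
    if matrix.n_individuals == 0:
        raise GenotypeError("cannot collapse an empty matrix")
    if (matrix.calls == MISSING).any():
        raise GenotypeError("matrix contains MISSING calls; run handle_missing first")
    groups: dict[tuple[int, ...], list[str]] = {}
    for ind, row in zip(matrix.individual_ids, matrix.calls):
        groups.setdefault(tuple(int(x) for x in row), []).append(ind)
    width = max(3, len(str(len(groups))))
    haplotypes = [
        Haplotype(
            haplotype_id=f"H{k + 1:0{width}d}",
            alleles=vec,
            members=frozenset(members),
        )
        for k, (vec, members) in enumerate(sorted(groups.items()))
    ]
    assert sum(h.count for h in haplotypes) == matrix.n_individuals
    return haplotypes


def expand_haplotypes(
    haplotypes: Iterable[Haplotype], variants: Sequence[VariantDef]
) -> GenotypeMatrix:
    """Inverse of :func:`collapse_haplotypes` (member order sorted)."""
    ids: list[str] = []
    rows: list[tuple[int, ...]] = []
    for h in haplotypes:
        for ind in sorted(h.members):
            ids.append(ind)
            rows.append(h.alleles)
    return GenotypeMatrix(
        individual_ids=ids,
        variants=list(variants),
        calls=np.array(rows, dtype=np.int8),
    )
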