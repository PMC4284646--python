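"""Readers and writers for PLINK-style PED/MAP text files, VCF and
tab-separated phenotype tables.

PED/MAP parsing is done in-package (the text format is trivial and no
PLINK reader exists in the dependency stack); VCF goes through
``pysam.VariantFile``. All tabular outputs carry a ``#``-prefixed comment
header recording the package version and, when available, a config hash.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from . import __version__
from .datamodel import (
    AFFECTED,
    UNAFFECTED,
    UNKNOWN,
    GenotypeMatrix,
    Marker,
    ParseError,
    PedRecord,
    Pedigree,
    PhenotypeTable,
)
from .filters import (
    CLASS_CODES,
    CLASS_NAMES,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    VariantKey,
    VariantPanel,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_SEX_IN = {"1": "male", "2": "female"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
_AFFECTION_IN = {"2": AFFECTED, "1": UNAFFECTED}
_AFFECTION_OUT = {AFFECTED: "2", UNAFFECTED: "1", UNKNOWN: "0"}


def read_map(map_source: PathLike) -> list[Marker]:
    """Parse a PLINK MAP file (chrom, id, cM, bp). Alleles are unknown at
    this stage and filled in by :func:`read_ped_map`."""
    markers: list[Marker] = []
    for lineno, line in enumerate(Path(map_source).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ParseError(f"{map_source}: line {lineno}: expected 4 MAP columns, got {len(fields)}")
        chrom, mid, cm, bp = fields
        try:
            markers.append(Marker(mid, chrom, int(bp), "N", "A", cm=float(cm)))
        except ValueError as exc:
            raise ParseError(f"{map_source}: line {lineno}: {exc}") from exc
    return markers


def read_ped_map(
    ped_source: PathLike,
    map_source: PathLike,
    allele_ref: Optional[Mapping[str, tuple[str, str]]] = None,
) -> tuple[Pedigree, GenotypeMatrix]:
    """Read a PED/MAP pair into a pedigree and a dosage matrix.

    Dosages count copies of the alt allele. With no ``allele_ref`` table
    (marker id -> (ref, alt)) the first allele seen per marker, scanning
    samples in file order, is taken as alt. "0 0" genotypes are missing.
    Affection codes in PED column 6 are retained; use
    :func:`phenotypes_from_ped` to recover them as a table.
    """
    markers = read_map(map_source)
    m = len(markers)
    records: list[PedRecord] = []
    sample_ids: list[str] = []
    affections: dict[str, str] = {}
    allele_rows: list[list[str]] = []

    for lineno, line in enumerate(Path(ped_source).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * m:
            raise ParseError(
                f"{ped_source}: line {lineno}: expected {6 + 2 * m} columns "
                f"(6 + 2x{m} markers), got {len(fields)}"
            )
        fam, iid, sire, dam, sex, pheno = fields[:6]
        if iid in affections:
            raise ParseError(f"{ped_source}: line {lineno}: duplicate sample id {iid!r}")
        records.append(
            PedRecord(
                iid,
                sire if sire != "0" else None,
                dam if dam != "0" else None,
                _SEX_IN.get(sex, "unknown"),
                fam,
            )
        )
        sample_ids.append(iid)
        affections[iid] = _AFFECTION_IN.get(pheno, UNKNOWN)
        allele_rows.append(fields[6:])

    # resolve per-marker alt/ref orientation
    resolved: list[Marker] = []
    dosage = np.full((len(sample_ids), m), np.nan)
    for j, marker in enumerate(markers):
        if allele_ref and marker.id in allele_ref:
            ref, alt = allele_ref[marker.id]
        else:
            alt = ref = None
            for row in allele_rows:
                for a in (row[2 * j], row[2 * j + 1]):
                    if a == "0":
                        continue
                    if alt is None:
                        alt = a
                    elif a != alt:
                        ref = a
                        break
                if ref is not None:
                    break
            alt = alt or "A"
            ref = ref or ("N" if alt != "N" else "M")
        resolved.append(Marker(marker.id, marker.chromosome, marker.position_bp, ref, alt, cm=marker.cm))
        for i, row in enumerate(allele_rows):
            a1, a2 = row[2 * j], row[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            for a in (a1, a2):
                if a not in (ref, alt):
                    raise ParseError(
                        f"{ped_source}: sample {sample_ids[i]!r}, marker {marker.id!r}: "
                        f"allele {a!r} not in {{ref={ref!r}, alt={alt!r}}}"
                    )
            dosage[i, j] = (a1 == alt) + (a2 == alt)

    pedigree = Pedigree(records)
    genotypes = GenotypeMatrix(sample_ids, resolved, dosage)
    genotypes.affection_codes = affections  # type: ignore[attr-defined]
    return pedigree, genotypes


def phenotypes_from_ped(genotypes: GenotypeMatrix) -> PhenotypeTable:
    """Affection table from PED column 6 of a matrix read by read_ped_map."""
    affections = getattr(genotypes, "affection_codes", {})
    return PhenotypeTable.from_records(genotypes.samples, affection=affections)


def write_ped_map(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    ped_path: PathLike,
    map_path: PathLike,
    phenotypes: Optional[PhenotypeTable] = None,
) -> None:
    """Write a PED/MAP pair. Hets are written alt-first so the reader's
    first-seen-is-alt rule round-trips; pass an allele-reference table on
    read for data where the first genotype may be homozygous reference."""
    with open(map_path, "w") as fh:
        for mk in genotypes.markers:
            fh.write(f"{mk.chromosome}\t{mk.id}\t{mk.cm:g}\t{mk.position_bp}\n")
    ped_index = {r.individual_id: r for r in pedigree.records}
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(genotypes.samples):
            rec = ped_index.get(sample, PedRecord(sample, None, None))
            aff = phenotypes.affection(sample) if phenotypes is not None else UNKNOWN
            lead = [
                rec.family_id,
                sample,
                rec.sire_id or "0",
                rec.dam_id or "0",
                _SEX_OUT[rec.sex],
                _AFFECTION_OUT[aff],
            ]
            alleles: list[str] = []
            for j, mk in enumerate(genotypes.markers):
                d = genotypes.dosage[i, j]
                if np.isnan(d):
                    alleles += ["0", "0"]
                elif d == 0:
                    alleles += [mk.ref_allele, mk.ref_allele]
                elif d == 1:
                    alleles += [mk.alt_allele, mk.ref_allele]
                else:
                    alleles += [mk.alt_allele, mk.alt_allele]
            fh.write("\t".join(lead + alleles) + "\n")


def allele_reference(genotypes: GenotypeMatrix) -> dict[str, tuple[str, str]]:
    """Marker id -> (ref, alt) table for orientation-stable re-reading."""
    return {m.id: (m.ref_allele, m.alt_allele) for m in genotypes.markers}


# ---------------------------------------------------------------- VCF


def read_vcf(
    vcf_source: PathLike,
    sample_groups: Optional[Mapping[str, Sequence[str]]] = None,
) -> VariantPanel:
    """Read a VCF into a :class:`VariantPanel` of genotype classes.

    Each ALT of a multi-allelic record becomes its own variant entry; a
    sample's class for that entry counts copies of that ALT (so ``0/2``
    is hom-ref with respect to the first ALT). ``./.`` or half-missing
    genotypes are missing; phase separators are accepted, phase ignored.
    """
    try:
        vf = pysam.VariantFile(str(vcf_source))
    except (ValueError, OSError) as exc:
        raise ParseError(f"{vcf_source}: cannot parse VCF: {exc}") from exc
    samples = list(vf.header.samples)
    variants: list[VariantKey] = []
    columns: list[np.ndarray] = []
    with vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            if "GT" not in rec.format:
                raise ParseError(
                    f"{vcf_source}: {rec.chrom}:{rec.pos}: record lacks GT format key"
                )
            alts = rec.alts or ()
            for k, alt in enumerate(alts, start=1):
                key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                col = np.full(len(samples), MISSING, dtype=np.int8)
                for i, sample in enumerate(samples):
                    gt = rec.samples[sample].get("GT")
                    if gt is None or any(a is None for a in gt) or len(gt) == 0:
                        continue
                    copies = sum(1 for a in gt if a == k)
                    col[i] = HOM_ALT if copies >= 2 else (HET if copies == 1 else HOM_REF)
                variants.append(key)
                columns.append(col)
    classes = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0), dtype=np.int8)
    )
    return VariantPanel(samples, variants, classes, sample_groups)


def write_vcf(panel: VariantPanel, path: PathLike) -> None:
    """Write a panel as an uncompressed VCF v4.2 with GT fields only."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(v.chromosome for v in panel.variants):
        header.contigs.add(chrom)
    for sample in panel.samples:
        header.add_sample(sample)
    gt_by_class = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        order = sorted(range(panel.n_variants),
                       key=lambda j: (panel.variants[j].chromosome, panel.variants[j].position_bp))
        for j in order:
            key = panel.variants[j]
            rec = out.new_record(
                contig=key.chromosome,
                start=key.position_bp - 1,
                alleles=(key.ref, key.alt),
            )
            for i, sample in enumerate(panel.samples):
                rec.samples[sample]["GT"] = gt_by_class[int(panel.classes[i, j])]
            out.write(rec)


# ---------------------------------------------------------------- TSV


def read_phenotypes(path: PathLike) -> PhenotypeTable:
    """Read a tab-separated phenotype/covariate table.

    The first column is the sample id; an ``affection`` column may use the
    words affected/unaffected/unknown or PLINK codes 2/1/0. Numeric
    columns are quantitative scores/covariates, others categorical.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    frame = frame.set_index(frame.columns[0])
    if "affection" in frame.columns:
        frame["affection"] = (
            frame["affection"]
            .astype(str)
            .map(lambda v: _AFFECTION_IN.get(v, v if v in (AFFECTED, UNAFFECTED) else UNKNOWN))
        )
    return PhenotypeTable(frame)


def write_phenotypes(table: PhenotypeTable, path: PathLike, **meta: str) -> None:
    write_table(table.frame.reset_index(), path, **meta)


def write_table(frame: pd.DataFrame, path: PathLike, **meta: str) -> None:
    """Write a TSV with a comment header recording provenance."""
    with open(path, "w") as fh:
        fh.write(f"# domscan {__version__}\n")
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
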