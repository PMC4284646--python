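"""Minimal variant consequence annotation against single-transcript gene
models.

Classifies a variant as exonic CDS (missense / nonsense / synonymous /
frameshift / inframe_indel), exonic UTR, intronic or intergenic. One
transcript per gene, no splice-site classes — sufficient to separate
protein-changing candidates from the rest when filtering under a
dominant model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .datamodel import DomscanError
from .filters import VariantKey

CDS_CLASSES = frozenset({"missense", "nonsense", "synonymous", "frameshift", "inframe_indel"})


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene structure on 1-based closed intervals."""

    gene_id: str
    chromosome: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    frame_offset: int = 0  # bases of the first CDS segment before codon 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
        for start, end in self.cds:
            if not any(s <= start and end <= e for s, e in exons):
                raise ValueError(f"{self.gene_id}: CDS segment outside exons")
        object.__setattr__(self, "exons", tuple(exons))
        object.__setattr__(self, "cds", tuple(sorted(self.cds)))

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def cds_offset(self, pos: int) -> int:
        """0-based position within the spliced CDS in genomic (+) order."""
        offset = 0
        for start, end in self.cds:
            if pos > end:
                offset += end - start + 1
            elif pos >= start:
                return offset + pos - start
            else:
                break
        raise ValueError(f"position {pos} not in CDS of {self.gene_id}")

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def spliced_cds(self, reference: str) -> str:
        """CDS sequence in genomic (+) orientation from a chromosome string."""
        return "".join(reference[s - 1 : e] for s, e in self.cds)


@dataclass(frozen=True)
class Consequence:
    """Annotation outcome; ``subtype`` is set for exonic_cds variants."""

    category: str  # exonic_cds | exonic_utr | intronic | intergenic
    subtype: Optional[str] = None
    gene_id: Optional[str] = None
    codon_change: Optional[str] = None
    aa_change: Optional[str] = None

    @property
    def label(self) -> str:
        return self.subtype or self.category


def annotate_consequence(
    variant: VariantKey,
    models: Sequence[GeneModel],
    reference: Optional[Mapping[str, str]] = None,
) -> Consequence:
    """Classify a variant against gene models.

    ``reference`` optionally maps chromosome name to its (toy) sequence;
    with a reference, SNVs in CDS are translated to distinguish
    missense / nonsense / synonymous, and a ref-allele mismatch raises.
    Without one, a CDS SNV is reported as subtype ``coding_snv``.
    Indels whose length change is not a multiple of three are
    frameshifts regardless of reference availability.
    """
    variant = VariantKey(*variant)
    chrom_models = [m for m in models if m.chromosome == variant.chromosome]
    ref_seq = (reference or {}).get(variant.chromosome)
    if ref_seq is not None:
        window = ref_seq[variant.position_bp - 1 : variant.position_bp - 1 + len(variant.ref)]
        if window.upper() != variant.ref.upper():
            raise DomscanError(
                f"reference mismatch at {variant}: reference has {window!r}"
            )

    hit_exon = hit_intron = None
    for model in chrom_models:
        positions = _affected_positions(variant)
        if any(model.in_cds(p) for p in positions):
            return _classify_cds(variant, model, ref_seq)
        if any(model.in_exon(p) for p in positions):
            hit_exon = model
        elif any(model.span[0] <= p <= model.span[1] for p in positions):
            hit_intron = model
    if hit_exon is not None:
        return Consequence("exonic_utr", gene_id=hit_exon.gene_id)
    if hit_intron is not None:
        return Consequence("intronic", gene_id=hit_intron.gene_id)
    return Consequence("intergenic")


def _affected_positions(variant: VariantKey) -> list[int]:
    """Genomic positions touched by the ref allele (SNV: one base)."""
    return list(range(variant.position_bp, variant.position_bp + len(variant.ref)))


def _classify_cds(
    variant: VariantKey, model: GeneModel, ref_seq: Optional[str]
) -> Consequence:
    length_change = len(variant.alt) - len(variant.ref)
    if length_change != 0:
        subtype = "frameshift" if length_change % 3 != 0 else "inframe_indel"
        return Consequence("exonic_cds", subtype, model.gene_id)
    if len(variant.ref) != 1:
        # multi-base substitution: classify by translating when possible
        if ref_seq is None:
            return Consequence("exonic_cds", "coding_mnv", model.gene_id)
    if ref_seq is None:
        return Consequence("exonic_cds", "coding_snv", model.gene_id)

    cds_seq = model.spliced_cds(ref_seq)
    mutated = list(cds_seq)
    for i, (ref_base, alt_base) in enumerate(zip(variant.ref, variant.alt)):
        pos = variant.position_bp + i
        if not model.in_cds(pos):
            continue
        off = model.cds_offset(pos)
        mutated[off] = alt_base
    mutated_seq = "".join(mutated)

    if model.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        mutated_seq = str(Seq(mutated_seq).reverse_complement())
    cds_seq = cds_seq[model.frame_offset :]
    mutated_seq = mutated_seq[model.frame_offset :]
    usable = len(cds_seq) - len(cds_seq) % 3
    aa_ref = str(Seq(cds_seq[:usable]).translate())
    aa_alt = str(Seq(mutated_seq[:usable]).translate())

    diffs = [(i, r, a) for i, (r, a) in enumerate(zip(aa_ref, aa_alt)) if r != a]
    if not diffs:
        return Consequence("exonic_cds", "synonymous", model.gene_id)
    idx, old, new = diffs[0]
    aa_change = f"p.{old}{idx + 1}{new if new != '*' else '*'}"
    subtype = "nonsense" if new == "*" else "missense"
    return Consequence("exonic_cds", subtype, model.gene_id, aa_change=aa_change)
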