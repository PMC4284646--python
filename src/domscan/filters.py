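"""Candidate-mutation discovery filters under a dominant, heterozygous model.

Two rule-based filters operate on a multi-sample variant panel:

* :func:`dominant_candidate_filter` — keeps variants heterozygous in every
  obligate carrier, homozygous-reference in every obligate non-carrier, and
  previously unobserved in caller-supplied variant databases.
* :func:`breed_contrast_filter` — keeps variants carried by every member of
  one group (fixed-in) and absent from every member of another
  (absent-out), optionally restricted to a genomic region.

Both return an audit trail assigning each removed variant exactly one
first-failing rule. Missing-genotype semantics are asymmetric by default:
presence must be proven (a missing call in a required-carrier disqualifies)
while absence is presumed but flagged ``unconfirmed_absence``; ``strict``
mode makes missing calls disqualifying on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import DomscanError

# genotype class codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

CLASS_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}


class VariantKey(NamedTuple):
    """Exact-match variant identity; indels are assumed pre-normalized."""

    chromosome: str
    position_bp: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.position_bp}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class Region:
    """Closed 1-based interval; ``start``/``end`` of None mean unbounded."""

    chromosome: str
    start: Optional[int] = None
    end: Optional[int] = None

    def contains(self, key: VariantKey) -> bool:
        if key.chromosome != self.chromosome:
            return False
        if self.start is not None and key.position_bp < self.start:
            return False
        if self.end is not None and key.position_bp > self.end:
            return False
        return True


class VariantPanel:
    """Multi-sample genotype classes over a list of sequence variants.

    ``classes`` is an int8 array of shape (n_samples, n_variants) with
    codes ``HOM_REF``/``HET``/``HOM_ALT``/``MISSING``. ``sample_groups``
    names sample sets such as breed labels or a population database.
    """

    def __init__(
        self,
        samples: Sequence[str],
        variants: Sequence[VariantKey],
        classes: np.ndarray,
        sample_groups: Optional[Mapping[str, Iterable[str]]] = None,
    ):
        samples = list(samples)
        variants = [VariantKey(*v) for v in variants]
        classes = np.asarray(classes, dtype=np.int8)
        if classes.shape != (len(samples), len(variants)):
            raise ValueError(
                f"classes shape {classes.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        if len(set(variants)) != len(variants):
            raise ValueError("duplicate variant keys")
        if not np.isin(classes, (HOM_REF, HET, HOM_ALT, MISSING)).all():
            raise ValueError("invalid genotype class codes")
        self.samples = samples
        self.variants = variants
        self.classes = classes
        self._sample_index = {s: i for i, s in enumerate(samples)}
        self._variant_index = {v: j for j, v in enumerate(variants)}
        self.sample_groups: dict[str, list[str]] = {}
        for name, members in (sample_groups or {}).items():
            members = list(members)
            unknown = [m for m in members if m not in self._sample_index]
            if unknown:
                raise ValueError(f"group {name!r} references unknown samples: {unknown}")
            self.sample_groups[name] = members

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_rows(self, sample_ids: Iterable[str]) -> np.ndarray:
        return np.array([self._sample_index[s] for s in sample_ids], dtype=int)

    def genotype_class(self, sample_id: str, key: VariantKey) -> int:
        return int(self.classes[self._sample_index[sample_id], self._variant_index[key]])

    def classes_at(self, key: VariantKey) -> dict[str, int]:
        col = self.classes[:, self._variant_index[VariantKey(*key)]]
        return dict(zip(self.samples, (int(c) for c in col)))

    def group(self, name: str) -> list[str]:
        return list(self.sample_groups[name])


@dataclass
class FilterCriteria:
    """Dominant-model candidate criteria.

    ``exclude_seen_in`` maps database names to sets of variant keys; any
    key present in any database is removed ("previously observed").
    """

    required_het: frozenset[str] = frozenset()
    required_absent: frozenset[str] = frozenset()
    exclude_seen_in: dict[str, frozenset[VariantKey]] = field(default_factory=dict)
    region: Optional[Region] = None
    consequence_classes: Optional[frozenset[str]] = None
    strict_absence: bool = False

    def __post_init__(self) -> None:
        self.required_het = frozenset(self.required_het)
        self.required_absent = frozenset(self.required_absent)
        if self.required_het & self.required_absent:
            raise ValueError("required_het and required_absent overlap")
        self.exclude_seen_in = {
            name: frozenset(VariantKey(*k) for k in keys)
            for name, keys in self.exclude_seen_in.items()
        }


@dataclass
class FilterAudit:
    """Per-variant outcome: kept or the single first rule that removed it."""

    variant: VariantKey
    kept: bool
    failed_rule: Optional[str] = None
    flags: tuple[str, ...] = ()

    def as_row(self) -> dict:
        return {
            "variant": str(self.variant),
            "kept": self.kept,
            "failed_rule": self.failed_rule or "",
            "flags": ";".join(self.flags),
        }


def audit_frame(audits: Sequence[FilterAudit]) -> pd.DataFrame:
    return pd.DataFrame([a.as_row() for a in audits],
                        columns=["variant", "kept", "failed_rule", "flags"])


def dominant_candidate_filter(
    panel: VariantPanel,
    crit: FilterCriteria,
    consequences: Optional[Mapping[VariantKey, str]] = None,
) -> tuple[list[VariantKey], list[FilterAudit]]:
    """Filter a panel to previously unobserved dominant-model candidates.

    A variant survives iff it is (i) het in every ``required_het`` sample,
    (ii) hom-ref in every ``required_absent`` sample, (iii) absent from
    every ``exclude_seen_in`` database, (iv) inside ``region`` when set,
    and (v) of an allowed consequence class when ``consequence_classes``
    is set (``consequences`` maps keys to class labels, e.g. from
    :func:`domscan.consequence.annotate_consequence`).

    Rules are checked in the order region, seen-in, carrier het, absence,
    consequence; the audit trail records the first failing rule only.
    """
    if not crit.required_het:
        raise ValueError("required_het must be non-empty")
    kept: list[VariantKey] = []
    audits: list[FilterAudit] = []
    het_rows = panel.sample_rows(crit.required_het)
    absent_rows = panel.sample_rows(crit.required_absent)

    for j, key in enumerate(panel.variants):
        col = panel.classes[:, j]
        flags: list[str] = []
        failed: Optional[str] = None

        if crit.region is not None and not crit.region.contains(key):
            failed = "outside_region"
        if failed is None:
            for name, seen in crit.exclude_seen_in.items():
                if key in seen:
                    failed = f"seen_in:{name}"
                    break
        if failed is None and not (col[het_rows] == HET).all():
            # a missing call fails the carrier rule: presence must be proven
            failed = "not_het_in_required_carrier"
        if failed is None and len(absent_rows):
            vals = col[absent_rows]
            if crit.strict_absence:
                if not (vals == HOM_REF).all():
                    failed = "not_absent_in_required_noncarrier"
            else:
                if ((vals == HET) | (vals == HOM_ALT)).any():
                    failed = "not_absent_in_required_noncarrier"
                elif (vals == MISSING).any():
                    flags.append("unconfirmed_absence")
        if failed is None and crit.consequence_classes is not None:
            cls = (consequences or {}).get(key, "unannotated")
            if cls not in crit.consequence_classes:
                failed = f"consequence:{cls}"

        if failed is None:
            kept.append(key)
            audits.append(FilterAudit(key, True, None, tuple(flags)))
        else:
            audits.append(FilterAudit(key, False, failed, tuple(flags)))
    return kept, audits


def breed_contrast_filter(
    panel: VariantPanel,
    in_group: Iterable[str],
    out_group: Iterable[str],
    region: Optional[Region] = None,
    strict_absence: bool = False,
) -> tuple[list[VariantKey], list[FilterAudit]]:
    """Keep variants carried by all of ``in_group`` and absent from all of
    ``out_group`` (fixed-in / absent-out breed contrast).

    Carriage means het or hom-alt. A missing call inside ``in_group``
    disqualifies (presence unconfirmed); a missing call in ``out_group``
    flags ``unconfirmed_absence`` without disqualifying unless
    ``strict_absence``.
    """
    in_ids = list(in_group)
    out_ids = list(out_group)
    if not in_ids or not out_ids:
        raise ValueError("in_group and out_group must be non-empty")
    if set(in_ids) & set(out_ids):
        raise ValueError("in_group and out_group overlap")
    in_rows = panel.sample_rows(in_ids)
    out_rows = panel.sample_rows(out_ids)

    kept: list[VariantKey] = []
    audits: list[FilterAudit] = []
    for j, key in enumerate(panel.variants):
        col = panel.classes[:, j]
        flags: list[str] = []
        failed: Optional[str] = None
        if region is not None and not region.contains(key):
            failed = "outside_region"
        if failed is None:
            iv = col[in_rows]
            if not ((iv == HET) | (iv == HOM_ALT)).all():
                failed = "not_carried_by_all_in_group"
        if failed is None:
            ov = col[out_rows]
            if ((ov == HET) | (ov == HOM_ALT)).any():
                failed = "carried_in_out_group"
            elif (ov == MISSING).any():
                if strict_absence:
                    failed = "missing_in_out_group"
                else:
                    flags.append("unconfirmed_absence")
        if failed is None:
            kept.append(key)
            audits.append(FilterAudit(key, True, None, tuple(flags)))
        else:
            audits.append(FilterAudit(key, False, failed, tuple(flags)))
    return kept, audits


@dataclass
class ConcordanceResult:
    """Agreement between dominant-model predicted and observed phenotype."""

    n_concordant: int
    n_discordant: int
    discordant_ids: tuple[str, ...]
    n_missing_genotype: int = 0

    @property
    def n_tested(self) -> int:
        return self.n_concordant + self.n_discordant


def concordance_check(
    genotype_classes: Mapping[str, int],
    phenotype: Mapping[str, bool],
    dominance: bool = True,
) -> ConcordanceResult:
    """Count samples whose phenotype matches the genotype prediction.

    Under dominance the predicted-affected set is {het, hom_alt}; under a
    recessive coding it is {hom_alt}. ``phenotype`` maps sample id to
    True (affected) / False (unaffected); samples with missing genotype
    are excluded from the tally and counted separately.
    """
    carrier_classes = {HET, HOM_ALT} if dominance else {HOM_ALT}
    n_conc = 0
    discordant: list[str] = []
    n_miss = 0
    for sample, affected in phenotype.items():
        cls = genotype_classes.get(sample, MISSING)
        if cls == MISSING:
            n_miss += 1
            continue
        predicted = cls in carrier_classes
        if predicted == bool(affected):
            n_conc += 1
        else:
            discordant.append(sample)
    return ConcordanceResult(n_conc, len(discordant), tuple(sorted(discordant)), n_miss)
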