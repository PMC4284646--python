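"""Core domain types shared across the mapping pipeline.

Genotypes are held as alt-allele dosages (0/1/2, NaN = missing) in a dense
sample x marker matrix; pedigrees as flat record lists with referential
checks; phenotypes as a table carrying affection status, quantitative
scores and covariates. Coordinates are 1-based inclusive throughout,
following VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"


class DomscanError(Exception):
    """Base class for package errors."""


class ParseError(DomscanError):
    """Malformed input file."""


class PedigreeError(DomscanError):
    """Inconsistent pedigree structure."""


@dataclass(frozen=True)
class Marker:
    """A biallelic marker with 1-based physical position.

    ``cm`` is the genetic-map position in centimorgans; it is optional for
    formats that do not carry one (VCF) and required for gene-dropping
    simulation.
    """

    id: str
    chromosome: str
    position_bp: int
    ref_allele: str
    alt_allele: str
    cm: float = 0.0

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"marker {self.id}: position_bp must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"marker {self.id}: ref and alt alleles identical")


class GenotypeMatrix:
    """Dense sample x marker alt-allele dosage matrix.

    Parameters
    ----------
    samples : ordered sample ids (unique).
    markers : ordered :class:`Marker` objects (ids unique).
    dosage : float array of shape (n_samples, n_markers) with entries in
        {0, 1, 2} or NaN for missing.
    """

    def __init__(self, samples: Sequence[str], markers: Sequence[Marker], dosage: np.ndarray):
        samples = list(samples)
        markers = list(markers)
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(samples), len(markers)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(samples)} samples x {len(markers)} markers"
            )
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        ids = [m.id for m in markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids")
        finite = dosage[~np.isnan(dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        self.samples = samples
        self.markers = markers
        self.dosage = dosage
        self._sample_index = {s: i for i, s in enumerate(samples)}
        self._marker_index = {m.id: j for j, m in enumerate(markers)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def marker_index(self, marker_id: str) -> int:
        return self._marker_index[marker_id]

    def column(self, marker_id: str) -> np.ndarray:
        """Dosage vector over samples for one marker."""
        return self.dosage[:, self._marker_index[marker_id]]

    def dosages_for(self, marker_id: str) -> dict[str, float]:
        """Mapping sample id -> dosage (NaN for missing) at one marker."""
        col = self.column(marker_id)
        return dict(zip(self.samples, col))

    def alt_frequency(self) -> np.ndarray:
        """Per-marker alt-allele frequency over non-missing chromosomes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency (NaN when fully missing)."""
        p = self.alt_frequency()
        return np.minimum(p, 1.0 - p)

    def sample_call_rate(self) -> np.ndarray:
        """Per-sample fraction of non-missing genotypes."""
        if self.n_markers == 0:
            return np.ones(self.n_samples)
        return 1.0 - np.isnan(self.dosage).mean(axis=1)

    def subset(self, samples: Optional[Sequence[str]] = None,
               markers: Optional[Sequence[str]] = None) -> "GenotypeMatrix":
        """New matrix restricted to the given sample/marker ids (order kept)."""
        rows = range(self.n_samples) if samples is None else [self._sample_index[s] for s in samples]
        cols = range(self.n_markers) if markers is None else [self._marker_index[m] for m in markers]
        rows = list(rows)
        cols = list(cols)
        return GenotypeMatrix(
            [self.samples[i] for i in rows],
            [self.markers[j] for j in cols],
            self.dosage[np.ix_(rows, cols)],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.markers == other.markers
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )


@dataclass(frozen=True)
class PedRecord:
    individual_id: str
    sire_id: Optional[str]
    dam_id: Optional[str]
    sex: str = "unknown"  # "male" / "female" / "unknown"
    family_id: str = "0"


class Pedigree:
    """Flat pedigree: records plus derived parent/offspring lookups.

    Parents referenced but not present as records are treated as external
    founders and listed in :attr:`external_founders`. Construction fails if
    the parent graph contains a cycle (an individual being its own
    ancestor).
    """

    def __init__(self, records: Iterable[PedRecord]):
        records = list(records)
        ids = [r.individual_id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate individual ids: {dup}")
        self.records = records
        self._by_id = {r.individual_id: r for r in records}
        present = set(ids)
        refs = {p for r in records for p in (r.sire_id, r.dam_id) if p}
        self.external_founders = sorted(refs - present)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(node: str, stack: list[str]) -> None:
            if node not in self._by_id or state.get(node) == 1:
                return
            if state.get(node) == 0:
                raise PedigreeError(f"pedigree cycle involving {node}: {stack}")
            state[node] = 0
            rec = self._by_id[node]
            for parent in (rec.sire_id, rec.dam_id):
                if parent:
                    visit(parent, stack + [node])
            state[node] = 1

        for r in self.records:
            visit(r.individual_id, [])

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def record(self, individual_id: str) -> PedRecord:
        return self._by_id[individual_id]

    def parents_of(self, individual_id: str) -> tuple[Optional[str], Optional[str]]:
        r = self._by_id[individual_id]
        return r.sire_id, r.dam_id

    def offspring_of(self, parent_id: str) -> list[str]:
        return [r.individual_id for r in self.records
                if parent_id in (r.sire_id, r.dam_id)]


class PhenotypeTable:
    """Per-sample affection status, quantitative scores and covariates.

    Backed by a DataFrame indexed by sample id. The ``affection`` column
    holds {affected, unaffected, unknown}; any other numeric column is a
    quantitative score or real covariate; object columns are categorical
    covariates.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.has_duplicates:
            raise ValueError("duplicate sample ids in phenotype table")
        if "affection" not in frame.columns:
            frame["affection"] = UNKNOWN
        bad = set(frame["affection"].dropna().unique()) - {AFFECTED, UNAFFECTED, UNKNOWN}
        if bad:
            raise ValueError(f"invalid affection values: {sorted(bad)}")
        frame["affection"] = frame["affection"].fillna(UNKNOWN)
        if "coat_score" in frame.columns:
            scores = frame["coat_score"].dropna()
            if len(scores) and ((scores < 1) | (scores > 4)).any():
                raise ValueError("coat_score values must lie in [1, 4]")
        self.frame = frame

    @classmethod
    def from_records(
        cls,
        samples: Sequence[str],
        affection: Optional[Mapping[str, str]] = None,
        scores: Optional[Mapping[str, Mapping[str, float]]] = None,
        covariates: Optional[Mapping[str, Mapping[str, object]]] = None,
    ) -> "PhenotypeTable":
        frame = pd.DataFrame(index=pd.Index(list(samples), name="sample"))
        frame["affection"] = [
            (affection or {}).get(s, UNKNOWN) for s in samples
        ]
        for name, mapping in (scores or {}).items():
            frame[name] = [mapping.get(s, np.nan) for s in samples]
        for name, mapping in (covariates or {}).items():
            frame[name] = [mapping.get(s) for s in samples]
        return cls(frame)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    def affection(self, sample_id: str) -> str:
        if sample_id not in self.frame.index:
            return UNKNOWN
        return self.frame.loc[sample_id, "affection"]

    def affection_map(self) -> dict[str, str]:
        return dict(self.frame["affection"])

    def score(self, name: str) -> dict[str, float]:
        """Mapping sample -> score, omitting missing values."""
        col = self.frame[name].dropna()
        return dict(col)

    def validate_against(self, known_samples: Iterable[str]) -> None:
        known = set(known_samples)
        unknown = [s for s in self.frame.index if s not in known]
        if unknown:
            raise ValueError(f"phenotyped samples not in pedigree/genotypes: {unknown[:5]}")


@dataclass
class QcThresholds:
    """Marker/sample QC cutoffs applied before association testing.

    Defaults: markers excluded below 1% minor allele frequency, samples
    below 90% genotype call rate.
    """

    maf_min: float = 0.01
    call_rate_min: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not 0.0 <= self.call_rate_min <= 1.0:
            raise ValueError("call_rate_min must lie in [0, 1]")
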