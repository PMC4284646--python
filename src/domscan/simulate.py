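"""Seeded generators emulating the study's data structures.

Three generators produce truth-known synthetic data shaped like the
mapping designs the pipeline targets:

* :func:`simulate_cohort` — a two-founder-sire pedigree (nuclear trios
  plus large paternal half-sib families) segregating a fully penetrant
  heterozygous dominant variant, gene-dropped with Haldane
  recombination;
* :func:`simulate_crossbred_slick` — a crossbred cohort scored on an
  ordinal 1-4 coat scale, with the causal mutation riding a contiguous
  founder haplotype and a configurable number of phenotype-discordant
  animals;
* :func:`simulate_variant_panels` — multi-breed variant panels with one
  planted variant private to a target breed, plus a population database
  of previously observed variation.

All generators are deterministic given their config (same seed →
byte-identical emitted files).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    AFFECTED,
    UNAFFECTED,
    DomscanError,
    GenotypeMatrix,
    Marker,
    PedRecord,
    Pedigree,
    PhenotypeTable,
)
from .filters import HET, HOM_ALT, HOM_REF, MISSING, VariantKey, VariantPanel


def haldane(distance_cm: float) -> float:
    """Map distance in cM to recombination fraction, no interference."""
    return (1.0 - math.exp(-2.0 * distance_cm / 100.0)) / 2.0


@dataclass
class TruthRecord:
    """Ground truth emitted alongside simulated data for recovery tests."""

    causal_key: str
    carriers: frozenset[str]
    block_marker_ids: tuple[str, ...] = ()
    phase: Optional[dict[str, tuple[tuple[int, ...], tuple[int, ...]]]] = None
    causal_classes: Optional[dict[str, int]] = None

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"record": "causal", "key": self.causal_key}) + "\n")
            fh.write(
                json.dumps({"record": "carriers", "ids": sorted(self.carriers)}) + "\n"
            )
            if self.block_marker_ids:
                fh.write(
                    json.dumps({"record": "block", "markers": list(self.block_marker_ids)})
                    + "\n"
                )


# ------------------------------------------------------------------ cohort


@dataclass
class SimConfig:
    """Gene-dropping pedigree simulation.

    Defaults mirror the mapping design: 22 nuclear trios and 55
    paternal half-sib offspring split across the two carrier founder
    sires, a fully penetrant dominant causal allele private to the
    sires, and no phenotype misassignment.
    """

    seed: int = 0
    n_trios: int = 22
    n_halfsibs_per_sire: tuple[int, ...] = (28, 27)
    n_chromosomes: int = 5
    markers_per_chromosome: int = 40
    cm_spacing: float = 2.5
    bp_spacing: int = 500_000
    freq_low: float = 0.05
    freq_high: float = 0.5
    causal_index: int = 20  # marker index carrying the planted dominant allele
    shared_block_cm: float = 20.0  # sire-shared haplotype half-width around causal
    penetrance: float = 1.0
    misassignment_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")
        if not 0.0 <= self.misassignment_rate <= 1.0:
            raise ValueError("misassignment_rate must lie in [0, 1]")
        if not 0.0 < self.freq_low <= self.freq_high <= 0.5:
            raise ValueError("allele frequencies must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.causal_index < self.n_markers:
            raise DomscanError(
                f"causal_index {self.causal_index} out of range 0..{self.n_markers - 1}"
            )

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome


def _make_markers(cfg: SimConfig) -> list[Marker]:
    markers = []
    for c in range(cfg.n_chromosomes):
        for k in range(cfg.markers_per_chromosome):
            markers.append(
                Marker(
                    id=f"snp{c + 1}_{k + 1}",
                    chromosome=str(c + 1),
                    position_bp=(k + 1) * cfg.bp_spacing,
                    ref_allele="A",
                    alt_allele="G",
                    cm=k * cfg.cm_spacing,
                )
            )
    return markers


def _meiosis(
    haplotypes: tuple[np.ndarray, np.ndarray],
    markers: Sequence[Marker],
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete: copy parental haplotypes with Haldane crossovers."""
    m = len(markers)
    gamete = np.empty(m, dtype=np.int8)
    current = int(rng.integers(2))
    for j in range(m):
        if j > 0:
            prev = markers[j - 1]
            cur = markers[j]
            if cur.chromosome != prev.chromosome:
                current = int(rng.integers(2))
            else:
                r = haldane(cur.cm - prev.cm)
                if rng.random() < r:
                    current = 1 - current
        gamete[j] = haplotypes[current][j]
    return gamete


def simulate_cohort(
    cfg: SimConfig = SimConfig(),
) -> tuple[Pedigree, GenotypeMatrix, PhenotypeTable, TruthRecord]:
    """Gene-drop a dominant variant through the two-sire mapping pedigree.

    Both founder sires are heterozygous carriers on a shared haplotype
    (father-and-son carrier sires); each trio's father is one of the two
    sires and its dam is genotyped, while half-sib dams are simulated but
    not emitted. Affection is carrier-with-probability-penetrance, never
    phenocopy, then flipped at the misassignment rate.
    """
    rng = np.random.default_rng(cfg.seed)
    markers = _make_markers(cfg)
    m = len(markers)
    freqs = rng.uniform(cfg.freq_low, cfg.freq_high, size=m)
    freqs[cfg.causal_index] = 0.0  # causal allele is private to the sires
    causal_chrom = markers[cfg.causal_index].chromosome
    causal_cm = markers[cfg.causal_index].cm

    def founder_haplotypes() -> tuple[np.ndarray, np.ndarray]:
        return (
            (rng.random(m) < freqs).astype(np.int8),
            (rng.random(m) < freqs).astype(np.int8),
        )

    phase: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    sire_ids = ["sire1", "sire2"]
    for sid in sire_ids:
        phase[sid] = founder_haplotypes()
    # carrier haplotype: sire1's first haplotype, marked at the causal site;
    # sire2 (his carrier son) shares it across the surrounding block
    phase["sire1"][0][cfg.causal_index] = 1
    shared = [
        j
        for j, mk in enumerate(markers)
        if mk.chromosome == causal_chrom and abs(mk.cm - causal_cm) <= cfg.shared_block_cm
    ]
    phase["sire2"][0][shared] = phase["sire1"][0][shared]

    records = [
        PedRecord("sire1", None, None, "male", "F1"),
        PedRecord("sire2", None, None, "male", "F1"),
    ]
    genotyped: list[str] = list(sire_ids)

    trio_dams = []
    for i in range(cfg.n_trios):
        dam = f"dam{i + 1}"
        trio_dams.append(dam)
        phase[dam] = founder_haplotypes()
        records.append(PedRecord(dam, None, None, "female", "F1"))
        genotyped.append(dam)

    offspring: list[str] = []
    for i in range(cfg.n_trios):
        child = f"trio_off{i + 1}"
        father = sire_ids[i % 2]
        mother = trio_dams[i]
        phase[child] = (
            _meiosis(phase[father], markers, rng),
            _meiosis(phase[mother], markers, rng),
        )
        records.append(PedRecord(child, father, mother, "unknown", "F1"))
        offspring.append(child)
        genotyped.append(child)

    hs_counter = 0
    for s, n_hs in enumerate(cfg.n_halfsibs_per_sire):
        father = sire_ids[s]
        for _ in range(n_hs):
            hs_counter += 1
            dam = f"hsdam{hs_counter}"  # simulated, not genotyped, not recorded
            dam_haps = founder_haplotypes()
            child = f"hs_off{hs_counter}"
            phase[child] = (
                _meiosis(phase[father], markers, rng),
                _meiosis(dam_haps, markers, rng),
            )
            records.append(PedRecord(child, father, None, "unknown", "F1"))
            offspring.append(child)
            genotyped.append(child)

    dosage = np.array(
        [phase[s][0].astype(float) + phase[s][1].astype(float) for s in genotyped]
    )
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan

    carriers = frozenset(
        s for s in genotyped
        if phase[s][0][cfg.causal_index] + phase[s][1][cfg.causal_index] >= 1
    )
    affection: dict[str, str] = {}
    for s in genotyped:
        if s in carriers:
            affected = rng.random() < cfg.penetrance
        else:
            affected = False
        if cfg.misassignment_rate > 0 and rng.random() < cfg.misassignment_rate:
            affected = not affected
        affection[s] = AFFECTED if affected else UNAFFECTED

    pedigree = Pedigree(records)
    genotypes = GenotypeMatrix(genotyped, markers, dosage)
    phenotypes = PhenotypeTable.from_records(genotyped, affection=affection)
    truth = TruthRecord(
        causal_key=markers[cfg.causal_index].id,
        carriers=carriers,
        phase={s: (tuple(phase[s][0]), tuple(phase[s][1])) for s in genotyped},
    )
    return pedigree, genotypes, phenotypes, truth


# ------------------------------------------------------------------ slick


@dataclass
class SlickConfig:
    """Crossbred coat-score cohort around a planted causal haplotype.

    Defaults reproduce the study cohort's shape: 82 animals, 25 interval
    markers, 43 true carriers, and 3 phenotype-discordant animals (two
    carriers scored 2, one non-carrier scored 1), giving 42 slick-coded
    cases and 40 controls with 79/82 genotype-phenotype concordance.
    """

    seed: int = 0
    n_animals: int = 82
    n_markers: int = 25
    chromosome: str = "20"
    interval_start: int = 38_600_000
    interval_end: int = 39_600_000
    causal_position: int = 39_136_558
    n_carriers: int = 43
    block_markers: int = 6  # markers spanned by the founder haplotype block
    n_discordant_carriers: int = 2  # carriers scored 2 (not slick-coded)
    n_discordant_noncarriers: int = 1  # non-carriers scored 1 (slick-coded)
    carrier_score: float = 1.0
    score_sd: float = 0.0
    freq_low: float = 0.05
    freq_high: float = 0.5

    def __post_init__(self) -> None:
        n_disc = self.n_discordant_carriers + self.n_discordant_noncarriers
        if n_disc > self.n_animals:
            raise DomscanError("discordant count exceeds cohort size")
        if self.n_carriers > self.n_animals:
            raise DomscanError("carrier count exceeds cohort size")
        if self.n_discordant_carriers > self.n_carriers:
            raise DomscanError("discordant carriers exceed carrier count")
        if self.block_markers > self.n_markers:
            raise DomscanError("block cannot exceed marker count")


def simulate_crossbred_slick(
    cfg: SlickConfig = SlickConfig(),
) -> tuple[GenotypeMatrix, PhenotypeTable, TruthRecord]:
    """Simulate the crossbred cohort used for haplotype fine-mapping.

    Carriers are heterozygous for the causal mutation and carry one copy
    of a contiguous founder haplotype over ``block_markers`` markers
    centred in the interval; scores are 1 for carriers and 2-4 for
    non-carriers (plus Gaussian jitter when ``score_sd`` > 0, clamped to
    the scale), with the configured discordant animals injected.
    """
    rng = np.random.default_rng(cfg.seed)
    positions = np.linspace(
        cfg.interval_start, cfg.interval_end, cfg.n_markers, dtype=int
    )
    markers = [
        Marker(f"iv_snp{k + 1}", cfg.chromosome, int(pos), "A", "G",
               cm=float(k) * 0.04)
        for k, pos in enumerate(positions)
    ]
    freqs = rng.uniform(cfg.freq_low, cfg.freq_high, size=cfg.n_markers)

    block_start = (cfg.n_markers - cfg.block_markers) // 2
    block = list(range(block_start, block_start + cfg.block_markers))
    founder_block = (rng.random(cfg.n_markers) < 0.5).astype(np.int8)

    samples = [f"cx{i + 1}" for i in range(cfg.n_animals)]
    carrier_ids = samples[: cfg.n_carriers]  # shuffled below via score assignment
    phase: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s in samples:
        hap_a = (rng.random(cfg.n_markers) < freqs).astype(np.int8)
        hap_b = (rng.random(cfg.n_markers) < freqs).astype(np.int8)
        if s in set(carrier_ids):
            hap_a[block] = founder_block[block]
        phase[s] = (hap_a, hap_b)

    dosage = np.array(
        [phase[s][0].astype(float) + phase[s][1].astype(float) for s in samples]
    )

    carriers = set(carrier_ids)
    noncarriers = [s for s in samples if s not in carriers]
    disc_carriers = carrier_ids[: cfg.n_discordant_carriers]
    disc_noncarriers = noncarriers[: cfg.n_discordant_noncarriers]

    scores: dict[str, float] = {}
    for s in samples:
        if s in disc_carriers:
            base = 2.0
        elif s in disc_noncarriers:
            base = 1.0
        elif s in carriers:
            base = cfg.carrier_score
        else:
            base = float(rng.integers(2, 5))  # non-carrier coats score 2-4
        if cfg.score_sd > 0:
            base += rng.normal(0.0, cfg.score_sd)
        lo = 2.0 if (s not in carriers and s not in disc_noncarriers) else 1.0
        scores[s] = float(min(max(base, lo), 4.0))

    affection = {
        s: AFFECTED if scores[s] < 1.5 else UNAFFECTED for s in samples
    }
    phenotypes = PhenotypeTable.from_records(
        samples, affection=affection, scores={"coat_score": scores}
    )
    genotypes = GenotypeMatrix(samples, markers, dosage)
    causal_key = VariantKey(cfg.chromosome, cfg.causal_position, "GC", "G")
    causal_classes = {s: (HET if s in carriers else HOM_REF) for s in samples}
    truth = TruthRecord(
        causal_key=str(causal_key),
        carriers=frozenset(carriers),
        block_marker_ids=tuple(markers[j].id for j in block),
        phase={s: (tuple(phase[s][0]), tuple(phase[s][1])) for s in samples},
        causal_classes=causal_classes,
    )
    return genotypes, phenotypes, truth


# ------------------------------------------------------------------ panels


DEFAULT_BREEDS = {
    "Senepol": 9,
    "Angus": 9,
    "BelgianBlue": 29,
    "Brahman": 10,
    "Charolais": 10,
    "HolsteinFriesian": 10,
    "Jersey": 10,
    "Nelore": 10,
    "Simmental": 10,
    "Yak": 8,
}


@dataclass
class PanelConfig:
    """Multi-breed variant panel with one planted private causal variant.

    Breed sizes default to the exome panel's composition (115 animals
    over ten breeds); a separate ``population_db`` group models the
    previously-observed variation database.
    """

    seed: int = 0
    breeds: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BREEDS))
    target_breed: str = "Senepol"
    population_db_n: int = 50
    n_variants: int = 150
    chromosome: str = "20"
    region_start: int = 38_600_000
    region_end: int = 39_600_000
    planted_position: int = 39_136_558
    planted_ref: str = "GC"
    planted_alt: str = "G"
    plant: bool = True
    dbsnp_fraction: float = 0.7
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.target_breed not in self.breeds:
            raise DomscanError(f"target breed {self.target_breed!r} not in breeds")


def simulate_variant_panels(
    cfg: PanelConfig = PanelConfig(),
) -> tuple[VariantPanel, dict[str, frozenset[VariantKey]], TruthRecord]:
    """Build a breed-structured panel plus previously-seen variant sets.

    Background variants are polymorphic (never fixed within the target
    breed) and every background variant is previously observed — either
    listed in the dbSNP-like key set or carried by at least one
    population-database animal. The planted variant is het in every
    target-breed animal, absent everywhere else and previously unseen.
    Returns (panel, seen_sets, truth); ``seen_sets`` holds the
    dbSNP-like key set under ``"dbsnp"``.
    """
    rng = np.random.default_rng(cfg.seed)
    samples: list[str] = []
    groups: dict[str, list[str]] = {}
    for breed, n in cfg.breeds.items():
        ids = [f"{breed}_{i + 1}" for i in range(n)]
        groups[breed] = ids
        samples += ids
    db_ids = [f"popdb_{i + 1}" for i in range(cfg.population_db_n)]
    groups["population_db"] = db_ids
    samples += db_ids

    n_bg = cfg.n_variants - (1 if cfg.plant else 0)
    step = max((cfg.region_end - cfg.region_start) // (cfg.n_variants + 1), 1)
    positions = [cfg.region_start + (j + 1) * step for j in range(n_bg)]
    bases = ["A", "C", "G", "T"]
    variants: list[VariantKey] = []
    columns: list[np.ndarray] = []
    in_dbsnp: list[bool] = []
    target_rows = [samples.index(s) for s in groups[cfg.target_breed]]
    db_rows = [samples.index(s) for s in db_ids]

    for j, pos in enumerate(positions):
        if pos == cfg.planted_position:
            pos += 1
        ref, alt = rng.choice(bases, size=2, replace=False)
        key = VariantKey(cfg.chromosome, int(pos), str(ref), str(alt))
        # some variants are breed-private polymorphisms, the rest shared
        if rng.random() < 0.3:
            breed = str(rng.choice(list(cfg.breeds)))
            freq_by_sample = {
                s: (rng.uniform(0.1, 0.4) if s in set(groups[breed]) else 0.0)
                for s in samples
            }
            # database animals may carry breed-private variation at low rate
            for s in db_ids:
                freq_by_sample[s] = rng.uniform(0.0, 0.1)
            freqs = np.array([freq_by_sample[s] for s in samples])
        else:
            freqs = np.full(len(samples), rng.uniform(0.05, 0.4))
        draws = rng.random((len(samples), 2)) < freqs[:, None]
        col = draws.sum(axis=1).astype(np.int8)
        # keep background variation polymorphic within the target breed
        carried = (col[target_rows] > 0)
        if carried.all():
            col[target_rows[int(rng.integers(len(target_rows)))]] = HOM_REF
        seen_in_dbsnp = bool(rng.random() < cfg.dbsnp_fraction)
        if not seen_in_dbsnp and not (col[db_rows] > 0).any():
            # previously observed by construction: plant one db carrier
            col[db_rows[int(rng.integers(len(db_rows)))]] = HET
        variants.append(key)
        columns.append(col)
        in_dbsnp.append(seen_in_dbsnp)

    carriers: frozenset[str] = frozenset()
    planted_key = VariantKey(
        cfg.chromosome, cfg.planted_position, cfg.planted_ref, cfg.planted_alt
    )
    if cfg.plant:
        col = np.zeros(len(samples), dtype=np.int8)
        for i in target_rows:
            col[i] = HET
        variants.append(planted_key)
        columns.append(col)
        in_dbsnp.append(False)
        carriers = frozenset(groups[cfg.target_breed])

    classes = np.column_stack(columns)
    if cfg.missing_rate > 0:
        mask = rng.random(classes.shape) < cfg.missing_rate
        if cfg.plant:  # never blank the planted variant's carriers
            mask[:, -1] = False
        classes = classes.copy()
        classes[mask] = MISSING

    order = np.argsort([v.position_bp for v in variants], kind="stable")
    variants = [variants[j] for j in order]
    classes = classes[:, order]
    in_dbsnp = [in_dbsnp[j] for j in order]

    panel = VariantPanel(samples, variants, classes, groups)
    seen_sets = {
        "dbsnp": frozenset(v for v, seen in zip(variants, in_dbsnp) if seen)
    }
    truth = TruthRecord(causal_key=str(planted_key), carriers=carriers)
    return panel, seen_sets, truth


def observed_in_group(panel: VariantPanel, group: str) -> frozenset[VariantKey]:
    """Variant keys carried by at least one member of a sample group."""
    rows = panel.sample_rows(panel.group(group))
    seen = []
    for j, key in enumerate(panel.variants):
        col = panel.classes[rows, j]
        if ((col == HET) | (col == HOM_ALT)).any():
            seen.append(key)
    return frozenset(seen)
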