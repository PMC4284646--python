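"""Family-based association testing for a dominant binary trait.

The pedigree is decomposed into two kinds of scoring clusters:

* **trios** (father, mother, offspring; both parents genotyped), scored
  by counting alt-allele transmissions from heterozygous parents to the
  affected offspring — the classic TDT contribution;
* **sibships** (>= 2 siblings sharing a sire, typically paternal
  half-sibs), scored by comparing alt-allele counts of affected versus
  unaffected siblings against the within-family permutation null — the
  sib-TDT contribution.

Each cluster i contributes an observed count O_i, its null expectation
E_i and null variance V_i; the per-marker statistic is the stratified
(Cochran–Mantel–Haenszel-style) 1-df chi-square

    X = (sum_i (O_i - E_i))^2 / sum_i V_i ,

which reduces exactly to the classic TDT (b-c)^2/(b+c) when only trios
are present, and to the sib-TDT for pure sibship data. Clusters with
V_i = 0 are uninformative at a marker and are excluded from both sums.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import AFFECTED, UNAFFECTED, DomscanError, GenotypeMatrix, Pedigree, PhenotypeTable
from .stats import bonferroni, format_threshold

logger = logging.getLogger(__name__)

LOG10 = math.log(10.0)


@dataclass(frozen=True)
class FamilyCluster:
    """A disjoint scoring unit: one trio or one sibship."""

    kind: str  # "trio" | "sibship"
    members: tuple[str, ...]  # trio: (father, mother, offspring); sibship: siblings
    affected_ids: frozenset[str]
    sire_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("trio", "sibship"):
            raise ValueError(f"unknown cluster kind {self.kind!r}")
        if self.kind == "trio" and len(self.members) != 3:
            raise ValueError("trio cluster needs exactly (father, mother, offspring)")
        if self.kind == "sibship" and len(self.members) < 2:
            raise ValueError("sibship cluster needs >= 2 siblings")


@dataclass
class ClusterScore:
    """Observed, expected and variance components of one cluster at one marker."""

    observed: float
    expected: float
    variance: float
    n_transmissions_alt: int = 0  # trio-only bookkeeping (b)
    n_transmissions_ref: int = 0  # trio-only bookkeeping (c)
    mendelian_error: bool = False

    def __post_init__(self) -> None:
        if self.variance < -1e-12:
            raise ValueError("negative cluster variance")
        if self.variance <= 0.0 and abs(self.observed - self.expected) > 1e-9:
            raise ValueError("V = 0 requires O = E")


@dataclass
class TdtResult:
    """Per-marker combined TDT/sib-TDT outcome."""

    marker_id: str
    statistic: float
    p_value: float
    log10_p: float
    n_informative_clusters: int
    transmissions: tuple[int, int]  # (b, c) alt transmitted / untransmitted, trio part
    uninformative: bool = False
    n_mendelian_errors: int = 0


def build_clusters(
    pedigree: Pedigree,
    phenotypes: PhenotypeTable,
    genotyped: Iterable[str],
) -> list[FamilyCluster]:
    """Decompose a pedigree into disjoint trio and sibship clusters.

    Offspring with both parents genotyped form trios; the remaining
    genotyped offspring are grouped into one sibship per shared sire
    (paternal half-sib families). Offspring with unknown affection are
    excluded with a warning; singletons with no genotyped relatives are
    dropped with a warning.
    """
    genotyped = set(genotyped)
    clusters: list[FamilyCluster] = []
    sibs_by_sire: dict[str, list[str]] = {}

    for rec in pedigree.records:
        iid = rec.individual_id
        if iid not in genotyped:
            continue
        sire, dam = rec.sire_id, rec.dam_id
        if sire is None and dam is None:
            continue  # founder, not an offspring
        affection = phenotypes.affection(iid)
        if affection not in (AFFECTED, UNAFFECTED):
            logger.warning("offspring %s has unknown affection; excluded", iid)
            continue
        if sire in genotyped and dam in genotyped:
            clusters.append(
                FamilyCluster(
                    "trio",
                    (sire, dam, iid),
                    frozenset({iid}) if affection == AFFECTED else frozenset(),
                    sire_id=sire,
                )
            )
        elif sire is not None:
            sibs_by_sire.setdefault(sire, []).append(iid)
        else:
            logger.warning("offspring %s has no genotyped relatives; dropped", iid)

    for sire, sibs in sorted(sibs_by_sire.items()):
        if len(sibs) < 2:
            logger.warning("offspring %s has no genotyped relatives; dropped", sibs[0])
            continue
        affected = frozenset(s for s in sibs if phenotypes.affection(s) == AFFECTED)
        clusters.append(FamilyCluster("sibship", tuple(sibs), affected, sire_id=sire))
    return clusters


def cluster_score(
    dosages: Mapping[str, float],
    cluster: FamilyCluster,
) -> ClusterScore:
    """Score one cluster at one marker.

    Trio: per heterozygous parent with an affected offspring the
    transmitted allele is deduced; O += alt copies transmitted, E += 1/2,
    V += 1/4. The double-het/het-offspring ambiguity contributes the
    expectation over both consistent transmissions (O += 1, E += 1,
    V += 1/2 over the two parents). Mendelian-inconsistent trios are
    skipped at this marker and flagged.

    Sibship of n genotyped sibs with dosages g_j and a affected:
    O = sum of affected dosages, E = a*mean(g), and the within-family
    label-permutation variance V = a(n-a)/(n-1) * (1/n) sum (g_j-gbar)^2.
    """
    if cluster.kind == "trio":
        return _score_trio(dosages, cluster)
    return _score_sibship(dosages, cluster)


def _score_trio(dosages: Mapping[str, float], cluster: FamilyCluster) -> ClusterScore:
    father, mother, child = cluster.members
    if child not in cluster.affected_ids:
        return ClusterScore(0.0, 0.0, 0.0)  # classic TDT counts affected offspring only
    gf, gm, gc = (dosages.get(s, math.nan) for s in cluster.members)
    if any(math.isnan(g) for g in (gf, gm, gc)):
        return ClusterScore(0.0, 0.0, 0.0)

    def gametes(g: float) -> tuple[int, ...]:
        return (0, 1) if g == 1 else ((1,) if g == 2 else (0,))

    consistent = [
        (tf, tm) for tf in set(gametes(gf)) for tm in set(gametes(gm)) if tf + tm == gc
    ]
    if not consistent:
        return ClusterScore(0.0, 0.0, 0.0, mendelian_error=True)

    o = e = v = 0.0
    b = c = 0
    if len(consistent) == 1:
        tf, tm = consistent[0]
        for parent_g, t in ((gf, tf), (gm, tm)):
            if parent_g == 1:  # only het parents are informative
                o += t
                e += 0.5
                v += 0.25
                if t == 1:
                    b += 1
                else:
                    c += 1
    else:
        # both parents het, child het: the two phase assignments are
        # equally likely; contribute their average over the two parents
        o += 1.0
        e += 1.0
        v += 0.5
        b += 1
        c += 1
    return ClusterScore(o, e, v, b, c)


def _score_sibship(dosages: Mapping[str, float], cluster: FamilyCluster) -> ClusterScore:
    pairs = [
        (s, dosages[s])
        for s in cluster.members
        if s in dosages and not math.isnan(dosages[s])
    ]
    n = len(pairs)
    if n < 2:
        return ClusterScore(0.0, 0.0, 0.0)
    g = np.array([d for _, d in pairs])
    affected = np.array([s in cluster.affected_ids for s, _ in pairs])
    a = int(affected.sum())
    gbar = float(g.mean())
    observed = float(g[affected].sum())
    expected = a * gbar
    if a == 0 or a == n or np.all(g == g[0]):
        return ClusterScore(expected, expected, 0.0)
    variance = a * (n - a) / (n - 1) * float(np.mean((g - gbar) ** 2))
    return ClusterScore(observed, expected, variance)


def dfam_test(
    dosages: Mapping[str, float],
    clusters: Sequence[FamilyCluster],
    marker_id: str = "",
) -> TdtResult:
    """Combined TDT/sib-TDT 1-df chi-square at one marker.

    Clusters with zero variance are excluded from both sums; if no
    cluster is informative the marker is flagged and p = 1.
    """
    if not clusters:
        raise DomscanError("dfam_test needs at least one cluster")
    o_minus_e = 0.0
    v_sum = 0.0
    n_informative = 0
    b = c = 0
    n_mend = 0
    for cluster in clusters:
        score = cluster_score(dosages, cluster)
        if score.mendelian_error:
            n_mend += 1
            continue
        b += score.n_transmissions_alt
        c += score.n_transmissions_ref
        if score.variance > 0.0:
            o_minus_e += score.observed - score.expected
            v_sum += score.variance
            n_informative += 1
    if v_sum <= 0.0:
        return TdtResult(marker_id, 0.0, 1.0, 0.0, 0, (b, c),
                         uninformative=True, n_mendelian_errors=n_mend)
    stat = o_minus_e**2 / v_sum
    logsf = float(sps.chi2.logsf(stat, df=1))
    p = float(np.exp(logsf))
    return TdtResult(
        marker_id, float(stat), p, logsf / LOG10, n_informative, (b, c),
        n_mendelian_errors=n_mend,
    )


@dataclass
class ScanResult:
    """Genome-scan output: per-marker table plus the Bonferroni context."""

    table: pd.DataFrame  # chrom, bp, id, statistic, p, log10_p, n_clusters, b, c
    n_tests: int
    alpha: float

    @property
    def threshold(self) -> float:
        return bonferroni(self.alpha, self.n_tests)

    def top(self) -> pd.Series:
        """Row with the smallest p-value (most negative log10 p)."""
        return self.table.loc[self.table["log10_p"].idxmin()]

    def sorted_by_p(self) -> pd.DataFrame:
        return self.table.sort_values("log10_p").reset_index(drop=True)

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] < self.threshold]

    def summary(self) -> str:
        top = self.top()
        lines = [
            f"DFAM genome scan: {len(self.table)} markers tested, "
            f"{int(self.table['uninformative'].sum())} uninformative",
            f"Bonferroni threshold (alpha={self.alpha:g}, m={self.n_tests}): "
            f"{format_threshold(self.threshold)}",
            f"top marker: {top['id']} ({top['chrom']}:{int(top['bp'])}) "
            f"X={top['statistic']:.2f} p={top['p']:.3g}",
            f"markers below threshold: {len(self.significant())}",
        ]
        return "\n".join(lines)


def genome_scan(
    genotypes: GenotypeMatrix,
    clusters: Sequence[FamilyCluster],
    alpha: float = 0.05,
    count_informative_only: bool = False,
) -> ScanResult:
    """Run the combined family test at every marker of a QC'd matrix.

    The Bonferroni denominator counts all tested markers by default;
    ``count_informative_only`` restricts it to informative markers.
    """
    if not clusters:
        raise DomscanError("genome_scan needs at least one cluster")
    rows = []
    n_informative_markers = 0
    for j, marker in enumerate(genotypes.markers):
        col = genotypes.dosage[:, j]
        dosages = dict(zip(genotypes.samples, col))
        res = dfam_test(dosages, clusters, marker.id)
        if not res.uninformative:
            n_informative_markers += 1
        rows.append(
            {
                "chrom": marker.chromosome,
                "bp": marker.position_bp,
                "id": marker.id,
                "statistic": res.statistic,
                "p": res.p_value,
                "log10_p": res.log10_p,
                "neg_log10_p": -res.log10_p,
                "n_clusters": res.n_informative_clusters,
                "b": res.transmissions[0],
                "c": res.transmissions[1],
                "uninformative": res.uninformative,
                "mendelian_errors": res.n_mendelian_errors,
            }
        )
    if n_informative_markers == 0:
        raise DomscanError("no informative markers in scan")
    n_tests = n_informative_markers if count_informative_only else len(rows)
    return ScanResult(pd.DataFrame(rows), n_tests, alpha)


def manhattan_plot(scan: ScanResult, path: Optional[str] = None):
    """-log10(p) against genome position, with the Bonferroni line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = scan.table
    fig, ax = plt.subplots(figsize=(10, 4))
    offset = 0
    ticks, labels = [], []
    for chrom, sub in table.groupby("chrom", sort=False):
        x = sub["bp"].to_numpy() + offset
        ax.scatter(x, sub["neg_log10_p"], s=8)
        ticks.append(offset + sub["bp"].mean())
        labels.append(str(chrom))
        offset += sub["bp"].max() + 1
    ax.axhline(-math.log10(scan.threshold), color="red", linestyle="--", linewidth=1)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 p")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
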