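"""Family clustering and the combined TDT/sib-TDT statistic: transmission
enumeration oracles, the within-sibship permutation variance, classic-TDT
equivalence and allele-relabelling invariance."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from domscan.datamodel import (
    AFFECTED,
    DomscanError,
    PedRecord,
    Pedigree,
    PhenotypeTable,
    UNAFFECTED,
)
from domscan.family import (
    FamilyCluster,
    build_clusters,
    cluster_score,
    dfam_test,
    genome_scan,
)
from domscan.simulate import SimConfig, simulate_cohort

from conftest import make_matrix


def affection_table(affected, unaffected):
    samples = list(affected) + list(unaffected)
    return PhenotypeTable.from_records(
        samples,
        affection={**{s: AFFECTED for s in affected}, **{s: UNAFFECTED for s in unaffected}},
    )


class TestBuildClusters:
    def test_study_shaped_pedigree_decomposition(self):
        """22 genotyped trios + 55 half-sibs of 2 sires -> 22 trios + 2 sibships."""
        ped, geno, phen, _ = simulate_cohort(
            SimConfig(seed=3, n_chromosomes=1, markers_per_chromosome=5, causal_index=2)
        )
        clusters = build_clusters(ped, phen, geno.samples)
        kinds = [c.kind for c in clusters]
        assert kinds.count("trio") == 22
        assert kinds.count("sibship") == 2
        sib_sizes = sorted(len(c.members) for c in clusters if c.kind == "sibship")
        assert sum(sib_sizes) == 55

    def test_parentless_unrelated_offspring_dropped(self):
        ped = Pedigree([PedRecord(f"x{i}", None, None) for i in range(5)])
        phen = affection_table(["x0"], ["x1", "x2", "x3", "x4"])
        assert build_clusters(ped, phen, [f"x{i}" for i in range(5)]) == []

    def test_mixed_trio_and_sibship_assignment(self, trio_pedigree):
        ped = Pedigree(
            [
                PedRecord("sireA", None, None, "male"),
                PedRecord("damA", None, None, "female"),
                PedRecord("k1", "sireA", "damA"),
                PedRecord("k2", "sireA", None),
                PedRecord("k3", "sireA", None),
            ]
        )
        phen = affection_table(["k1", "k2"], ["k3"])
        clusters = build_clusters(ped, phen, ["sireA", "damA", "k1", "k2", "k3"])
        kinds = sorted(c.kind for c in clusters)
        assert kinds == ["sibship", "trio"]
        sib = next(c for c in clusters if c.kind == "sibship")
        assert set(sib.members) == {"k2", "k3"}

    def test_unknown_affection_excluded_not_error(self):
        ped = Pedigree(
            [
                PedRecord("f", None, None, "male"),
                PedRecord("m", None, None, "female"),
                PedRecord("c", "f", "m"),
            ]
        )
        phen = PhenotypeTable.from_records(["f", "m", "c"])  # all unknown
        assert build_clusters(ped, phen, ["f", "m", "c"]) == []


def sibship_permutation_oracle(dosages, affected_count):
    """Mean and variance of the affected-allele count over all affection
    label placements within the sibship."""
    n = len(dosages)
    observed = []
    for idx in itertools.combinations(range(n), affected_count):
        observed.append(sum(dosages[i] for i in idx))
    return float(np.mean(observed)), float(np.var(observed))


class TestClusterScore:
    def test_trio_single_consistent_transmission(self):
        cluster = FamilyCluster("trio", ("f", "m", "c"), frozenset({"c"}))
        score = cluster_score({"f": 1, "m": 0, "c": 1}, cluster)
        assert (score.observed, score.expected, score.variance) == (1.0, 0.5, 0.25)
        assert score.n_transmissions_alt == 1

    def test_trio_double_het_ambiguity_contributes_expectation(self):
        cluster = FamilyCluster("trio", ("f", "m", "c"), frozenset({"c"}))
        score = cluster_score({"f": 1, "m": 1, "c": 1}, cluster)
        assert (score.observed, score.expected, score.variance) == (1.0, 1.0, 0.5)

    def test_trio_mendelian_error_flagged(self):
        cluster = FamilyCluster("trio", ("f", "m", "c"), frozenset({"c"}))
        score = cluster_score({"f": 0, "m": 0, "c": 2}, cluster)
        assert score.mendelian_error

    def test_unaffected_trio_offspring_contributes_nothing(self):
        cluster = FamilyCluster("trio", ("f", "m", "c"), frozenset())
        score = cluster_score({"f": 1, "m": 1, "c": 1}, cluster)
        assert score.variance == 0.0 and score.observed == score.expected

    def test_sibship_example_against_permutation_oracle(self):
        cluster = FamilyCluster("sibship", ("a", "b", "c", "d"), frozenset({"a"}))
        score = cluster_score({"a": 2, "b": 0, "c": 0, "d": 0}, cluster)
        assert (score.observed, score.expected, score.variance) == (2.0, 0.5, 0.75)
        mean, var = sibship_permutation_oracle([2, 0, 0, 0], 1)
        assert score.expected == pytest.approx(mean)
        assert score.variance == pytest.approx(var)

    @pytest.mark.parametrize("seed", range(8))
    def test_sibship_moments_match_label_permutations(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        dosages = rng.integers(0, 3, size=n).tolist()
        a = int(rng.integers(1, n))
        sibs = tuple(f"s{i}" for i in range(n))
        cluster = FamilyCluster("sibship", sibs, frozenset(sibs[:a]))
        score = cluster_score(dict(zip(sibs, map(float, dosages))), cluster)
        mean, var = sibship_permutation_oracle(dosages, a)
        # the cluster E is for the *observed* labels; the oracle variance is
        # over permutations, matching the analytic finite-population form
        assert score.variance == pytest.approx(var, abs=1e-12)
        assert score.expected == pytest.approx(a * np.mean(dosages))

    def test_monomorphic_sibship_uninformative(self):
        cluster = FamilyCluster("sibship", ("a", "b", "c"), frozenset({"a"}))
        score = cluster_score({"a": 1, "b": 1, "c": 1}, cluster)
        assert score.variance == 0.0 and score.observed == score.expected


def trio_clusters_with_transmissions(b, c):
    """Build trio data realizing exactly b alt and c ref transmissions."""
    clusters, dosages = [], {}
    for i in range(b + c):
        f, m, ch = f"f{i}", f"m{i}", f"c{i}"
        clusters.append(FamilyCluster("trio", (f, m, ch), frozenset({ch})))
        dosages[f] = 1.0
        dosages[m] = 0.0
        dosages[ch] = 1.0 if i < b else 0.0
    return dosages, clusters


class TestDfamTest:
    @pytest.mark.parametrize("b,c,expected_x", [(10, 0, 10.0), (8, 2, 3.6)])
    def test_classic_tdt_closed_form(self, b, c, expected_x):
        dosages, clusters = trio_clusters_with_transmissions(b, c)
        res = dfam_test(dosages, clusters)
        assert res.statistic == pytest.approx(expected_x, rel=1e-12)
        assert res.transmissions == (b, c)
        assert res.p_value == pytest.approx(sps.chi2.sf(expected_x, 1), rel=1e-12)
        if (b, c) == (10, 0):
            assert res.p_value == pytest.approx(1.565e-3, rel=1e-3)

    def test_monomorphic_everywhere_uninformative(self):
        clusters = [FamilyCluster("sibship", ("a", "b"), frozenset({"a"}))]
        res = dfam_test({"a": 0.0, "b": 0.0}, clusters)
        assert res.uninformative and res.p_value == 1.0

    def test_trio_only_equivalence_random_datasets(self):
        """On 1,000 random trio-only datasets the statistic equals the
        classic TDT (b-c)^2/(b+c) computed by direct transmission counting."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n_trios = int(rng.integers(4, 30))
            dosages, clusters, b, c = {}, [], 0, 0
            for i in range(n_trios):
                f, m, ch = f"f{i}", f"m{i}", f"c{i}"
                gf, gm = int(rng.integers(0, 3)), int(rng.integers(0, 3))
                tf = rng.integers(0, 2) if gf == 1 else gf // 2
                tm = rng.integers(0, 2) if gm == 1 else gm // 2
                gc = int(tf + tm)
                clusters.append(FamilyCluster("trio", (f, m, ch), frozenset({ch})))
                dosages.update({f: float(gf), m: float(gm), ch: float(gc)})
                # direct transmission counting oracle over het parents
                if gf == 1 and gm == 1 and gc == 1:
                    b += 1
                    c += 1
                else:
                    for g, t in ((gf, tf), (gm, tm)):
                        if g == 1:
                            b += t
                            c += 1 - t
            res = dfam_test(dosages, clusters)
            if b + c == 0:
                assert res.uninformative
            else:
                assert res.statistic == pytest.approx((b - c) ** 2 / (b + c), rel=1e-9)

    def test_invariant_to_allele_relabelling(self):
        ped, geno, phen, _ = simulate_cohort(
            SimConfig(seed=8, n_trios=6, n_halfsibs_per_sire=(6, 5),
                      n_chromosomes=1, markers_per_chromosome=10, causal_index=4)
        )
        clusters = build_clusters(ped, phen, geno.samples)
        for marker in geno.markers[:5]:
            dosages = geno.dosages_for(marker.id)
            flipped = {s: (2.0 - d if not math.isnan(d) else d) for s, d in dosages.items()}
            a = dfam_test(dosages, clusters)
            bres = dfam_test(flipped, clusters)
            assert a.statistic == pytest.approx(bres.statistic, rel=1e-9, abs=1e-12)


def matrix_from_dosages(dosages, n_copies):
    """Matrix repeating one dosage vector over ``n_copies`` markers."""
    from domscan.datamodel import GenotypeMatrix, Marker

    samples = list(dosages)
    markers = [Marker(f"m{j + 1}", "1", (j + 1) * 1000, "A", "G") for j in range(n_copies)]
    arr = np.array([[dosages[s]] * n_copies for s in samples])
    return GenotypeMatrix(samples, markers, arr)


class TestGenomeScan:
    def test_threshold_counts_all_tested_markers(self):
        dosages, clusters = trio_clusters_with_transmissions(6, 1)
        scan = genome_scan(matrix_from_dosages(dosages, 2), clusters, alpha=0.05)
        assert scan.n_tests == 2
        assert scan.threshold == pytest.approx(0.025)

    def test_single_marker_threshold_is_alpha(self):
        dosages, clusters = trio_clusters_with_transmissions(5, 0)
        scan = genome_scan(matrix_from_dosages(dosages, 1), clusters, alpha=0.05)
        assert scan.n_tests == 1 and scan.threshold == 0.05

    def test_causal_marker_attains_scan_minimum(self):
        cfg = SimConfig(seed=21)
        ped, geno, phen, truth = simulate_cohort(cfg)
        clusters = build_clusters(ped, phen, geno.samples)
        scan = genome_scan(geno, clusters)
        assert scan.top()["id"] == truth.causal_key

    def test_zero_informative_markers_is_error(self):
        clusters = [FamilyCluster("sibship", ("a", "b"), frozenset({"a"}))]
        geno = matrix_from_dosages({"a": 0.0, "b": 0.0}, 1)
        with pytest.raises(DomscanError):
            genome_scan(geno, clusters)
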