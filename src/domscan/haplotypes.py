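"""Sliding-window haplotype association for quantitative fine-mapping.

Short marker windows (default six markers, three-marker step) tile a
target interval. Each window is phased by an Excoffier–Slatkin-style EM
over haplotype frequencies with exact enumeration of the
genotype-compatible haplotype pairs — deterministic, and adequate for
windows of up to eight markers. Per window, each haplotype with at least
``min_carriers`` carriers (modal-phase coding) is tested for association
with a quantitative score by a two-sided two-sample t-test of carriers
versus non-carriers under a dominance model.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import DomscanError, GenotypeMatrix, Marker
from .stats import bonferroni, format_threshold, two_sample_t

logger = logging.getLogger(__name__)

MAX_WINDOW = 8  # exact pair enumeration is exponential in het count


@dataclass(frozen=True)
class WindowSpec:
    """Window tiling: ``size`` markers advancing by ``step``."""

    size: int = 6
    step: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.step <= self.size:
            raise ValueError("require 1 <= step <= size")
        if self.size > MAX_WINDOW:
            raise ValueError(f"window size {self.size} exceeds EM limit {MAX_WINDOW}")


def make_windows(n_markers: int, spec: WindowSpec = WindowSpec()) -> list[range]:
    """0-based marker index ranges tiling ``n_markers`` markers.

    Starts advance by ``step`` while a full window fits; if trailing
    markers would be uncovered, one extra window anchored at the end
    (start = M - size) is appended so every marker is covered.
    """
    if n_markers < spec.size:
        logger.warning(
            "only %d markers for window size %d; using a single window",
            n_markers, spec.size,
        )
        return [range(0, n_markers)]
    starts = list(range(0, n_markers - spec.size + 1, spec.step))
    last_covered = starts[-1] + spec.size
    if last_covered < n_markers:
        starts.append(n_markers - spec.size)
    return [range(s, s + spec.size) for s in starts]


@dataclass
class HaplotypeWindow:
    """EM-phased window: haplotype frequencies and per-individual phase."""

    marker_indices: tuple[int, ...]
    marker_ids: tuple[str, ...]
    haplotypes: tuple[tuple[int, ...], ...]  # alt-allele indicator vectors
    frequencies: np.ndarray
    best_phase: dict[str, tuple[int, int]]  # sample -> (hap index, hap index)
    log_likelihood: float
    ll_history: list[float]
    excluded: tuple[str, ...]  # samples dropped for in-window missingness
    n_iter: int

    def haplotype_label(self, h: int, markers: Optional[Sequence[Marker]] = None) -> str:
        hap = self.haplotypes[h]
        if markers is None:
            return "".join(str(a) for a in hap)
        return "".join(
            (markers[j].alt_allele if a else markers[j].ref_allele)
            for j, a in zip(self.marker_indices, hap)
        )

    def carriers(self, h: int) -> list[str]:
        """Samples whose modal phase contains >= 1 copy of haplotype h."""
        return [s for s, (p, q) in self.best_phase.items() if h in (p, q)]


def _compatible_pairs(dosage_row: np.ndarray) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered haplotype pairs consistent with a dosage vector."""
    het_positions = [j for j, d in enumerate(dosage_row) if d == 1]
    base = [1 if d == 2 else 0 for d in dosage_row]
    if not het_positions:
        hap = tuple(base)
        return [(hap, hap)]
    pairs = []
    # fix the first het to allele 1 on haplotype a to avoid double counting
    for assignment in itertools.product((0, 1), repeat=len(het_positions) - 1):
        hap_a = list(base)
        hap_b = list(base)
        hap_a[het_positions[0]] = 1
        for pos, bit in zip(het_positions[1:], assignment):
            hap_a[pos] = bit
            hap_b[pos] = 1 - bit
        pairs.append((tuple(hap_a), tuple(hap_b)))
    return pairs


def em_phase(
    genotypes: GenotypeMatrix,
    window: range,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> HaplotypeWindow:
    """Excoffier–Slatkin EM haplotype-frequency estimation on one window.

    The E-step weights each individual's compatible ordered pairs by
    f_a * f_b; the M-step re-estimates frequencies from expected counts.
    Initialization is uniform over the haplotypes appearing in any
    compatible pair, so the run is deterministic. Individuals with a
    missing genotype inside the window are excluded and logged. The
    modal phase is the highest-posterior compatible pair, ties broken by
    lexicographic haplotype order.
    """
    cols = list(window)
    if len(cols) > MAX_WINDOW:
        raise DomscanError(f"window of {len(cols)} markers exceeds EM limit {MAX_WINDOW}")
    sub = genotypes.dosage[:, cols]
    complete = ~np.isnan(sub).any(axis=1)
    excluded = tuple(s for s, ok in zip(genotypes.samples, complete) if not ok)
    if excluded:
        logger.info("window %s: excluded %d individuals with missing genotypes",
                    cols, len(excluded))
    kept_samples = [s for s, ok in zip(genotypes.samples, complete) if ok]
    rows = sub[complete].astype(int)
    n = len(kept_samples)
    if n == 0:
        raise DomscanError("no individuals with complete genotypes in window")

    pair_lists = [_compatible_pairs(rows[i]) for i in range(n)]
    hap_set = sorted({h for pairs in pair_lists for pair in pairs for h in pair})
    hap_index = {h: k for k, h in enumerate(hap_set)}
    n_hap = len(hap_set)
    pair_idx = [
        [(hap_index[a], hap_index[b]) for a, b in pairs] for pairs in pair_lists
    ]

    f = np.full(n_hap, 1.0 / n_hap)
    ll_history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        counts = np.zeros(n_hap)
        ll = 0.0
        for pairs in pair_idx:
            weights = np.array(
                [(1.0 if a == b else 2.0) * f[a] * f[b] for a, b in pairs]
            )
            total = weights.sum()
            if total <= 0.0:
                # degenerate under current f; fall back to uniform weights
                weights = np.ones(len(pairs))
                total = weights.sum()
                ll += -np.inf
            else:
                ll += math.log(total)
            weights /= total
            for w, (a, b) in zip(weights, pairs):
                counts[a] += w
                counts[b] += w
        ll_history.append(ll)
        new_f = counts / (2.0 * n)
        delta = float(np.abs(new_f - f).max())
        f = new_f
        if delta < tol:
            break

    # final log-likelihood under converged frequencies
    ll = 0.0
    best_phase: dict[str, tuple[int, int]] = {}
    for sample, pairs in zip(kept_samples, pair_idx):
        weights = [(1.0 if a == b else 2.0) * f[a] * f[b] for a, b in pairs]
        total = sum(weights)
        ll += math.log(total) if total > 0 else -np.inf
        order = sorted(
            range(len(pairs)),
            key=lambda t: (-weights[t], hap_set[pairs[t][0]], hap_set[pairs[t][1]]),
        )
        a, b = pairs[order[0]]
        best_phase[sample] = (a, b) if hap_set[a] <= hap_set[b] else (b, a)
    ll_history.append(ll)

    return HaplotypeWindow(
        marker_indices=tuple(cols),
        marker_ids=tuple(genotypes.markers[j].id for j in cols),
        haplotypes=tuple(hap_set),
        frequencies=f,
        best_phase=best_phase,
        log_likelihood=ll,
        ll_history=ll_history,
        excluded=excluded,
        n_iter=n_iter,
    )


@dataclass
class HaplotypeAssocResult:
    window_id: str
    haplotype: str
    n_carriers: int
    n_noncarriers: int
    t_statistic: float
    df: float
    p_value: float
    carrier_mean: float
    noncarrier_mean: float


@dataclass
class HapScanResult:
    """Windowed haplotype scan: result table + tests-performed ledger."""

    table: pd.DataFrame
    n_tests: int
    alpha: float
    skipped: pd.DataFrame  # window_id, haplotype, reason

    @property
    def threshold(self) -> float:
        return bonferroni(self.alpha, self.n_tests)

    def top(self) -> pd.Series:
        return self.table.loc[self.table["p"].idxmin()]

    def summary(self) -> str:
        lines = [
            f"haplotype dominance scan: {self.n_tests} tests performed",
            f"Bonferroni threshold (alpha={self.alpha:g}, m={self.n_tests}): "
            f"{format_threshold(self.threshold)}",
        ]
        if len(self.table):
            top = self.top()
            lines.append(
                f"top haplotype: window {top['window_id']} hap {top['haplotype']} "
                f"(n={top['n_carriers']} carriers) t={top['t']:.2f} p={top['p']:.3g}"
            )
        return "\n".join(lines)


def haplotype_dominance_scan(
    genotypes: GenotypeMatrix,
    phenotype: Mapping[str, float],
    spec: WindowSpec = WindowSpec(),
    min_carriers: int = 5,
    alpha: float = 0.05,
    t_variant: str = "pooled",
) -> HapScanResult:
    """Phase every window and t-test each common haplotype for association.

    Carrier status is dominance-coded from the modal phase (>= 1 copy).
    Only haplotypes with >= ``min_carriers`` carriers and >= 2
    non-carriers with phenotype are tested; the Bonferroni threshold
    divides alpha by the number of tests actually performed.
    """
    windows = make_windows(genotypes.n_markers, spec)
    rows: list[dict] = []
    skipped: list[dict] = []
    for window in windows:
        win = em_phase(genotypes, window)
        window_id = f"{win.marker_ids[0]}..{win.marker_ids[-1]}"
        phased = [s for s in win.best_phase if s in phenotype]
        for h in range(len(win.haplotypes)):
            label = win.haplotype_label(h, genotypes.markers)
            carriers = [s for s in win.carriers(h) if s in phenotype]
            noncarriers = [s for s in phased if s not in set(carriers)]
            if len(carriers) < min_carriers:
                skipped.append(
                    {"window_id": window_id, "haplotype": label,
                     "reason": f"carriers<{min_carriers}"}
                )
                continue
            if len(noncarriers) < 2:
                skipped.append(
                    {"window_id": window_id, "haplotype": label,
                     "reason": "no noncarrier contrast"}
                )
                continue
            x = [phenotype[s] for s in carriers]
            y = [phenotype[s] for s in noncarriers]
            res = two_sample_t(x, y, variant=t_variant)
            rows.append(
                {
                    "window_id": window_id,
                    "haplotype": label,
                    "n_carriers": len(carriers),
                    "n_noncarriers": len(noncarriers),
                    "t": res.statistic,
                    "df": res.df,
                    "p": res.p_value,
                    "carrier_mean": float(np.mean(x)),
                    "noncarrier_mean": float(np.mean(y)),
                }
            )
    if not rows:
        logger.warning("no haplotype reached min_carriers anywhere; empty scan")
        return HapScanResult(
            pd.DataFrame(
                columns=["window_id", "haplotype", "n_carriers", "n_noncarriers",
                         "t", "df", "p", "carrier_mean", "noncarrier_mean"]
            ),
            n_tests=1,
            alpha=alpha,
            skipped=pd.DataFrame(skipped, columns=["window_id", "haplotype", "reason"]),
        )
    table = pd.DataFrame(rows)
    return HapScanResult(
        table,
        n_tests=len(rows),
        alpha=alpha,
        skipped=pd.DataFrame(skipped, columns=["window_id", "haplotype", "reason"]),
    )
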