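"""Pre-association genotype QC: sample call-rate then marker MAF filters.

Samples are removed first (call rate below threshold), then marker minor
allele frequencies are recomputed on the surviving samples and low-MAF
markers removed. MAF uses non-missing chromosomes only. The operation is
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DomscanError, GenotypeMatrix, QcThresholds


@dataclass
class QcReport:
    """Exclusions with reasons, one row each, plus surviving counts."""

    exclusions: pd.DataFrame  # columns: kind, id, reason, value
    n_samples_kept: int
    n_markers_kept: int

    @property
    def n_samples_excluded(self) -> int:
        return int((self.exclusions["kind"] == "sample").sum())

    @property
    def n_markers_excluded(self) -> int:
        return int((self.exclusions["kind"] == "marker").sum())


def qc_filter(
    genotypes: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply call-rate then MAF filters; returns filtered matrix + report."""
    if genotypes.n_samples == 0 or genotypes.n_markers == 0:
        raise DomscanError("cannot QC an empty genotype matrix")

    rows: list[dict] = []
    call_rate = genotypes.sample_call_rate()
    keep_samples = [
        s for s, cr in zip(genotypes.samples, call_rate) if cr >= thresholds.call_rate_min
    ]
    for s, cr in zip(genotypes.samples, call_rate):
        if cr < thresholds.call_rate_min:
            rows.append(
                {"kind": "sample", "id": s,
                 "reason": f"call_rate<{thresholds.call_rate_min:g}", "value": float(cr)}
            )
    if not keep_samples:
        raise DomscanError("no samples survive QC")

    trimmed = genotypes.subset(samples=keep_samples)
    maf = trimmed.maf()
    keep_markers = []
    for mk, f in zip(trimmed.markers, maf):
        if np.isnan(f) or f < thresholds.maf_min:
            rows.append(
                {"kind": "marker", "id": mk.id,
                 "reason": f"maf<{thresholds.maf_min:g}",
                 "value": float(f) if not np.isnan(f) else np.nan}
            )
        else:
            keep_markers.append(mk.id)

    filtered = trimmed.subset(markers=keep_markers)
    report = QcReport(
        exclusions=pd.DataFrame(rows, columns=["kind", "id", "reason", "value"]),
        n_samples_kept=filtered.n_samples,
        n_markers_kept=filtered.n_markers,
    )
    return filtered, report
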