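"""Pool inclusion probabilities across imputation chains and build the
cross-tier summary report.

Each imputation chain yields its own posterior inclusion probability per
analyte; the chains are pooled by their mean with a normal-approximation
95% confidence interval (mean ± 1.96 sd / sqrt(M), truncated to [0, 1]).
When every chain returns the same value — notably the 100%-inclusion case
for a dominant analyte — the across-chain variance is zero and no interval
is reported.  An analyte whose pooled inclusion probability is 95% or above
(boundary inclusive) is classified highly predictive; the cross-tier report
tabulates these flags per sparsity tier with "k/4"-style totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

HIGH_PREDICTIVE_THRESHOLD = 0.95
Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class AnalyteSummary:
    analyte_id: str
    tier: float
    per_chain_rho: list[float]
    pooled_rho: float
    ci_low: float | None
    ci_high: float | None
    high_predictive: bool


@dataclass
class CrossTierReport:
    table: pd.DataFrame  # one row per analyte: per-tier flags, totals, rho
    tiers: list[float]

    def to_text(self) -> str:
        return self.table.to_csv(sep="\t", index=False)


def pool_across_chains(per_chain_rho: Sequence[float]) -> tuple[float, tuple[float, float] | None]:
    """Mean across chains plus a truncated normal-approximation 95% CI.

    The CI is absent when only one chain is available or the chains agree
    exactly (zero spread), mirroring the degenerate all-chains-100% case.
    """
    rhos = np.asarray(list(per_chain_rho), dtype=float)
    if rhos.size == 0:
        raise ValueError("no chain values to pool")
    pooled = float(rhos.mean())
    if rhos.size < 2:
        return pooled, None
    sd = float(rhos.std(ddof=1))
    if sd == 0.0:
        return pooled, None
    half = Z_95 * sd / np.sqrt(rhos.size)
    return pooled, (max(0.0, pooled - half), min(1.0, pooled + half))


def classify_high_predictive(pooled_rho: float, threshold: float = HIGH_PREDICTIVE_THRESHOLD) -> bool:
    """Boundary-inclusive rule: inclusion probability of 95% and above."""
    if not 0.0 <= pooled_rho <= 1.0:
        raise ValueError("pooled_rho must be in [0, 1]")
    return pooled_rho >= threshold


def summarize_analyte(
    analyte_id: str,
    tier: float,
    per_chain_rho: Sequence[float],
    threshold: float = HIGH_PREDICTIVE_THRESHOLD,
) -> AnalyteSummary:
    pooled, ci = pool_across_chains(per_chain_rho)
    return AnalyteSummary(
        analyte_id=analyte_id,
        tier=tier,
        per_chain_rho=[float(r) for r in per_chain_rho],
        pooled_rho=pooled,
        ci_low=None if ci is None else ci[0],
        ci_high=None if ci is None else ci[1],
        high_predictive=classify_high_predictive(pooled, threshold),
    )


def build_report(tier_summaries: dict[float, list[AnalyteSummary]]) -> CrossTierReport:
    """Cross-tier table of highly-predictive flags with k/N totals.

    Analytes excluded from a tier by sparsity are shown as "—" there (they
    were not modeled, which is different from not selected) and count as
    not-included in the total.  Rows are sorted by total, then by the
    largest pooled inclusion probability, descending.
    """
    tiers = sorted(tier_summaries)
    if not tiers:
        return CrossTierReport(table=pd.DataFrame(), tiers=[])
    universe: list[str] = []
    for t in tiers:
        for s in tier_summaries[t]:
            if s.analyte_id not in universe:
                universe.append(s.analyte_id)
    by_tier = {t: {s.analyte_id: s for s in tier_summaries[t]} for t in tiers}

    rows = []
    for a in universe:
        row: dict[str, object] = {"analyte": a}
        total = 0
        best_rho = -1.0
        for t in tiers:
            s = by_tier[t].get(a)
            col = f"tier_{t:g}"
            if s is None:
                row[col] = "—"
                row[f"rho_{t:g}"] = np.nan
                row[f"ci_{t:g}"] = ""
            else:
                row[col] = "+" if s.high_predictive else ""
                row[f"rho_{t:g}"] = s.pooled_rho
                row[f"ci_{t:g}"] = (
                    "" if s.ci_low is None else f"[{s.ci_low:.3f}, {s.ci_high:.3f}]"
                )
                total += int(s.high_predictive)
                best_rho = max(best_rho, s.pooled_rho)
        row["total"] = f"{total}/{len(tiers)}"
        row["_total"] = total
        row["_best"] = best_rho
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(["_total", "_best"], ascending=False, kind="stable")
    df = df.drop(columns=["_total", "_best"]).reset_index(drop=True)
    return CrossTierReport(table=df, tiers=[float(t) for t in tiers])
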