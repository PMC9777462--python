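"""Sparsity-tiered analyte subsets.

Retrospective lab matrices are sparse because each patient gets an
individual panel.  Rather than dropping incomplete cases, the analysis is
run on nested analyte subsets defined by a maximum tolerated missingness
fraction (default tiers 20/40/60/80%): the 20%-sparsity tier keeps only
analytes measured in at least 80% of cases, and so on, with each tier a
superset of the stricter ones.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import LabMatrix

DEFAULT_TIERS = (0.2, 0.4, 0.6, 0.8)


@dataclass
class SparsityTier:
    max_missing_fraction: float
    analyte_ids: list[str]


def analyte_coverage(matrix: LabMatrix) -> dict[str, float]:
    """Fraction of cases with an observed value, per analyte."""
    if matrix.n_cases == 0:
        raise ValueError("coverage undefined for a matrix with zero cases")
    frac = matrix.observed_mask.mean(axis=0)
    return {a: float(f) for a, f in zip(matrix.analytes, frac)}


def subset_by_sparsity(matrix: LabMatrix, max_missing_fraction: float) -> LabMatrix:
    """Keep analytes with coverage >= 1 - max_missing_fraction (inclusive).

    The case set is unchanged; only columns are dropped.  Floating-point
    coverage is compared with a small tolerance so that an analyte observed
    in exactly 80% of cases lands in the 20%-sparsity tier.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    cov = analyte_coverage(matrix)
    keep = [a for a in matrix.analytes if cov[a] >= 1.0 - max_missing_fraction - 1e-12]
    if not keep:
        raise ValueError(
            f"no analyte has coverage >= {1 - max_missing_fraction:.2f}; nothing to model"
        )
    return matrix.select_analytes(keep)


def make_tiers(
    matrix: LabMatrix, tiers: tuple[float, ...] = DEFAULT_TIERS
) -> list[SparsityTier]:
    """Build the nested tier structure for a list of missingness bounds."""
    cov = analyte_coverage(matrix)
    out = []
    for t in sorted(tiers):
        keep = [a for a in matrix.analytes if cov[a] >= 1.0 - t - 1e-12]
        out.append(SparsityTier(max_missing_fraction=float(t), analyte_ids=keep))
    return out
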