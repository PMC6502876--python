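"""Propagation of primer coverage into quantification bias.

A primer pair with coverage c over a taxon group recovers only the fraction
c of that group's true 16S gene copies, so a qPCR-style absolute
measurement is modeled as ``measured = coverage x true_abundance``.  This
module builds such theoretical measurements for a mock community, derives
relative abundances (normalization to total eubacteria, the practice the
analysis cautions against), quantifies between-primer disagreement as
percentage dissimilarity (Bray-Curtis x 100, the two-sample reduction of a
SIMPER analysis), and tests primer/group effects with ANOVA.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "MockCommunity",
    "TheoreticalMeasurement",
    "DissimilarityResult",
    "AnovaResult",
    "RelativeAbundanceWarning",
    "theoretical_abundance",
    "measurements_to_frame",
    "relative_abundance",
    "percent_dissimilarity",
    "pairwise_dissimilarity_matrix",
    "anova_two_way_no_rep",
    "anova_one_way",
]


class RelativeAbundanceWarning(UserWarning):
    """Relative abundance exceeded 1 or is undefined — the core caution."""


@dataclass(frozen=True)
class MockCommunity:
    """True composition: taxon group -> 16S gene copies/mL.

    Groups overlap (every subgroup is also part of EUB) but are modeled
    independently, as in a hypothetical worked composition; no consistency
    between the EUB entry and subgroup entries is enforced.
    """

    abundances: Mapping[str, float]

    def __post_init__(self) -> None:
        for group, value in self.abundances.items():
            if value < 0:
                raise ValueError(f"negative abundance {value} for group {group!r}")
        object.__setattr__(self, "abundances", dict(self.abundances))

    def __getitem__(self, group: str) -> float:
        return self.abundances[group]

    def __contains__(self, group: str) -> bool:
        return group in self.abundances

    @property
    def groups(self) -> list[str]:
        return list(self.abundances)

    def scaled(self, factor: float) -> "MockCommunity":
        return MockCommunity({g: v * factor for g, v in self.abundances.items()})


@dataclass(frozen=True)
class TheoreticalMeasurement:
    """Coverage-attenuated copy number for one (pair, group)."""

    pair_name: str
    group_label: str
    true_abundance: float
    coverage: float
    measured: float


@dataclass(frozen=True)
class DissimilarityResult:
    """Percentage dissimilarity between two primer pairs on one sample."""

    sample: str
    pair_x: str
    pair_y: str
    dissimilarity_pct: float


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df: tuple[int, int]
    p_value: float


def theoretical_abundance(
    coverage_table: pd.DataFrame,
    community: MockCommunity,
) -> list[TheoreticalMeasurement]:
    """measured(pair, group) = coverage(pair, group) x true abundance(group).

    ``coverage_table`` is indexed by pair name with one column per group
    (as produced by the coverage engine); every column must have a
    community entry.
    """
    out = []
    for group in coverage_table.columns:
        if group not in community:
            raise KeyError(f"community has no abundance for group {group!r}")
        true = community[group]
        for pair_name, cov in coverage_table[group].items():
            cov = float(cov)
            out.append(
                TheoreticalMeasurement(pair_name, group, true, cov, cov * true)
            )
    return out


def measurements_to_frame(measurements: Sequence[TheoreticalMeasurement]) -> pd.DataFrame:
    """Pair x group table of measured copies/mL."""
    df = pd.DataFrame(
        [(m.pair_name, m.group_label, m.measured) for m in measurements],
        columns=["pair", "group", "measured"],
    )
    return df.pivot(index="pair", columns="group", values="measured")


def relative_abundance(
    measurements: Sequence[TheoreticalMeasurement],
    eub_group: str = "EUB",
) -> pd.DataFrame:
    """Normalize each pair's group measurements to its own EUB measurement.

    rel(pair, group) = measured(pair, group) / measured(pair, EUB).  Values
    may exceed 1 whenever a group's coverage exceeds the EUB coverage of the
    same pair — the central caution against this normalization — in which
    case a :class:`RelativeAbundanceWarning` is emitted.  Pairs whose EUB
    measurement is zero get NaN for every group (flagged, not dropped).
    """
    table = measurements_to_frame(measurements)
    if eub_group not in table.columns:
        raise KeyError(f"no {eub_group!r} measurement present")
    eub = table[eub_group]
    zero_pairs = eub.index[eub == 0].tolist()
    if zero_pairs:
        warnings.warn(
            f"zero {eub_group} measurement for pairs {zero_pairs}; relative "
            "abundances undefined (NaN) for those pairs",
            RelativeAbundanceWarning,
            stacklevel=2,
        )
    rel = table.div(eub.replace(0, np.nan), axis=0)
    over = rel.drop(columns=eub_group).stack()
    over = over[over > 1]
    if len(over):
        worst = over.idxmax()
        warnings.warn(
            f"relative abundance exceeds 1 for {len(over)} (pair, group) "
            f"cells (max {over.max():.3g} at {worst}); normalization to "
            "total eubacteria is not reliable",
            RelativeAbundanceWarning,
            stacklevel=2,
        )
    return rel


def percent_dissimilarity(x, y) -> float:
    """Bray-Curtis dissimilarity between two replicate vectors, in percent.

    D = sum|x_i - y_i| / sum(x_i + y_i) x 100; 0 for identical vectors,
    100 for disjoint supports.  Inputs must be non-negative and of equal
    length; two all-zero vectors make D undefined (ValueError).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size == 0:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 1")
    if (xa < 0).any() or (ya < 0).any():
        raise ValueError("abundance vectors must be non-negative")
    total = float(np.sum(xa + ya))
    if total == 0:
        raise ValueError("percent dissimilarity undefined for two all-zero vectors")
    return float(np.sum(np.abs(xa - ya)) / total * 100.0)


def pairwise_dissimilarity_matrix(
    sample_measurements: Mapping[str, Mapping[str, Sequence[float]]],
) -> list[DissimilarityResult]:
    """All unordered primer-pair dissimilarities for each sample.

    ``sample_measurements`` maps sample label -> {pair name -> replicate
    vector}.  For k pairs per sample, C(k, 2) comparisons are produced
    (an empty list for a single pair, which is not an error).
    """
    out = []
    for sample, by_pair in sample_measurements.items():
        for px, py in itertools.combinations(sorted(by_pair), 2):
            d = percent_dissimilarity(by_pair[px], by_pair[py])
            out.append(DissimilarityResult(sample, px, py, d))
    return out


def anova_two_way_no_rep(table: pd.DataFrame) -> tuple[AnovaResult, AnovaResult]:
    """Two-way ANOVA without replication (randomized-block decomposition).

    ``table`` holds one observation per (row factor, column factor) cell on
    the raw scale.  The classical additive model partitions SS into row,
    column and residual terms with df (a-1), (b-1) and (a-1)(b-1); no
    interaction term is estimable with a single observation per cell.
    Returns (row-effect result, column-effect result).

    The decomposition is computed directly so the perfectly additive table
    (zero residual SS) is handled exactly: a zero-SS effect then has F = 0,
    p = 1, a non-zero one F = inf, p = 0, instead of a 0/0 artifact.
    """
    if table.isna().any().any():
        raise ValueError("two-way ANOVA requires a complete table (no missing cells)")
    a, b = table.shape
    if a < 2 or b < 2:
        raise ValueError("each factor needs at least 2 levels")
    values = table.to_numpy(dtype=float)
    grand = values.mean()
    ss_row = b * float(((values.mean(axis=1) - grand) ** 2).sum())
    ss_col = a * float(((values.mean(axis=0) - grand) ** 2).sum())
    # residual = interaction-free remainder of the additive fit
    fitted = (values.mean(axis=1, keepdims=True)
              + values.mean(axis=0, keepdims=True) - grand)
    ss_res = float(((values - fitted) ** 2).sum())
    df_row, df_col, df_res = a - 1, b - 1, (a - 1) * (b - 1)

    def _one(effect: str, ss: float, df_eff: int) -> AnovaResult:
        if ss_res == 0.0:
            if ss == 0.0:
                return AnovaResult(effect, 0.0, (df_eff, df_res), 1.0)
            return AnovaResult(effect, float("inf"), (df_eff, df_res), 0.0)
        f = (ss / df_eff) / (ss_res / df_res)
        p = float(scipy.stats.f.sf(f, df_eff, df_res))
        return AnovaResult(effect, f, (df_eff, df_res), p)

    return (
        _one(table.index.name or "row", ss_row, df_row),
        _one(table.columns.name or "col", ss_col, df_col),
    )


def anova_one_way(groups: Sequence[Sequence[float]],
                  labels: Optional[Sequence[str]] = None) -> AnovaResult:
    """One-way ANOVA across replicate vectors (between/within decomposition).

    Each group needs >= 2 replicates.  When the within-group variance is
    exactly zero the F statistic is undefined; this degenerate case is
    reported explicitly as F = inf (differing means) or F = NaN with
    p = 1 (all observations identical) rather than raising inside scipy.
    """
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs at least 2 replicates")
    k = len(arrays)
    n = sum(g.size for g in arrays)
    df = (k - 1, n - k)
    within_ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    if within_ss == 0.0:
        means = [g.mean() for g in arrays]
        if np.ptp(means) == 0:
            return AnovaResult("group", float("nan"), df, 1.0)
        return AnovaResult("group", float("inf"), df, 0.0)
    stat = scipy.stats.f_oneway(*arrays)
    return AnovaResult("group", float(stat.statistic), df, float(stat.pvalue))
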