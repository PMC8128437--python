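"""qPCR quantification, tumor-burden metrics and cohort statistics.

qPCR quantities assume exact per-cycle doubling, so all relative levels are
powers of two of Ct differences:

* relative level vs a reference gene: ``2^(Ct_ref - Ct_target)``,
* recombined-allele fraction: ``rel_del / (rel_wt + rel_del)``,
* allele copy number: ``2 * rel_tumor / rel_normal`` (normal tissue carries
  two copies),
* relative expression: ``2^-dCt`` vs actin, or ``2^-ddCt`` when a calibrator
  dCt is supplied.

Tumor metrics use the ellipsoid approximation volume = L*W^2/2 (mm^3), with
per-mouse burden the sum of volumes and multiplicity the tumor count; sizes
are binned at 100 mm^3.  Group comparisons dispatch to the standard tests
(two-tailed Mann-Whitney U, two-sided Fisher exact, Kruskal-Wallis with
Dunn's post-hoc, one-way ANOVA with Holm-Sidak-adjusted pairwise t tests,
Spearman correlation).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SIZE_BIN_MM3 = 100.0


class InsufficientDataError(ValueError):
    """A statistical test was requested with too few observations."""


# -- qPCR --------------------------------------------------------------------


def relative_level(target_ct: float, reference_ct: float) -> float:
    """Relative abundance of the target vs the reference gene: 2^(dCt)."""
    return 2.0 ** (reference_ct - target_ct)


def recombination_fraction(rel_del: float, rel_wt: float) -> float:
    """Fraction of recombined template: rel_del / (rel_wt + rel_del)."""
    if rel_del < 0 or rel_wt < 0:
        raise ValueError("relative levels must be non-negative")
    total = rel_del + rel_wt
    if total == 0:
        return math.nan
    return rel_del / total


def copy_number(
    tumor_rel: float, normal_rel: float, reference_copies: float = 2.0
) -> float:
    """Allele copies in tumor relative to 2-copy normal tissue."""
    if normal_rel <= 0:
        raise ValueError("normal-tissue relative level must be positive")
    return reference_copies * tumor_rel / normal_rel


def expression_ddct(
    target_ct: float, actin_ct: float, calibrator_dct: float | None = None
) -> float:
    """Relative expression by the comparative Ct method.

    With a calibrator dCt this is 2^-ddCt; without one it is 2^-dCt
    normalised to actin.
    """
    dct = target_ct - actin_ct
    if calibrator_dct is not None:
        dct -= calibrator_dct
    return 2.0 ** (-dct)


def load_ct_table(path: str | Path) -> pd.DataFrame:
    """Load a Ct TSV (sample_id, target, ct[, replicate]).

    Replicates are averaged on the Ct scale; Ct values must be positive and
    finite.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "target", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive and finite")
    return (
        df.groupby(["sample_id", "target"], as_index=False)["ct"].mean()
    )


# -- tumor metrics ------------------------------------------------------------


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid approximation: volume = length * width^2 / 2 (mm^3)."""
    if length_mm < 0 or width_mm < 0:
        raise ValueError("tumor dimensions must be non-negative")
    if width_mm > length_mm:  # convention: length is the larger dimension
        length_mm, width_mm = width_mm, length_mm
    return 0.5 * length_mm * width_mm**2


@dataclass
class TumorMetrics:
    per_tumor: pd.DataFrame  # + volume_mm3, size_bin
    per_mouse: pd.DataFrame  # mouse_id, arm, burden_mm3, multiplicity
    per_arm_bins: pd.DataFrame  # arm, n_tumors, frac_ge_100, frac_lt_100


def tumor_metrics(
    records: pd.DataFrame,
    roster: pd.DataFrame | None = None,
    size_bin_mm3: float = SIZE_BIN_MM3,
) -> TumorMetrics:
    """Per-mouse burden/multiplicity and per-arm size-bin fractions.

    ``records`` needs columns mouse_id, arm, length_mm, width_mm.  A
    ``roster`` (mouse_id, arm) adds tumor-free mice as burden 0 /
    multiplicity 0 rows; the size binning is >= ``size_bin_mm3`` (inclusive)
    versus below.
    """
    df = records.copy()
    if (df[["length_mm", "width_mm"]] < 0).any().any():
        raise ValueError("tumor dimensions must be non-negative")
    df["volume_mm3"] = [
        tumor_volume(l, w) for l, w in zip(df["length_mm"], df["width_mm"])
    ]
    df["size_bin"] = np.where(
        df["volume_mm3"] >= size_bin_mm3, f">={size_bin_mm3:g}", f"<{size_bin_mm3:g}"
    )

    per_mouse = (
        df.groupby(["mouse_id", "arm"], as_index=False)
        .agg(burden_mm3=("volume_mm3", "sum"), multiplicity=("volume_mm3", "size"))
    )
    if roster is not None:
        missing = roster[~roster["mouse_id"].isin(per_mouse["mouse_id"])]
        if not missing.empty:
            zeros = missing[["mouse_id", "arm"]].copy()
            zeros["burden_mm3"] = 0.0
            zeros["multiplicity"] = 0
            per_mouse = pd.concat([per_mouse, zeros], ignore_index=True)
    per_mouse = per_mouse.sort_values("mouse_id", ignore_index=True)

    bins = []
    for arm, sub in df.groupby("arm"):
        n = len(sub)
        ge = int((sub["volume_mm3"] >= size_bin_mm3).sum())
        bins.append(
            {
                "arm": arm,
                "n_tumors": n,
                "frac_ge_100": ge / n if n else math.nan,
                "frac_lt_100": (n - ge) / n if n else math.nan,
            }
        )
    return TumorMetrics(df, per_mouse, pd.DataFrame(bins))


# -- group comparisons --------------------------------------------------------


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame | None = None  # group1, group2, statistic, p, p_adj
    extra: dict = field(default_factory=dict)


def _as_groups(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    return {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}


def _require_sizes(groups: Mapping[str, np.ndarray], minimum: int) -> None:
    small = [g for g, v in groups.items() if len(v) < minimum]
    if small:
        raise InsufficientDataError(
            f"groups {small} have fewer than {minimum} observations"
        )


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based z tests after Kruskal-Wallis, with tie correction."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in labels:
        n = len(groups[g])
        mean_ranks[g] = ranks[start : start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        se = math.sqrt(variance_base * (1 / len(groups[g1]) + 1 / len(groups[g2])))
        z = abs(mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(z)
        rows.append({"group1": g1, "group2": g2, "statistic": z, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="holm-sidak")[1]
    return out


def _pairwise_t(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        t, p = stats.ttest_ind(groups[g1], groups[g2], equal_var=True)
        rows.append({"group1": g1, "group2": g2, "statistic": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="holm-sidak")[1]
    return out


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]] | Sequence[Sequence[int]],
    test: str,
) -> ComparisonResult:
    """Dispatch a named statistical comparison.

    ``values_by_group`` is a mapping group label -> observations for the rank
    and ANOVA tests, a 2x2 count table for ``fisher_exact_2sided``, and a
    mapping with exactly two equal-length arrays (x, y) for ``spearman``.
    """
    if test == "fisher_exact_2sided":
        table = np.asarray(values_by_group, dtype=int)
        if table.shape != (2, 2):
            raise ValueError("Fisher exact test needs a 2x2 count table")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return ComparisonResult(test, float(odds), float(p))

    groups = _as_groups(values_by_group)

    if test == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("Mann-Whitney compares exactly two groups")
        _require_sizes(groups, 2)
        (a, b) = groups.values()
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return ComparisonResult(test, float(u), float(p))

    if test == "spearman":
        if len(groups) != 2:
            raise ValueError("Spearman needs paired x and y arrays")
        x, y = groups.values()
        if len(x) != len(y):
            raise ValueError("Spearman arrays must be paired (equal length)")
        if len(x) < 3:
            raise InsufficientDataError("Spearman needs at least 3 pairs")
        rho, p = stats.spearmanr(x, y)
        return ComparisonResult(test, float(rho), float(p))

    if test == "kruskal_dunn":
        _require_sizes(groups, 2)
        h, p = stats.kruskal(*groups.values())
        return ComparisonResult(test, float(h), float(p), _dunn_posthoc(groups))

    if test == "anova_holm_sidak":
        _require_sizes(groups, 2)
        f, p = stats.f_oneway(*groups.values())
        return ComparisonResult(test, float(f), float(p), _pairwise_t(groups))

    raise ValueError(f"unknown test {test!r}")
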