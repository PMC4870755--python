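"""Reproductive-capacity computations: qPCR copy-number quantification,
fold changes, developmental-efficiency indices, phenotype summaries, group
comparisons (normality-gated), exact Fisher tests, and Pearson correlations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import defaults
from .genome import MthapError


# ---------------------------------------------------------------------------
# qPCR standard curve and absolute quantification
# ---------------------------------------------------------------------------

@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r2: float
    amount_range: tuple[float, float] = (0.0, 0.0)  # min/max standard amount

    @property
    def efficiency(self) -> float:
        """Amplification efficiency: 1.0 means perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(standards: pd.DataFrame) -> StandardCurve:
    """OLS of Ct on log10(template amount) over a dilution series.

    Expects columns ``amount_ng`` and ``ct`` (>= 3 points).
    """
    if len(standards) < 3:
        raise MthapError("need >= 3 dilution points to fit a standard curve")
    amounts = standards["amount_ng"].to_numpy(dtype=float)
    ct = standards["ct"].to_numpy(dtype=float)
    if np.any(amounts <= 0):
        raise MthapError("template amounts must be positive")
    x = np.log10(amounts)
    if np.allclose(x, x[0]):
        raise MthapError("degenerate dilution series: all amounts identical")
    order = np.argsort(x)
    if np.any(np.diff(ct[order]) > 0):
        warnings.warn("Ct values are not monotone across the dilution series",
                      stacklevel=2)
    res = stats.linregress(x, ct)
    if res.slope >= 0:
        raise MthapError(f"standard-curve slope must be negative, "
                         f"got {res.slope:.3f}")
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r2=float(res.rvalue ** 2),
                         amount_range=(float(amounts.min()),
                                       float(amounts.max())))


def quantify_copies(ct: float, curve: StandardCurve,
                    length_bp: int = defaults.PIG_MTDNA_LENGTH,
                    dilution_factor: float = defaults.OOCYTE_DILUTION_FACTOR,
                    ) -> float:
    """Absolute copies per sample from a Ct against the standard curve.

    amount(ng) = 10^((Ct - intercept)/slope); copies per reaction convert at
    660 g/mol/bp; per-sample copies scale by the dilution factor (default 25:
    2 uL assayed of a 50 uL sample). Cts outside the standard range raise an
    extrapolation warning.
    """
    amount_ng = 10.0 ** ((ct - curve.intercept) / curve.slope)
    lo, hi = curve.amount_range
    if hi > 0 and not (lo <= amount_ng <= hi):
        warnings.warn(f"Ct {ct:.2f} implies {amount_ng:.3g} ng, outside the "
                      "standard range (extrapolation)", stacklevel=2)
    copies_rxn = (amount_ng * 1e-9 * defaults.AVOGADRO
                  / (length_bp * defaults.DNA_GRAMS_PER_MOL_BP))
    return copies_rxn * dilution_factor


def fold_change(numerator: Sequence[float],
                denominator: Sequence[float]) -> float:
    """mean(numerator) / mean(denominator), e.g. blastocyst over MII copies."""
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if len(num) == 0 or len(den) == 0:
        raise MthapError("both groups must be non-empty")
    dmean = den.mean()
    if dmean == 0:
        raise MthapError("denominator group has zero mean")
    return float(num.mean() / dmean)


# ---------------------------------------------------------------------------
# efficiency index
# ---------------------------------------------------------------------------

EFFICIENCY_STAGES = ("BCB_ratio", "maturation", "fertilization", "blastocyst")


def efficiency_index(stage_means: dict[str, dict[str, float]],
                     litter_means: dict[str, float]) -> pd.DataFrame:
    """Stage mean divided by mean litter size, per haplotype and stage.

    Lower values indicate more efficient conversion to offspring. Values are
    rounded to 4 decimals for reporting.
    """
    missing = set(stage_means) ^ set(litter_means)
    if missing:
        raise MthapError(f"haplotype keys do not match: {sorted(missing)}")
    rows = []
    for hap in sorted(stage_means):
        litter = litter_means[hap]
        if litter <= 0:
            raise MthapError(f"litter mean for {hap} must be positive")
        for stage, value in stage_means[hap].items():
            if value < 0:
                raise MthapError(f"{hap}/{stage}: stage mean must be >= 0")
            rows.append((hap, stage, round(value / litter, 4)))
    return pd.DataFrame(rows, columns=["haplotype", "stage", "index"])


# ---------------------------------------------------------------------------
# phenotype summaries
# ---------------------------------------------------------------------------

def summarize_phenotypes(sows: pd.DataFrame,
                         hyperprolific_litter: int = 15,
                         hyperprolific_times: int = 3) -> pd.DataFrame:
    """Per-haplotype litter summary with each parity as one observation.

    Live born per litter = litter size - stillborn; SEM = SD/sqrt(n litters).
    A sow is flagged hyperprolific when >= ``hyperprolific_times`` of her
    parities reached >= ``hyperprolific_litter`` piglets. Sows with zero
    parities are excluded.
    """
    df = sows.copy()
    if (df["stillborn"] > df["litter_size"]).any():
        raise MthapError("stillborn exceeds litter size in input")
    df["live_born"] = df["litter_size"] - df["stillborn"]

    rows = []
    for hap, g in df.groupby("haplotype", sort=True):
        n_litters = len(g)
        by_sow = g.groupby("sow_id")
        hyper = sum(
            (sow_g["litter_size"] >= hyperprolific_litter).sum()
            >= hyperprolific_times
            for _, sow_g in by_sow)
        sem = lambda v: float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0
        rows.append(dict(
            haplotype=hap,
            n_sows=by_sow.ngroups,
            n_litters=n_litters,
            litter_mean=float(g["litter_size"].mean()),
            litter_sem=sem(g["litter_size"]),
            stillborn_mean=float(g["stillborn"].mean()),
            stillborn_sem=sem(g["stillborn"]),
            live_mean=float(g["live_born"].mean()),
            live_sem=sem(g["live_born"]),
            n_hyperprolific_sows=int(hyper),
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_value: float


@dataclass
class GroupComparisonReport:
    design: str
    family: str                 # parametric | rank
    omnibus_statistic: float
    omnibus_p: float
    normality_p: dict[str, float] = field(default_factory=dict)
    pairwise: list[PairwiseResult] = field(default_factory=list)


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> list[PairwiseResult]:
    """Dunn's post-hoc z tests on mean ranks after a Kruskal-Wallis test."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    mean_ranks, sizes = {}, {}
    i = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[i: i + k].mean()
        sizes[g] = k
        i += k
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    out = []
    for a, b in combinations(names, 2):
        se = math.sqrt((n * (n + 1) / 12.0 - tie_term)
                       * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        out.append(PairwiseResult(a, b, float(z), float(p)))
    return out


def group_comparison(values_by_group: dict[str, Sequence[float]],
                     design: str = "auto",
                     reference: Optional[str] = None,
                     alpha: float = 0.05) -> GroupComparisonReport:
    """Omnibus + pairwise comparison across haplotype groups.

    Designs: ``anova_vs_reference`` (one-way ANOVA, multiple comparison
    against a reference group), ``anova_tukey``, ``kruskal_dunn``,
    ``t_test`` (two groups), or ``auto``. With ``auto`` — and as a gate for
    the parametric designs — Shapiro-Wilk normality at the given alpha routes
    to the parametric or rank-based family.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise MthapError("need >= 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise MthapError(f"group {g} has < 2 observations")
        if np.all(v == v[0]):
            raise MthapError(f"group {g} has zero variance")

    normality = {}
    for g, v in groups.items():
        normality[g] = float(stats.shapiro(v).pvalue) if 3 <= len(v) <= 5000 else 1.0
    normal = all(p >= alpha for p in normality.values())

    if design == "auto":
        design = "anova_vs_reference" if normal else "kruskal_dunn"
    if design in ("anova_vs_reference", "anova_tukey") and not normal:
        design = "kruskal_dunn"

    names = list(groups)
    arrays = [groups[g] for g in names]
    pairwise: list[PairwiseResult] = []

    if design == "t_test":
        if len(names) != 2:
            raise MthapError("t_test design needs exactly 2 groups")
        res = stats.ttest_ind(arrays[0], arrays[1])
        return GroupComparisonReport(
            design=design, family="parametric",
            omnibus_statistic=float(res.statistic), omnibus_p=float(res.pvalue),
            normality_p=normality,
            pairwise=[PairwiseResult(names[0], names[1],
                                     float(res.statistic), float(res.pvalue))])

    if design == "kruskal_dunn":
        stat, p = stats.kruskal(*arrays)
        return GroupComparisonReport(
            design=design, family="rank",
            omnibus_statistic=float(stat), omnibus_p=float(p),
            normality_p=normality, pairwise=_dunn_pairwise(groups))

    stat, p = stats.f_oneway(*arrays)
    if design == "anova_tukey":
        res = stats.tukey_hsd(*arrays)
        for i, j in combinations(range(len(names)), 2):
            pairwise.append(PairwiseResult(
                names[i], names[j], float(res.statistic[i][j]),
                float(res.pvalue[i][j])))
    elif design == "anova_vs_reference":
        ref = reference if reference is not None else names[0]
        if ref not in groups:
            raise MthapError(f"reference group {ref!r} not present")
        others = [g for g in names if g != ref]
        res = stats.dunnett(*[groups[g] for g in others],
                            control=groups[ref])
        for g, st, pv in zip(others, np.atleast_1d(res.statistic),
                             np.atleast_1d(res.pvalue)):
            pairwise.append(PairwiseResult(ref, g, float(st), float(pv)))
    else:
        raise MthapError(f"unknown design {design!r}")
    return GroupComparisonReport(
        design=design, family="parametric",
        omnibus_statistic=float(stat), omnibus_p=float(p),
        normality_p=normality, pairwise=pairwise)


# ---------------------------------------------------------------------------
# Fisher's exact test (exact enumeration)
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p for table [[a, b], [c, d]].

    Exact hypergeometric enumeration over all tables with the observed
    margins: p = sum of probabilities of tables no more probable than the
    observed one. Returned as an exact Fraction.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise MthapError("table entries must be non-negative integers")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise MthapError("empty table")
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return total


def proportion_test(counts_by_group: dict[str, tuple[int, int]]
                    ) -> pd.DataFrame:
    """Pairwise two-sided Fisher exact tests on success/total counts."""
    for g, (succ, total) in counts_by_group.items():
        if total <= 0:
            raise MthapError(f"group {g} has zero total")
        if not 0 <= succ <= total:
            raise MthapError(f"group {g}: successes outside [0, total]")
    rows = []
    for ga, gb in combinations(sorted(counts_by_group), 2):
        sa, ta = counts_by_group[ga]
        sb, tb = counts_by_group[gb]
        p = fisher_exact_two_sided(sa, ta - sa, sb, tb - sb)
        rows.append((ga, gb, sa, ta, sb, tb, float(p)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "success_a",
                                       "total_a", "success_b", "total_b",
                                       "p_value"])


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def correlate(x: Sequence[float], y: Sequence[float]
              ) -> tuple[float, float, float]:
    """Pearson r, R^2 and two-tailed p (t transform, n-2 df)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya):
        raise MthapError("x and y must be paired")
    if len(xa) < 3:
        raise MthapError("need >= 3 paired observations")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise MthapError("zero variance in x or y")
    res = stats.pearsonr(xa, ya)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)
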