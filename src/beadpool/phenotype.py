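"""Phenotype statistics for the 2x2 diet design.

Covers group summaries (mean +/- SEM with per-metric n), exact small-sample
Mann-Whitney U tests, the two-stage contrast scheme used for the diet
factors (combined-group test first, then each diet against its own control
with Bonferroni correction over the follow-up family), and the diet energy
arithmetic (Atwater factors 4/4/9 kcal per g of protein/carbohydrate/fat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .ftest import bonferroni

#: Pooling of the four diet groups by experimental factor.
FACTOR_POOLS = {
    "fat-content": (("HFD", "HFD+BB"), ("NCD", "NCD+BB")),
    "bilberry": (("NCD+BB", "HFD+BB"), ("NCD", "HFD")),
}

#: Diet-versus-own-control pairs tested in the follow-up stage.
FOLLOWUP_PAIRS = {
    "fat-content": (("HFD", "NCD"), ("HFD+BB", "NCD+BB")),
    "bilberry": (("NCD+BB", "NCD"), ("HFD+BB", "HFD")),
}

#: Largest combined sample size for which the exact Mann-Whitney null
#: distribution is enumerated; beyond it the tie-corrected normal
#: approximation is used and flagged.
EXACT_LIMIT = 20


def group_summary(records: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Mean and SEM of one metric per group, with the non-missing n.

    Groups where the metric is entirely missing are omitted (with the
    standard pandas missing-data semantics, not an error), so tables can
    report per-metric n the way study tables print "(4)" after a value.
    """
    if metric not in records.columns:
        raise ValidationError(f"unknown metric {metric!r}")
    rows = []
    for group, sub in records.groupby("group", sort=False):
        vals = sub[metric].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            {
                "group": group,
                "metric": metric,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sem": sd / math.sqrt(vals.size),
            }
        )
    return pd.DataFrame(rows, columns=["group", "metric", "n", "mean", "sem"])


def _rank_sum_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """U statistics for both samples via average ranks of the pooled data."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # average ranks under ties
    ra = ranks[: a.size].sum()
    ua = ra - a.size * (a.size + 1) / 2.0
    ub = a.size * b.size - ua
    return ua, ub


@dataclass
class MannWhitneyResult:
    u: float  # min(U_a, U_b)
    p: float  # two-sided
    exact: bool
    n_a: int
    n_b: int


def mann_whitney_exact(
    a,
    b,
    two_sided: str = "double",
) -> MannWhitneyResult:
    """Mann-Whitney U test with an exact small-sample p-value.

    For combined n <= 20 the null distribution of U is enumerated over all
    C(n_a + n_b, n_a) group labelings of the pooled values (ties handled by
    average ranks, so the enumeration is exact under ties too).  Larger
    samples fall back to the tie-corrected normal approximation, flagged via
    ``exact=False``.

    The reported U is min(U_a, U_b).  ``two_sided="double"`` doubles the
    lower tail P(U <= u_obs) and caps at 1; ``two_sided="two-tails"`` sums
    both tails of the (symmetric) null distribution instead.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    if two_sided not in ("double", "two-tails"):
        raise ValidationError("two_sided must be 'double' or 'two-tails'")
    ua, ub = _rank_sum_u(a, b)
    u_obs = min(ua, ub)
    n_a, n_b = int(a.size), int(b.size)

    if n_a + n_b <= EXACT_LIMIT:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        base = n_a * (n_a + 1) / 2.0
        # null distribution of U_a over every labeling of the pooled values
        ua_all = np.asarray(
            [
                sum(ranks[i] for i in combo) - base
                for combo in combinations(range(n_a + n_b), n_a)
            ]
        )
        total = ua_all.size
        eps = 1e-9
        lower = ua_all <= u_obs + eps
        if two_sided == "double":
            p = 2.0 * np.count_nonzero(lower) / total
        else:
            upper = ua_all >= n_a * n_b - u_obs - eps
            p = np.count_nonzero(lower | upper) / total
        return MannWhitneyResult(float(u_obs), min(1.0, float(p)), True, n_a, n_b)

    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(float(u_obs), float(res.pvalue), False, n_a, n_b)


@dataclass
class DietContrastReport:
    """Two-stage contrast of a metric across the 2x2 diet design."""

    metric: str
    factor: str
    combined: MannWhitneyResult
    followups: pd.DataFrame  # pair, u, p, p_bonf, exact
    differences: pd.DataFrame = field(default_factory=pd.DataFrame)
    # pair, mean_diet, mean_control, abs_diff, pct_diff


def combined_diet_contrast(
    records: pd.DataFrame, metric: str, factor: str
) -> DietContrastReport:
    """Combined-group Mann-Whitney test plus per-pair follow-ups.

    Stage 1 pools the four groups by ``factor`` ("fat-content": high-fat
    diets vs control diets; "bilberry": supplemented vs unsupplemented) and
    tests the pooled samples.  Stage 2 tests each diet against its own
    control, Bonferroni-corrected over the follow-up family (2 tests).
    The report also gives the absolute and percent difference of group
    means for each follow-up pair.
    """
    if factor not in FACTOR_POOLS:
        raise ValidationError(
            f"unknown factor {factor!r}; expected one of {sorted(FACTOR_POOLS)}"
        )
    if metric not in records.columns:
        raise ValidationError(f"unknown metric {metric!r}")
    present = set(records["group"])
    needed = {g for pool in FACTOR_POOLS[factor] for g in pool}
    if not needed <= present:
        raise ValidationError(f"missing group(s): {sorted(needed - present)}")

    def values(groups) -> np.ndarray:
        sel = records["group"].isin(groups)
        return records.loc[sel, metric].dropna().to_numpy(dtype=float)

    pool_hi, pool_lo = FACTOR_POOLS[factor]
    combined = mann_whitney_exact(values(pool_hi), values(pool_lo))

    rows, diffs = [], []
    raw_ps = []
    for diet, control in FOLLOWUP_PAIRS[factor]:
        res = mann_whitney_exact(values([diet]), values([control]))
        rows.append(
            {
                "pair": f"{diet} vs {control}",
                "u": res.u,
                "p": res.p,
                "exact": res.exact,
            }
        )
        raw_ps.append(res.p)
        m_diet = float(values([diet]).mean())
        m_ctrl = float(values([control]).mean())
        diffs.append(
            {
                "pair": f"{diet} vs {control}",
                "mean_diet": m_diet,
                "mean_control": m_ctrl,
                "abs_diff": m_diet - m_ctrl,
                "pct_diff": 100.0 * (m_diet - m_ctrl) / m_ctrl if m_ctrl != 0 else np.nan,
            }
        )
    followups = pd.DataFrame(rows)
    followups["p_bonf"] = bonferroni(raw_ps, len(raw_ps))
    return DietContrastReport(
        metric=metric,
        factor=factor,
        combined=combined,
        followups=followups,
        differences=pd.DataFrame(diffs),
    )


# Diet energy arithmetic -----------------------------------------------------

#: Atwater energy factors, kcal per gram.
ATWATER = {"protein": 4.0, "carbohydrate": 4.0, "fat": 9.0}


@dataclass(frozen=True)
class DietSpec:
    """Macronutrient composition of a diet, grams per 100 g of feed."""

    name: str
    protein: float
    carbohydrate: float
    fat: float
    factors: tuple[float, float, float] = (
        ATWATER["protein"],
        ATWATER["carbohydrate"],
        ATWATER["fat"],
    )

    def __post_init__(self) -> None:
        if min(self.protein, self.carbohydrate, self.fat) < 0:
            raise ValidationError("macronutrient grams must be non-negative")
        if min(self.factors) <= 0:
            raise ValidationError("energy factors must be positive")

    @property
    def macro_kcal(self) -> tuple[float, float, float]:
        fp, fc, ff = self.factors
        return (fp * self.protein, fc * self.carbohydrate, ff * self.fat)


def energy_density(diet: DietSpec) -> float:
    """Energy density in kcal per gram of feed (per-100 g composition)."""
    return sum(diet.macro_kcal) / 100.0


def energy_share(diet: DietSpec, macronutrient: str) -> float:
    """Percent of total energy contributed by one macronutrient (unrounded)."""
    order = ("protein", "carbohydrate", "fat")
    if macronutrient not in order:
        raise ValidationError(f"unknown macronutrient {macronutrient!r}")
    kcal = dict(zip(order, diet.macro_kcal))
    total = sum(kcal.values())
    if total == 0:
        raise ValidationError("diet has zero total energy")
    return 100.0 * kcal[macronutrient] / total
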