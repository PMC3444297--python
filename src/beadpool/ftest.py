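"""The pooled-design variance-ratio (F) test.

A pooled design hybridizes a single RNA pool per condition, so there are no
biological replicates and an ordinary ANOVA is impossible.  The test
implemented here substitutes the technical bead-level replicates: for each
probe the between-treatment variance is the sample variance of the k group
means, the within-treatment variance comes from the bead intensity variance
reported by the scanner software, and the ratio is referred to an F
distribution whose denominator degrees of freedom are set to the average
number of beads used for that probe.  This is deliberately rough — it is a
screening statistic for a design with n=1 per condition, not a calibrated
ANOVA — and the defaults below expose rather than hide its ambiguities:

* numerator df defaults to the conventional k-1, with a switch to set both
  dfs to the average bead count (the literal reading of "degrees of freedom
  set to the average number of beads");
* the within-variance defaults to the variance of each group *mean*
  (bead_variance / n_beads), dimensionally matching the between-variance of
  group means, with a switch for the unscaled bead variance.

Both raw-scale and log2-scale testing are supported; on the log2 scale the
bead variances are mapped through the delta method,
``var_log2 = var / ((signal + offset)^2 * ln(2)^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BeadSummary, NormalizedMatrix
from .errors import ValidationError

DF1_GROUPS_MINUS_ONE = "groups-minus-one"
DF1_AVERAGE_BEADS = "average-beads"
DF2_AVERAGE_BEADS = "average-beads"
DF2_AVERAGE_BEADS_MINUS_ONE = "average-beads-minus-one"


@dataclass
class FTestConfig:
    """Configuration of the pooled-variance F test.

    alpha / strict_alpha are the primary and secondary significance levels
    used in downstream screens; df rules and scale are documented in the
    module docstring.  ``integer_df`` rounds the average bead count to an
    integer df with round-half-to-even; the F distribution also accepts
    fractional dfs, so rounding can be disabled.
    """

    alpha: float = 0.05
    strict_alpha: float = 0.01
    df1_rule: str = DF1_GROUPS_MINUS_ONE
    df2_rule: str = DF2_AVERAGE_BEADS
    scale: str = "log2"
    offset: float = 1.0
    variance_of_mean: bool = True
    integer_df: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.strict_alpha <= self.alpha < 1.0):
            raise ValidationError("need 0 < strict_alpha <= alpha < 1")
        if self.df1_rule not in (DF1_GROUPS_MINUS_ONE, DF1_AVERAGE_BEADS):
            raise ValidationError(f"unknown df1_rule {self.df1_rule!r}")
        if self.df2_rule not in (DF2_AVERAGE_BEADS, DF2_AVERAGE_BEADS_MINUS_ONE):
            raise ValidationError(f"unknown df2_rule {self.df2_rule!r}")
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")


@dataclass
class FTestResult:
    """Per-probe F statistics with raw and Bonferroni-adjusted p-values."""

    table: pd.DataFrame  # probe_id index; between, within, F, df1, df2, p, p_bonf, degenerate
    config: FTestConfig = field(default_factory=FTestConfig)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_tested(self) -> int:
        return len(self.table)

    @property
    def n_significant_raw(self) -> int:
        """Probes with raw p below the primary level."""
        return int((self.table["p"] < self.config.alpha).sum())

    @property
    def n_significant_bonf(self) -> int:
        """Probes with Bonferroni-adjusted p below the primary level."""
        return int((self.table["p_bonf"] < self.config.alpha).sum())

    def significant(self, level: float | None = None, adjusted: bool = False) -> list[str]:
        level = self.config.alpha if level is None else level
        col = "p_bonf" if adjusted else "p"
        return list(self.table.index[self.table[col] < level])


def within_treatment_variance(
    bs: BeadSummary,
    probe: str | None = None,
    groups: list[str] | None = None,
    variance_of_mean: bool = True,
) -> pd.Series | float:
    """Within-treatment variance per probe, from the bead-level variances.

    The default estimate is the mean over the selected groups of
    ``bead_variance / n_beads`` — the variance of each group's *mean*
    intensity — so it is commensurable with the between-variance of group
    means.  ``variance_of_mean=False`` averages the unscaled bead variances
    instead.  Returns a Series over all probes, or a scalar when ``probe``
    is given.
    """
    groups = list(bs.group_labels) if groups is None else list(groups)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    var = bs.bead_variance[groups]
    nb = bs.n_beads[groups]
    if (nb.to_numpy() < 1).any():
        raise ValidationError("n_beads must be >= 1")
    per_group = var / nb if variance_of_mean else var
    out = per_group.mean(axis=1)
    if probe is not None:
        if probe not in out.index:
            raise ValidationError(f"unknown probe {probe!r}")
        return float(out.loc[probe])
    return out


def between_treatment_variance(means) -> float | np.ndarray:
    """Sample variance (denominator k-1) of k group means.

    Accepts a 1-D array of group means (returns a scalar) or a probes x
    groups 2-D array / DataFrame (returns a per-probe vector).
    """
    x = np.asarray(means, dtype=float)
    if x.ndim == 1:
        if x.size < 2:
            raise ValidationError("need at least 2 group means")
        return float(np.var(x, ddof=1))
    if x.shape[1] < 2:
        raise ValidationError("need at least 2 group means")
    return np.var(x, axis=1, ddof=1)


def _round_half_even(x: np.ndarray) -> np.ndarray:
    return np.rint(x)  # numpy rounds half to even


def adhoc_f_test(
    bs: BeadSummary,
    config: FTestConfig | None = None,
    means: NormalizedMatrix | None = None,
) -> FTestResult:
    """Run the pooled-design F test on every probe.

    Parameters
    ----------
    bs
        Bead summary on the raw linear scale (source of bead variances and
        bead counts, and of the group means when ``means`` is omitted).
    config
        Test configuration; defaults to log2-scale testing.
    means
        Optional normalized log2 matrix whose columns replace the group
        means (e.g. after quantile normalization).  Bead variances are not
        rescaled by the normalization map; on the log2 scale they are
        delta-method converted against the raw signals.

    Degenerate probes (within-variance exactly 0) get p = 1 when the group
    means are also equal and p = 0 with ``degenerate=True`` otherwise.
    """
    config = FTestConfig() if config is None else config
    groups = bs.group_labels
    k = len(groups)
    if k < 2:
        raise ValidationError("need at least 2 groups")

    raw = bs.mean_signal.to_numpy(dtype=float)
    if not np.isfinite(raw).all():
        bad = bs.mean_signal.index[~np.isfinite(raw).all(axis=1)][0]
        raise ValidationError(f"non-finite signal for probe {bad!r}")

    within = within_treatment_variance(
        bs, variance_of_mean=config.variance_of_mean
    ).to_numpy()
    if config.scale == "log2":
        if means is not None:
            if list(means.values.index) != bs.probe_ids:
                raise ValidationError("means matrix not aligned with bead summary")
            m = means.values[groups].to_numpy(dtype=float)
        else:
            m = np.log2(raw + config.offset)
        # delta method: var(log2 f(X)) ~ var(X) / ((x + offset)^2 ln(2)^2),
        # applied per group then averaged, mirroring within_treatment_variance
        per_group = bs.bead_variance.to_numpy(dtype=float)
        if config.variance_of_mean:
            per_group = per_group / bs.n_beads.to_numpy(dtype=float)
        per_group = per_group / ((raw + config.offset) ** 2 * np.log(2.0) ** 2)
        within = per_group.mean(axis=1)
    else:
        m = raw

    between = between_treatment_variance(m)

    nb_mean = bs.n_beads.to_numpy(dtype=float).mean(axis=1)
    df2 = nb_mean if config.df2_rule == DF2_AVERAGE_BEADS else nb_mean - 1.0
    df1 = np.full_like(df2, float(k - 1)) if config.df1_rule == DF1_GROUPS_MINUS_ONE else df2.copy()
    if config.integer_df:
        df1 = _round_half_even(df1)
        df2 = _round_half_even(df2)
    df2 = np.maximum(df2, 1.0)

    degenerate = within == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(degenerate, np.where(between > 0, np.inf, 0.0), between / np.where(degenerate, 1.0, within))
    p = np.empty_like(F)
    ok = ~degenerate
    p[ok] = stats.f.sf(F[ok], df1[ok], df2[ok])
    p[degenerate & (between > 0)] = 0.0
    p[degenerate & (between == 0)] = 1.0

    m_tests = len(p)
    table = pd.DataFrame(
        {
            "between_variance": between,
            "within_variance": within,
            "F": F,
            "df1": df1,
            "df2": df2,
            "p": p,
            "p_bonf": bonferroni(p, m_tests),
            "degenerate": degenerate & (between > 0),
        },
        index=bs.mean_signal.index,
    )
    return FTestResult(table, config)


def bonferroni(p, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m * p)`` elementwise.

    ``m`` defaults to the vector length; values larger than the length are
    allowed (testing a subset of a larger family).
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    if m < p.size:
        raise ValidationError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)
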