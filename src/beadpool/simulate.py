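"""Seeded synthetic-data generators with planted ground truth.

Two generators mirror the study design end to end so every pipeline stage
is testable without any external download:

* a bead-summary generator — one pooled array per diet group, ~30 bead
  replicates per probe, bead-level noise normal on the log2 scale (i.e.
  lognormal intensities), and an optional planted-effect table of per-group
  log2 shifts (defaulting to nothing; a crystallin-patterned 13-probe block
  is available from :mod:`beadpool.datasets`);
* a phenotype generator — 24 mice in four groups of six, normal draws per
  metric around the printed group means, weekly weight trajectories that
  diverge between the high-fat and control arms from a configurable week,
  and cage-level intake metrics attributed to both cage mates.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .containers import DEFAULT_GROUPS, SCALE_LINEAR, BeadSummary
from .errors import ValidationError


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    planted_shifts: pd.DataFrame | None = None  # probes x groups, log2 units
    phenotype_means: dict[str, dict[str, float]] = field(default_factory=dict)
    phenotype_sds: dict[str, dict[str, float]] = field(default_factory=dict)

    def planted_probes(self) -> list[str]:
        if self.planted_shifts is None:
            return []
        nonzero = (self.planted_shifts != 0).any(axis=1)
        return list(self.planted_shifts.index[nonzero])


@dataclass
class SimConfig:
    """Configuration of the bead-summary generator.

    Baseline log2 expression is drawn per probe from
    ``Normal(baseline_mean, baseline_sd)``; bead counts per probe x group
    are ``max(min_beads, Poisson(mean_beads))``; individual bead intensities
    are the probe baseline plus the planted group shift plus
    ``Normal(0, noise_sd)``, all in log2 units, exponentiated to the linear
    scale before summarization.  ``planted_effects`` maps probe id ->
    {group: log2 shift}; planted probes are placed first in the emitted
    probe order under their own ids.
    """

    seed: int
    n_probes: int = 5000
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    mean_beads: float = 30.0
    min_beads: int = 5
    noise_sd: float = 0.5
    planted_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    unexpressed_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_probes < len(self.planted_effects):
            raise ValidationError("n_probes smaller than the planted block")
        if self.n_probes < 1 or len(self.group_labels) < 2:
            raise ValidationError("need >=1 probe and >=2 groups")
        if self.baseline_sd < 0 or self.noise_sd < 0:
            raise ValidationError("spreads must be non-negative")
        if self.min_beads < 2:
            raise ValidationError("min_beads must be >= 2 (bead variance needs n >= 2)")
        if not 0.0 <= self.unexpressed_fraction <= 1.0:
            raise ValidationError("unexpressed_fraction must lie in [0, 1]")
        for pid, shifts in self.planted_effects.items():
            unknown = set(shifts) - set(self.group_labels)
            if unknown:
                raise ValidationError(
                    f"planted effect for {pid!r} names unknown group(s) {sorted(unknown)}"
                )


def crystallin_block_config(
    seed: int, n_probes: int = 5000, **overrides
) -> SimConfig:
    """A SimConfig with the 13-probe crystallin-patterned planted block.

    The block plants the induction-and-partial-reversion pattern: strong
    upward shifts in the high-fat group, smaller shifts in the supplemented
    groups, relative to the control baseline.
    """
    return SimConfig(
        seed=seed,
        n_probes=n_probes,
        planted_effects=datasets.crystallin_shift_table(),
        **overrides,
    )


def generate_bead_summary(cfg: SimConfig) -> tuple[BeadSummary, SyntheticTruth]:
    """Simulate a pooled one-array-per-group bead-summary matrix."""
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.group_labels)
    G = len(groups)
    P = cfg.n_probes

    planted_ids = list(cfg.planted_effects)
    n_fill = P - len(planted_ids)
    probe_ids = planted_ids + [f"probe_{i:05d}" for i in range(1, n_fill + 1)]

    shifts = pd.DataFrame(0.0, index=probe_ids, columns=groups)
    for pid, by_group in cfg.planted_effects.items():
        for g, s in by_group.items():
            shifts.at[pid, g] = float(s)

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, P)
    n_beads = np.maximum(rng.poisson(cfg.mean_beads, (P, G)), cfg.min_beads)
    nmax = int(n_beads.max())
    noise = rng.normal(0.0, cfg.noise_sd, (P, G, nmax)) if cfg.noise_sd > 0 else np.zeros((P, G, nmax))
    mask = np.arange(nmax)[None, None, :] < n_beads[:, :, None]

    log2_beads = baseline[:, None, None] + shifts.to_numpy()[:, :, None] + noise
    beads = np.where(mask, np.exp2(log2_beads), 0.0)
    mean = beads.sum(axis=2) / n_beads
    # two-pass (centered) sample variance: avoids the cancellation of the
    # sum-of-squares formula and is exactly 0 for constant beads
    centered = np.where(mask, beads - mean[:, :, None], 0.0)
    var = (centered**2).sum(axis=2) / (n_beads - 1)

    n_unexpr = int(round(cfg.unexpressed_fraction * P))
    unexpressed = np.zeros(P, dtype=bool)
    if n_unexpr:
        # never mark planted probes as unexpressed
        candidates = np.arange(len(planted_ids), P)
        unexpressed[rng.choice(candidates, size=min(n_unexpr, candidates.size), replace=False)] = True
    det = rng.beta(1.0, 50.0, (P, G))
    det[unexpressed] = rng.uniform(0.0, 1.0, (int(unexpressed.sum()), G))

    idx = pd.Index(probe_ids, name="probe_id")
    bs = BeadSummary(
        mean_signal=pd.DataFrame(mean, index=idx, columns=groups),
        bead_variance=pd.DataFrame(var, index=idx, columns=groups),
        n_beads=pd.DataFrame(n_beads, index=idx, columns=groups),
        detection_p=pd.DataFrame(det, index=idx, columns=groups),
        scale=SCALE_LINEAR,
    )
    return bs, SyntheticTruth(planted_shifts=shifts)


# Phenotype generation -------------------------------------------------------

#: Cage intake metrics (per day, cage of two mice): mean and SD per group.
_DEFAULT_INTAKES = {
    "water": {"NCD": (4.0, 0.7), "NCD+BB": (3.3, 0.2), "HFD": (4.0, 0.35), "HFD+BB": (3.2, 0.35)},
    "feed": {"NCD": (3.3, 0.17), "NCD+BB": (3.4, 0.17), "HFD": (2.9, 0.1), "HFD+BB": (3.0, 0.1)},
    "energy": {"NCD": (12.6, 0.5), "NCD+BB": (12.5, 0.7), "HFD": (13.7, 0.35), "HFD+BB": (13.9, 1.4)},
}


def _default_metric_tables() -> tuple[dict, dict, dict]:
    means, sds, ns = {}, {}, {}
    for metric, per_group in datasets.PHENOTYPE_SUMMARIES.items():
        means[metric] = {g: m for g, (m, _s, _n) in per_group.items()}
        sds[metric] = {g: s * n**0.5 for g, (_m, s, n) in per_group.items()}
        ns[metric] = {g: n for g, (_m, _s, n) in per_group.items()}
    return means, sds, ns


@dataclass
class PhenoSimConfig:
    """Configuration of the 24-mouse phenotype generator.

    Metric means and SDs default to the printed end-of-study group
    summaries (SD recovered as SEM * sqrt(n)); per-metric missingness
    reproduces the printed per-metric n.  Weight trajectories share a
    common weekly gain until ``divergence_week``, after which the high-fat
    groups add ``extra_gain`` per week.  ``noise_scale`` multiplies every
    SD (0 gives a noiseless dataset with group means reproduced exactly).
    """

    seed: int
    n_per_group: int = 6
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    metric_means: dict[str, dict[str, float]] = field(default_factory=dict)
    metric_sds: dict[str, dict[str, float]] = field(default_factory=dict)
    metric_n: dict[str, dict[str, int]] = field(default_factory=dict)
    apply_missingness: bool = True
    n_weeks: int = 12
    start_weight: float = 20.0
    start_weight_sd: float = 1.0
    base_gain: float = 0.6  # g per week, all groups
    extra_gain: float = 0.225  # g per week added in high-fat groups
    divergence_week: int = 5
    weight_noise_sd: float = 0.3
    intake_tables: dict = field(default_factory=lambda: dict(_DEFAULT_INTAKES))
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.metric_means:
            m, s, n = _default_metric_tables()
            self.metric_means, self.metric_sds, self.metric_n = m, s, n
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be non-negative")
        if not 0 <= self.divergence_week <= self.n_weeks:
            raise ValidationError("divergence_week out of range")

    def noiseless(self) -> "PhenoSimConfig":
        """Copy of this config with all random spread and missingness off."""
        import copy

        cfg = copy.deepcopy(self)
        cfg.noise_scale = 0.0
        cfg.apply_missingness = False
        return cfg


def generate_phenotype(cfg: PhenoSimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a per-animal phenotype table for the four-group design.

    Returns one row per mouse with columns ``mouse_id``, ``group``, the
    end-of-study metrics, the cage intake metrics, and weekly weights
    ``weight_wk00`` ... ``weight_wk{n}``.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.group_labels)
    n = cfg.n_per_group
    rows: list[dict] = []
    for g in groups:
        for i in range(n):
            rows.append({"mouse_id": f"{g}_{i + 1}", "group": g})
    df = pd.DataFrame(rows)

    for metric in cfg.metric_means:
        vals = np.empty(len(df))
        for gi, g in enumerate(groups):
            mu = cfg.metric_means[metric][g]
            sd = cfg.metric_sds.get(metric, {}).get(g, 0.0) * cfg.noise_scale
            draw = rng.normal(mu, sd, n) if sd > 0 else np.full(n, mu)
            vals[gi * n : (gi + 1) * n] = np.maximum(draw, 0.0)
        df[metric] = vals
        if cfg.apply_missingness and metric in cfg.metric_n:
            for gi, g in enumerate(groups):
                keep = min(cfg.metric_n[metric].get(g, n), n)
                if keep < n:
                    drop = rng.choice(np.arange(n), size=n - keep, replace=False)
                    df.loc[df.index[gi * n + drop], metric] = np.nan

    # cage intakes: mice are housed in pairs; a cage draw is shared by both
    for metric, per_group in cfg.intake_tables.items():
        vals = np.empty(len(df))
        for gi, g in enumerate(groups):
            mu, sd = per_group[g]
            sd = sd * cfg.noise_scale
            n_cages = (n + 1) // 2
            cage_vals = rng.normal(mu, sd, n_cages) if sd > 0 else np.full(n_cages, mu)
            per_mouse = np.repeat(np.maximum(cage_vals, 0.0), 2)[:n]
            vals[gi * n : (gi + 1) * n] = per_mouse
        df[metric] = vals

    # weekly weight trajectories
    high_fat = {g for g in groups if g.startswith("HFD")}
    weeks = np.arange(cfg.n_weeks + 1)
    start = (
        rng.normal(cfg.start_weight, cfg.start_weight_sd * cfg.noise_scale, len(df))
        if cfg.start_weight_sd * cfg.noise_scale > 0
        else np.full(len(df), cfg.start_weight)
    )
    for wi, w in enumerate(weeks):
        gain = cfg.base_gain * w + np.array(
            [
                cfg.extra_gain * max(0, w - cfg.divergence_week)
                if g in high_fat
                else 0.0
                for g in df["group"]
            ]
        )
        noise = (
            rng.normal(0.0, cfg.weight_noise_sd * cfg.noise_scale, len(df))
            if wi > 0 and cfg.weight_noise_sd * cfg.noise_scale > 0
            else np.zeros(len(df))
        )
        df[f"weight_wk{w:02d}"] = np.maximum(start + gain + noise, 0.0)

    truth = SyntheticTruth(
        phenotype_means={m: dict(v) for m, v in cfg.metric_means.items()},
        phenotype_sds={
            m: {g: sd * cfg.noise_scale for g, sd in v.items()}
            for m, v in cfg.metric_sds.items()
        },
    )
    return df, truth
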