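"""Log-ratio contrast tables, fold-change screens, and cross-screens.

The study design compares a high-fat diet (HFD) and a control diet (NCD),
each with and without a 5% bilberry supplement (+BB).  The contrasts of
interest are diet-induced expression (HFD/NCD), supplement effects against
each background (NCD+BB/NCD, HFD+BB/HFD) and the combined arm (HFD+BB/NCD).
Because contrasts are log2 differences of group means, any contrast can be
derived from two others sharing a reference group:
``lr(C/B) = lr(C/A) - lr(B/A)`` — the composition identity used to fill in
a derived contrast column from printed pairwise columns.

Screens select probes by a p-value gate plus an absolute log-ratio cutoff
(the conventional ">=1.3-fold" screen is |lr| >= 0.4 in log2 units here),
and cross-screens intersect a base screen with probes moving in the
*opposite* direction in a comparison contrast — the question "which
diet-induced changes does the supplement revert?".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix, ProbeAnnotation
from .errors import ValidationError
from .ftest import FTestResult


def contrast_name(numerator: str, denominator: str) -> str:
    return f"{numerator}/{denominator}"


#: The four standard contrasts of the 2x2 diet design.
DEFAULT_PAIRS = (
    ("HFD", "NCD"),
    ("HFD+BB", "NCD"),
    ("NCD+BB", "NCD"),
    ("HFD+BB", "HFD"),
)


@dataclass
class ContrastTable:
    """Per-probe log2 ratios for a list of named, ordered group contrasts."""

    log_ratios: pd.DataFrame  # probe_id index; one column per contrast name
    pairs: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if set(self.log_ratios.columns) != set(self.pairs):
            raise ValidationError("contrast columns and pairs disagree")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.log_ratios.index)

    def column(self, contrast: str) -> pd.Series:
        if contrast not in self.log_ratios.columns:
            raise ValidationError(f"unknown contrast {contrast!r}")
        return self.log_ratios[contrast]

    def derive(self, numerator_contrast: str, denominator_contrast: str) -> pd.Series:
        """Compose two contrasts sharing a denominator into a third.

        Given lr(C/A) and lr(B/A), returns lr(C/B) = lr(C/A) - lr(B/A).
        """
        ca = self.pairs.get(numerator_contrast)
        ba = self.pairs.get(denominator_contrast)
        if ca is None or ba is None:
            raise ValidationError("unknown contrast name")
        if ca[1] != ba[1]:
            raise ValidationError(
                "contrasts must share a denominator group to compose"
            )
        out = self.column(numerator_contrast) - self.column(denominator_contrast)
        out.name = contrast_name(ca[0], ba[0])
        return out


@dataclass
class ScreenConfig:
    """Cutoffs for fold-change screens.

    ``log_ratio_cutoff`` of 0.4 log2 units is the ">=1.3-fold" convention
    (log2(1.3) = 0.379, quoted as 0.4).  ``secondary_cutoff`` 0 is the
    zero-cutoff variant: strictly opposite sign, no magnitude requirement.
    ``p_gate`` selects which p-value column gates screen membership.
    """

    log_ratio_cutoff: float = 0.4
    secondary_cutoff: float = 0.0
    p_column: str = "p"  # "p" (raw) or "p_bonf"
    p_level: float = 0.05

    def __post_init__(self) -> None:
        if self.log_ratio_cutoff < 0 or self.secondary_cutoff < 0:
            raise ValidationError("cutoffs must be non-negative")
        if self.p_column not in ("p", "p_bonf"):
            raise ValidationError("p_column must be 'p' or 'p_bonf'")


@dataclass
class ScreenResult:
    """Outcome of one screen: the selected probes plus gene-level counts."""

    name: str
    contrast: str
    direction: str  # "up" or "down"
    cutoff: float
    probes: list[str]
    genes: list[str] = field(default_factory=list)
    n_unknown: int = 0

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def build_contrasts(
    m: NormalizedMatrix, pairs=DEFAULT_PAIRS
) -> ContrastTable:
    """Build per-probe log2 ratios for ordered group pairs.

    lr = mean log2(numerator group) - mean log2(denominator group), i.e. a
    plain column difference of the log2 matrix.
    """
    cols = {}
    named: dict[str, tuple[str, str]] = {}
    for num, den in pairs:
        if num == den:
            raise ValidationError(f"contrast {num!r}/{den!r} is degenerate")
        for g in (num, den):
            if g not in m.values.columns:
                raise ValidationError(f"unknown group label {g!r}")
        name = contrast_name(num, den)
        cols[name] = m.values[num] - m.values[den]
        named[name] = (num, den)
    return ContrastTable(pd.DataFrame(cols), named)


def _gene_collapse(result: ScreenResult, annotation: ProbeAnnotation | None) -> None:
    if annotation is not None:
        result.genes, result.n_unknown = annotation.collapse(result.probes)


def threshold_screen(
    ct: ContrastTable,
    contrast: str,
    direction: str,
    cfg: ScreenConfig,
    gate: FTestResult,
    annotation: ProbeAnnotation | None = None,
) -> ScreenResult:
    """Select probes passing the p gate with |lr| >= cutoff in one direction.

    ``direction`` is "up" (lr >= +cutoff) or "down" (lr <= -cutoff); with a
    zero cutoff this degenerates to a strict sign test (lr > 0 / lr < 0).
    """
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    lr = ct.column(contrast)
    if list(gate.table.index) != list(lr.index):
        raise ValidationError("gate and contrast table cover different probes")
    passed = gate.table[cfg.p_column] < cfg.p_level
    c = cfg.log_ratio_cutoff
    if direction == "up":
        sel = lr >= c if c > 0 else lr > 0
    else:
        sel = lr <= -c if c > 0 else lr < 0
    probes = list(lr.index[passed & sel])
    result = ScreenResult(
        name=f"{contrast} {direction}",
        contrast=contrast,
        direction=direction,
        cutoff=c,
        probes=probes,
    )
    _gene_collapse(result, annotation)
    return result


def opposite_fc_screen(
    base: ScreenResult,
    ct: ContrastTable,
    comparison_contrast: str,
    cfg: ScreenConfig,
    cutoff: float | None = None,
    annotation: ProbeAnnotation | None = None,
) -> ScreenResult:
    """Intersect a base screen with opposite-direction movement elsewhere.

    Keeps base probes whose log ratio in ``comparison_contrast`` has the
    opposite sign and magnitude >= cutoff (strictly opposite sign when the
    cutoff is 0; lr == 0 never counts as opposite).  ``cutoff`` defaults to
    ``cfg.log_ratio_cutoff``; pass ``cfg.secondary_cutoff`` (0) for the
    zero-cutoff variant used when the strict screen returns too few genes.
    """
    lr = ct.column(comparison_contrast)
    missing = [p for p in base.probes if p not in lr.index]
    if missing:
        raise ValidationError(
            f"base screen probes absent from contrast table: {missing[:5]}"
        )
    c = cfg.log_ratio_cutoff if cutoff is None else cutoff
    if c < 0:
        raise ValidationError("cutoff must be non-negative")
    sub = lr.loc[base.probes]
    if base.direction == "up":
        sel = sub <= -c if c > 0 else sub < 0
    else:
        sel = sub >= c if c > 0 else sub > 0
    probes = list(sub.index[sel])
    result = ScreenResult(
        name=f"{base.name} vs {comparison_contrast} opposite",
        contrast=comparison_contrast,
        direction="down" if base.direction == "up" else "up",
        cutoff=c,
        probes=probes,
    )
    _gene_collapse(result, annotation)
    return result


def top_gene_table(
    gate: FTestResult,
    ct: ContrastTable,
    annotation: ProbeAnnotation | None = None,
    p_level: float = 0.01,
) -> pd.DataFrame:
    """Rank probes below a p level by ascending p, annotated with contrasts.

    Output columns: rank (1-based), probe_id, gene_symbol, entrez_id, the
    F-test p, and every contrast log-ratio column.  Ties in p are broken by
    descending F, then probe id, for a deterministic order.
    """
    if list(gate.table.index) != list(ct.log_ratios.index):
        raise ValidationError("gate and contrast table cover different probes")
    tab = gate.table[gate.table["p"] < p_level].copy()
    tab["_probe"] = tab.index
    tab = tab.sort_values(["p", "F", "_probe"], ascending=[True, False, True], kind="stable")
    order = tab.index
    out = pd.DataFrame({"probe_id": order})
    out.insert(0, "rank", np.arange(1, len(order) + 1))
    if annotation is not None:
        out["gene_symbol"] = [annotation.symbol(p) for p in order]
        out["entrez_id"] = [
            annotation.table["entrez_id"].get(p, pd.NA) for p in order
        ]
    out["p"] = tab["p"].to_numpy()
    for col in ct.log_ratios.columns:
        out[col] = ct.log_ratios.loc[order, col].to_numpy()
    return out


def screen_summary(screens: list[ScreenResult]) -> pd.DataFrame:
    """Summary table of screens: probe and gene counts side by side."""
    return pd.DataFrame(
        {
            "screen": [s.name for s in screens],
            "contrast": [s.contrast for s in screens],
            "direction": [s.direction for s in screens],
            "cutoff": [s.cutoff for s in screens],
            "n_probes": [s.n_probes for s in screens],
            "n_genes": [s.n_genes for s in screens],
            "n_unknown": [s.n_unknown for s in screens],
        }
    )
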