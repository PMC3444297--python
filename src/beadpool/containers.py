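"""In-memory containers for bead-summary expression data and its annotations.

Illumina BeadChips measure each probe with ~30 physical bead replicates per
array.  Scanner software summarizes these into per-probe aggregates: the mean
signal, the variance (or standard error) of the bead-level intensities, the
number of beads used, and a detection p-value against the negative-control
beads.  In a pooled design — one hybridized sample per condition — those
bead-level replicates are the only source of within-condition variance, which
is why they are carried as first-class data here rather than discarded after
summarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The four diet conditions of the study design this package models:
#: normal control diet, high-fat diet, and each supplemented with 5%
#: freeze-dried bilberries.
DEFAULT_GROUPS = ("NCD", "HFD", "NCD+BB", "HFD+BB")

SCALE_LINEAR = "linear"
SCALE_LOG2 = "log2"


def _check_frame(name: str, df: pd.DataFrame, probe_ids, group_labels) -> None:
    if list(df.index) != list(probe_ids):
        raise ValidationError(f"{name}: row index does not match probe_ids")
    if list(df.columns) != list(group_labels):
        raise ValidationError(f"{name}: columns do not match group_labels")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValidationError(f"{name}: contains non-finite values")


@dataclass
class BeadSummary:
    """Per-probe bead-summary statistics for one array per group.

    All matrices are probes x groups, indexed identically.  ``bead_variance``
    is the variance of the bead-level intensities within one array (squared
    intensity units), not the variance of the group mean; dividing by
    ``n_beads`` yields the variance of the mean.
    """

    mean_signal: pd.DataFrame
    bead_variance: pd.DataFrame
    n_beads: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    scale: str = SCALE_LINEAR

    def __post_init__(self) -> None:
        probes = self.mean_signal.index
        groups = self.mean_signal.columns
        if probes.has_duplicates:
            dups = probes[probes.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe_ids: {dups}")
        if groups.has_duplicates:
            raise ValidationError("duplicate group labels")
        if self.scale not in (SCALE_LINEAR, SCALE_LOG2):
            raise ValidationError(f"unknown scale {self.scale!r}")
        _check_frame("mean_signal", self.mean_signal, probes, groups)
        _check_frame("bead_variance", self.bead_variance, probes, groups)
        _check_frame("n_beads", self.n_beads, probes, groups)
        if (self.bead_variance.to_numpy() < 0).any():
            raise ValidationError("bead_variance must be non-negative")
        nb = self.n_beads.to_numpy()
        if (nb < 1).any():
            raise ValidationError("n_beads must be >= 1 everywhere")
        if not np.allclose(nb, np.rint(nb)):
            raise ValidationError("n_beads must be integral")
        if self.detection_p is not None:
            _check_frame("detection_p", self.detection_p, probes, groups)
            dp = self.detection_p.to_numpy()
            if ((dp < 0) | (dp > 1)).any():
                raise ValidationError("detection_p must lie in [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.mean_signal.index)

    @property
    def group_labels(self) -> list[str]:
        return list(self.mean_signal.columns)

    @property
    def n_probes(self) -> int:
        return self.mean_signal.shape[0]


@dataclass
class NormalizedMatrix:
    """A probes x groups expression matrix on the log2 scale.

    ``provenance`` records the transform chain applied (e.g.
    ``["log2(x+1)", "quantile"]``) so downstream results can state exactly
    how the values were produced.
    """

    values: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate probe_ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("values must be finite")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def group_labels(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProbeAnnotation:
    """Maps probe ids to gene symbols and (optionally missing) Entrez ids.

    Many-probes-to-one-gene is expected: bead-array manifests routinely carry
    two or more probes against the same transcript.
    """

    table: pd.DataFrame  # index probe_id; columns gene_symbol, entrez_id

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate probe_ids in annotation")
        for col in ("gene_symbol", "entrez_id"):
            if col not in self.table.columns:
                raise ValidationError(f"annotation missing column {col!r}")
        ez = self.table["entrez_id"]
        bad = ez.dropna() <= 0
        if bad.any():
            raise ValidationError("entrez_id must be positive where present")

    def symbol(self, probe_id: str) -> str | None:
        if probe_id not in self.table.index:
            return None
        sym = self.table.at[probe_id, "gene_symbol"]
        return None if pd.isna(sym) else str(sym)

    def collapse(self, probe_ids) -> tuple[list[str], int]:
        """Collapse probes to unique gene symbols.

        Returns the sorted unique symbols plus the count of probes without
        any annotation ("unknown"), kept separate so list-size bookkeeping
        can report "n genes, m unknown".
        """
        symbols: set[str] = set()
        unknown = 0
        for pid in probe_ids:
            sym = self.symbol(pid)
            if sym is None:
                unknown += 1
            else:
                symbols.add(sym)
        return sorted(symbols), unknown


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} is empty")


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (pathways, ontology terms, ...)."""

    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for sid, gs in self.sets.items():
            if sid != gs.set_id:
                raise ValidationError(f"key {sid!r} != set_id {gs.set_id!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with a background universe, dropping empties."""
        out = {}
        for gs in self:
            m = gs.members & universe
            if m:
                out[gs.set_id] = GeneSet(gs.set_id, gs.description, frozenset(m))
        return GeneSetCollection(out)
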