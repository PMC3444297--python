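"""Readers and writers for every on-disk artifact.

Formats: tab-delimited bead-summary tables in the scanner-export style
(per-group ``AVG_Signal`` / ``BEAD_STDERR`` / ``Avg_NBEADS`` /
``Detection_Pval`` columns), probe-annotation TSV, GMT gene-set files,
per-animal phenotype CSV, and the deterministic results TSVs the pipeline
emits.  Column naming varies between scanner-software versions, so the
bead-summary reader is parameterized by a small :class:`Dialect` column map
instead of hard-coding one vendor export.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_GROUPS,
    SCALE_LINEAR,
    BeadSummary,
    GeneSet,
    GeneSetCollection,
    ProbeAnnotation,
)
from .errors import FormatError, ValidationError

#: Significant digits used for all numeric TSV output; chosen so that a
#: write -> read round trip reproduces doubles to 12 significant digits.
_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class Dialect:
    """Column-name templates mapping a bead-summary export to groups.

    ``{group}`` in each template is replaced by the group label.  Exactly one
    of the standard-error or variance columns must be present per group; a
    standard-error column is converted at read time via
    ``variance = SE**2 * n_beads`` so downstream code sees one representation.
    """

    probe_col: str = "ProbeID"
    mean: str = "AVG_Signal.{group}"
    stderr: str = "BEAD_STDERR.{group}"
    variance: str = "BEAD_VARIANCE.{group}"
    n_beads: str = "Avg_NBEADS.{group}"
    detection: str = "Detection_Pval.{group}"
    scale: str = SCALE_LINEAR


DEFAULT_DIALECT = Dialect()


def _numeric(df: pd.DataFrame, col: str, path: str) -> pd.Series:
    s = pd.to_numeric(df[col], errors="coerce")
    if s.isna().any() and not df[col].isna().any():
        row = int(s.index[s.isna() & ~df[col].isna()][0])
        raise FormatError(
            f"{path}: non-numeric value in column {col!r}, data row {row}"
        )
    return s


def read_bead_summary(
    path: str | os.PathLike,
    groups: list[str] | None = None,
    dialect: Dialect = DEFAULT_DIALECT,
) -> BeadSummary:
    """Read a tab-delimited bead-summary table.

    Parameters
    ----------
    path
        Tab-delimited file, one row per probe.
    groups
        Group labels to read.  If omitted, groups are inferred from the
        columns matching the dialect's mean-signal template.
    dialect
        Column-name map; see :class:`Dialect`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    path = str(path)
    if dialect.probe_col not in df.columns:
        raise FormatError(f"{path}: missing probe column {dialect.probe_col!r}")
    if groups is None:
        prefix, _, suffix = dialect.mean.partition("{group}")
        groups = [
            c[len(prefix) : len(c) - len(suffix) or None]
            for c in df.columns
            if c.startswith(prefix) and c.endswith(suffix) and c != prefix + suffix
        ]
        if not groups:
            raise FormatError(f"{path}: no columns match template {dialect.mean!r}")

    probe_ids = df[dialect.probe_col].astype(str)
    if probe_ids.duplicated().any():
        dups = probe_ids[probe_ids.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate probe_id(s) {dups}")

    def col(template: str, group: str, required: bool = True) -> pd.Series | None:
        name = template.format(group=group)
        if name not in df.columns:
            if required:
                raise FormatError(f"{path}: missing mandatory column {name!r}")
            return None
        return _numeric(df, name, path)

    mean, var, nbeads, detp = {}, {}, {}, {}
    have_detection = True
    for g in groups:
        mean[g] = col(dialect.mean, g)
        nbeads[g] = col(dialect.n_beads, g)
        v = col(dialect.variance, g, required=False)
        if v is None:
            se = col(dialect.stderr, g, required=False)
            if se is None:
                raise FormatError(
                    f"{path}: group {g!r} has neither a "
                    f"{dialect.variance.format(group=g)!r} nor a "
                    f"{dialect.stderr.format(group=g)!r} column"
                )
            v = se**2 * nbeads[g]
        var[g] = v
        d = col(dialect.detection, g, required=False)
        if d is None:
            have_detection = False
        detp[g] = d

    def frame(d: dict) -> pd.DataFrame:
        out = pd.DataFrame({g: d[g].astype(float) for g in groups})
        out.index = pd.Index(probe_ids, name="probe_id")
        return out

    return BeadSummary(
        mean_signal=frame(mean),
        bead_variance=frame(var),
        n_beads=frame(nbeads).round().astype(int),
        detection_p=frame(detp) if have_detection else None,
        scale=dialect.scale,
    )


def write_bead_summary(
    bs: BeadSummary, path: str | os.PathLike, dialect: Dialect = DEFAULT_DIALECT
) -> None:
    """Write a bead summary in the dialect's variance-column form."""
    out = pd.DataFrame({dialect.probe_col: bs.probe_ids})
    for g in bs.group_labels:
        out[dialect.mean.format(group=g)] = bs.mean_signal[g].to_numpy()
        out[dialect.variance.format(group=g)] = bs.bead_variance[g].to_numpy()
        out[dialect.n_beads.format(group=g)] = bs.n_beads[g].to_numpy()
        if bs.detection_p is not None:
            out[dialect.detection.format(group=g)] = bs.detection_p[g].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT gene-set file: ``set_id TAB description TAB member...``.

    Duplicate members within a line are de-duplicated; duplicate set ids
    across lines are an error.
    """
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            set_id, desc = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {set_id!r} is empty")
            if set_id in sets:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate set id {set_id!r}"
                )
            sets[set_id] = GeneSet(set_id, desc, members)
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in coll:
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.members)]))
            fh.write("\n")


def read_probe_annotation(path: str | os.PathLike) -> ProbeAnnotation:
    """Read a probe-annotation TSV: probe_id, gene_symbol, entrez_id."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str})
    for col in ("probe_id", "gene_symbol", "entrez_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    df = df.set_index("probe_id")
    df["entrez_id"] = pd.to_numeric(df["entrez_id"], errors="coerce").astype("Int64")
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path: str | os.PathLike) -> None:
    ann.table.to_csv(path, sep="\t", index_label="probe_id")


# Phenotype tables.  One row per mouse; metric columns may be missing per
# animal (empty cell), mirroring per-metric n in real study tables.

PHENOTYPE_ID_COLS = ("mouse_id", "group")


def read_phenotype(
    path: str | os.PathLike, valid_groups: tuple[str, ...] = DEFAULT_GROUPS
) -> pd.DataFrame:
    """Read a per-animal phenotype CSV.

    Returns a DataFrame with ``mouse_id``, ``group`` and one column per
    metric; missing metric values stay NaN.  Group labels outside
    ``valid_groups`` raise a validation error.
    """
    df = pd.read_csv(path, dtype={"mouse_id": str, "group": str})
    for col in PHENOTYPE_ID_COLS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    unknown = set(df["group"]) - set(valid_groups)
    if unknown:
        raise ValidationError(f"{path}: unknown group label(s) {sorted(unknown)}")
    if df["mouse_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate mouse_id")
    return df


def write_phenotype(records: pd.DataFrame, path: str | os.PathLike) -> None:
    records.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_results_tsv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a results table deterministically (stable column order, 12
    significant digits) so reruns are byte-identical."""
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_results_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
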