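"""Overrepresentation analysis of gene lists against gene-set collections.

For a list of n analyzed genes drawn from a universe of N, and a gene set
with R members inside that universe, the overlap r is referred to the
hypergeometric distribution.  Three statistics are reported per set:

* the exact upper-tail probability P(X >= r),
* the fold enrichment (r/n) / (R/N) — the ratio of the set's share of the
  list to its share of the universe,
* the z-score (r - mu) / sigma with the hypergeometric mean
  mu = n R / N and variance sigma^2 = n (R/N)(1 - R/N)(1 - (n-1)/(N-1)),
  the pathway-ranking convention of graphical pathway tools.

An optional EASE-style conservative variant replaces r by r - 1 in the
upper-tail probability.  No continuity correction is applied to the z-score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection
from .errors import ValidationError


def _check_counts(r: int, n: int, R: int, N: int) -> None:
    if not (0 <= r <= min(n, R) <= N) or n > N or R > N:
        raise ValidationError(
            f"inconsistent counts r={r}, n={n}, R={R}, N={N}"
        )


def hypergeom_overlap_p(r: int, n: int, R: int, N: int, ease: bool = False) -> float:
    """Exact upper-tail hypergeometric probability P(X >= r).

    X counts set members in a size-n draw without replacement from a
    universe of N containing R set members.  ``ease=True`` computes
    P(X >= r - 1) (the EASE-score convention), which is more conservative.
    """
    _check_counts(r, n, R, N)
    if ease:
        r = max(r - 1, 0)
    # sf(r-1) = P(X >= r); exact in scipy's implementation
    return float(stats.hypergeom.sf(r - 1, N, R, n))


def fold_enrichment(r: int, n: int, R: int, N: int) -> float:
    """DAVID-style enrichment ratio (r/n) / (R/N)."""
    _check_counts(r, n, R, N)
    if n == 0 or R == 0 or N == 0:
        raise ValidationError("n, R and N must be positive")
    return (r / n) / (R / N)


def overlap_z(r: int, n: int, R: int, N: int) -> float:
    """Standardized overlap count under hypergeometric sampling."""
    _check_counts(r, n, R, N)
    if n == 0 or R == 0 or R == N:
        raise ValidationError("z-score undefined: zero hypergeometric variance")
    p = R / N
    mu = n * p
    var = n * p * (1.0 - p) * (1.0 - (n - 1) / (N - 1))
    if var <= 0:
        raise ValidationError("z-score undefined: zero hypergeometric variance")
    return (r - mu) / math.sqrt(var)


@dataclass
class EnrichmentThresholds:
    """Reporting filters: minimum overlap, z cutoff, p cutoff, set size."""

    min_count: int = 3
    z_min: float = 2.0
    p_max: float = 0.05
    min_set_size: int = 1
    max_set_size: int | None = None


def enrich_list(
    gene_list,
    universe,
    sets: GeneSetCollection,
    thresholds: EnrichmentThresholds | None = None,
    rank_by: str = "z",
    ease: bool = False,
) -> pd.DataFrame:
    """Score every gene set against an analyzed gene list.

    Sets are intersected with the universe before counting; the analyzed
    list must be a subset of the universe.  One row per set with overlap
    ``r >= min_count``, with boolean flags for the z and p criteria.
    ``rank_by`` orders the output by "z" descending or "p" ascending.
    """
    thresholds = EnrichmentThresholds() if thresholds is None else thresholds
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    gene_list = set(gene_list)
    outside = gene_list - universe
    if outside:
        raise ValidationError(
            f"list member(s) outside the universe: {sorted(outside)[:5]}"
        )
    if rank_by not in ("z", "p"):
        raise ValidationError("rank_by must be 'z' or 'p'")
    N = len(universe)
    n = len(gene_list)
    rows = []
    for gs in sets.restricted_to(universe):
        R = len(gs.members)
        if R < thresholds.min_set_size:
            continue
        if thresholds.max_set_size is not None and R > thresholds.max_set_size:
            continue
        r = len(gs.members & gene_list)
        if r < thresholds.min_count:
            continue
        p = hypergeom_overlap_p(r, n, R, N, ease=ease)
        fe = fold_enrichment(r, n, R, N)
        # z undefined at zero hypergeometric variance (n in {0, N}, R in {0, N})
        z = overlap_z(r, n, R, N) if 0 < R < N and 0 < n < N else np.nan
        rows.append(
            {
                "set_id": gs.set_id,
                "description": gs.description,
                "r": r,
                "n": n,
                "R": R,
                "N": N,
                "fold_enrichment": fe,
                "p_hyper": p,
                "z": z,
                "passes_z": bool(z > thresholds.z_min) if np.isfinite(z) else False,
                "passes_p": p <= thresholds.p_max,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_id", "description", "r", "n", "R", "N",
            "fold_enrichment", "p_hyper", "z", "passes_z", "passes_p",
        ],
    )
    if len(out):
        if rank_by == "z":
            out = out.sort_values(["z", "set_id"], ascending=[False, True], kind="stable")
        else:
            out = out.sort_values(["p_hyper", "set_id"], kind="stable")
        out = out.reset_index(drop=True)
    return out
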