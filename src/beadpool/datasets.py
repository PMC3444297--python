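"""Built-in study-design tables for the four-diet mouse feeding trial.

These are the printed design values the synthetic-data generator emulates:
diet macronutrient compositions, phenotype group means and SEMs, and the
13-probe pattern of lens-crystallin log ratios in which high-fat feeding
induces the crystallins and the bilberry supplement partially reverts the
induction.  They serve as generator defaults and as worked-example inputs;
they are not measurements produced by this package.
"""

from __future__ import annotations

import pandas as pd

from .phenotype import DietSpec

#: Macronutrient composition (g per 100 g of feed) of the control and
#: high-fat diets, with and without the 5% bilberry supplement.
DIET_COMPOSITIONS = {
    "NCD": DietSpec("NCD", protein=19.2, carbohydrate=67.3, fat=4.3),
    "HFD": DietSpec("HFD", protein=23.7, carbohydrate=41.4, fat=23.6),
    "NCD+BB": DietSpec("NCD+BB", protein=18.7, carbohydrate=64.0, fat=4.2),
    "HFD+BB": DietSpec("HFD+BB", protein=23.0, carbohydrate=38.8, fat=23.0),
}

#: End-of-study phenotype summaries per diet group: mean, SEM and the
#: non-missing n for systolic blood pressure (mmHg), blood glucose (mmol/l)
#: and serum free fatty acids (mmol/l).  n=6 mice per group; some metrics
#: have fewer valid measurements.
PHENOTYPE_SUMMARIES = {
    "sbp": {
        "NCD": (96.0, 5.0, 2),
        "NCD+BB": (97.0, 4.0, 4),
        "HFD": (113.0, 5.0, 5),
        "HFD+BB": (101.0, 3.0, 2),
    },
    "glucose": {
        "NCD": (9.0, 1.0, 6),
        "NCD+BB": (9.7, 1.7, 6),
        "HFD": (12.5, 1.1, 6),
        "HFD+BB": (14.3, 2.2, 6),
    },
    "ffa": {
        "NCD": (1.0, 0.08, 4),
        "NCD+BB": (1.0, 0.10, 5),
        "HFD": (1.2, 0.15, 5),
        "HFD+BB": (1.3, 0.12, 6),
    },
}


def phenotype_group_means(metric: str) -> dict[str, float]:
    """True group means used as generator defaults for one metric."""
    return {g: m for g, (m, _s, _n) in PHENOTYPE_SUMMARIES[metric].items()}


def phenotype_group_sds(metric: str) -> dict[str, float]:
    """Group standard deviations implied by the printed SEM and n."""
    return {g: s * n**0.5 for g, (_m, s, n) in PHENOTYPE_SUMMARIES[metric].items()}


#: Log2 ratios of the 13 crystallin probes across the standard contrasts.
#: Columns: diet induction (HFD/NCD), combined arm (HFD+BB/NCD), supplement
#: on the control background (NCD+BB/NCD), and the derived supplement-on-
#: high-fat contrast (HFD+BB/HFD).  Two probes target Cryba1 — probe-level
#: rows, not gene-level.
_CRYSTALLIN_ROWS = [
    # symbol, entrez, HFD/NCD, HFD+BB/NCD, NCD+BB/NCD, HFD+BB/HFD
    ("Crybb2", 12961, 3.16, 1.16, 0.94, -2.00),
    ("Crygs", 12970, 3.08, 1.16, 0.72, -1.93),
    ("Cryba2", 12958, 3.03, 0.90, 0.70, -2.13),
    ("Cryba1", 12957, 2.96, 0.83, 0.74, -2.13),
    ("Cryba4", 12959, 2.05, 0.35, 0.25, -1.70),
    ("Cryba1", 12957, 2.53, 0.76, 0.68, -1.77),
    ("Cryaa", 12954, 1.74, 0.45, 0.00, -1.29),
    ("Crybb1", 12960, 0.77, 0.10, 0.12, -0.67),
    ("Crybb3", 12962, 0.86, 0.10, 0.03, -0.76),
    ("Crygb", 12965, 0.82, 0.20, 0.00, -0.62),
    ("Crygc", 12966, 0.64, 0.20, 0.13, -0.44),
    ("Cryab", 12955, 0.83, 0.52, 0.09, -0.32),
    ("Crygd", 12967, 0.55, 0.03, 0.16, -0.52),
]


def crystallin_contrasts() -> pd.DataFrame:
    """The 13-probe crystallin log-ratio pattern as a DataFrame.

    Index is a synthetic probe id (``cry_01`` ...); columns are gene_symbol,
    entrez_id, and the four contrast log2 ratios.
    """
    rows = []
    for i, (sym, ez, a, b, c, d) in enumerate(_CRYSTALLIN_ROWS, start=1):
        rows.append(
            {
                "probe_id": f"cry_{i:02d}",
                "gene_symbol": sym,
                "entrez_id": ez,
                "HFD/NCD": a,
                "HFD+BB/NCD": b,
                "NCD+BB/NCD": c,
                "HFD+BB/HFD": d,
            }
        )
    return pd.DataFrame(rows).set_index("probe_id")


def crystallin_shift_table() -> dict[str, dict[str, float]]:
    """Planted-effect table for the simulator: log2 shifts per group.

    Shifts are relative to the control group (NCD = 0), taken from the
    probe's printed contrast columns so the simulated block reproduces the
    induction-and-partial-reversion pattern.
    """
    ct = crystallin_contrasts()
    out: dict[str, dict[str, float]] = {}
    for pid, row in ct.iterrows():
        out[str(pid)] = {
            "HFD": float(row["HFD/NCD"]),
            "HFD+BB": float(row["HFD+BB/NCD"]),
            "NCD+BB": float(row["NCD+BB/NCD"]),
        }
    return out
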