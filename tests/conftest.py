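import numpy as np
import pandas as pd
import pytest

from beadpool.containers import BeadSummary, ProbeAnnotation

GROUPS = ["NCD", "HFD", "NCD+BB", "HFD+BB"]


def make_bead_summary(mean, var, nbeads, groups=None, probe_ids=None, detection=None):
    """Assemble a BeadSummary from plain nested lists/arrays."""
    mean = np.asarray(mean, dtype=float)
    groups = groups or GROUPS[: mean.shape[1]]
    probe_ids = probe_ids or [f"p{i}" for i in range(mean.shape[0])]
    idx = pd.Index(probe_ids, name="probe_id")

    def frame(x):
        return pd.DataFrame(np.asarray(x, dtype=float), index=idx, columns=groups)

    return BeadSummary(
        mean_signal=frame(mean),
        bead_variance=frame(var),
        n_beads=pd.DataFrame(np.asarray(nbeads, dtype=int), index=idx, columns=groups),
        detection_p=frame(detection) if detection is not None else None,
    )


@pytest.fixture
def small_bead_summary():
    """3 probes x 4 groups with distinct means and simple variances."""
    return make_bead_summary(
        mean=[[100, 200, 120, 150], [50, 50, 50, 50], [10, 40, 20, 30]],
        var=[[400, 500, 450, 420], [100, 100, 100, 100], [9, 25, 16, 20]],
        nbeads=[[25, 20, 30, 28], [30, 30, 30, 30], [10, 12, 9, 11]],
    )


@pytest.fixture
def toy_annotation():
    tab = pd.DataFrame(
        {
            "probe_id": ["p0", "p1", "p2"],
            "gene_symbol": ["GeneA", "GeneB", "GeneA"],
            "entrez_id": [11, 22, 11],
        }
    ).set_index("probe_id")
    tab["entrez_id"] = tab["entrez_id"].astype("Int64")
    return ProbeAnnotation(tab)
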