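"""DR tip speciation rates (inverse equal splits) and their cell medians.

For tip *i* with root-to-tip edges e_1 (pendant) ... e_N (rootmost), the
equal-splits measure is ``ES_i = sum_j len(e_j) * 2^-(j-1)`` and the DR
statistic is ``1 / ES_i`` (per Ma). DR is a proxy for the recent speciation
rate of the lineage; spatial patterns are summarized as the median DR of
the species co-occurring in each grid cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Phylogeny, PresenceAbsenceMatrix, TreeError


def equal_splits(phy: Phylogeny) -> pd.Series:
    """Equal-splits measure (Ma) per tip; requires strictly positive branch lengths."""
    for v in range(phy.n_nodes):
        if v != phy.root and phy.branch_length[v] <= 0:
            raise TreeError("equal splits requires strictly positive branch lengths")
    out = {}
    for tip in phy.tip_indices:
        es, weight, v = 0.0, 1.0, int(tip)
        while v != phy.root:
            es += phy.branch_length[v] * weight
            weight *= 0.5
            v = int(phy.parent[v])
        out[phy.labels[tip]] = es
    return pd.Series(out, name="es")


def dr_statistic(phy: Phylogeny) -> pd.Series:
    """DR speciation-rate statistic (per Ma) per tip: the inverse of equal splits."""
    es = equal_splits(phy)
    return (1.0 / es).rename("dr")


def cell_median_rate(pam: PresenceAbsenceMatrix, rates: pd.Series) -> pd.Series:
    """Median tip rate over the species present in each cell (NaN if empty).

    Even counts use the midpoint of the two central values.
    """
    missing = set(pam.species) - set(rates.index)
    if missing:
        raise ValueError(f"rates missing for species: {sorted(missing)[:5]}")
    r = rates.loc[pam.species].to_numpy(dtype=float)
    out = {}
    for i, cell in enumerate(pam.cell_ids):
        present = pam.matrix[i].astype(bool)
        out[cell] = float(np.median(r[present])) if present.any() else np.nan
    return pd.Series(out, name="dr")
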