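"""Selection of substrate-responsive and lignocellulose-specific SOM nodes.

Two printed rules are applied exactly as stated, including their mixed
strict/non-strict inequalities:

* responsive: a node is selected for a substrate if its mean normalized
  log2 read count on that substrate is >= 12 (highly transcribed) or its
  node-level fold change vs maltose is >= 4 (up-regulated);
* specific (lignocellulose, not cellulose): (i) mean > 12 on wheat straw or
  aspen AND < 12 on both maltose and avicel, or (ii) fold change >= 4 on
  wheat straw or aspen AND <= 4 on avicel.

"Cellulose" is mapped to the avicel condition (the cellulose-enriched
substrate of the design).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import FilterConfig
from .som import NodeStats, SOMModel

HIGH_EXPRESSION = "high_expression"
UP_REGULATED = "up_regulated"
SPECIFIC_I = "specific_i"
SPECIFIC_II = "specific_ii"


def select_responsive(stats: NodeStats, substrate: str,
                      cfg: FilterConfig = FilterConfig()) -> pd.DataFrame:
    """Nodes highly transcribed or up-regulated on ``substrate``.

    Returns one row per (node, criterion); a node satisfying both rules
    appears once per criterion. Empty nodes (missing means) are never
    selected.
    """
    if substrate not in stats.means.columns:
        raise ValueError(f"unknown substrate {substrate!r}")
    means = stats.means[substrate]
    fc = stats.fold_change[substrate]
    rows = []
    for node in stats.means.index:
        if np.isnan(means[node]):
            continue
        if means[node] >= cfg.high_expr_log2:
            rows.append({"node": node, "substrate": substrate,
                         "criterion": HIGH_EXPRESSION})
        if fc[node] >= cfg.fc_threshold:
            rows.append({"node": node, "substrate": substrate,
                         "criterion": UP_REGULATED})
    return pd.DataFrame(rows, columns=["node", "substrate", "criterion"])


def select_specific(stats: NodeStats,
                    target_substrates=("wheat_straw", "aspen"),
                    excluded=("avicel",),
                    cfg: FilterConfig = FilterConfig()) -> pd.DataFrame:
    """Nodes regulated on complex lignocellulose but not on cellulose.

    Criterion (i): mean log2 > 12 on some target substrate AND < 12 on the
    control and every excluded substrate. Criterion (ii): FC >= 4 on some
    target AND <= 4 on every excluded substrate. One row per (node,
    satisfied criterion) with the triggering target substrate.
    """
    needed = set(target_substrates) | set(excluded) | {cfg.control_substrate}
    missing = needed - set(stats.means.columns)
    if missing:
        raise ValueError(f"missing conditions in node stats: {sorted(missing)}")
    rows = []
    for node in stats.means.index:
        m = stats.means.loc[node]
        f = stats.fold_change.loc[node]
        if m.isna().any():
            continue
        guard_i = (m[cfg.control_substrate] < cfg.high_expr_log2
                   and all(m[e] < cfg.high_expr_log2 for e in excluded))
        guard_ii = all(f[e] <= cfg.fc_threshold for e in excluded)
        for target in target_substrates:
            if guard_i and m[target] > cfg.high_expr_log2:
                rows.append({"node": node, "substrate": target,
                             "criterion": SPECIFIC_I})
            if guard_ii and f[target] >= cfg.fc_threshold:
                rows.append({"node": node, "substrate": target,
                             "criterion": SPECIFIC_II})
    return pd.DataFrame(rows, columns=["node", "substrate", "criterion"])


def genes_of_selection(selection: pd.DataFrame, som: SOMModel | pd.Series,
                       annotations: pd.DataFrame) -> pd.DataFrame:
    """Member genes of the selected nodes with their functional labels.

    Sorted by node then family. An empty selection yields an empty table.
    """
    assignment = som.assignment if isinstance(som, SOMModel) else som
    cols = ["node", "gene_id", "species", "family", "secreted", "ssp"]
    if selection.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for node in sorted(selection["node"].unique()):
        genes = assignment.index[assignment == node]
        for g in genes:
            ann = annotations.loc[g]
            rows.append({"node": node, "gene_id": g,
                         "species": ann["species"], "family": ann["family"],
                         "secreted": bool(ann["secreted"]),
                         "ssp": bool(ann["ssp"])})
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["node", "family", "gene_id"],
                           ignore_index=True)
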