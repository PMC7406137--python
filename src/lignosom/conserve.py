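"""Cross-species conservation of transcriptional regulation.

Works on one-to-one ortholog groups (co-orthologs): a group x
(species, substrate) matrix of log2 fold changes versus the control
substrate, a conservation call per (group, substrate) -- conserved-up when
every species' member clears the fold-change threshold in the same
direction -- family-level aggregation, and the sample x sample Pearson
correlation structure over the co-ortholog gene set.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import OrthoGroups
from .som import SOMModel


def coortholog_fold_matrix(calls: pd.DataFrame,
                           groups: OrthoGroups) -> pd.DataFrame:
    """Group x (species, substrate) matrix of log2 fold changes.

    ``calls`` is the long per-gene regulation table (columns gene_id,
    substrate, fold_change, log2_fc, direction) pooled over species; groups
    must be one-to-one. A condition absent for one species (e.g. a dropped
    substrate block) yields a missing cell; a member gene with no calls at
    all is an error.
    """
    indexed = calls.set_index(["gene_id", "substrate"])["log2_fc"]
    genes_with_calls = set(calls["gene_id"])
    substrates = list(pd.unique(calls["substrate"]))
    species = list(groups.species)
    columns = pd.MultiIndex.from_product([species, substrates],
                                         names=["species", "substrate"])
    data = {}
    for gid, members in groups.groups.items():
        row = np.full(len(columns), np.nan)
        for sp in species:
            genes = members.get(sp, [])
            if len(genes) != 1:
                raise ValueError(f"group {gid!r} is not one-to-one")
            gene = genes[0]
            if gene not in genes_with_calls:
                raise ValueError(f"no regulation calls for {gene!r}")
            for k, sub in enumerate(substrates):
                key = (gene, sub)
                if key in indexed.index:
                    row[species.index(sp) * len(substrates) + k] = \
                        indexed[key]
        data[gid] = row
    fmat = pd.DataFrame.from_dict(data, orient="index", columns=columns)
    fmat.index.name = "group_id"
    return fmat


def conserved_regulation(fold_matrix: pd.DataFrame, threshold: float = 4.0,
                         min_species: int | None = None) -> pd.DataFrame:
    """Conservation calls per (group, substrate).

    Conserved-up requires every species' log2 FC >= log2(threshold)
    (conserved-down: <= -log2(threshold)). ``min_species`` relaxes the
    strict all-species rule: with e.g. 2-of-3, a call only needs that many
    species in agreement and none in the opposite direction. Species with a
    missing cell never count toward agreement. Symmetric under species
    permutation.
    """
    log2_thr = np.log2(threshold)
    species = fold_matrix.columns.get_level_values("species").unique()
    substrates = fold_matrix.columns.get_level_values("substrate").unique()
    need = len(species) if min_species is None else min_species
    rows = []
    for gid in fold_matrix.index:
        for sub in substrates:
            vals = fold_matrix.loc[gid].xs(sub, level="substrate")
            observed = vals.dropna()
            n_up = int((observed >= log2_thr).sum())
            n_down = int((observed <= -log2_thr).sum())
            conserved = "none"
            if n_up >= need and n_down == 0:
                conserved = "up"
            elif n_down >= need and n_up == 0:
                conserved = "down"
            rows.append({"group_id": gid, "substrate": sub,
                         "n_species": len(observed), "n_up": n_up,
                         "n_down": n_down, "conserved": conserved})
    return pd.DataFrame(rows)


def group_family(groups: OrthoGroups, annotations: pd.DataFrame) -> pd.Series:
    """Modal family label of each group's member genes."""
    fams = {}
    for gid, members in groups.groups.items():
        labels = [annotations.loc[g, "family"]
                  for genes in members.values() for g in genes]
        fams[gid] = pd.Series(labels).mode().iloc[0]
    return pd.Series(fams, name="family")


def family_summary(fold_matrix: pd.DataFrame, conserved: pd.DataFrame,
                   groups: OrthoGroups, annotations: pd.DataFrame,
                   threshold: float = 4.0) -> tuple[pd.DataFrame,
                                                    pd.DataFrame]:
    """Family-level counts of regulated co-orthologs and conserved groups.

    Returns ``(per_species, conserved_counts)``: the first counts, per
    (family, species, substrate), the one-to-one groups whose member in
    that species is up/down at the threshold; the second counts conserved
    groups per (family, substrate). Per-species marginals of the first
    table equal the per-species regulated-group counts.
    """
    fam = group_family(groups, annotations)
    log2_thr = np.log2(threshold)
    per_rows = []
    species = fold_matrix.columns.get_level_values("species").unique()
    substrates = fold_matrix.columns.get_level_values("substrate").unique()
    for sp in species:
        for sub in substrates:
            col = fold_matrix[(sp, sub)]
            for direction, mask in (("up", col >= log2_thr),
                                    ("down", col <= -log2_thr)):
                counts = fam.loc[fold_matrix.index[mask]].value_counts()
                for family, n in counts.items():
                    per_rows.append({"family": family, "species": sp,
                                     "substrate": sub,
                                     "direction": direction, "n_genes": n})
    per_species = pd.DataFrame(
        per_rows, columns=["family", "species", "substrate", "direction",
                           "n_genes"])

    cons_rows = []
    hit = conserved[conserved["conserved"] != "none"]
    for (sub, direction), block in hit.groupby(["substrate", "conserved"]):
        counts = fam.loc[block["group_id"]].value_counts()
        for family, n in counts.items():
            cons_rows.append({"family": family, "substrate": sub,
                              "direction": direction, "n_groups": n})
    conserved_counts = pd.DataFrame(
        cons_rows, columns=["family", "substrate", "direction", "n_groups"])
    return per_species, conserved_counts


def align_ortholog_expression(expr: pd.DataFrame,
                              groups: OrthoGroups) -> pd.DataFrame:
    """Rebuild a shared row space from the species-stacked matrix.

    ``expr`` has genes (all species, namespaced ids) as rows and condition
    slots as columns; the result has one row per one-to-one group and a
    (species, condition) MultiIndex of columns, so all species' samples
    live in one matrix and can be correlated pairwise.
    """
    species = list(groups.species)
    columns = pd.MultiIndex.from_product(
        [species, list(expr.columns)], names=["species", "condition"])
    data = np.full((len(groups), len(columns)), np.nan)
    gids = list(groups.groups)
    for r, gid in enumerate(gids):
        members = groups.groups[gid]
        for s, sp in enumerate(species):
            genes = members.get(sp, [])
            if len(genes) != 1 or genes[0] not in expr.index:
                continue
            data[r, s * expr.shape[1]:(s + 1) * expr.shape[1]] = \
                expr.loc[genes[0]].to_numpy()
    out = pd.DataFrame(data, index=pd.Index(gids, name="group_id"),
                       columns=columns)
    return out.dropna(axis=1, how="all")


def sample_correlation(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every pair of sample columns.

    Exactly symmetric with unit diagonal; columns with zero variance give
    missing coefficients (including their own diagonal).
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two samples")
    corr = expr.corr(method="pearson")
    # zero-variance samples: pandas leaves NaN, which we keep as "missing"
    valid = expr.std() > 0
    for c in corr.columns[valid]:
        corr.loc[c, c] = 1.0
    corr = (corr + corr.T) / 2.0
    return corr


def family_conode_query(som: SOMModel | pd.Series, annotations: pd.DataFrame,
                        family_a: str, family_b: str) -> pd.DataFrame:
    """Nodes whose members include at least one gene of each family.

    Returns the member genes of both families in those nodes; an unknown
    family label produces a warning and an empty result.
    """
    assignment = som.assignment if isinstance(som, SOMModel) else som
    cols = ["node", "gene_id", "species", "family"]
    fams = set(annotations["family"])
    empty = pd.DataFrame(columns=cols)
    for fam in (family_a, family_b):
        if fam not in fams:
            warnings.warn(f"unknown family {fam!r}", stacklevel=2)
            return empty
    ann = annotations.loc[assignment.index]
    nodes_a = set(assignment[ann["family"] == family_a])
    nodes_b = set(assignment[ann["family"] == family_b])
    shared = sorted(nodes_a & nodes_b)
    if not shared:
        return empty
    rows = []
    for node in shared:
        genes = assignment.index[assignment == node]
        for g in genes:
            fam = annotations.loc[g, "family"]
            if fam in (family_a, family_b):
                rows.append({"node": node, "gene_id": g,
                             "species": annotations.loc[g, "species"],
                             "family": fam})
    return pd.DataFrame(rows, columns=cols)
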