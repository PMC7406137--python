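"""MS secretome validation and integration with node selections.

A protein identification is validated when it rests on at least two unique
peptides with a log10 E-value strictly below -2.6. Validated detections are
overlaid on the SOM node selections to measure how often the enzymes encoded
by up-regulated genes are actually found in the culture medium, and to test
whether co-regulated enzyme family pairs (shared SOM node) are also
co-secreted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import FilterConfig
from .som import SOMModel


def validate_secretome(table: pd.DataFrame,
                       cfg: FilterConfig = FilterConfig()) -> pd.DataFrame:
    """Apply the peptide-count and E-value validation thresholds.

    Returns one row per (species, substrate, gene_id) with a boolean
    ``detected``; duplicate rows collapse by OR. Validation is idempotent
    and monotone: tightening either threshold never adds detections. Raw
    E-values must be supplied as log10 already (ingestion handles the
    transform).
    """
    if (table["n_unique_peptides"] < 0).any():
        raise ValueError("negative unique-peptide count")
    ok = ((table["n_unique_peptides"] >= cfg.min_unique_peptides)
          & (table["log_evalue"] < cfg.max_log_evalue))
    out = (table.assign(detected=ok)
           .groupby(["species", "substrate", "gene_id"], sort=True)
           ["detected"].any().reset_index())
    return out


def detected_genes(evidence: pd.DataFrame) -> set[str]:
    """Genes with a validated detection on any substrate."""
    return set(evidence.loc[evidence["detected"], "gene_id"])


def overlay_nodes(selection: pd.DataFrame, som: SOMModel | pd.Series,
                  evidence: pd.DataFrame, calls: pd.DataFrame,
                  annotations: pd.DataFrame | None = None
                  ) -> tuple[pd.DataFrame, dict]:
    """Protein-detection statistics for the selected nodes.

    Per node: member genes, up-regulated members (on a substrate the node
    was selected for) and detected members. Globally: the fraction of
    up-regulated genes across the selected nodes whose protein was detected
    on any tested substrate -- reported over all up-regulated genes, over
    the secreted-annotated subset, and per substrate.
    """
    assignment = som.assignment if isinstance(som, SOMModel) else som
    det_any = detected_genes(evidence)
    up_idx = calls[calls["direction"] == "up"].set_index(
        ["gene_id", "substrate"]).index
    per_rows = []
    up_global: set[str] = set()
    up_by_substrate: dict[str, set] = {}
    for (node, substrate), _ in selection.groupby(["node", "substrate"]):
        genes = list(assignment.index[assignment == node])
        up = [g for g in genes if (g, substrate) in up_idx]
        up_global.update(up)
        up_by_substrate.setdefault(substrate, set()).update(up)
        detected = [g for g in up if g in det_any]
        per_rows.append({
            "node": node, "substrate": substrate, "n_genes": len(genes),
            "n_up": len(up), "n_up_detected": len(detected),
            "fraction_detected": (len(detected) / len(up)) if up
            else np.nan,
        })
    per_node = pd.DataFrame(
        per_rows, columns=["node", "substrate", "n_genes", "n_up",
                           "n_up_detected", "fraction_detected"])
    n_up = len(up_global)
    n_det = len(up_global & det_any)
    out = {
        "n_up_regulated": n_up,
        "n_up_detected": n_det,
        "fraction_detected": (n_det / n_up) if n_up else np.nan,
        "per_substrate": {
            sub: (len(genes & det_any) / len(genes)) if genes else np.nan
            for sub, genes in sorted(up_by_substrate.items())
        },
    }
    if annotations is not None:
        secreted = set(annotations.index[annotations["secreted"]])
        up_sec = up_global & secreted
        out["n_up_secreted"] = len(up_sec)
        out["fraction_detected_secreted"] = (
            len(up_sec & det_any) / len(up_sec)) if up_sec else np.nan
    return per_node, out


def coexpression_cosecretion_report(som: SOMModel | pd.Series,
                                    annotations: pd.DataFrame,
                                    evidence: pd.DataFrame,
                                    family_pairs) -> pd.DataFrame:
    """Co-regulation (shared SOM node) vs co-secretion per family pair.

    For each requested pair: the shared nodes, the substrates on which both
    families have validated detections, and whether transcriptional
    co-regulation coincides with co-detection in the medium.
    """
    from .conserve import family_conode_query

    det = evidence[evidence["detected"]]
    fam_of = annotations["family"]
    rows = []
    for fam_a, fam_b in family_pairs:
        shared = family_conode_query(som, annotations, fam_a, fam_b)
        nodes = sorted(shared["node"].unique()) if not shared.empty else []
        det_fam = det.assign(family=fam_of.loc[det["gene_id"]].to_numpy())
        subs_a = set(det_fam.loc[det_fam["family"] == fam_a, "substrate"])
        subs_b = set(det_fam.loc[det_fam["family"] == fam_b, "substrate"])
        co_subs = sorted(subs_a & subs_b)
        co_reg = bool(nodes)
        co_sec = bool(co_subs)
        rows.append({
            "family_a": fam_a, "family_b": fam_b,
            "shared_nodes": ",".join(str(n) for n in nodes),
            "co_regulated": co_reg,
            "co_detected_substrates": ",".join(co_subs),
            "co_secreted": co_sec,
            "co_regulated_and_co_secreted": co_reg and co_sec,
        })
    return pd.DataFrame(rows)
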