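"""Data model and TSV readers/writers for the cross-species pipeline.

All tables are UTF-8 TSV with '.' decimal separator and no quoting. Gene
identifiers are namespaced ``"<species>|<id>"`` so that genes from different
genomes never collide once matrices are combined.

Containers are plain :class:`pandas.DataFrame` objects with fixed layouts:

* counts -- genes x samples, nonnegative integers, one matrix per species
* sample info -- indexed by sample id: species, substrate, replicate, batch
* gene annotations -- indexed by gene id: species, family, protein_length,
  secreted, ssp
* secretome -- long table (species, substrate, gene_id, n_unique_peptides,
  log_evalue)

Ortholog groups use a small dedicated container (:class:`OrthoGroups`)
because members are ragged lists per species; the on-disk layout is the
OrthoFinder ``Orthogroups.tsv`` convention (one column per species,
comma-separated gene lists).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The five growth substrates of the study design. Maltose is the
#: non-inducing control carbon source; avicel is the cellulose-enriched
#: substrate; wheat straw, pine and aspen represent Gramineae, softwood and
#: hardwood lignocellulose.
SUBSTRATES = ("maltose", "avicel", "wheat_straw", "pine", "aspen")

CONTROL_SUBSTRATE = "maltose"


class TableFormatError(ValueError):
    """Structural problem in an input table (duplicate ids, bad header...)."""


@dataclass(frozen=True)
class FilterConfig:
    """All fixed thresholds of the analysis, in one place.

    low_count_mean
        Genes whose mean raw count within a (species, substrate) replicate
        group is strictly below this are considered not transcribed in that
        condition and masked to zero. Unit: raw read counts.
    high_expr_log2
        "Highly transcribed" cutoff on normalized log2 read counts.
    fc_threshold
        Linear fold-change cutoff for up/down regulation calls (a log2
        difference of 2 is the equivalent rule).
    ssp_max_len
        Secreted proteins strictly shorter than this many amino acids are
        small secreted proteins (SSPs).
    min_unique_peptides / max_log_evalue
        MS validation: at least two unique peptides and log10 E-value
        strictly below -2.6.
    """

    low_count_mean: float = 5.0
    high_expr_log2: float = 12.0
    fc_threshold: float = 4.0
    ssp_max_len: int = 300
    min_unique_peptides: int = 2
    max_log_evalue: float = -2.6
    control_substrate: str = CONTROL_SUBSTRATE

    def __post_init__(self) -> None:
        for name in ("low_count_mean", "high_expr_log2", "fc_threshold",
                     "ssp_max_len", "min_unique_peptides"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class OrthoGroups:
    """Ortholog groups: group id -> {species -> list of member gene ids}."""

    species: tuple[str, ...]
    groups: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.groups)

    def subset(self, group_ids) -> "OrthoGroups":
        return OrthoGroups(self.species,
                           {g: self.groups[g] for g in group_ids})

    def members_flat(self) -> list[tuple[str, str, str]]:
        """(group_id, species, gene_id) triples."""
        out = []
        for gid, members in self.groups.items():
            for sp, genes in members.items():
                for g in genes:
                    out.append((gid, sp, g))
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample raw count matrix.

    The first column holds gene ids, the header row sample ids. Raises
    :class:`TableFormatError` for duplicated ids and :class:`ValueError`
    for negative or non-integer entries.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise TableFormatError(f"duplicated sample id {dup!r} in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise TableFormatError(f"duplicated gene id {dup!r} in {path}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric count entry in {path}")
    if (values < 0).any():
        raise ValueError(f"negative count entry in {path}")
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"non-integer count entry in {path}")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_info(path) -> pd.DataFrame:
    info = pd.read_csv(path, sep="\t", index_col="sample_id",
                       dtype={"species": str, "substrate": str})
    if info.index.has_duplicates:
        raise TableFormatError(f"duplicated sample id in {path}")
    if "batch" not in info.columns:
        info["batch"] = info["species"]
    info["batch"] = info["batch"].fillna(info["species"])
    info["replicate"] = info["replicate"].astype(int)
    validate_sample_info(info)
    return info


def write_sample_info(info: pd.DataFrame, path) -> None:
    info.to_csv(path, sep="\t", index_label="sample_id")


def read_annotations(path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", index_col="gene_id")
    if annot.index.has_duplicates:
        raise TableFormatError(f"duplicated gene id in {path}")
    for col in ("secreted", "ssp"):
        if col in annot.columns and annot[col].dtype != bool:
            annot[col] = annot[col].astype(str).str.lower().isin(
                ("true", "1", "yes"))
    return annot


def write_annotations(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index_label="gene_id")


def read_orthogroups(path) -> OrthoGroups:
    """Read ortholog groups in OrthoFinder ``Orthogroups.tsv`` layout.

    First column is the group id; each further column is a species and holds
    a comma-separated list of that species' member genes. Member ids lacking
    the ``species|`` namespace prefix are namespaced on ingestion.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise TableFormatError(f"duplicated group id in {path}")
    species = tuple(df.columns)
    groups: dict[str, dict[str, list[str]]] = {}
    for gid, row in df.iterrows():
        members = {}
        for sp in species:
            cell = row[sp]
            if pd.isna(cell) or not str(cell).strip():
                continue
            genes = [g.strip() for g in str(cell).split(",") if g.strip()]
            genes = [g if "|" in g else f"{sp}|{g}" for g in genes]
            members[sp] = genes
        groups[str(gid)] = members
    return OrthoGroups(species, groups)


def write_orthogroups(ortho: OrthoGroups, path) -> None:
    rows = {}
    for gid, members in ortho.groups.items():
        rows[gid] = {sp: ", ".join(members.get(sp, []))
                     for sp in ortho.species}
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=list(ortho.species))
    df.to_csv(path, sep="\t", index_label="Orthogroup")


def read_secretome(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t",
                        dtype={"species": str, "substrate": str,
                               "gene_id": str})
    required = {"species", "substrate", "gene_id", "n_unique_peptides",
                "log_evalue"}
    missing = required - set(table.columns)
    if missing:
        raise TableFormatError(f"secretome table missing columns {missing}")
    if (table["n_unique_peptides"] < 0).any():
        raise ValueError("negative unique-peptide count")
    table["n_unique_peptides"] = table["n_unique_peptides"].astype(int)
    return table


def write_secretome(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    """Write a real-valued matrix with full float precision (round-trip safe)."""
    df.to_csv(path, sep="\t", index_label=index_label,
              float_format="%.17g")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


# ---------------------------------------------------------------------------
# validators
# ---------------------------------------------------------------------------

def validate_counts(counts: pd.DataFrame, sample_info: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        raise TableFormatError("duplicated gene ids")
    if counts.columns.has_duplicates:
        raise TableFormatError("duplicated sample ids")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    unknown = set(counts.columns) - set(sample_info.index)
    if unknown:
        raise ValueError(f"samples absent from sample info: {sorted(unknown)}")


def validate_sample_info(info: pd.DataFrame) -> None:
    key = info[["species", "substrate", "replicate"]]
    if key.duplicated().any():
        raise TableFormatError(
            "(species, substrate, replicate) combinations must be unique")
    if (info["replicate"] < 1).any():
        raise ValueError("replicate numbers must be positive")


def validate_annotations(annot: pd.DataFrame) -> None:
    if "ssp" in annot.columns:
        bad = annot["ssp"] & ~(annot["secreted"]
                               & (annot["protein_length"] < 300))
        if bad.any():
            raise ValueError(
                f"ssp flag inconsistent for {list(annot.index[bad])[:5]}")


def validate_orthogroups(ortho: OrthoGroups, annot: pd.DataFrame) -> None:
    known = set(annot.index)
    for gid, members in ortho.groups.items():
        for sp, genes in members.items():
            for g in genes:
                if g not in known:
                    raise ValueError(f"group {gid}: unknown gene {g!r}")
                if annot.loc[g, "species"] != sp:
                    raise ValueError(
                        f"group {gid}: gene {g!r} is not from species {sp}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def annotate_ssp(annot: pd.DataFrame, max_len: int = 300) -> pd.DataFrame:
    """Set the SSP flag: secreted and strictly shorter than ``max_len`` aa.

    Idempotent; no other column is modified. Raises if any protein length is
    missing.
    """
    if annot["protein_length"].isna().any():
        missing = annot.index[annot["protein_length"].isna()][0]
        raise ValueError(f"missing protein length for {missing!r}")
    out = annot.copy()
    out["ssp"] = out["secreted"] & (out["protein_length"] < max_len)
    return out


def one_to_one_groups(ortho: OrthoGroups, species_set) -> OrthoGroups:
    """Keep exactly the groups with one member gene in every listed species.

    The result is a subset of the input and the operation is idempotent.
    """
    species_set = tuple(species_set)
    if not species_set:
        raise ValueError("species_set must be non-empty")
    unknown = set(species_set) - set(ortho.species)
    if unknown:
        raise ValueError(f"unknown species {sorted(unknown)}")
    kept = {}
    for gid, members in ortho.groups.items():
        if all(len(members.get(sp, [])) == 1 for sp in species_set):
            kept[gid] = members
    return OrthoGroups(ortho.species, kept)


def species_of_gene(gene_id: str) -> str:
    """Extract the species namespace of a gene id ``"<species>|<id>"``."""
    sp, _, rest = gene_id.partition("|")
    if not rest:
        raise ValueError(f"gene id {gene_id!r} is not namespaced")
    return sp
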