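"""Synthetic multi-species RNA-seq + secretome generator with planted truth.

The generator emulates the study design every downstream stage expects:
three fungal species grown in triplicate on five substrates (maltose as the
non-inducing control), negative-binomial read counts, species-level batch
effects, planted substrate-responsive gene modules partly shared across
species through one-to-one ortholog groups, and conditional detection of
secreted proteins in the culture medium.

Counts are drawn NB(mean mu, dispersion alpha) with Var = mu + alpha mu^2,
where

    mu = baseline_g x substrate effect x 2^(batch shift) x library factor

Module genes carry a linear ``module_fold_change`` on their responsive
substrate(s). Batch effects are injected on the log2 scale as an additive
per-species shift plus an optional multiplicative scale around the global
baseline center -- exactly the structure a location-scale batch adjustment
can remove. Secreted proteins are detected Bernoulli(p_secrete_detect)
whenever the gene's expected expression on that substrate clears the
``detect_log2`` threshold, mirroring that proteomics only sees proteins
whose genes are strongly expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CONTROL_SUBSTRATE, SUBSTRATES, OrthoGroups

DEFAULT_SPECIES = ("sp_a", "sp_b", "sp_c")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study design scale: 3 species x 5 substrates x
    3 replicates and ~742 curated secretome-coding genes per species
    (2,226 genes in the combined analysis). Eight 25-gene modules are
    planted, cycling through the four inducing substrates; half of the
    modules are conserved (responsive in all species and mapped to
    one-to-one orthogroups), the rest respond in a single species.
    """

    n_species: int = 3
    species_names: tuple[str, ...] = DEFAULT_SPECIES
    substrates: tuple[str, ...] = SUBSTRATES
    control_substrate: str = CONTROL_SUBSTRATE
    n_replicates: int = 3
    n_genes_per_species: int = 742
    n_modules: int = 8
    module_size: int = 25
    module_fold_change: float = 8.0
    frac_conserved_modules: float = 0.5
    # natural-log scale baseline expression (lognormal across genes)
    baseline_log_mean: float = math.log(200.0)
    baseline_log_sd: float = 1.0
    # responsive-module genes are both induced and highly expressed
    module_baseline_boost: float = 6.0
    module_baseline_sd: float = 0.5
    nb_dispersion: float = 0.1
    batch_log2_shift: tuple[float, ...] = (0.0, 1.5, -1.0)
    batch_scale: tuple[float, ...] = (1.0, 1.0, 1.0)
    library_size_sd: float = 0.3
    library_size_factors: tuple[float, ...] | None = None
    p_secrete_detect: float = 0.6
    detect_log2: float = 12.0
    frac_secreted_module: float = 0.8
    frac_secreted_background: float = 0.3
    n_paralog_groups: int = 5
    drop_blocks: tuple[tuple[str, str], ...] = ()
    seed: int = 7

    def __post_init__(self) -> None:
        if len(self.species_names) < self.n_species:
            raise ValueError("not enough species names")
        if self.n_modules * self.module_size > self.n_genes_per_species:
            raise ValueError("modules do not fit into the gene set")
        for p in (self.frac_conserved_modules, self.p_secrete_detect,
                  self.frac_secreted_module, self.frac_secreted_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.control_substrate not in self.substrates:
            raise ValueError("control substrate must be among substrates")

    @property
    def species(self) -> tuple[str, ...]:
        return self.species_names[: self.n_species]

    @property
    def inducible_substrates(self) -> tuple[str, ...]:
        return tuple(s for s in self.substrates
                     if s != self.control_substrate)


@dataclass
class SimResult:
    counts: dict[str, pd.DataFrame]
    sample_info: pd.DataFrame
    annotations: pd.DataFrame
    orthogroups: OrthoGroups
    secretome: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_groups: pd.DataFrame
    config: SimConfig


def default_study_config(seed: int = 7) -> SimConfig:
    """The study-design configuration (3 species x 5 substrates x 3 reps)."""
    return SimConfig(seed=seed)


# family labels rotated over module/background genes; the first positions of
# the first two modules plant the co-regulation pairs the integration stage
# looks for (CDH with AA9 LPMOs on cellulose; MnP with GLOX on lignocellulose)
_MODULE_FAMILIES_CELLULOSE = (
    "AA8-AA3_1 CDH", "AA9", "AA9", "AA9", "GH7", "GH6", "GH5_5", "GH131",
    "GH10", "GH12", "GH74", "CE1", "GH28", "GH3", "GH1", "CE15",
)
_MODULE_FAMILIES_LIGNO = (
    "AA2 MnP", "AA5_1 GLOX", "AA1_1 laccase", "AA3_2 GMC", "GH16", "GH27",
    "GH30", "GH51", "CE16", "CE4", "GH2", "GH31", "PL14_4", "GH28",
    "peptidase", "GH18",
)
_BACKGROUND_FAMILIES = (
    "GH18", "GH76", "peptidase", "hydrophobin", "SSP", "GST", "CYP450",
    "GH5_7", "GH115", "CE8", "other",
)


def _module_layout(config: SimConfig):
    """Index ranges, responsive substrate and conservation of each module."""
    inducible = config.inducible_substrates
    n_conserved = int(round(config.frac_conserved_modules * config.n_modules))
    layout = []
    for k in range(config.n_modules):
        start = k * config.module_size
        layout.append({
            "module": k,
            "genes": range(start, start + config.module_size),
            "substrate": inducible[k % len(inducible)],
            "conserved": k < n_conserved,
            # non-conserved modules respond in a single species, round-robin
            "species": None if k < n_conserved
            else config.species[k % config.n_species],
        })
    return layout


def _family_for(idx: int, module: dict | None) -> str:
    if module is None:
        return _BACKGROUND_FAMILIES[idx % len(_BACKGROUND_FAMILIES)]
    pos = idx - module["genes"].start
    fams = (_MODULE_FAMILIES_CELLULOSE if module["substrate"] == "avicel"
            else _MODULE_FAMILIES_LIGNO)
    return fams[pos % len(fams)]


def simulate(config: SimConfig) -> SimResult:
    """Draw one synthetic study; identical config + seed => identical output."""
    rng = np.random.default_rng(config.seed)
    species = config.species
    n_genes = config.n_genes_per_species
    layout = _module_layout(config)
    module_of = {}
    for mod in layout:
        for i in mod["genes"]:
            module_of[i] = mod

    # --- sample metadata -------------------------------------------------
    rows = []
    for sp in species:
        for sub in config.substrates:
            if (sp, sub) in config.drop_blocks:
                continue
            for rep in range(1, config.n_replicates + 1):
                rows.append({"sample_id": f"{sp}.{sub}.{rep}", "species": sp,
                             "substrate": sub, "replicate": rep, "batch": sp})
    sample_info = pd.DataFrame(rows).set_index("sample_id")

    if config.library_size_factors is not None:
        if len(config.library_size_factors) != len(sample_info):
            raise ValueError("library_size_factors length mismatch")
        lib = np.asarray(config.library_size_factors, dtype=float)
    else:
        lib = np.exp(rng.normal(0.0, config.library_size_sd,
                                len(sample_info)))
    lib_of = pd.Series(lib, index=sample_info.index)

    # --- per-species baselines, counts -----------------------------------
    ln2 = math.log(2.0)
    center_log2 = config.baseline_log_mean / ln2
    counts: dict[str, pd.DataFrame] = {}
    baselines: dict[str, np.ndarray] = {}
    for si, sp in enumerate(species):
        base = np.exp(rng.normal(config.baseline_log_mean,
                                 config.baseline_log_sd, n_genes))
        is_module = np.array([i in module_of for i in range(n_genes)])
        boosted = np.exp(rng.normal(
            config.baseline_log_mean + math.log(config.module_baseline_boost),
            config.module_baseline_sd, n_genes))
        base = np.where(is_module, boosted, base)
        baselines[sp] = base

        cols = sample_info.index[sample_info["species"] == sp]
        mu = np.empty((n_genes, len(cols)))
        for j, sample in enumerate(cols):
            sub = sample_info.loc[sample, "substrate"]
            effect = np.ones(n_genes)
            for mod in layout:
                if mod["substrate"] != sub:
                    continue
                if mod["conserved"] or mod["species"] == sp:
                    effect[list(mod["genes"])] = config.module_fold_change
            m = base * effect
            shift = config.batch_log2_shift[si]
            scale = config.batch_scale[si]
            log2m = np.log2(np.maximum(m, 1e-12))
            log2m = center_log2 + scale * (log2m - center_log2) + shift
            mu[:, j] = np.exp2(log2m) * lib_of[sample]
        n_nb = 1.0 / config.nb_dispersion
        p_nb = n_nb / (n_nb + mu)
        draws = rng.negative_binomial(n_nb, p_nb)
        gene_ids = [f"{sp}|g{i:04d}" for i in range(n_genes)]
        counts[sp] = pd.DataFrame(draws, index=pd.Index(gene_ids,
                                                        name="gene_id"),
                                  columns=cols)

    # --- annotations ------------------------------------------------------
    annot_rows = []
    for sp in species:
        sec_draw = rng.random(n_genes)
        length = np.round(np.exp(rng.normal(math.log(400.0), 0.4,
                                            n_genes))).astype(int)
        for i in range(n_genes):
            mod = module_of.get(i)
            fam = _family_for(i, mod)
            if fam in ("AA8-AA3_1 CDH", "AA9", "AA2 MnP", "AA5_1 GLOX",
                       "hydrophobin", "SSP"):
                secreted = True
            elif mod is not None:
                secreted = sec_draw[i] < config.frac_secreted_module
            else:
                secreted = sec_draw[i] < config.frac_secreted_background
            plen = int(length[i])
            if fam == "SSP":
                plen = 120 + (i * 13) % 160  # < 300 aa by construction
            annot_rows.append({
                "gene_id": f"{sp}|g{i:04d}", "species": sp, "family": fam,
                "protein_length": plen, "secreted": bool(secreted),
            })
    annotations = pd.DataFrame(annot_rows).set_index("gene_id")
    annotations["ssp"] = (annotations["secreted"]
                          & (annotations["protein_length"] < 300))

    # --- orthogroups ------------------------------------------------------
    # every gene index is a 1-to-1 group across species, except the last
    # 2 x n_paralog_groups background indices which form within-species
    # paralog pairs (not 1-to-1, exercised by the retrieval filter)
    paralog_idx = set()
    pairs = []
    for j in range(config.n_paralog_groups):
        a = n_genes - 2 * (j + 1)
        b = a + 1
        if a in module_of or b in module_of or a < 0:
            break
        paralog_idx.update((a, b))
        pairs.append((a, b))
    groups: dict[str, dict[str, list[str]]] = {}
    for i in range(n_genes):
        if i in paralog_idx:
            continue
        groups[f"OG{i:05d}"] = {sp: [f"{sp}|g{i:04d}"] for sp in species}
    for j, (a, b) in enumerate(pairs):
        members = {sp: [f"{sp}|g{a:04d}"] for sp in species[1:]}
        members[species[0]] = [f"{species[0]}|g{a:04d}",
                               f"{species[0]}|g{b:04d}"]
        groups[f"OGP{j:03d}"] = members
        for sp in species[1:]:
            groups[f"OGS{j:03d}.{sp}"] = {sp: [f"{sp}|g{b:04d}"]}
    orthogroups = OrthoGroups(tuple(species), groups)

    # --- truth tables -----------------------------------------------------
    truth_rows = []
    for sp in species:
        for i in range(n_genes):
            mod = module_of.get(i)
            responsive = ""
            fc = 1.0
            mid = -1
            if mod is not None:
                mid = mod["module"]
                if mod["conserved"] or mod["species"] == sp:
                    responsive = mod["substrate"]
                    fc = config.module_fold_change
            truth_rows.append({"gene_id": f"{sp}|g{i:04d}", "species": sp,
                               "module": mid,
                               "responsive_substrates": responsive,
                               "fold_change": fc})
    truth_genes = pd.DataFrame(truth_rows).set_index("gene_id")

    group_rows = []
    for gid, members in groups.items():
        conserved = False
        substrate = ""
        if all(len(members.get(sp, [])) == 1 for sp in species):
            i = int(next(iter(members.values()))[0].split("g")[-1])
            mod = module_of.get(i)
            if mod is not None and mod["conserved"]:
                conserved = True
                substrate = mod["substrate"]
        group_rows.append({"group_id": gid, "conserved": conserved,
                           "substrate": substrate})
    truth_groups = pd.DataFrame(group_rows).set_index("group_id")

    # --- secretome --------------------------------------------------------
    sec_rows = []
    for sp in species:
        for sub in config.substrates:
            if (sp, sub) in config.drop_blocks:
                continue
            for i in range(n_genes):
                gene = f"{sp}|g{i:04d}"
                if not annotations.loc[gene, "secreted"]:
                    continue
                mod = module_of.get(i)
                effect = 1.0
                if (mod is not None and mod["substrate"] == sub
                        and (mod["conserved"] or mod["species"] == sp)):
                    effect = config.module_fold_change
                expected_log2 = math.log2(baselines[sp][i] * effect + 1.0)
                if expected_log2 <= config.detect_log2:
                    # sparse sub-threshold junk rows keep validation honest
                    if rng.random() < 0.01:
                        sec_rows.append({
                            "species": sp, "substrate": sub, "gene_id": gene,
                            "n_unique_peptides": int(rng.integers(1, 3)),
                            "log_evalue": float(-2.6 + rng.random()),
                        })
                    continue
                if rng.random() < config.p_secrete_detect:
                    sec_rows.append({
                        "species": sp, "substrate": sub, "gene_id": gene,
                        "n_unique_peptides": 2 + int(rng.poisson(3.0)),
                        "log_evalue": float(-2.7 - rng.exponential(3.0)),
                    })
    secretome = pd.DataFrame(
        sec_rows, columns=["species", "substrate", "gene_id",
                           "n_unique_peptides", "log_evalue"])

    return SimResult(counts=counts, sample_info=sample_info,
                     annotations=annotations, orthogroups=orthogroups,
                     secretome=secretome, truth_genes=truth_genes,
                     truth_groups=truth_groups, config=config)
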