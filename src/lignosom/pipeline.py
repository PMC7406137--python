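"""End-to-end orchestration: simulate (or load) -> normalize -> harmonize ->
cluster -> select -> conserve -> overlay -> report.

Every stage writes plain TSV so each is independently inspectable and
testable; a JSON manifest records the seed, all stage parameters and the
SHA-256 of every output, so a rerun with the same configuration is
bit-identical.

The combined cross-species matrix stacks each species' genes as rows over
shared (substrate, replicate) condition slots, restricted to the substrates
available in every species (a species with a dropped substrate block simply
excludes that substrate from the cross-species map, while its per-species
fold-change calls still cover all of its own substrates). Species-level
batch structure therefore runs along the rows, and the location-scale
adjustment is applied to the transposed matrix with the gene's species as
its batch label.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import batch as batch_mod
from . import conserve as conserve_mod
from . import io as io_mod
from . import nodesel, normalize, secretome, som as som_mod
from .io import FilterConfig
from .simulate import SimConfig, SimResult, simulate
from .som import SOMConfig
from .util import sha256_of, truncated_percent, write_json

DEFAULT_QUERIES = (("AA8-AA3_1 CDH", "AA9"), ("AA2 MnP", "AA5_1 GLOX"))


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    som: SOMConfig = field(default_factory=SOMConfig)
    outdir: str = "run"
    seed: int = 7
    queries: tuple[tuple[str, str], ...] = DEFAULT_QUERIES
    responsive_substrates: tuple[str, ...] = ("avicel", "wheat_straw",
                                              "aspen")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "sim" in raw:
            sim = dict(raw["sim"])
            for key in ("species_names", "substrates", "batch_log2_shift",
                        "batch_scale", "library_size_factors"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            if "drop_blocks" in sim:
                sim["drop_blocks"] = tuple(tuple(b)
                                           for b in sim["drop_blocks"])
            kwargs["sim"] = SimConfig(**sim)
        if "filters" in raw:
            kwargs["filters"] = FilterConfig(**raw["filters"])
        if "som" in raw:
            kwargs["som"] = SOMConfig(**raw["som"])
        for key in ("outdir", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "queries" in raw:
            kwargs["queries"] = tuple(tuple(q) for q in raw["queries"])
        if "responsive_substrates" in raw:
            kwargs["responsive_substrates"] = tuple(
                raw["responsive_substrates"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "sim": dataclasses.asdict(self.sim),
            "filters": dataclasses.asdict(self.filters),
            "som": dataclasses.asdict(self.som),
            "outdir": str(self.outdir), "seed": self.seed,
            "queries": [list(q) for q in self.queries],
            "responsive_substrates": list(self.responsive_substrates),
        }


def derive_seed(seed: int, offset: int) -> int:
    """Fan one master seed out to per-stage seeds (kept below 2^31)."""
    return (seed * 1009 + offset) % (2 ** 31)


def combine_species(log2_expr: dict[str, pd.DataFrame],
                    sample_info: pd.DataFrame) -> tuple[pd.DataFrame,
                                                        pd.Series]:
    """Stack per-species log2 matrices over shared condition slots.

    Returns the stacked genes x condition matrix (columns named
    ``"<substrate>.<k>"``) and a Series mapping each column to its
    substrate. Only substrates present in every species are kept; per
    substrate, the number of replicate slots is the minimum across species,
    and each species' replicates fill the slots in replicate-number order.
    """
    species = list(log2_expr)
    per_species_subs = []
    for sp in species:
        info = sample_info[sample_info["species"] == sp]
        per_species_subs.append(set(info["substrate"]))
    shared = sorted(set.intersection(*per_species_subs),
                    key=list(io_mod.SUBSTRATES).index)
    blocks = []
    cond_of_col: dict[str, str] = {}
    for sp in species:
        info = sample_info[sample_info["species"] == sp]
        cols, names = [], []
        for sub in shared:
            samples = info[info["substrate"] == sub].sort_values("replicate")
            n_slots = min(
                len(sample_info[(sample_info["species"] == s)
                                & (sample_info["substrate"] == sub)])
                for s in species)
            for k, sample in enumerate(samples.index[:n_slots], start=1):
                cols.append(sample)
                names.append(f"{sub}.{k}")
                cond_of_col[f"{sub}.{k}"] = sub
        block = log2_expr[sp][cols]
        block.columns = names
        blocks.append(block)
    combined = pd.concat(blocks, axis=0)
    return combined, pd.Series(cond_of_col)


def recovery_metrics(truth_genes: pd.DataFrame, selection: pd.DataFrame,
                     assignment: pd.Series, substrate: str) -> dict:
    """Sensitivity/FDR of a node selection against planted module genes."""
    planted = set(truth_genes.index[
        truth_genes["responsive_substrates"] == substrate])
    nodes = set(selection.loc[selection["substrate"] == substrate, "node"])
    selected = set(assignment.index[assignment.isin(nodes)])
    tp = len(planted & selected)
    return {
        "substrate": substrate,
        "n_planted": len(planted), "n_selected": len(selected),
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "fdr": (len(selected) - tp) / len(selected) if selected
        else float("nan"),
    }


def conserved_recovery(truth_groups: pd.DataFrame,
                       conserved: pd.DataFrame) -> dict:
    """Fraction of planted conserved orthogroups called conserved-up on
    their planted substrate (among groups whose substrate was analysed)."""
    truth = truth_groups[truth_groups["conserved"]]
    calls = conserved.set_index(["group_id", "substrate"])["conserved"]
    analysed = [(gid, row["substrate"]) for gid, row in truth.iterrows()
                if (gid, row["substrate"]) in calls.index]
    if not analysed:
        return {"n_groups": 0, "fraction_conserved_up": float("nan")}
    n_up = sum(calls[key] == "up" for key in analysed)
    return {"n_groups": len(analysed),
            "fraction_conserved_up": n_up / len(analysed)}


def run_pipeline(config: PipelineConfig,
                 sim_result: SimResult | None = None) -> dict:
    """Execute every stage, write all artifacts under ``config.outdir`` and
    return the run manifest."""
    out = Path(config.outdir)
    artifacts: dict[str, Path] = {}

    def save(name: str, writer, *args) -> None:
        path = out / name
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(*args, path)
        artifacts[name] = path

    # -- stage 1: synthetic study -----------------------------------------
    stage = "simulate"
    try:
        if sim_result is None:
            sim_cfg = replace(config.sim, seed=derive_seed(config.seed, 1))
            sim_result = simulate(sim_cfg)
        sim = sim_result
        for sp, counts in sim.counts.items():
            save(f"01_sim/counts_{sp}.tsv", io_mod.write_counts, counts)
        save("01_sim/sample_info.tsv", io_mod.write_sample_info,
             sim.sample_info)
        save("01_sim/annotations.tsv", io_mod.write_annotations,
             sim.annotations)
        save("01_sim/orthogroups.tsv", io_mod.write_orthogroups,
             sim.orthogroups)
        save("01_sim/secretome.tsv", io_mod.write_secretome, sim.secretome)
        save("01_sim/truth_genes.tsv", io_mod.write_annotations,
             sim.truth_genes)
        save("01_sim/truth_groups.tsv",
             lambda df, p: df.to_csv(p, sep="\t"), sim.truth_groups)

        # -- stage 2: per-species normalization ---------------------------
        stage = "normalize"
        cfg = config.filters
        log2_expr: dict[str, pd.DataFrame] = {}
        calls_frames = []
        sf_rows = []
        for sp, counts in sim.counts.items():
            masked = normalize.mask_low_counts(counts, sim.sample_info,
                                               cfg.low_count_mean)
            factors = normalize.size_factors(masked)
            log2_expr[sp] = normalize.normalize_log2(masked, factors)
            calls = normalize.fold_changes(
                masked, factors, sim.sample_info,
                control=cfg.control_substrate,
                fc_threshold=cfg.fc_threshold)
            calls.insert(0, "species", sp)
            calls_frames.append(calls)
            sf_rows.append(factors)
            save(f"02_normalize/log2_{sp}.tsv", io_mod.write_matrix,
                 log2_expr[sp])
        calls = pd.concat(calls_frames, ignore_index=True)
        save("02_normalize/size_factors.tsv",
             lambda s, p: pd.concat(s).to_csv(p, sep="\t",
                                              index_label="sample_id",
                                              header=["size_factor"]),
             sf_rows)
        save("02_normalize/calls.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), calls)

        # -- stage 3: combine + batch adjust + quantile normalize ---------
        stage = "harmonize"
        combined, cond_of_col = combine_species(log2_expr, sim.sample_info)
        save("03_harmonize/combined.tsv", io_mod.write_matrix, combined)
        gene_species = pd.Series(
            [io_mod.species_of_gene(g) for g in combined.index],
            index=combined.index)
        adjusted_t, model = batch_mod.batch_adjust(
            combined.T, batch=gene_species, covariate=None)
        adjusted = adjusted_t.T
        save("03_harmonize/adjusted.tsv", io_mod.write_matrix, adjusted)
        if model is not None:
            save("03_harmonize/batch_model.tsv",
                 lambda m, p: m.to_frame().to_csv(p, sep="\t", index=False),
                 model)
        harmonized = batch_mod.quantile_normalize(adjusted)
        save("03_harmonize/quantile.tsv", io_mod.write_matrix, harmonized)

        # -- stage 4: SOM --------------------------------------------------
        stage = "cluster"
        som_cfg = replace(config.som, seed=derive_seed(config.seed, 2))
        model_som = som_mod.train_som(harmonized, som_cfg)
        stats = som_mod.node_stats(model_som, harmonized, cond_of_col,
                                   control=cfg.control_substrate)
        save("04_som/codebook.tsv",
             lambda m, p: pd.DataFrame(
                 m.codebook, columns=m.feature_names).to_csv(
                 p, sep="\t", index_label="node"), model_som)
        assign_table = pd.DataFrame({
            "node": model_som.assignment,
            "row": [model_som.unit_position(u)[0]
                    for u in model_som.assignment],
            "col": [model_som.unit_position(u)[1]
                    for u in model_som.assignment],
        })
        save("04_som/assignment.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index_label="gene_id"),
             assign_table)
        save("04_som/node_means.tsv", io_mod.write_matrix, stats.means)
        save("04_som/node_fc.tsv", io_mod.write_matrix, stats.fold_change)

        # -- stage 5: node selection ---------------------------------------
        stage = "select"
        selections = []
        for sub in config.responsive_substrates:
            if sub not in stats.means.columns:
                continue
            selections.append(nodesel.select_responsive(stats, sub, cfg))
        responsive = (pd.concat(selections, ignore_index=True) if selections
                      else pd.DataFrame(columns=["node", "substrate",
                                                 "criterion"]))
        specific_targets = [s for s in ("wheat_straw", "aspen")
                            if s in stats.means.columns]
        specific = nodesel.select_specific(
            stats, target_substrates=specific_targets, cfg=cfg) \
            if specific_targets else pd.DataFrame(
                columns=["node", "substrate", "criterion"])
        genes_sel = nodesel.genes_of_selection(responsive, model_som,
                                               sim.annotations)
        save("05_select/responsive.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), responsive)
        save("05_select/specific.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), specific)
        save("05_select/genes_selected.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), genes_sel)

        # -- stage 6: conservation -----------------------------------------
        stage = "conserve"
        one2one = io_mod.one_to_one_groups(sim.orthogroups,
                                           sim.orthogroups.species)
        fmat = conserve_mod.coortholog_fold_matrix(calls, one2one)
        conserved = conserve_mod.conserved_regulation(
            fmat, threshold=cfg.fc_threshold)
        per_species, cons_counts = conserve_mod.family_summary(
            fmat, conserved, one2one, sim.annotations, cfg.fc_threshold)
        aligned = conserve_mod.align_ortholog_expression(harmonized, one2one)
        corr = conserve_mod.sample_correlation(aligned)
        flat = fmat.copy()
        flat.columns = [f"{sp}.{sub}" for sp, sub in fmat.columns]
        save("06_conserve/fold_matrix.tsv", io_mod.write_matrix, flat)
        save("06_conserve/conserved.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), conserved)
        save("06_conserve/family_per_species.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), per_species)
        save("06_conserve/family_conserved.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), cons_counts)
        corr_flat = corr.copy()
        corr_flat.columns = [f"{a}.{b}" for a, b in corr.columns]
        corr_flat.index = corr_flat.columns
        save("06_conserve/correlation.tsv", io_mod.write_matrix, corr_flat)

        # -- stage 7: secretome overlay --------------------------------------
        stage = "overlay"
        evidence = secretome.validate_secretome(sim.secretome, cfg)
        per_node, global_stats = secretome.overlay_nodes(
            responsive, model_som, evidence, calls, sim.annotations)
        cosec = secretome.coexpression_cosecretion_report(
            model_som, sim.annotations, evidence, config.queries)
        save("07_secretome/evidence.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), evidence)
        save("07_secretome/overlay_nodes.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), per_node)
        save("07_secretome/overlay_global.json", write_json, global_stats)
        save("07_secretome/cosecretion.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), cosec)

        # -- stage 8: report --------------------------------------------------
        stage = "report"
        recov = [recovery_metrics(sim.truth_genes, responsive,
                                  model_som.assignment, sub)
                 for sub in config.responsive_substrates
                 if sub in stats.means.columns]
        recovery = pd.DataFrame(recov)
        save("08_report/recovery.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), recovery)
        cons_recov = conserved_recovery(sim.truth_groups, conserved)
        save("08_report/conserved_recovery.json", write_json, cons_recov)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "quant_error": model_som.quant_error,
        "map": {"rows": model_som.rows, "cols": model_som.cols,
                "units": model_som.units},
        "outputs": {name: sha256_of(path)
                    for name, path in sorted(artifacts.items())},
    }
    write_json(manifest, out / "manifest.json")
    return manifest


def report(run_dir) -> dict:
    """Summarize a completed run; recovery metrics are included when the
    truth tables are present."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}: incomplete run")
    import json
    manifest = json.loads(manifest_path.read_text())
    needed = ["05_select/responsive.tsv", "06_conserve/conserved.tsv",
              "07_secretome/overlay_global.json"]
    for name in needed:
        if not (run_dir / name).exists():
            raise FileNotFoundError(f"incomplete run: missing {name}")
    responsive = pd.read_csv(run_dir / "05_select/responsive.tsv", sep="\t")
    conserved = pd.read_csv(run_dir / "06_conserve/conserved.tsv", sep="\t")
    overlay = json.loads(
        (run_dir / "07_secretome/overlay_global.json").read_text())
    summary = {
        "seed": manifest["seed"],
        "n_selected_nodes": int(responsive["node"].nunique())
        if not responsive.empty else 0,
        "n_conserved_up": int((conserved["conserved"] == "up").sum()),
        "n_conserved_down": int((conserved["conserved"] == "down").sum()),
        "secretome_overlay": overlay,
    }
    recovery_path = run_dir / "08_report/recovery.tsv"
    if recovery_path.exists():
        summary["recovery"] = pd.read_csv(
            recovery_path, sep="\t").to_dict("records")
        cr = run_dir / "08_report/conserved_recovery.json"
        if cr.exists():
            summary["conserved_recovery"] = json.loads(cr.read_text())
    lines = ["# Run summary", ""]
    lines.append(f"- seed: {summary['seed']}")
    lines.append(f"- selected nodes: {summary['n_selected_nodes']}")
    lines.append(f"- conserved-up (group, substrate) calls: "
                 f"{summary['n_conserved_up']}")
    frac = overlay.get("fraction_detected")
    if frac is not None and not (isinstance(frac, float) and np.isnan(frac)):
        lines.append(f"- up-regulated genes with validated protein "
                     f"detection: {truncated_percent(overlay['n_up_detected'], max(overlay['n_up_regulated'], 1))}%")
    (run_dir / "08_report").mkdir(exist_ok=True, parents=True)
    (run_dir / "08_report/summary.md").write_text("\n".join(lines) + "\n")
    return summary
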