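"""End-to-end pipeline: simulate/load -> validate -> stats -> network -> assembly.

A :class:`RunConfig` (loadable from a ``key = value`` file) fully
determines a run; identical config + seed give byte-identical outputs and
an identical manifest.  Each stage writes its artifacts under the output
directory and records them, with SHA-256 checksums and record counts, in
``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assembly import beta_nti, fit_neutral, niche_breadth, partition_processes, raup_crick_bray
from .diversity import bray_curtis, core_taxa, enrichment, pcoa, permanova, shannon_per_sample
from .errors import PhylloError, ValidationError
from .network import network_from_table, node_metrics, summarize, write_edge_list, write_node_table
from .simulate import DesignSpec, ScenarioParams, simulate_scenario
from .tables import (
    FeatureTable,
    SampleMetadata,
    read_feature_table,
    read_metadata,
    read_tree,
    write_feature_table,
    write_metadata,
    write_taxonomy,
    write_tree,
)

log = logging.getLogger("phyllo")

_BOOLS = {"true": True, "false": False, "yes": True, "no": False}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults equal the published thresholds wherever the study states one
    (rare filter 0.01 %, core 100 % prevalence / >0.1 % abundance, |log2FC|
    > 2 at FDR < 0.01, |rho| > 0.6 at adjusted p < 0.01, βNTI cut 2, RC cut
    0.95) and the module's documented decision otherwise.
    """

    # inputs: either file paths ...
    table_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    # ... or a simulation spec
    scenario: str | None = "neutral"
    n_sites: int = 3
    n_genotypes: int = 2
    n_replicates: int = 5
    n_taxa_per_kingdom: int = 200
    reads_per_sample: int = 20_000
    nm: float = 50.0

    # stage toggles
    run_diversity: bool = True
    run_core: bool = True
    run_enrichment: bool = True
    run_network: bool = True
    run_assembly: bool = True

    # thresholds
    rare_min: float = 0.0001
    prevalence_min: float = 1.0
    abundance_min: float = 0.001
    lfc_min: float = 2.0
    fdr_max: float = 0.01
    rho_min: float = 0.6
    p_max: float = 0.01
    nti_cut: float = 2.0
    rc_cut: float = 0.95

    n_permutations: int = 999
    n_null: int = 999
    seed: int = 0
    outdir: str = "phyllo_run"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        values: dict[str, object] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
            typ = fields[key].type
            if val.lower() == "none":
                values[key] = None
            elif "bool" in str(typ):
                values[key] = _BOOLS[val.lower()]
            elif "int" in str(typ):
                values[key] = int(val)
            elif "float" in str(typ):
                values[key] = float(val)
            else:
                values[key] = val
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    def validate(self) -> None:
        for name, lo, hi in (
            ("rare_min", 0.0, 1.0), ("prevalence_min", 0.0, 1.0), ("abundance_min", 0.0, 1.0),
            ("fdr_max", 0.0, 1.0), ("rho_min", 0.0, 1.0), ("p_max", 0.0, 1.0),
            ("rc_cut", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValidationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.table_path is None and self.scenario is None:
            raise ValidationError("config needs either input paths or a simulation scenario")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in ("rare_min", "prevalence_min", "abundance_min", "lfc_min",
                      "fdr_max", "rho_min", "p_max", "nti_cut", "rc_cut")
        },
        "stages": {},
    }

    def record(stage: str, path: Path, n_records: int) -> None:
        manifest["stages"].setdefault(stage, []).append(
            {"path": str(path.relative_to(outdir)), "sha256": _sha256(path), "n_records": n_records}
        )

    stage = "input"
    try:
        trees = {}
        if config.table_path is not None:
            table = read_feature_table(config.table_path, config.taxonomy_path)
            meta = read_metadata(config.metadata_path).align_to(table)
            if config.tree_path is not None:
                trees["all"] = read_tree(config.tree_path)
        else:
            log.info("simulating scenario %s (seed %d)", config.scenario, config.seed)
            design = DesignSpec(
                n_sites=config.n_sites, n_genotypes=config.n_genotypes,
                n_replicates=config.n_replicates,
                n_taxa_per_kingdom=config.n_taxa_per_kingdom,
                reads_per_sample=config.reads_per_sample, seed=config.seed,
            )
            params = ScenarioParams(scenario=config.scenario, nm=config.nm)
            sim = simulate_scenario(design, params)
            table, meta, trees = sim.table, sim.metadata, sim.trees
            write_feature_table(table, outdir / "table.tsv")
            write_taxonomy(table, outdir / "taxonomy.tsv")
            write_metadata(meta, outdir / "metadata.tsv")
            for king, tree in trees.items():
                write_tree(tree, outdir / f"tree_{king}.nwk")
                record("simulate", outdir / f"tree_{king}.nwk", len(tree.taxon_namespace))
            record("simulate", outdir / "table.tsv", table.shape[0])
            record("simulate", outdir / "metadata.tsv", len(meta.sample_ids))
        manifest["n_taxa"], manifest["n_samples"] = table.shape

        if config.run_diversity:
            stage = "diversity"
            sh = shannon_per_sample(table)
            sh.to_csv(outdir / "shannon.tsv", sep="\t", header=True)
            record(stage, outdir / "shannon.tsv", len(sh))
            dm = bray_curtis(table)
            pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.sample_ids).to_csv(
                outdir / "bray_curtis.tsv", sep="\t"
            )
            record(stage, outdir / "bray_curtis.tsv", len(dm.sample_ids))
            ord_res = pcoa(dm, k=2)
            coords = pd.DataFrame(ord_res.coordinates, index=ord_res.sample_ids,
                                  columns=[f"PCo{i+1}" for i in range(ord_res.coordinates.shape[1])])
            with open(outdir / "pcoa.tsv", "w") as fh:
                fh.write("# eigenvalues: " + ",".join(f"{v:.6g}" for v in ord_res.eigenvalues) + "\n")
                fh.write("# proportion_explained: "
                         + ",".join(f"{v:.6g}" for v in ord_res.proportion_explained) + "\n")
                coords.to_csv(fh, sep="\t")
            record(stage, outdir / "pcoa.tsv", len(ord_res.sample_ids))
            perm_rows = []
            for factor in ("site", "genotype"):
                if meta.frame[factor].nunique() > 1:
                    res = permanova(dm, meta, factor, config.n_permutations, config.seed)
                    perm_rows.append((factor, res.r2, res.pseudo_f, res.p_value, res.n_permutations))
            perm = pd.DataFrame(perm_rows, columns=["factor", "R2", "pseudo_F", "p", "n_permutations"])
            perm.to_csv(outdir / "permanova.tsv", sep="\t", index=False)
            record(stage, outdir / "permanova.tsv", len(perm))

        if config.run_core:
            stage = "core"
            core = core_taxa(table, config.prevalence_min, config.abundance_min)
            core_df = pd.DataFrame(
                {"prevalence": core.prevalence, "mean_relabund": core.mean_relabund}
            ).loc[core.core_ids]
            core_df.index.name = "#ASV_ID"
            core_df.to_csv(outdir / "core_taxa.tsv", sep="\t")
            record(stage, outdir / "core_taxa.tsv", len(core_df))

        if config.run_enrichment and meta.frame["genotype"].nunique() == 2:
            stage = "enrichment"
            enr = enrichment(table, meta, "genotype", config.lfc_min, config.fdr_max)
            enr.index.name = "#ASV_ID"
            enr.to_csv(outdir / "enrichment.tsv", sep="\t")
            record(stage, outdir / "enrichment.tsv", len(enr))

        if config.run_network:
            stage = "network"
            for geno in pd.unique(meta.frame["genotype"]):
                sub = table.subset_samples(meta.samples_for("genotype", geno)).drop_absent_taxa()
                g = network_from_table(sub, config.rho_min, config.p_max, config.rare_min)
                write_edge_list(g, outdir / f"network_{geno}_edges.tsv")
                write_node_table(g, outdir / f"network_{geno}_nodes.tsv")
                summary = summarize(g)
                (outdir / f"network_{geno}_summary.json").write_text(
                    json.dumps(dataclasses.asdict(summary), indent=2, sort_keys=True)
                )
                record(stage, outdir / f"network_{geno}_edges.tsv", g.number_of_edges())
                record(stage, outdir / f"network_{geno}_nodes.tsv", g.number_of_nodes())
                record(stage, outdir / f"network_{geno}_summary.json", 1)

        if config.run_assembly:
            stage = "assembly"
            if config.run_assembly and not trees and config.tree_path is None and config.table_path is not None:
                raise ValidationError("assembly stage requires a tree (tree_path)")
            for geno in pd.unique(meta.frame["genotype"]):
                samples = meta.samples_for("genotype", geno)
                sub = table.subset_samples(samples).drop_absent_taxa()
                for king, tree in trees.items():
                    king_taxa = [t for t in sub.taxon_ids
                                 if king == "all" or sub.kingdom[t] == king]
                    ksub = FeatureTable(sub.counts.loc[king_taxa], sub.kingdom.loc[king_taxa])
                    fit = fit_neutral(ksub)
                    fit.per_taxon.to_csv(outdir / f"neutral_{geno}_{king}.tsv", sep="\t")
                    (outdir / f"neutral_{geno}_{king}_summary.json").write_text(json.dumps({
                        "m": fit.m, "Nm": fit.nm, "N": fit.n, "R2": fit.r2,
                        "fraction_deviating": fit.fraction_deviating,
                    }, indent=2, sort_keys=True))
                    record(stage, outdir / f"neutral_{geno}_{king}.tsv", len(fit.per_taxon))
                    record(stage, outdir / f"neutral_{geno}_{king}_summary.json", 1)
                    nb = niche_breadth(ksub)
                    nb.per_taxon.to_csv(outdir / f"niche_breadth_{geno}_{king}.tsv",
                                        sep="\t", header=True)
                    record(stage, outdir / f"niche_breadth_{geno}_{king}.tsv", len(nb.per_taxon))
                    nti = beta_nti(ksub, tree, n_null=config.n_null, seed=config.seed)
                    rc = raup_crick_bray(ksub, n_null=config.n_null, seed=config.seed)
                    frac = partition_processes(nti.beta_nti, rc, config.nti_cut, config.rc_cut)
                    nti.beta_nti.to_csv(outdir / f"betanti_{geno}_{king}.tsv", sep="\t")
                    rc.to_csv(outdir / f"rcbray_{geno}_{king}.tsv", sep="\t")
                    pd.Series(frac.fractions).to_csv(
                        outdir / f"processes_{geno}_{king}.tsv", sep="\t", header=False
                    )
                    record(stage, outdir / f"processes_{geno}_{king}.tsv", frac.n_pairs)
    except PhylloError as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
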