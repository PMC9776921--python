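"""End-to-end orchestration of the differential co-expression analysis.

The pipeline reproduces the full analysis graph on any pair of cohorts
(files on disk or the built-in simulator):

1. differential expression per cohort (Welch t + Benjamini–Hochberg);
2. top-K up/down selection and cross-cohort intersection (common
   gene lists);
3. over-representation of the common lists in a gene-set catalog and
   per-gene pathway counts;
4. co-expression network construction per cohort (variance filter,
   soft threshold, TOM, modules, eigengenes, kME);
5. modular differential connectivity with permutation p per cohort;
6. over-representation of the common lists in each network's modules;
7. three-criterion key-gene selection (PPI degree, pathway count,
   module hubness in every cohort's enriched modules);
8. cross-validated logistic ROC of the key genes plus a random-gene
   baseline.

Every intermediate is written as plain text into the output directory
and recorded in a JSON manifest.  One global seed deterministically
derives all stage seeds, so identical configuration yields
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, diffexpr, enrichment, io, keygenes, mdc, network, simulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline", "stage_seed"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % 2**31


@dataclass
class PipelineConfig:
    """All pipeline inputs and stage parameters in one place.

    Either ``simulation`` (a :class:`~mdconet.simulate.SimulationConfig`)
    or the four path groups must be supplied.  The stage defaults are
    the analysis constants of the workflow: K = 500 top genes,
    alpha = 0.05, fold-change 2, 1000 permutations, eigengene merge cut
    0.25, |kME| threshold 0.85, top-20 criterion cuts, 3 folds.
    """

    simulation: simulate.SimulationConfig | None = None
    expression_paths: tuple[str, str] | None = None
    label_paths: tuple[str, str] | None = None
    gmt_path: str | None = None
    ppi_path: str | None = None

    k: int = 500
    alpha: float = 0.05
    fc_threshold: float = 2.0
    n_perm: int = 1000
    network_config: network.NetworkConfig = field(default_factory=network.NetworkConfig)
    kme_threshold: float = 0.85
    top_n: int = 20
    folds: int = 3
    baseline_draws: int = 50
    classify_cohort: int = 1
    seed: int = 0
    out_dir: str = "mdconet_run"

    def validate(self) -> None:
        if self.simulation is None:
            for name in ("expression_paths", "label_paths", "gmt_path", "ppi_path"):
                if getattr(self, name) is None:
                    raise PipelineError(
                        f"config needs either a simulation block or {name}"
                    )
        if self.k < 1 or not 0 < self.alpha < 1 or self.n_perm < 100:
            raise PipelineError("stage parameters out of range")
        self.network_config.validate()


@dataclass
class RunManifest:
    """Per-stage record of inputs, outputs, parameters and warnings."""

    out_dir: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    results: dict = field(default_factory=dict)

    def record(self, name: str, outputs: list[str], params: dict, elapsed: float,
               warnings: list[str] | None = None) -> None:
        self.stages.append(
            {
                "stage": name,
                "outputs": outputs,
                "params": params,
                "wall_time_s": round(elapsed, 3),
                "warnings": warnings or [],
            }
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"out_dir": self.out_dir, "seed": self.seed, "stages": self.stages,
                 "results": self.results},
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def _load_inputs(config: PipelineConfig, out: Path):
    """Load or simulate the cohorts, catalog, PPI graph and (maybe) truth."""
    if config.simulation is not None:
        sim = config.simulation
        cohorts, truth = simulate.simulate_paired_cohorts(sim)
        catalog = simulate.simulate_gene_sets(truth, seed=stage_seed(config.seed, "gene_sets"))
        ppi = simulate.simulate_ppi(truth, seed=stage_seed(config.seed, "ppi"))
        for c, (mat, lab) in enumerate(cohorts, start=1):
            io.write_expression(mat, out / f"cohort{c}_expression.tsv")
            io.write_labels(lab, out / f"cohort{c}_labels.tsv")
        io.write_gmt(catalog, out / "gene_sets.gmt")
        io.write_edge_list(ppi, out / "ppi_edges.tsv")
        return cohorts, catalog, ppi, truth
    cohorts = []
    for expr_path, label_path in zip(config.expression_paths, config.label_paths):
        mat = io.read_expression(expr_path)
        lab = io.read_labels(label_path)
        lab.validate_against(mat)
        cohorts.append((mat, lab))
    catalog = io.read_gmt(config.gmt_path)
    ppi = io.read_edge_list(config.ppi_path)
    return cohorts, catalog, ppi, None


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis graph; returns the run manifest.

    Any stage error aborts with :class:`PipelineError` naming the stage;
    the manifest written so far remains in the output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(str(out), config.seed)

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    manifest.write(out / "manifest.json")
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                return False

            def done(self_inner, outputs, params, warnings=None):
                manifest.record(
                    name, outputs, params, time.perf_counter() - self_inner.t0, warnings
                )

        return _Stage()

    # -- inputs -------------------------------------------------------------
    with stage("inputs") as st:
        cohorts, catalog, ppi, truth = _load_inputs(config, out)
        st.done(
            [str(out / "manifest.json")],
            {"n_cohorts": len(cohorts), "simulated": config.simulation is not None},
        )

    # -- differential expression per cohort --------------------------------
    de_tables = []
    top_lists = []
    with stage("diffexpr") as st:
        for c, (mat, lab) in enumerate(cohorts, start=1):
            de = diffexpr.two_group_test(mat, lab)
            de.to_csv(out / f"cohort{c}_de.tsv", sep="\t", float_format="%.6g")
            de_tables.append(de)
            top_lists.append(
                (
                    diffexpr.select_top_k(de, config.k, "up", alpha=config.alpha),
                    diffexpr.select_top_k(de, config.k, "down", alpha=config.alpha),
                )
            )
        st.done(
            [str(out / f"cohort{c}_de.tsv") for c in range(1, len(cohorts) + 1)],
            {"k": config.k, "alpha": config.alpha},
        )

    # -- cross-cohort common gene lists -------------------------------------
    with stage("common_genes") as st:
        common = diffexpr.common_pattern_genes(top_lists[0], top_lists[1], k=config.k)
        for name, genes in (("up", common.common_up), ("down", common.common_down)):
            (out / f"common_{name}.txt").write_text(
                "\n".join(sorted(genes)) + ("\n" if genes else "")
            )
        st.done(
            [str(out / "common_up.txt"), str(out / "common_down.txt")],
            {"n_up": len(common.common_up), "n_down": len(common.common_down)},
        )

    universe = set(cohorts[0][0].genes)

    # -- enrichment of the common lists -------------------------------------
    ora_results = {}
    pathway_counts = {}
    with stage("enrichment") as st:
        for direction, genes in (("up", common.common_up), ("down", common.common_down)):
            if not genes:
                ora_results[direction] = pd.DataFrame(
                    columns=["set_size", "overlap", "pvalue", "padj"]
                )
                pathway_counts[direction] = {}
                continue
            ora = enrichment.ora_hypergeometric(genes, catalog, universe)
            ora.to_csv(out / f"ora_{direction}.tsv", sep="\t", float_format="%.6g")
            ora_results[direction] = ora
            pathway_counts[direction] = enrichment.pathway_membership_counts(
                genes, ora, catalog, alpha=config.alpha
            )
        st.done(
            [str(out / f"ora_{d}.tsv") for d in ("up", "down")],
            {"alpha": config.alpha, "n_sets": len(catalog)},
        )

    # -- co-expression networks per cohort ----------------------------------
    networks = []
    with stage("network") as st:
        for c, (mat, lab) in enumerate(cohorts, start=1):
            filtered, partition, eigen, kme_table, power = network.build_network(
                mat, config.network_config
            )
            partition.to_frame().to_csv(out / f"cohort{c}_modules.tsv", sep="\t")
            eigen.to_frame().to_csv(
                out / f"cohort{c}_eigengenes.tsv", sep="\t", float_format="%.6g"
            )
            kme_table.to_csv(out / f"cohort{c}_kme.tsv", sep="\t", float_format="%.6g")
            networks.append((filtered, partition, eigen, kme_table, power))
        st.done(
            [str(out / f"cohort{c}_{x}.tsv") for c in (1, 2) for x in ("modules", "eigengenes", "kme")],
            {
                "powers": [n[4] for n in networks],
                "n_modules": [n[1].n_modules for n in networks],
            },
        )

    # -- modular differential connectivity ----------------------------------
    mdc_tables = []
    with stage("mdc") as st:
        for c, ((mat, lab), net) in enumerate(zip(cohorts, networks), start=1):
            filtered, partition = net[0], net[1]
            table = mdc.mdc_permutation_test(
                filtered,
                lab,
                partition,
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"mdc{c}"),
                alpha=config.alpha,
            )
            table.to_csv(out / f"cohort{c}_mdc.tsv", sep="\t", float_format="%.6g")
            mdc_tables.append(table)
        st.done(
            [str(out / f"cohort{c}_mdc.tsv") for c in (1, 2)],
            {"n_perm": config.n_perm},
        )

    # -- module over-representation of the common lists ---------------------
    enriched_modules = {}
    with stage("module_enrichment") as st:
        outputs = []
        for direction, genes in (("up", common.common_up), ("down", common.common_down)):
            per_net = []
            for c, net in enumerate(networks, start=1):
                partition = net[1]
                if genes:
                    table = keygenes.module_overrepresentation(
                        genes & set(partition.genes), partition,
                        universe, alpha=config.alpha
                    )
                else:
                    table = pd.DataFrame(
                        columns=["set_size", "overlap", "pvalue", "padj", "enriched"]
                    )
                path = out / f"cohort{c}_module_enrichment_{direction}.tsv"
                table.to_csv(path, sep="\t", float_format="%.6g")
                outputs.append(str(path))
                per_net.append(
                    {int(m[1:]) for m in table.index[table["enriched"]]}
                )
            enriched_modules[direction] = per_net
        st.done(outputs, {"alpha": config.alpha})

    # -- key genes ----------------------------------------------------------
    with stage("keygenes") as st:
        all_keys: set[str] = set()
        tables = []
        for direction, genes in (("up", common.common_up), ("down", common.common_down)):
            if not genes:
                continue
            degree_table = keygenes.ppi_degree_rank(ppi, genes, top_n=config.top_n)
            counts = {g: pathway_counts[direction].get(g, 0) for g in genes}
            # hub evidence comes from the largest cohort's network: kME
            # estimates from the small cohort are too noisy to threshold
            primary = max(
                range(len(cohorts)), key=lambda c: cohorts[c][0].n_samples
            )
            evidence = [
                keygenes.NetworkEvidence(
                    networks[primary][1],
                    networks[primary][3],
                    enriched_modules[direction][primary],
                )
            ]
            report = keygenes.select_key_genes(
                degree_table,
                counts,
                evidence,
                top_n=config.top_n,
                kme_threshold=config.kme_threshold,
            )
            report.table.to_csv(
                out / f"keygenes_{direction}.tsv", sep="\t", float_format="%.6g"
            )
            tables.append(report.table.assign(direction=direction))
            all_keys |= report.key_genes
        (out / "key_genes.txt").write_text(
            "\n".join(sorted(all_keys)) + ("\n" if all_keys else "")
        )
        manifest.results["key_genes"] = sorted(all_keys)
        st.done(
            [str(out / "key_genes.txt")],
            {"top_n": config.top_n, "kme_threshold": config.kme_threshold,
             "n_key_genes": len(all_keys)},
        )

    # -- classifier ---------------------------------------------------------
    with stage("classify") as st:
        mat, lab = cohorts[config.classify_cohort]
        if all_keys:
            roc = classify.cross_validated_roc(
                mat,
                lab,
                sorted(all_keys),
                k_folds=config.folds,
                seed=stage_seed(config.seed, "classify"),
            )
            summary = {
                "fold_aucs": [round(a, 6) for a in roc.fold_aucs],
                "average_auc": round(roc.average_auc, 6),
            }
            if config.baseline_draws > 0:
                baseline = classify.random_gene_baseline(
                    mat,
                    lab,
                    n_genes=len(all_keys),
                    n_draws=config.baseline_draws,
                    k_folds=config.folds,
                    seed=stage_seed(config.seed, "baseline"),
                    exclude=sorted(all_keys),
                )
                summary["baseline_mean_auc"] = round(float(np.mean(baseline)), 6)
                summary["baseline_draws"] = int(baseline.size)
        else:
            summary = {"note": "no key genes; classifier skipped"}
        (out / "classifier.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        manifest.results["classifier"] = summary
        st.done([str(out / "classifier.json")], {"folds": config.folds})

    manifest.results["common_up"] = sorted(common.common_up)
    manifest.results["common_down"] = sorted(common.common_down)
    manifest.results["n_modules"] = [n[1].n_modules for n in networks]
    if truth is not None:
        manifest.results["planted_key_genes"] = sorted(truth.key_genes)
    manifest.write(out / "manifest.json")
    return manifest
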