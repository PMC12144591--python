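"""End-to-end pipeline orchestration and summary reporting.

Runs the full analysis on synthetic inputs from one YAML configuration:
simulate parental pools and a hybrid cohort, filter SNPs, estimate
admixture proportions, build simulation-calibrated generation bins,
classify the cohort, summarize class proportions, compute Phi-ST and the
mtDNA haplotype network, and fit the genotype-environment turnover model
with genomic offset. Every stage writes delimited-text artifacts recorded
in a manifest (inputs, parameters, seed, checksums); a rerun with the same
seed reproduces the outputs byte for byte, and stages whose artifacts
already exist can be skipped (resume).
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from duckmix import ancestry, gea, genofilter, hybridclass, popgen, synthio
from duckmix._rng import substream

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "synth": {
        "n_loci": 1000,
        "fst_target": 0.11,
        "n_per_pool": 50,
        "missing_rate": 0.02,
        "mtdna_per_group": 10,
        "mtdna_mutation_steps": 3,
        "n_depth_profiles": 40,
        "env": {"n_sites": 20, "n_variables": 8, "n_loci": 300,
                "n_adaptive_loci": 40, "n_individuals_per_site": 10,
                "effect_slope": 2.0, "noise_sd": 0.2, "grid_dims": [8, 8]},
    },
    "filter": {"min_allele_presence": 0.8, "maf_min": 0.002,
               "max_missing_per_snp": 0.2, "ld_window": 2, "ld_step": 1,
               "ld_r2_max": 0.5},
    "admix": {"K": 2, "replicates": 5},
    "bins": {"K": 2, "n_replicate_simulations": 10, "runs_per_sim": 25,
             "n_f1": 10, "lineages_per_side": 5, "generations": 9,
             "pure_threshold": 0.05},
    "gea": {"min_polymorphic_sites": 5, "n_trees": 100, "top_k": 5,
            "n_null": 100, "future_shift": 1.0},
    "stages": ["synth", "filter", "admix", "bins", "classify",
               "popgen", "gea"],
    "inputs": {},
}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Merge a YAML config over the defaults (paper-style stage parameters)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if path is not None:
        with open(path) as fh:
            merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        merge(cfg, overrides)
    for key, p in (cfg.get("inputs") or {}).items():
        if p and not Path(p).exists():
            raise FileNotFoundError(f"configured input path missing: {key}={p}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Stage runner writing artifacts plus a manifest into a run directory."""

    def __init__(self, config: dict, out_dir: str | Path, resume: bool = False):
        self.cfg = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.resume = resume
        self.manifest_path = self.out / "manifest.json"
        self.manifest: dict = {"seed": config["seed"], "stages": {}}
        if resume and self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        self.state: dict = {}

    def _record(self, stage: str, params: dict, artifacts: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "parameters": params,
            "artifacts": {str(p.relative_to(self.out)): _sha256(p)
                          for p in artifacts},
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2,
                                                 default=str) + "\n")

    # -- stages -------------------------------------------------------------

    def stage_synth(self) -> None:
        cfg, seed = self.cfg["synth"], self.cfg["seed"]
        pools = synthio.simulate_parental_pools(synthio.PoolSpec(
            n_loci=cfg["n_loci"], fst_target=cfg["fst_target"], seed=seed))
        spec = hybridclass.PedigreeSpec(
            n_f1=self.cfg["bins"]["n_f1"],
            n_backcross_lineages_per_side=self.cfg["bins"]["lineages_per_side"],
            max_backcross_generations=self.cfg["bins"]["generations"],
            n_replicate_simulations=1)
        cohort = hybridclass.simulate_replicate(
            pools[0], pools[1], spec, n_ref=cfg["n_per_pool"],
            seed=seed + 7, replicate_id=99)
        matrix = cohort.to_matrix()
        if cfg["missing_rate"] > 0:
            rng = substream(seed, "pipeline-missing")
            mask = rng.random(matrix.genotypes.shape) < cfg["missing_rate"]
            matrix.genotypes[mask] = genofilter.MISSING
        refs = synthio.make_haplogroup_references(seed=seed)
        mtdna = synthio.simulate_mtdna(
            refs, {g: cfg["mtdna_per_group"] for g in synthio.HAPLOGROUPS},
            mutation_steps=cfg["mtdna_mutation_steps"], seed=seed)
        sex_truth = ["male", "female"] * (cfg["n_depth_profiles"] // 2)
        depth = synthio.simulate_depth_profiles(sex_truth, seed=seed)
        e = cfg["env"]
        env_matrix, env_table, grid = synthio.simulate_env_dataset(
            synthio.EnvScenario(n_sites=e["n_sites"], n_variables=e["n_variables"],
                                n_loci=e["n_loci"],
                                n_adaptive_loci=e["n_adaptive_loci"],
                                n_individuals_per_site=e["n_individuals_per_site"],
                                effect_slope=e["effect_slope"],
                                noise_sd=e["noise_sd"],
                                grid_dims=tuple(e["grid_dims"])),
            seed=seed)

        paths = {
            "genotypes": self.out / "genotypes.vcf",
            "truth": self.out / "pedigree_truth.tsv",
            "mtdna": self.out / "mtdna.fasta",
            "mtdna_refs": self.out / "mtdna_refs.fasta",
            "depth": self.out / "depth_profiles.tsv",
            "env_genotypes": self.out / "env_genotypes.tsv",
            "env_table": self.out / "env_table.tsv",
            "env_grid": self.out / "env_grid.tsv",
        }
        genofilter.write_vcf(matrix, paths["genotypes"])
        cohort.table.to_csv(paths["truth"], sep="\t", index=False)
        popgen.write_fasta(mtdna, paths["mtdna"])
        popgen.write_fasta(refs, paths["mtdna_refs"])
        depth.to_csv(paths["depth"], sep="\t", index=False)
        genofilter.write_table(env_matrix, paths["env_genotypes"])
        synthio.write_env_table(env_table, paths["env_table"])
        synthio.write_env_table(grid, paths["env_grid"])
        self.state.update(matrix=matrix, cohort=cohort, pools=pools,
                          mtdna=mtdna, mtdna_refs=refs, depth=depth,
                          env_matrix=env_matrix, env_table=env_table, grid=grid)
        self._record("synth", cfg, list(paths.values()))

    def stage_filter(self) -> None:
        cfg = self.cfg["filter"]
        params = genofilter.FilterParams(
            min_allele_presence=cfg["min_allele_presence"],
            maf_min=cfg["maf_min"],
            max_missing_per_snp=cfg["max_missing_per_snp"],
            ld_window=cfg["ld_window"], ld_step=cfg["ld_step"],
            ld_r2_max=cfg["ld_r2_max"])
        filtered, report = genofilter.apply_filter_cascade(
            self.state["matrix"], params, seed=self.cfg["seed"])
        p1 = self.out / "genotypes_filtered.vcf"
        p2 = self.out / "filter_report.tsv"
        genofilter.write_vcf(filtered, p1)
        report.to_csv(p2, sep="\t", index=False)
        sexes = genofilter.call_sex(self.state["depth"])
        p3 = self.out / "sex_calls.tsv"
        sexes.rename_axis("individual_id").reset_index().to_csv(
            p3, sep="\t", index=False)
        self.state["filtered"] = filtered
        self._record("filter", cfg, [p1, p2, p3])

    def stage_admix(self) -> None:
        cfg, seed = self.cfg["admix"], self.cfg["seed"]
        fits = [ancestry.fit_admixture(self.state["filtered"], cfg["K"],
                                       seed=seed + r)
                for r in range(cfg["replicates"])]
        aligned = ancestry.align_replicates(fits)
        q = aligned.consensus_frame()
        p = self.out / "admixture_Q.tsv"
        q.rename_axis("individual_id").reset_index().to_csv(p, sep="\t",
                                                            index=False)
        scores, expl = ancestry.pca(self.state["filtered"])
        pca_df = pd.DataFrame(scores[:, :5],
                              index=self.state["filtered"].individual_ids,
                              columns=[f"PC{i + 1}" for i in range(scores[:, :5].shape[1])])
        p2 = self.out / "pca_scores.tsv"
        pca_df.rename_axis("individual_id").reset_index().to_csv(p2, sep="\t",
                                                                 index=False)
        self.state["consensus_Q"] = aligned.consensus_Q
        self._record("admix", cfg, [p, p2])

    def stage_bins(self) -> None:
        cfg, seed = self.cfg["bins"], self.cfg["seed"]
        truth = self.state["cohort"].table
        is_a = (truth["pedigree_class"] == "pure_A").to_numpy()
        is_b = (truth["pedigree_class"] == "pure_B").to_numpy()
        Q = self.state["consensus_Q"]
        cluster_taxa = [hybridclass.TAXON_A
                        if Q[is_a, k].mean() >= Q[is_b, k].mean()
                        else hybridclass.TAXON_B for k in range(Q.shape[1])]
        placeholder_P = np.zeros((Q.shape[1], self.state["filtered"].n_loci))
        fitted = ancestry.AncestryMatrix(
            self.state["filtered"].individual_ids, Q.shape[1], Q,
            placeholder_P, 0.0)
        pure = hybridclass.vet_parentals(fitted, cluster_taxa,
                                         threshold=cfg["pure_threshold"])
        pool_a = hybridclass.pool_from_matrix(self.state["filtered"],
                                              pure[hybridclass.TAXON_A], "A")
        pool_b = hybridclass.pool_from_matrix(self.state["filtered"],
                                              pure[hybridclass.TAXON_B], "B")
        spec = hybridclass.PedigreeSpec(
            n_f1=cfg["n_f1"],
            n_backcross_lineages_per_side=cfg["lineages_per_side"],
            max_backcross_generations=cfg["generations"],
            n_replicate_simulations=cfg["n_replicate_simulations"])
        bins, _ = hybridclass.build_generation_bins(
            pool_a, pool_b, spec, K=cfg["K"],
            runs_per_sim=cfg["runs_per_sim"], seed=seed + 31)
        p = self.out / "generation_bins.tsv"
        bins.save(p)
        self.state.update(bins=bins, cluster_taxa=cluster_taxa)
        self._record("bins", cfg, [p])

    def stage_classify(self) -> None:
        records = hybridclass.classify(
            self.state["consensus_Q"], self.state["cluster_taxa"],
            self.state["bins"],
            individual_ids=self.state["filtered"].individual_ids)
        p = self.out / "classification.tsv"
        records.to_csv(p, sep="\t", index=False)
        summary = hybridclass.summarize_classes(records)
        p2 = self.out / "class_summary.tsv"
        summary["by_class"].rename_axis("assigned_class").reset_index().to_csv(
            p2, sep="\t", index=False)
        self.state["records"] = records
        self._record("classify", {}, [p, p2])

    def stage_popgen(self) -> None:
        truth = self.state["cohort"].table
        pure = truth["pedigree_class"].isin(["pure_A", "pure_B"]).to_numpy()
        sub = self.state["filtered"].take_individuals(pure)
        labels = [c for c, keep in zip(truth["pedigree_class"], pure) if keep]
        phi = popgen.phi_st_snps(sub, labels, partition="autosomal")
        mt = self.state["mtdna"]
        phi_mt = popgen.phi_st_sequences(mt, mt.groups, partition="mtDNA")
        p = self.out / "phi_st.tsv"
        pd.DataFrame([
            {"partition": r.partition, "groups": "|".join(r.groups),
             "phi_st": r.phi_st} for r in (phi, phi_mt)
        ]).to_csv(p, sep="\t", index=False)
        haps = popgen.collapse_haplotypes(mt)
        net = popgen.median_joining_network(haps)
        p_nodes = self.out / "network_nodes.tsv"
        p_edges = self.out / "network_edges.tsv"
        popgen.export_network(net, p_nodes, p_edges,
                              self.out / "network.graphml")
        groups = popgen.assign_haplogroups(mt, self.state["mtdna_refs"])
        p_h = self.out / "haplogroups.tsv"
        groups.rename_axis("individual_id").reset_index().to_csv(p_h, sep="\t",
                                                                 index=False)
        self._record("popgen", {}, [p, p_nodes, p_edges, p_h])

    def stage_gea(self) -> None:
        cfg, seed = self.cfg["gea"], self.cfg["seed"]
        freqs = gea.site_allele_frequencies(
            self.state["env_matrix"],
            min_polymorphic_sites=cfg["min_polymorphic_sites"])
        model = gea.fit_turnover(freqs, self.state["env_table"],
                                 n_trees=cfg["n_trees"], seed=seed)
        grid = self.state["grid"]
        transformed = gea.transform_environment(model, grid, top_k=cfg["top_k"])
        rgb = gea.map_rgb(transformed)
        future = grid.copy()
        future["env1"] = future["env1"] + cfg["future_shift"]
        offset = gea.genomic_offset(model, grid, future, top_k=cfg["top_k"])
        p1 = self.out / "turnover_importance.tsv"
        model.variable_importance.rename_axis("variable").rename("importance") \
            .reset_index().to_csv(p1, sep="\t", index=False)
        p2 = self.out / "landscape_rgb.tsv"
        rgb.to_csv(p2, sep="\t", index=False)
        p3 = self.out / "genomic_offset.tsv"
        offset.to_csv(p3, sep="\t", index=False)
        self._record("gea", {k: v for k, v in cfg.items()}, [p1, p2, p3])

    def run(self) -> dict:
        order = ["synth", "filter", "admix", "bins", "classify",
                 "popgen", "gea"]
        for stage in order:
            if stage not in self.cfg["stages"]:
                continue
            if (self.resume and stage in self.manifest["stages"]
                    and all((self.out / a).exists()
                            for a in self.manifest["stages"][stage]["artifacts"])
                    and stage not in ("synth", "filter", "admix", "bins",
                                      "classify")):
                continue
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:  # machine-readable failure record
                (self.out / "error.json").write_text(json.dumps(
                    {"stage": stage, "error": type(exc).__name__,
                     "message": str(exc)}) + "\n")
                raise
        return self.manifest


def run_pipeline(config: dict, out_dir: str | Path, resume: bool = False) -> dict:
    return PipelineRun(config, out_dir, resume=resume).run()


# ---------------------------------------------------------------------------
# Summary reporting arithmetic
# ---------------------------------------------------------------------------


def percent(part: float, whole: float) -> dict:
    """Full-precision percentage with a nearest-integer display value."""
    if whole == 0:
        return {"percent": float("nan"), "display": None}
    p = 100.0 * part / whole
    return {"percent": p, "display": int(round(p))}


def report_summary(records: pd.DataFrame,
                   groups: pd.Series | None = None) -> dict:
    """Class-count report with percentages and a conservation check.

    Wraps :func:`duckmix.hybridclass.summarize_classes`, adding the
    aggregate early-backcross (F2-F4) fraction and swarm directionality in
    the display style used for field summaries (full precision alongside
    nearest-integer).
    """
    summary = hybridclass.summarize_classes(records, groups=groups)
    total = summary["total"]
    by_class = summary["by_class"]
    if total:
        early = int(by_class.loc[[c for c in by_class.index
                                  if c.startswith("F") and c != "F1"
                                  and 2 <= hybridclass._generation_rank(c) <= 4],
                                 "count"].sum())
        swarm = int(by_class.loc[by_class.index == "hybrid_swarm",
                                 "count"].sum())
        summary["early_backcross_f2_f4"] = {"count": early, **percent(early, total)}
        summary["hybrid_swarm"] = {"count": swarm, **percent(swarm, total)}
    return summary
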