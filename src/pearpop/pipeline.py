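"""End-to-end study orchestration from a single YAML config.

Runs the full synthetic study — simulate (or load), filter, windowed
statistics, sweep and balancing scans, LD decay, IBD + ancestry painting,
bootstrap NJ tree, QTL enrichment — writing plain-text artifacts and a JSON
run manifest (stage parameters, input/output SHA-256 hashes, row counts).

Stages form a linear dependency chain.  A stage is re-executed when any of
its outputs is missing or any upstream stage re-ran, so deleting one
stage's outputs regenerates exactly that stage and its dependents.  A
single global seed deterministically derives per-stage seeds, and a rerun
with identical config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import sweeps as sweeps_mod
from .diversity import SWEEP_WINDOWS, WindowSpec, window_diversity, window_fst, window_rod
from .enrichment import permutation_enrichment, read_bed
from .ibd import aver_ibd, ibd_matrix, paint_ancestry
from .ld import LDFilterConfig, half_decay_distance, ld_decay_profile
from .matrix import group_name
from .phylo import bootstrap_consensus, p_distance_matrix, write_newick, write_phylip
from .vcfio import filter_variants, read_gff3, read_vcf, write_vcf

log = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "stats", "sweep", "ld", "ibd", "tree", "enrichment"]

DEFAULTS: dict[str, dict] = {
    "filter": {"max_missing_rate": 0.5, "per_group": True},
    "stats": {"window": 10_000, "step": 5_000},
    "sweep": {"fst_top_quantile": 0.05, "rod_min": 0.5, "tajd_bottom_quantile": 0.10,
              "fst_bottom_quantile": 0.05, "tajd_top_quantile": 0.05,
              "theta_pi_top_quantile": 0.10},
    "ld": {"max_distance": 200_000, "min_maf": 0.05, "min_genotyping_rate": 0.6,
           "hwe_p_cutoff": 0.01, "max_sites_per_chrom": 1000},
    "ibd": {"window": 10_000},
    "tree": {"n_replicates": 200},
    "enrichment": {"n_permutations": 2000, "scheme": "uniform"},
}


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunConfig:
    """Validated pipeline configuration (see module docstring for layout)."""

    def __init__(self, raw: dict):
        self.raw = raw
        self.seed = int(raw.get("seed", 0))
        self.out_dir = raw.get("out_dir", "pearpop_run")
        self.simulate = raw.get("simulate")
        self.inputs = raw.get("inputs")
        self.params = {
            stage: {**DEFAULTS.get(stage, {}), **(raw.get(stage) or {})}
            for stage in STAGES if stage in DEFAULTS
        }
        self.enabled = {
            stage: (raw.get(stage) or {}).get("enabled", True) for stage in STAGES
        }
        self.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must provide exactly one of 'simulate' or 'inputs'")
        if self.inputs is not None:
            required = ["vcf", "metadata"]
            if self.enabled.get("enrichment", True):
                required += ["qtl", "chrom_sizes"]
            if self.enabled.get("sweep", True):
                required += ["gff3"]
            missing = [key for key in required if key not in self.inputs]
            if missing:
                raise ValueError(f"inputs block lacks required entries {missing}")
            for key in required:
                if not os.path.exists(self.inputs[key]):
                    raise ValueError(f"input file {self.inputs[key]!r} does not exist")

    def cohort_config(self) -> cohort_mod.CohortConfig:
        cfg = cohort_mod.default_config(seed=stage_seed(self.seed, "simulate"))
        overrides = dict(self.simulate or {})
        overrides.pop("qtl_overlap_fraction", None)
        for key, value in overrides.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown simulate option {key!r}")
            setattr(cfg, key, value)
        return cfg


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute all enabled stages in order; returns the run manifest."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    upstream_reran = False
    state: dict = {}

    def path(name: str) -> str:
        return os.path.join(out, name)

    def record(stage: str, outputs: list[str], params: dict, counts: dict, ran: bool):
        manifest["stages"][stage] = {
            "ran": ran,
            "parameters": params,
            "seed": stage_seed(config.seed, stage),
            "outputs": {os.path.basename(p): _sha256(p) for p in outputs if os.path.exists(p)},
            "row_counts": counts,
        }

    def needs_run(outputs: list[str]) -> bool:
        return force or upstream_reran or any(not os.path.exists(p) for p in outputs)

    exclude = (cohort_mod.ADMIXED_SPECIES,)

    # -- simulate ----------------------------------------------------------
    if config.simulate is not None:
        sim_outputs = [path(n) for n in (
            "cohort.vcf", "samples.tsv", "truth_sweeps.bed", "truth_ibd.bed",
            "truth_admixture.bed", "truth_balanced.bed", "genes.gff3", "qtl.bed",
            "chrom_sizes.tsv")]
        ran = needs_run(sim_outputs)
        ccfg = config.cohort_config()
        matrix, truth = cohort_mod.simulate_cohort(ccfg)
        if ran:
            qof = (config.simulate or {}).get("qtl_overlap_fraction", 1.0)
            cohort_mod.emit_fixture(matrix, truth, out, qtl_overlap_fraction=qof,
                                    seed=stage_seed(config.seed, "simulate"))
            upstream_reran = True
        record("simulate", sim_outputs, {"cohort": str(ccfg)}, {"sites": matrix.n_sites,
               "samples": matrix.n_samples}, ran)
        state.update(matrix=matrix, truth=truth,
                     files={"gff3": path("genes.gff3"), "qtl": path("qtl.bed")})
    else:
        matrix = read_vcf(config.inputs["vcf"], config.inputs["metadata"])
        if "chrom_sizes" in config.inputs:
            sizes = pd.read_csv(config.inputs["chrom_sizes"], sep="\t", header=None,
                                names=["chrom", "length"])
            matrix.chrom_lengths = dict(zip(sizes["chrom"], sizes["length"].astype(int)))
        record("simulate", [], {"inputs": config.inputs},
               {"sites": matrix.n_sites, "samples": matrix.n_samples}, False)
        state.update(matrix=matrix, truth=None, files=dict(config.inputs))

    # -- filter ------------------------------------------------------------
    p = config.params["filter"]
    filt_out = [path("filtered.vcf")]
    ran = needs_run(filt_out)
    groups = sorted({
        group_name(r, s)
        for r, s in zip(state["matrix"].samples["region"], state["matrix"].samples["status"])
    })
    filtered = filter_variants(state["matrix"], p["max_missing_rate"],
                               groups=groups if p["per_group"] else None)
    if ran:
        write_vcf(filtered, filt_out[0])
        upstream_reran = True
    record("filter", filt_out, p, {"sites_in": state["matrix"].n_sites,
           "sites_out": filtered.n_sites}, ran)
    state["filtered"] = filtered

    region_pairs = [("Asian", "Asian_cultivated", "Asian_wild"),
                    ("European", "European_cultivated", "European_wild")]
    region_pairs = [
        (r, c, w) for r, c, w in region_pairs
        if filtered.group_indices(c, exclude).size >= 2
        and filtered.group_indices(w, exclude).size >= 2
    ]
    all_groups = [g for _, c, w in region_pairs for g in (c, w)]

    # -- stats -------------------------------------------------------------
    p = config.params["stats"]
    spec_slide = WindowSpec(window_size=p["window"], step=p["step"])
    stats_out = (
        [path(f"diversity_{g}.tsv") for g in all_groups]
        + [path(f"scan_{kind}_{r}.tsv") for r, _, _ in region_pairs
           for kind in ("fst", "rod", "div_cul", "div_wild")]
    )
    ran = needs_run(stats_out)
    scan_tables: dict[str, dict[str, pd.DataFrame]] = {}
    for region, cul, wild in region_pairs:
        div_c = window_diversity(filtered, cul, SWEEP_WINDOWS, exclude_species=exclude)
        div_w = window_diversity(filtered, wild, SWEEP_WINDOWS, exclude_species=exclude)
        fst = window_fst(filtered, cul, wild, SWEEP_WINDOWS, exclude_species=exclude)
        rod = window_rod(div_c, div_w)
        scan_tables[region] = {"fst": fst, "rod": rod, "div_cul": div_c, "div_wild": div_w}
    if ran:
        for g in all_groups:
            window_diversity(filtered, g, spec_slide, exclude_species=exclude).to_csv(
                path(f"diversity_{g}.tsv"), sep="\t", index=False)
        for region, tables in scan_tables.items():
            for kind, df in tables.items():
                df.to_csv(path(f"scan_{kind}_{region}.tsv"), sep="\t", index=False)
        upstream_reran = True
    record("stats", stats_out, p,
           {f"windows_{r}": len(t["fst"]) for r, t in scan_tables.items()}, ran)

    # -- sweep + balancing scans -------------------------------------------
    p = config.params["sweep"]
    sweep_out = [path(f"{kind}_{r}.bed") for r, _, _ in region_pairs
                 for kind in ("sweeps", "balancing")] + \
                [path(f"sweep_genes_{r}.tsv") for r, _, _ in region_pairs]
    ran = needs_run(sweep_out)
    gff = read_gff3(state["files"]["gff3"]) if "gff3" in state["files"] else None
    scan_results = {}
    for region, tables in scan_tables.items():
        sw = sweeps_mod.call_selective_sweeps(
            tables["fst"], tables["rod"], tables["div_cul"],
            sweeps_mod.SweepCriteria(p["fst_top_quantile"], p["rod_min"],
                                     p["tajd_bottom_quantile"]))
        bal = sweeps_mod.call_balancing_regions(
            tables["fst"], tables["div_cul"], tables["div_cul"],
            sweeps_mod.BalancingCriteria(p["fst_bottom_quantile"], p["tajd_top_quantile"],
                                         p["theta_pi_top_quantile"]))
        scan_results[region] = {"sweep": sw, "balancing": bal}
        if ran:
            sweeps_mod.write_regions_bed(sw.regions, path(f"sweeps_{region}.bed"), "max_fst")
            sweeps_mod.write_regions_bed(bal.regions, path(f"balancing_{region}.bed"))
            annotated = sweeps_mod.annotate_regions(sw.regions, gff) if gff is not None \
                else sw.regions.assign(gene_ids=[[] for _ in range(len(sw.regions))])
            annotated = annotated.assign(gene_ids=annotated["gene_ids"].map(",".join))
            annotated.to_csv(path(f"sweep_genes_{region}.tsv"), sep="\t", index=False)
    if ran:
        upstream_reran = True
    record("sweep", sweep_out, p,
           {f"sweep_regions_{r}": len(res["sweep"].regions) for r, res in scan_results.items()},
           ran)
    state["scan_results"] = scan_results

    # -- LD ----------------------------------------------------------------
    p = config.params["ld"]
    ld_groups = p.get("groups", all_groups)
    ld_out = [path(f"ld_decay_{g}.tsv") for g in ld_groups] + [path("ld_half_decay.json")]
    ran = needs_run(ld_out)
    if ran:
        half = {}
        filters = LDFilterConfig(p["max_distance"], p["min_maf"],
                                 p["min_genotyping_rate"], p["hwe_p_cutoff"])
        for g in ld_groups:
            profile = ld_decay_profile(filtered, g, filters,
                                       max_sites_per_chrom=p["max_sites_per_chrom"],
                                       exclude_species=exclude)
            profile.to_csv(path(f"ld_decay_{g}.tsv"), sep="\t", index=False)
            half[g] = half_decay_distance(profile) if len(profile) else None
        with open(path("ld_half_decay.json"), "w") as fh:
            json.dump(half, fh, indent=2, sort_keys=True)
        upstream_reran = True
    record("ld", ld_out, p, {}, ran)

    # -- IBD + painting ----------------------------------------------------
    p = config.params["ibd"]
    ibd_out = [path("pij_matrix.tsv"), path("aver_ibd.tsv")]
    admix = state["matrix"].samples["species"] == cohort_mod.ADMIXED_SPECIES
    has_admixed = bool(admix.any())
    if has_admixed:
        ibd_out += [path("painted_blocks.bed"), path("paint_proportions.json")]
    ran = needs_run(ibd_out)
    if ran:
        spec = WindowSpec(window_size=p["window"], step=p["window"], min_snps=11)
        pij = ibd_matrix(filtered, spec=spec)
        pij.to_csv(path("pij_matrix.tsv"), sep="\t")
        summaries = []
        ids_by_group = {
            g: list(filtered.samples.loc[
                filtered.group_indices(g, exclude), "sample_id"])
            for g in all_groups
        }
        for g, ids_g in ids_by_group.items():
            for ref, ids_r in ids_by_group.items():
                if g == ref:
                    continue
                s = aver_ibd(pij, ids_g, ids_r, group=g, reference_set=ref)
                summaries.append(vars(s))
        pd.DataFrame(summaries).to_csv(path("aver_ibd.tsv"), sep="\t", index=False)
        if has_admixed:
            target = state["matrix"].samples.loc[admix, "sample_id"].iloc[0]
            paint = paint_ancestry(filtered, target, "Asian_cultivated",
                                   "European_cultivated", spec=spec,
                                   exclude_species=exclude)
            painted = paint.windows[paint.windows["label"].isin(
                [paint.donor_a, paint.donor_b])]
            painted[["chrom", "start", "end", "label"]].to_csv(
                path("painted_blocks.bed"), sep="\t", header=False, index=False)
            with open(path("paint_proportions.json"), "w") as fh:
                json.dump(paint.proportions, fh, indent=2, sort_keys=True)
        upstream_reran = True
    record("ibd", ibd_out, p, {}, ran)

    # -- tree --------------------------------------------------------------
    p = config.params["tree"]
    tree_out = [path("tree.nwk"), path("distances.phylip")]
    ran = needs_run(tree_out)
    if ran:
        tree = bootstrap_consensus(filtered, n_replicates=p["n_replicates"],
                                   seed=stage_seed(config.seed, "tree"))
        write_newick(tree, tree_out[0])
        write_phylip(p_distance_matrix(filtered), tree_out[1])
        upstream_reran = True
    record("tree", tree_out, p, {}, ran)

    # -- enrichment --------------------------------------------------------
    if config.enabled.get("enrichment", True) and "qtl" in state["files"]:
        p = config.params["enrichment"]
        enr_out = [path("enrichment.json")]
        ran = needs_run(enr_out)
        if ran:
            qtl = read_bed(state["files"]["qtl"])
            results = {}
            for region, res in scan_results.items():
                grid = res["sweep"].grid
                windows = grid[res["sweep"].window_mask]
                r = permutation_enrichment(
                    windows, qtl, filtered.chrom_lengths,
                    n_permutations=p["n_permutations"],
                    seed=stage_seed(config.seed, "enrichment"),
                    scheme=p["scheme"])
                results[region] = r.to_dict()
            with open(enr_out[0], "w") as fh:
                json.dump(results, fh, indent=2, sort_keys=True)
            upstream_reran = True
        record("enrichment", enr_out, p, {}, ran)

    manifest_path = path("run_manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete; manifest at %s", manifest_path)
    return manifest
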