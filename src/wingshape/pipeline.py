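"""End-to-end study workflow with a config file and a machine-readable report.

Stages, in order: read inputs -> GPA -> tangent check -> relative warps ->
per-group disparity -> UPGMA phenogram -> maximum parsimony (full matrix
and, optionally, with listed characters excluded) -> ancestral shape
reconstruction on the first MPT -> Mantel comparisons (phenogram vs MPT,
and wing shape vs anatomical character regions).

One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([seed, stage_index])``, so any stochastic
stage can be rerun in isolation; every stage records the seed it used.
The report is written as JSON (stable schema) and Markdown.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml
from skbio import DistanceMatrix

from . import (ancestral, cladistics, disparity, formats, phenetics,
               superimposition, treecompare, warps)

logger = logging.getLogger(__name__)

_STAGE_IDS = {"disparity": 1, "search_full": 2, "search_reduced": 3,
              "bootstrap_full": 4, "bootstrap_reduced": 5, "mantel": 6}


def stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, _STAGE_IDS[stage]])
               .generate_state(1)[0] % (2 ** 31))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Execute the full workflow; returns the report dict and writes
    ``report.json`` / ``report.md`` plus the phenogram and MPT Newicks."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict = {"seed": seed}

    def run(stage: str, fn):
        try:
            logger.info("pipeline stage: %s", stage)
            return fn()
        except Exception as exc:
            _write_report(report, outdir)  # keep partial outputs
            raise StageError(stage, exc) from exc

    # -- inputs ------------------------------------------------------------
    def load():
        records = formats.read_tps(config["landmarks"])
        groups = formats.read_groups(config["groups"]) if config.get("groups") else {}
        configs = superimposition.configs_from_tps(records, groups)
        matrix = formats.read_character_matrix(config["characters"])
        return configs, matrix
    configs, matrix = run("formats", load)
    report["inputs"] = {"n_specimens": len(configs), "n_taxa": matrix.n_taxa,
                        "n_characters": matrix.n_characters}

    # -- superimposition ---------------------------------------------------
    aligned = run("superimposition", lambda: superimposition.gpa_align(configs))
    check = run("superimposition", lambda: superimposition.tangent_adequacy_check(aligned))
    report["tangent_check"] = {
        "correlation_through_origin": check.correlation_through_origin,
        "slope": check.slope, "pearson_correlation": check.pearson_correlation,
        "n_pairs": check.n_pairs,
        "gpa_iterations": aligned.iterations, "converged": aligned.converged}

    # -- relative warps ----------------------------------------------------
    def do_warps():
        pw = warps.partial_warp_scores(aligned)
        return warps.relative_warps(pw)
    rw = run("warps", do_warps)
    report["relative_warps"] = {
        "variance_fraction": rw.variance_fraction.tolist(),
        "first_two_percent": float(rw.variance_fraction[:2].sum() * 100)}

    # -- disparity ---------------------------------------------------------
    disp_cfg = config.get("disparity", {})
    disp_seed = stage_seed(seed, "disparity")
    table = run("disparity", lambda: disparity.disparity_table(
        aligned, n_boot=int(disp_cfg.get("n_boot", 10000)), seed=disp_seed))
    report["disparity"] = [
        {"group": r.group, "n": r.n, "md": r.md, "se": r.se,
         "n_boot": r.n_boot, "seed": disp_seed, "defined": r.defined}
        for r in table]

    # -- phenetics ---------------------------------------------------------
    def do_upgma():
        labels = [c.label for c in aligned.aligned]
        d = DistanceMatrix(superimposition.procrustes_distance_matrix(aligned),
                           ids=labels)
        return phenetics.upgma(d)
    phenogram = run("phenetics", do_upgma)
    formats.write_newick(phenogram, outdir / "phenogram.nwk")
    report["phenetics"] = {"newick": phenogram.to_newick()}

    # -- cladistics --------------------------------------------------------
    search_cfg = config.get("search", {})
    boot_cfg = config.get("bootstrap", {})
    outgroup = config.get("outgroup")
    analyses = {"full": matrix}
    excluded = config.get("exclude_characters") or []
    if excluded:
        analyses["reduced"] = matrix.exclude(excluded)
    report["cladistics"] = {}
    mpts: dict[str, list] = {}
    for name, mat in analyses.items():
        def do_search(mat=mat, name=name):
            return cladistics.heuristic_search(
                mat,
                n_addition_replicates=int(search_cfg.get("addition_replicates", 100)),
                swapper=search_cfg.get("swapper", "tbr"),
                max_trees=int(search_cfg.get("max_trees", 1000)),
                seed=stage_seed(seed, f"search_{name}"),
                outgroup=outgroup)
        result = run(f"cladistics:{name}", do_search)
        mpts[name] = result.best_trees
        entry = {
            "n_characters": mat.n_characters,
            "best_length": result.best_length,
            "n_trees": len(result.best_trees),
            "ci": result.stats.ci, "ri": result.stats.ri,
            "ci_rounded": round(result.stats.ci, 2),
            "ri_rounded": round(result.stats.ri, 2),
            "seed": result.seed,
            "newicks": [t.to_newick() for t in result.best_trees]}
        if len(result.best_trees) > 1:
            cons, n_collapsed = cladistics.strict_consensus(result.best_trees)
            entry["strict_consensus"] = cons.to_newick()
            entry["n_collapsed_nodes"] = n_collapsed
        if boot_cfg:
            boot_seed = stage_seed(seed, f"bootstrap_{name}")
            freqs = run(f"bootstrap:{name}", lambda mat=mat, s=boot_seed: cladistics.bootstrap_support(
                mat, n_reps=int(boot_cfg.get("n_reps", 1000)),
                addition_replicates=int(boot_cfg.get("addition_replicates", 10)),
                swapper=boot_cfg.get("swapper", "spr"), seed=s))
            annotated = cladistics.apply_support(result.best_trees[0].copy(), freqs)
            entry["bootstrap"] = {"n_reps": int(boot_cfg.get("n_reps", 1000)),
                                  "seed": boot_seed,
                                  "annotated_newick": annotated.to_newick()}
        report["cladistics"][name] = entry
        formats.write_newick(result.best_trees[0], outdir / f"mpt_{name}.nwk")

    # -- ancestral reconstruction ------------------------------------------
    def do_ancestral():
        tree = mpts["full"][0].copy()
        tangent = superimposition.tangent_project(aligned)
        tip_values = {c.label: tangent[i] for i, c in enumerate(aligned.aligned)}
        nodes = ancestral.squared_change_reconstruct(tree, tip_values)
        return tree, nodes
    anc_tree, node_values = run("ancestral", do_ancestral)
    report["ancestral"] = {
        "tree": anc_tree.to_newick(),
        "nodes": {name: vals.tolist() for name, vals in node_values.items()}}

    # -- tree comparison ---------------------------------------------------
    mantel_cfg = config.get("mantel", {})
    n_perm = int(mantel_cfg.get("n_permutations", 9999))
    mantel_seed = stage_seed(seed, "mantel")

    def do_compare():
        out = {}
        pheno_d = treecompare.tree_to_distances(phenogram, mode="cophenetic")
        for name, trees in mpts.items():
            for i, tree in enumerate(trees):
                clado_d = treecompare.tree_to_distances(tree, mode="nodal")
                res = treecompare.mantel_test(pheno_d, clado_d,
                                              n_permutations=n_perm,
                                              seed=mantel_seed)
                out[f"phenogram_vs_mpt_{name}_{i + 1}"] = {
                    "mode": "cophenetic vs nodal", "r": res.r,
                    "p_value": res.p_value, "n_permutations": n_perm,
                    "seed": mantel_seed,
                    "r_gt_half": res.significant_by_half_rule}
        regions = config.get("character_regions") or {}
        if regions:
            labels = [c.label for c in aligned.aligned]
            wing_d = DistanceMatrix(
                superimposition.procrustes_distance_matrix(aligned), ids=labels)
            region_res = treecompare.body_region_correlations(
                matrix, wing_d, {k: list(v) for k, v in regions.items()},
                n_permutations=n_perm, seed=mantel_seed)
            for rname, res in region_res.items():
                out[f"wing_vs_{rname}"] = {
                    "mode": "procrustes vs character mismatch", "r": res.r,
                    "p_value": res.p_value, "n_permutations": n_perm,
                    "seed": mantel_seed, "r_gt_half": res.significant_by_half_rule}
        return out
    report["mantel"] = run("treecompare", do_compare)

    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    (outdir / "report.md").write_text(_markdown(report))


def _markdown(report: dict) -> str:
    lines = ["# Wing shape analysis report", "",
             f"Global seed: {report.get('seed')}", ""]
    if "inputs" in report:
        i = report["inputs"]
        lines += ["## Inputs",
                  f"- specimens: {i['n_specimens']}; taxa: {i['n_taxa']}; "
                  f"characters: {i['n_characters']}", ""]
    if "tangent_check" in report:
        t = report["tangent_check"]
        lines += ["## Tangent-space adequacy",
                  f"- uncentered correlation: {t['correlation_through_origin']:.6f} "
                  f"(slope {t['slope']:.4f}, {t['n_pairs']} pairs)", ""]
    if "relative_warps" in report:
        rw = report["relative_warps"]
        lines += ["## Relative warps",
                  f"- RW1+RW2 explain {rw['first_two_percent']:.2f}% of variance", ""]
    if "disparity" in report:
        lines += ["## Metric disparity", "",
                  "| group | n | MD | SE |", "|---|---|---|---|"]
        for r in report["disparity"]:
            lines.append(f"| {r['group']} | {r['n']} | {r['md']:.6g} | {r['se']:.6g} |")
        lines.append("")
    for name, entry in report.get("cladistics", {}).items():
        lines += [f"## Parsimony ({name}, {entry['n_characters']} characters)",
                  f"- best length {entry['best_length']}, "
                  f"CI {entry['ci_rounded']:.2f}, RI {entry['ri_rounded']:.2f}, "
                  f"{entry['n_trees']} tree(s)", ""]
    if "mantel" in report:
        lines += ["## Matrix correspondence (Mantel)", "",
                  "| comparison | r | p |", "|---|---|---|"]
        for name, res in report["mantel"].items():
            lines.append(f"| {name} | {res['r']:.5f} | {res['p_value']:.4g} |")
        lines.append("")
    return "\n".join(lines)
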