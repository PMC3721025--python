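"""One-command orchestration: simulate/load -> enrich -> alpha -> beta.

Every stochastic stage consumes an explicit seed derived from the single
root seed by stable hashing of the stage name, so the run is
deterministic given (inputs, seed) and re-runs produce identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import pandas as pd

from . import __version__
from .alpha import diversity_report
from .beta import bioenv, distance_matrix, fit_vectors, nmds
from .enrichment import subtract_background
from .errors import ConfigurationError
from .io_model import read_metadata, read_newick, read_otu_table, read_taxonomy
from .synth import ScenarioConfig, make_scenario, write_scenario

logger = logging.getLogger("ventflow")


def stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed: crc32 of the stage name folded into the root seed."""
    return (int(root_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Run the full pipeline from a config mapping; returns the manifest.

    The config either names input files (``inputs: {table, metadata,
    taxonomy, tree}``) or requests simulation (``simulate: true``).
    Optional blocks ``enrich``, ``alpha`` and ``beta`` override stage
    defaults.  All outputs are TSV plus a JSON manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "stage_seeds": {},
        "stages": {},
        "outputs": {},
    }
    t0 = time.time()

    # --- inputs -----------------------------------------------------------
    if config.get("simulate"):
        sim_seed = stage_seed(seed, "simulate")
        manifest["stage_seeds"]["simulate"] = sim_seed
        scenario = make_scenario(ScenarioConfig(), seed=sim_seed)
        paths = write_scenario(scenario, outdir / "sim")
        manifest["outputs"].update(paths)
        table, meta = scenario.table, scenario.metadata
        tax, tree = scenario.taxonomy, scenario.tree
        manifest["stages"]["simulate"] = {
            "samples": table.n_samples, "otus": table.n_otus,
            "planted": {r: len(p) for r, p in scenario.truth.planted.items()},
        }
    elif "inputs" in config:
        inputs = config["inputs"]
        table = read_otu_table(inputs["table"], dialect=inputs.get("dialect", "mothur_shared"))
        meta = read_metadata(inputs["metadata"])
        tax = read_taxonomy(inputs["taxonomy"]) if "taxonomy" in inputs else None
        tree = read_newick(inputs["tree"]) if "tree" in inputs else None
    else:
        raise ConfigurationError("config needs either 'simulate: true' or an 'inputs' block")
    logger.info("inputs: %d samples x %d OTUs", table.n_samples, table.n_otus)

    # --- enrichment (background subtraction) ------------------------------
    e_cfg = config.get("enrich", {})
    vent_sets, enrichment_table = subtract_background(
        table, meta,
        alpha=e_cfg.get("alpha", 0.01),
        min_fold=e_cfg.get("min_fold", 2.0),
        rule=e_cfg.get("rule", "both"),
        fdr=e_cfg.get("fdr", False),
    )
    enrich_path = outdir / "enrichment.tsv"
    enrichment_table.to_csv(enrich_path, sep="\t", index=False)
    manifest["outputs"]["enrichment"] = str(enrich_path)
    manifest["stages"]["enrich"] = {
        "otus_tested": int(len(enrichment_table)),
        "per_region_union": {r: v.n_union for r, v in vent_sets.items()},
        "per_region_union_in_off_axis": {r: v.union_in_off_axis for r, v in vent_sets.items()},
        "per_sample_enriched": {
            s: len(otus) for v in vent_sets.values() for s, otus in v.per_sample.items()
        },
    }

    # --- alpha diversity --------------------------------------------------
    a_cfg = config.get("alpha", {})
    a_seed = stage_seed(seed, "alpha")
    manifest["stage_seeds"]["alpha"] = a_seed
    report = diversity_report(
        table, tax=tax, tree=tree, vent_sets=vent_sets,
        scopes=tuple(a_cfg.get("scopes", ("total", "vent_specific", "domain"))),
        pd_subsample=a_cfg.get("pd_subsample", 200),
        pd_reps=a_cfg.get("pd_reps", 1000),
        seed=a_seed,
    )
    alpha_path = outdir / "diversity.tsv"
    report.frame.to_csv(alpha_path, sep="\t", index=False)
    manifest["outputs"]["diversity"] = str(alpha_path)
    manifest["stages"]["alpha"] = {"rows": int(len(report.frame))}

    # --- beta diversity / ordination / environment correlation ------------
    b_cfg = config.get("beta", {})
    b_seed = stage_seed(seed, "beta")
    manifest["stage_seeds"]["beta"] = b_seed
    vent_samples = [s for s in table.sample_ids
                    if meta.data.loc[s, "habitat"] == "diffuse_flow"]
    union_all = sorted(set().union(*[v.union for v in vent_sets.values()]) or set())
    beta_stage: dict = {}
    if union_all and len(vent_samples) >= 3:
        sub = table.select_samples(vent_samples).select_otus(union_all)
        keep = [s for s in vent_samples if sub.data.loc[s].sum() > 0]
        sub = sub.select_samples(keep)
        dm = distance_matrix(sub, metric=b_cfg.get("metric", "thetayc"))
        dm_path = outdir / "distance.tsv"
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(dm_path, sep="\t")
        manifest["outputs"]["distance"] = str(dm_path)
        ordination = nmds(
            dm, k=b_cfg.get("dimensions", 2),
            restarts=b_cfg.get("restarts", 20),
            max_iter=b_cfg.get("max_iter", 500),
            tol=b_cfg.get("tol", 1e-7),
            seed=b_seed,
        )
        nmds_path = outdir / "nmds.tsv"
        ordination.coordinates.to_csv(nmds_path, sep="\t")
        manifest["outputs"]["nmds"] = str(nmds_path)
        beta_stage.update(stress=ordination.stress, converged=ordination.converged,
                          samples=len(keep), otus=len(union_all))
        # biplot vectors: OTU relative abundances and chemistry
        rel = sub.relative_abundance()
        otu_vectors = fit_vectors(ordination, rel, kind="otu",
                                  otu_totals=sub.data.sum(axis=0))
        otu_vec_path = outdir / "vectors_otu.tsv"
        otu_vectors.to_csv(otu_vec_path, sep="\t", index=False)
        manifest["outputs"]["vectors_otu"] = str(otu_vec_path)
        chem = meta.chemistry().reindex(keep)
        env_vectors = pd.DataFrame()
        chem_complete = chem.dropna(axis=1)
        if not chem_complete.empty:
            env_vectors = fit_vectors(ordination, chem_complete, kind="environment")
            env_vec_path = outdir / "vectors_env.tsv"
            env_vectors.to_csv(env_vec_path, sep="\t", index=False)
            manifest["outputs"]["vectors_env"] = str(env_vec_path)
            bio = bioenv(dm, chem_complete,
                         max_subset_size=b_cfg.get("max_subset_size"))
            bio_rows = [{"subset_size": size, "variables": ",".join(sub_), "rho": rho}
                        for size, (sub_, rho) in sorted(bio.per_size.items())]
            bio_path = outdir / "bioenv.tsv"
            pd.DataFrame(bio_rows).to_csv(bio_path, sep="\t", index=False)
            manifest["outputs"]["bioenv"] = str(bio_path)
            beta_stage.update(bioenv_best=list(bio.best_subset),
                              bioenv_rho=bio.best_rho)
    manifest["stages"]["beta"] = beta_stage

    # --- per-sample summary (library bookkeeping + headline estimators) ----
    total_rows = report.frame[(report.frame["scope"] == "total")
                              & (report.frame["domain"] == "all")]
    summary = total_rows.set_index("sample_id")[
        ["N", "coverage", "sobs", "chao1", "inv_simpson", "evenness", "np_shannon"]
    ].copy()
    vs_count = {s: c for v in vent_sets.values()
                for s, c in v.per_sample_seq_count.items()}
    vs_pct = {s: p for v in vent_sets.values()
              for s, p in v.per_sample_percent.items()}
    summary["vent_specific_seqs"] = pd.Series(vs_count)
    summary["vent_specific_pct"] = pd.Series(vs_pct)
    vs_rows = report.frame[(report.frame["scope"] == "vent_specific")
                           & (report.frame["domain"] == "all")]
    summary["vent_specific_pd"] = vs_rows.set_index("sample_id")["phylo_diversity_mean"]
    summary_path = outdir / "summary.tsv"
    summary.to_csv(summary_path, sep="\t")
    manifest["outputs"]["summary"] = str(summary_path)

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    manifest["checksums"] = {
        name: _sha256(Path(p)) for name, p in manifest["outputs"].items()
        if Path(p).is_file()
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
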