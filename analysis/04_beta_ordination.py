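#!/usr/bin/env python
"""Beta diversity of the vent-specific communities: theta_YC, NMDS, BIOENV.

Builds the Yue-Clayton distance matrix over the vent samples restricted
to the vent-specific OTU union, embeds it with nonmetric MDS, fits OTU
and (log-transformed) chemistry biplot vectors, clusters samples
(Bray-Curtis, average linkage), and searches chemistry subsets with
BIOENV.  Writes distance/ordination/vector/bioenv tables to results/.
"""

from pathlib import Path

import pandas as pd
from sklearn.metrics import silhouette_score

from ventflow.beta import bioenv, distance_matrix, fit_vectors, hier_cluster, nmds
from ventflow.enrichment import subtract_background
from ventflow.synth import make_scenario

SEED = 42
OUT = Path("results")
OUT.mkdir(exist_ok=True)

scenario = make_scenario(seed=SEED)
vent_sets, _ = subtract_background(scenario.table, scenario.metadata)
union = sorted(set().union(*[v.union for v in vent_sets.values()]))
vents = [s for s in scenario.table.sample_ids
         if scenario.metadata.data.loc[s, "habitat"] == "diffuse_flow"]
sub = scenario.table.select_samples(vents).select_otus(union)

dm = distance_matrix(sub, "thetayc")
pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
    OUT / "distance_thetayc.tsv", sep="\t")

ordination = nmds(dm, restarts=20, seed=SEED)
ordination.coordinates.to_csv(OUT / "nmds.tsv", sep="\t")
labels = [scenario.metadata.data.loc[s, "region"] for s in ordination.sample_ids]
sil = silhouette_score(ordination.coordinates.to_numpy(), labels)
print(f"NMDS: stress = {ordination.stress:.4f}, region silhouette = {sil:.3f}")

otu_vec = fit_vectors(ordination, sub.relative_abundance(), kind="otu",
                      otu_totals=sub.data.sum(axis=0))
otu_vec.to_csv(OUT / "vectors_otu.tsv", sep="\t", index=False)
print(f"OTU vectors retained (r >= 0.6, >= 200 seqs): {int(otu_vec['retained'].sum())}")

chem = scenario.metadata.chemistry().reindex(vents).dropna(axis=1)
env_vec = fit_vectors(ordination, chem, kind="environment")
env_vec.to_csv(OUT / "vectors_env.tsv", sep="\t", index=False)
kept = env_vec[env_vec["retained"]].sort_values("r", ascending=False)
print("chemistry vectors with r >= 0.2:",
      ", ".join(f"{r.variable} ({r.r:.2f})" for r in kept.itertuples()))

bc = distance_matrix(sub, "braycurtis")
dend = hier_cluster(bc, "average")
print("Bray-Curtis clustering merge heights:",
      ", ".join(f"{h:.3f}" for h in dend.merge_heights()))

result = bioenv(dm, chem)
rows = [{"subset_size": k, "variables": ",".join(v[0]), "rho": v[1]}
        for k, v in sorted(result.per_size.items())]
pd.DataFrame(rows).to_csv(OUT / "bioenv.tsv", sep="\t", index=False)
print(f"BIOENV best subset: {', '.join(result.best_subset)} "
      f"(rho = {result.best_rho:.3f}; planted drivers: "
      f"{', '.join(scenario.truth.chem_drivers)})")
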