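"""Synthetic two-region vent / off-axis scenario generator with known ground truth.

Emulates the statistical structure the pipeline assumes: two spreading
centres (EPR and GUAYMAS), each with one off-axis background library and
several diffuse-flow libraries.  The background community is dominated by
a Marine Group I Thaumarchaeota OTU (~60% of reads) with a secondary
SUP05 Gammaproteobacteria OTU (7% / 13% by region) over a lognormal tail.
Vent libraries are the background diluted by a planted set of
vent-enriched OTUs at configured fold changes, most of which are entirely
absent from background water.  Chemistry tables carry region contrasts
(Co x10 and Fe x30 higher at EPR, Ni x2.5 higher at Guaymas) over
lognormal noise, making {Co, Fe, Ni} the planted drivers of the
between-region community split.  Every downstream stage has a recorded
truth channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import ConfigurationError
from .io_model import (
    AbundanceVector,
    OtuTable,
    SampleMetadata,
    TaxonomyMap,
    TAXONOMY_RANKS,
)

logger = logging.getLogger("ventflow")

#: fixed, small lineage vocabulary so that domain-partition tests are deterministic
TAXONOMY_VOCABULARY = [
    ("Archaea", "Thaumarchaeota", "Nitrososphaeria", "Nitrosopumilales", "Nitrosopumilaceae", "Marine_Group_I"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Oceanospirillales", "SUP05_cluster", "SUP05"),
    ("Bacteria", "Proteobacteria", "Epsilonproteobacteria", "Campylobacterales", "Helicobacteraceae", "Sulfurovum"),
    ("Bacteria", "Proteobacteria", "Epsilonproteobacteria", "Campylobacterales", "Helicobacteraceae", "Sulfurimonas"),
    ("Bacteria", "Proteobacteria", "Epsilonproteobacteria", "Campylobacterales", "Campylobacteraceae", "Arcobacter"),
    ("Bacteria", "Planctomycetes", "Planctomycetia", "Planctomycetales", "Planctomycetaceae", "unclassified"),
    ("Archaea", "Euryarchaeota", "Thermococci", "Thermococcales", "Thermococcaceae", "Thermococcus"),
    ("Archaea", "Euryarchaeota", "Thermoplasmata", "Marine_Group_II", "unclassified", "unclassified"),
    ("Bacteria", "Deferribacteres", "SAR406", "Marine_Group_A", "unclassified", "unclassified"),
    ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Desulfobacterales", "Desulfobulbaceae", "unclassified"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Methylococcales", "Methylococcaceae", "unclassified"),
    ("unclassified", "unclassified", "unclassified", "unclassified", "unclassified", "unclassified"),
]
#: draw weights for tail/planted lineages (dominant/secondary are assigned directly)
_VOCAB_WEIGHTS = np.array([2, 2, 6, 5, 4, 4, 4, 3, 3, 3, 3, 2], dtype=float)


@dataclass
class RegionConfig:
    """Study-design knobs for one spreading centre."""

    name: str
    n_vents: int
    background_richness: int  # OTUs in the off-axis community, incl the 2 dominants
    n_enriched: int  # planted vent-enriched OTUs (region union)
    dominant_weight: float = 0.60
    secondary_weight: float = 0.07
    frac_absent_off_axis: float = 0.96


@dataclass
class ChemistryConfig:
    """Per-variable mean concentration by region, with lognormal noise.

    Defaults put Co x10 and Fe x30 higher at EPR and Ni x2.5 higher at
    Guaymas; the remaining variables have no region contrast and act as
    distractors for the BIOENV search.  pH is drawn normal (it is already
    a log quantity).  Units are nominal micromolar except temperature
    (deg C) and pH.
    """

    means: dict = field(default_factory=lambda: {
        "Co": {"EPR": 0.050, "GUAYMAS": 0.005},
        "Fe": {"EPR": 30.0, "GUAYMAS": 1.0},
        "Ni": {"EPR": 0.020, "GUAYMAS": 0.050},
        "NH4": {"EPR": 20.0, "GUAYMAS": 20.0},
        "sulfide": {"EPR": 50.0, "GUAYMAS": 50.0},
        "Mg": {"EPR": 50000.0, "GUAYMAS": 50000.0},
    })
    cv: float = 0.3
    ph_mean: float = 6.5
    ph_sd: float = 0.4
    drivers: tuple = ("Co", "Fe", "Ni")


@dataclass
class ScenarioConfig:
    """Full scenario: study design, community shape, and chemistry contrasts."""

    regions: tuple = (
        RegionConfig("EPR", n_vents=4, background_richness=500, n_enriched=396,
                     secondary_weight=0.07, frac_absent_off_axis=0.96),
        RegionConfig("GUAYMAS", n_vents=6, background_richness=300, n_enriched=90,
                     secondary_weight=0.13, frac_absent_off_axis=0.72),
    )
    depth_range: tuple = (15_000, 77_000)
    tail_log_sigma: float = 1.0  # lognormal sd of the background rank-abundance tail
    fold_range: tuple = (2.0, 100.0)  # log-uniform planted fold-change law
    denovo_median_abundance: float = 1e-4  # vent abundance of OTUs absent off axis
    denovo_log_sigma: float = 1.5
    sample_jitter_sigma: float = 0.5  # per-vent-sample lognormal jitter on planted mass
    # each vent sample carries a latent venting-intensity g ~ N(0,1) that scales
    # the planted community mass and the driver chemistry, so the chemistry
    # drivers track community structure within regions, not only between them
    intensity_community: float = 0.6
    intensity_chemistry: float = 0.75
    chemistry: ChemistryConfig = field(default_factory=ChemistryConfig)

    def validate(self) -> None:
        for reg in self.regions:
            if reg.dominant_weight + reg.secondary_weight >= 1.0:
                raise ConfigurationError(
                    f"{reg.name}: dominant + secondary weight must be < 1"
                )
            if reg.background_richness < 3:
                raise ConfigurationError(f"{reg.name}: background_richness must be >= 3")
            if reg.n_vents < 1:
                raise ConfigurationError(f"{reg.name}: need at least one vent sample")
        if self.fold_range[0] < 2.0:
            raise ConfigurationError("planted fold changes must be >= 2")
        if not (0 < self.depth_range[0] <= self.depth_range[1]):
            raise ConfigurationError("invalid depth range")


@dataclass
class GroundTruth:
    """Truth channel for recovery tests."""

    planted: dict = field(default_factory=dict)  # region -> {otu_id: nominal fold}
    planted_in_off_axis: dict = field(default_factory=dict)  # region -> set of otu_ids
    background: dict = field(default_factory=dict)  # region -> composition Series
    vent_compositions: dict = field(default_factory=dict)  # sample -> composition Series
    realized_folds: dict = field(default_factory=dict)  # sample -> Series (planted only)
    depths: dict = field(default_factory=dict)  # sample -> library depth
    intensities: dict = field(default_factory=dict)  # vent sample -> latent g
    chem_drivers: tuple = ()

    def expected_vent_count(self, sample: str, otu: str) -> float:
        comp = self.vent_compositions[sample]
        return float(comp.get(otu, 0.0)) * self.depths[sample]


@dataclass
class SimulatedScenario:
    table: OtuTable
    metadata: SampleMetadata
    taxonomy: TaxonomyMap
    tree: TreeNode
    truth: GroundTruth
    config: ScenarioConfig


# ---------------------------------------------------------------------------
# component generators
# ---------------------------------------------------------------------------

def make_background(config: ScenarioConfig, region: RegionConfig,
                    rng: np.random.Generator) -> tuple[pd.Series, pd.DataFrame]:
    """Off-axis background composition plus taxonomy labels for one region.

    The dominant OTU carries exactly ``dominant_weight`` of the community
    (MGI Thaumarchaeota), the secondary exactly ``secondary_weight``
    (SUP05); the remaining mass is a normalised lognormal tail.
    """
    w1, w2 = region.dominant_weight, region.secondary_weight
    n_tail = region.background_richness - 2
    tail_raw = rng.lognormal(mean=0.0, sigma=config.tail_log_sigma, size=n_tail)
    tail = tail_raw / tail_raw.sum() * (1.0 - w1 - w2)
    ids = [f"{region.name}_MGI", f"{region.name}_SUP05"] + [
        f"{region.name}_bg{i:04d}" for i in range(n_tail)
    ]
    comp = pd.Series(np.concatenate([[w1, w2], tail]), index=ids)
    vocab_idx = rng.choice(len(TAXONOMY_VOCABULARY), size=n_tail,
                           p=_VOCAB_WEIGHTS / _VOCAB_WEIGHTS.sum())
    lineages = [TAXONOMY_VOCABULARY[0], TAXONOMY_VOCABULARY[1]] + [
        TAXONOMY_VOCABULARY[i] for i in vocab_idx
    ]
    tax = pd.DataFrame(lineages, index=ids, columns=list(TAXONOMY_RANKS))
    return comp, tax


def make_vent_composition(
    background: pd.Series,
    planted_folds: pd.Series,
    denovo_abundance: pd.Series,
    rng: np.random.Generator,
    jitter_sigma: float = 0.0,
    log_scale=0.0,
) -> tuple[pd.Series, pd.Series]:
    """Build one vent composition from the background and the planted truth.

    Planted OTUs present in the background receive exactly ``fold x
    background abundance`` (after per-sample jitter, floored so the
    realized fold stays > 2); OTUs absent from the background enter at a
    de-novo abundance.  The remaining probability mass uniformly dilutes
    the non-planted background, so realized folds are recoverable from
    the two compositions to machine precision.

    Returns (composition, realized folds for the planted OTUs; +inf for
    de-novo OTUs).
    """
    planted_present = planted_folds.index.intersection(background.index)
    planted_absent = denovo_abundance.index
    if len(planted_absent.intersection(background.index)):
        raise ConfigurationError("de-novo planted OTUs must be absent from background")
    all_planted = planted_folds.index.append(planted_absent)
    if np.isscalar(log_scale):
        shift = pd.Series(float(log_scale), index=all_planted)
    else:
        shift = pd.Series(log_scale).reindex(all_planted).fillna(0.0)
    jitter = np.exp(rng.normal(shift[planted_folds.index].to_numpy(), jitter_sigma))
    jfolds = pd.Series(planted_folds.to_numpy() * jitter, index=planted_folds.index)
    jfolds = jfolds.clip(lower=2.0 + 1e-9)
    present_mass = (jfolds[planted_present] * background[planted_present]).astype(float)
    dj = np.exp(rng.normal(shift[planted_absent].to_numpy(), jitter_sigma))
    absent_mass = denovo_abundance.astype(float) * dj
    planted_total = float(present_mass.sum() + absent_mass.sum())
    if planted_total >= 1.0:
        raise ConfigurationError(
            f"planted mass {planted_total:.3f} >= 1; reduce folds or de-novo abundances"
        )
    non_planted = background.index.difference(planted_present)
    remaining = 1.0 - planted_total
    scale = remaining / float(background[non_planted].sum())
    comp = pd.concat([
        background[non_planted] * scale,
        present_mass,
        absent_mass,
    ])
    comp = comp.groupby(level=0).sum()  # defensive: indices are disjoint by construction
    realized = pd.Series(np.inf, index=planted_folds.index.union(planted_absent))
    realized[planted_present] = (
        comp[planted_present] / background[planted_present]
    )
    return comp, realized


def sample_reads(composition: pd.Series, depth: int,
                 rng: np.random.Generator) -> pd.Series:
    """One multinomial read draw from a composition; counts sum to ``depth``."""
    if depth < 1:
        raise ConfigurationError("library depth must be >= 1")
    p = composition.to_numpy(dtype=float)
    p = p / p.sum()
    counts = rng.multinomial(depth, p)
    return pd.Series(counts, index=composition.index)


def make_tree(otu_ids, rng: np.random.Generator,
              branch_scale: float = 0.1) -> TreeNode:
    """Random rooted binary tree over the OTUs with exponential branch lengths.

    Built by random pairwise joining (a coalescent-style topology) so that
    phylogenetic diversity has a nontrivial, testable structure.
    """
    otu_ids = list(map(str, otu_ids))
    if len(otu_ids) < 2:
        raise ConfigurationError("make_tree needs at least 2 OTUs")
    nodes = [TreeNode(name=name, length=float(rng.exponential(branch_scale)))
             for name in otu_ids]
    while len(nodes) > 2:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        parent = TreeNode(length=float(rng.exponential(branch_scale)),
                          children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes, length=0.0)
    return root


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

def make_scenario(config: ScenarioConfig | None = None, seed=None) -> SimulatedScenario:
    """Generate the full study design: OTU table, metadata, taxonomy, tree, truth.

    Defaults mirror the two-region layout: 4 EPR and 6 Guaymas diffuse-flow
    samples plus one off-axis sample per region; depths log-uniform over
    15,000-77,000 reads; 396 / 90 planted vent-enriched OTUs per region
    with log-uniform fold changes on [2, 100].  Fully reproducible from
    ``seed``.
    """
    config = config or ScenarioConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    truth = GroundTruth(chem_drivers=tuple(config.chemistry.drivers))
    intensities: dict[str, float] = {}
    all_counts: dict[str, pd.Series] = {}
    tax_frames = []
    meta_rows = []
    lo, hi = config.depth_range

    def draw_depth() -> int:
        return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    for region in config.regions:
        background, tax = make_background(config, region, rng)
        truth.background[region.name] = background
        tax_frames.append(tax)

        # choose planted OTUs: a few low-abundance background tail OTUs are
        # "also present off axis"; the rest are de novo, absent from background
        n_present = int(round((1.0 - region.frac_absent_off_axis) * region.n_enriched))
        n_absent = region.n_enriched - n_present
        tail_ids = background.index[2:]
        # enriched-but-also-present-off-axis OTUs come from the rare tail, keeping
        # the planted probability mass well below 1 even at high venting intensity
        rare_pool = background[tail_ids].nsmallest(max(n_present, len(tail_ids) // 4)).index
        present_ids = list(rng.choice(rare_pool, size=n_present, replace=False))
        absent_ids = [f"{region.name}_vent{i:04d}" for i in range(n_absent)]
        folds = pd.Series(
            np.exp(rng.uniform(np.log(config.fold_range[0]),
                               np.log(config.fold_range[1]),
                               size=region.n_enriched)),
            index=present_ids + absent_ids,
        )
        denovo = pd.Series(
            rng.lognormal(np.log(config.denovo_median_abundance),
                          config.denovo_log_sigma, size=n_absent),
            index=absent_ids,
        )
        truth.planted[region.name] = folds.to_dict()
        truth.planted_in_off_axis[region.name] = set(present_ids)
        # fixed per-OTU sensitivity to venting intensity: composition within the
        # planted set tilts along the intensity gradient instead of scaling
        # uniformly (which renormalisation would cancel)
        sensitivity = pd.Series(np.clip(rng.normal(size=region.n_enriched), -2.0, 2.0),
                                index=folds.index)
        vocab_idx = rng.choice(len(TAXONOMY_VOCABULARY), size=n_absent,
                               p=_VOCAB_WEIGHTS / _VOCAB_WEIGHTS.sum())
        tax_frames.append(pd.DataFrame(
            [TAXONOMY_VOCABULARY[i] for i in vocab_idx],
            index=absent_ids, columns=list(TAXONOMY_RANKS),
        ))

        # off-axis library
        oa_id = f"{region.name}-OA"
        oa_depth = draw_depth()
        all_counts[oa_id] = sample_reads(background, oa_depth, rng)
        truth.depths[oa_id] = oa_depth
        meta_rows.append({"sample_id": oa_id, "region": region.name,
                          "habitat": "off_axis", "macrofauna": False,
                          "temperature": 2.0})

        # vent libraries
        for v in range(region.n_vents):
            sample_id = f"{region.name}-V{v + 1}"
            g = float(np.clip(rng.normal(), -1.5, 1.5))  # venting intensity
            intensities[sample_id] = g
            comp, realized = make_vent_composition(
                background, folds[present_ids], denovo, rng,
                jitter_sigma=config.sample_jitter_sigma,
                log_scale=g * (0.3 + config.intensity_community * sensitivity),
            )
            depth = draw_depth()
            all_counts[sample_id] = sample_reads(comp, depth, rng)
            truth.vent_compositions[sample_id] = comp
            truth.realized_folds[sample_id] = realized
            truth.depths[sample_id] = depth
            meta_rows.append({
                "sample_id": sample_id, "region": region.name,
                "habitat": "diffuse_flow",
                "macrofauna": bool(v % 2 == 0),
                "temperature": float(np.round(rng.uniform(14.0, 36.0), 1)),
            })

    # chemistry: lognormal around region means for diffuse-flow samples only
    chem_cfg = config.chemistry
    sigma = np.sqrt(np.log1p(chem_cfg.cv**2))
    for row in meta_rows:
        if row["habitat"] != "diffuse_flow":
            for var in chem_cfg.means:
                row[var] = np.nan
            row["pH"] = np.nan
            continue
        g = intensities.get(row["sample_id"], 0.0)
        for var, means in chem_cfg.means.items():
            mu = means[row["region"]]
            if var in chem_cfg.drivers:
                mu *= np.exp(config.intensity_chemistry * g)
            row[var] = float(rng.lognormal(np.log(mu) - sigma**2 / 2.0, sigma))
        row["pH"] = float(rng.normal(chem_cfg.ph_mean, chem_cfg.ph_sd))

    truth.intensities = intensities
    all_otus = sorted(set().union(*[s.index for s in all_counts.values()]))
    matrix = pd.DataFrame(0, index=list(all_counts), columns=all_otus, dtype=np.int64)
    for sample, counts in all_counts.items():
        matrix.loc[sample, counts.index] = counts.to_numpy()
    table = OtuTable(matrix)  # all-zero OTUs (unsampled rare types) are dropped here
    tax_all = pd.concat(tax_frames)
    tax_all = tax_all[~tax_all.index.duplicated()]
    taxonomy = TaxonomyMap(tax_all.loc[tax_all.index.intersection(all_otus)].reindex(table.otu_ids))
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    tree = make_tree(table.otu_ids, rng)
    logger.info(
        "scenario: %d samples, %d OTUs, %d planted vent-enriched",
        table.n_samples, table.n_otus,
        sum(len(v) for v in truth.planted.values()),
    )
    return SimulatedScenario(table=table, metadata=metadata, taxonomy=taxonomy,
                             tree=tree, truth=truth, config=config)


def write_scenario(scenario: SimulatedScenario, outdir) -> dict:
    """Write shared.tsv, taxonomy.tsv, meta.tsv, tree.nwk, truth.tsv under ``outdir``."""
    from pathlib import Path

    from .io_model import write_metadata, write_newick, write_otu_table, write_taxonomy

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": outdir / "shared.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "meta.tsv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.tsv",
    }
    write_otu_table(scenario.table, paths["table"], dialect="mothur_shared")
    write_taxonomy(scenario.taxonomy, paths["taxonomy"])
    write_metadata(scenario.metadata, paths["metadata"])
    write_newick(scenario.tree, paths["tree"])
    rows = []
    for region, planted in scenario.truth.planted.items():
        present = scenario.truth.planted_in_off_axis[region]
        for otu, fold in planted.items():
            rows.append({"region": region, "otu_id": otu, "nominal_fold": fold,
                         "in_off_axis": otu in present})
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
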