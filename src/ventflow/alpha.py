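"""Nonparametric alpha-diversity estimators and rarefaction.

Implements the calculator battery applied per sample (and per domain, and
per vent-specific subset): observed richness, bias-corrected Chao1 with a
log-normal 95% CI, Good's coverage, inverse Simpson with a delta-method
CI, Simpson evenness, the Chao–Shen coverage-adjusted (nonparametric)
Shannon index, the analytic rarefaction curve, and rarefied Faith-type
phylogenetic diversity on a supplied tree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ValidationError
from .io_model import AbundanceVector, OtuTable, TaxonomyMap, restrict_by_domain

logger = logging.getLogger("ventflow")

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


def chao1(v: AbundanceVector, bias_corrected: bool = True) -> tuple[float, float, float]:
    """Chao1 richness estimate with a 95% log-normal confidence interval.

    The default is the bias-corrected form
    ``S = Sobs + n1 (n1 - 1) / (2 (n2 + 1))``; the classic form
    ``Sobs + n1^2 / (2 n2)`` is available via ``bias_corrected=False``
    (falling back to the corrected form when ``n2 = 0``).  With no
    singletons the estimate equals ``Sobs`` and the CI is degenerate.
    """
    if v.N < 1:
        raise ValidationError("chao1 requires a non-empty abundance vector")
    sobs = float(v.sobs)
    n1, n2 = float(v.n1), float(v.n2)
    if n1 == 0:
        return sobs, sobs, sobs
    if bias_corrected or n2 == 0:
        estimate = sobs + n1 * (n1 - 1.0) / (2.0 * (n2 + 1.0))
    else:
        estimate = sobs + n1 * n1 / (2.0 * n2)
    if n2 > 0:
        # classical variance of the bias-corrected estimator
        var = (
            n1 * (n1 - 1.0) / (2.0 * (n2 + 1.0))
            + n1 * (2.0 * n1 - 1.0) ** 2 / (4.0 * (n2 + 1.0) ** 2)
            + n1**2 * n2 * (n1 - 1.0) ** 2 / (4.0 * (n2 + 1.0) ** 4)
        )
    else:
        var = (
            n1 * (n1 - 1.0) / 2.0
            + n1 * (2.0 * n1 - 1.0) ** 2 / 4.0
            - n1**4 / (4.0 * estimate)
        )
    t = estimate - sobs
    if t <= 0 or var <= 0:
        return estimate, sobs, estimate
    kfac = np.exp(_Z95 * np.sqrt(np.log1p(var / t**2)))
    return float(estimate), float(sobs + t / kfac), float(sobs + t * kfac)


def goods_coverage(v: AbundanceVector) -> float:
    """Good's coverage C = 1 - n1/N: chance the next read is an already-seen OTU."""
    if v.N < 1:
        raise ValidationError("goods_coverage requires a non-empty abundance vector")
    return 1.0 - v.n1 / v.N


def inverse_simpson(v: AbundanceVector) -> tuple[float, float, float]:
    """Inverse Simpson diversity 1/D with an approximate 95% delta-method CI.

    ``D = sum n_i (n_i - 1) / (N (N - 1))`` is the unbiased estimator of the
    probability that two reads drawn without replacement share an OTU.  When
    every OTU is a singleton D = 0; the estimate is then reported as Sobs
    with a degeneracy warning and a collapsed CI.
    """
    N = v.N
    if N < 2:
        raise ValidationError("inverse_simpson requires at least 2 reads")
    n = v.nonzero().astype(float)
    D = float(np.sum(n * (n - 1.0)) / (N * (N - 1.0)))
    if D == 0.0:
        warnings.warn("all OTUs are singletons; inverse Simpson degenerate, reporting Sobs")
        return float(v.sobs), float(v.sobs), float(v.sobs)
    est = 1.0 / D
    p = n / N
    var_d = max(0.0, 4.0 / N * (float(np.sum(p**3)) - float(np.sum(p**2)) ** 2))
    sd = np.sqrt(var_d) / D**2
    return est, max(1.0, est - _Z95 * sd), est + _Z95 * sd


def simpson_evenness(inv_simpson_value: float, sobs: int) -> float:
    """Simpson evenness E = (1/D) / Sobs (computed from the unrounded 1/D)."""
    if sobs < 1:
        raise ValidationError("simpson_evenness requires sobs >= 1")
    return inv_simpson_value / sobs


def np_shannon(v: AbundanceVector) -> float:
    """Chao–Shen coverage-adjusted (nonparametric) Shannon index, natural log.

    Coverage-deflated frequencies ``p~_i = C n_i / N`` with ``C = 1 - n1/N``
    are combined with a Horvitz–Thompson correction for unseen OTUs::

        H = -sum  p~_i ln p~_i / (1 - (1 - p~_i)^N)
    """
    N = v.N
    if N < 1:
        raise ValidationError("np_shannon requires a non-empty abundance vector")
    n = v.nonzero().astype(float)
    C = 1.0 - v.n1 / N
    p = C * n / N
    p = p[p > 0]  # zero-coverage communities contribute nothing measurable
    if p.size == 0:
        return 0.0
    detect = -np.expm1(N * np.log1p(-np.minimum(p, 1.0 - 1e-300)))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p >= 1.0, 0.0, -p * np.log(p) / detect)
    return float(np.sum(terms))


def rarefaction_curve(v: AbundanceVector, depths) -> np.ndarray:
    """Analytic expected richness E[S_m] at each subsampling depth.

    Hypergeometric expectation ``E[S_m] = sum_i 1 - C(N - n_i, m) / C(N, m)``
    evaluated exactly through log-gamma.
    """
    N = v.N
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if np.any(depths < 1) or np.any(depths > N):
        raise ValidationError(f"rarefaction depths must lie in [1, N={N}]")
    n = v.nonzero().astype(np.int64)
    out = np.empty(depths.shape, dtype=float)
    for j, m in enumerate(depths):
        keep = (N - n) >= m
        log_excl = (
            gammaln(N - n[keep] + 1.0) - gammaln(N - n[keep] - m + 1.0)
            - gammaln(N + 1.0) + gammaln(N - m + 1.0)
        )
        out[j] = (np.count_nonzero(~keep)) + float(np.sum(-np.expm1(log_excl)))
    return out


# ---------------------------------------------------------------------------
# phylogenetic diversity
# ---------------------------------------------------------------------------

def faith_pd(tree, otu_ids) -> float:
    """Total branch length of the union of root-to-leaf paths for ``otu_ids``."""
    otu_ids = set(map(str, otu_ids))
    if not otu_ids:
        return 0.0
    tips = {t.name: t for t in tree.tips()}
    missing = sorted(otu_ids - tips.keys())
    if missing:
        raise ValidationError(f"OTU(s) missing from tree: {missing[:10]}")
    visited: set[int] = set()
    total = 0.0
    for name in otu_ids:
        node = tips[name]
        while node.parent is not None and id(node) not in visited:
            visited.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return total


def phylo_diversity(
    tree,
    counts: pd.Series,
    m: int = 200,
    reps: int = 1000,
    seed=None,
) -> tuple[float, float]:
    """Rarefied Faith-type phylogenetic diversity.

    Draws ``reps`` subsamples of ``m`` reads without replacement from the
    sample, and averages the total branch length spanned by the OTUs
    present in each subsample (root path included).  Returns the mean and
    its Monte-Carlo standard error.  ``m = N`` is deterministic.
    """
    counts = counts[counts > 0]
    v = AbundanceVector(counts.to_numpy())
    N = v.N
    if m > N:
        raise ValidationError(f"subsample size m={m} exceeds library size N={N}")
    if m < 1 or reps < 1:
        raise ValidationError("m and reps must be >= 1")
    otu_ids = [str(i) for i in counts.index]
    if m == N:
        return faith_pd(tree, otu_ids), 0.0
    rng = np.random.default_rng(seed)
    arr = v.counts
    values = np.empty(reps)
    for r in range(reps):
        sub = rng.multivariate_hypergeometric(arr, m)
        present = [otu_ids[i] for i in np.flatnonzero(sub)]
        values[r] = faith_pd(tree, present)
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(reps))


# ---------------------------------------------------------------------------
# per-sample report
# ---------------------------------------------------------------------------

@dataclass
class DiversityReport:
    """Tidy per-(sample x scope) alpha-diversity table."""

    frame: pd.DataFrame

    def __iter__(self):
        return (row for _, row in self.frame.iterrows())


def summarize_vector(v: AbundanceVector) -> dict:
    """All scalar estimators for one abundance vector; NaN where undefined."""
    out = {"N": v.N, "sobs": v.sobs}
    if v.N < 1:
        out.update({k: np.nan for k in (
            "chao1", "chao1_lci", "chao1_hci", "coverage",
            "inv_simpson", "inv_simpson_lci", "inv_simpson_hci",
            "evenness", "np_shannon")})
        return out
    est, lci, hci = chao1(v)
    out.update(chao1=est, chao1_lci=lci, chao1_hci=hci, coverage=goods_coverage(v))
    if v.N >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            inv, ilci, ihci = inverse_simpson(v)
        out.update(
            inv_simpson=inv, inv_simpson_lci=ilci, inv_simpson_hci=ihci,
            evenness=simpson_evenness(inv, v.sobs),
        )
    else:
        out.update(inv_simpson=np.nan, inv_simpson_lci=np.nan,
                   inv_simpson_hci=np.nan, evenness=np.nan)
    out["np_shannon"] = np_shannon(v)
    return out


def diversity_report(
    table: OtuTable,
    tax: TaxonomyMap | None = None,
    tree=None,
    vent_sets: dict | None = None,
    scopes=("total",),
    pd_subsample: int = 200,
    pd_reps: int = 1000,
    seed=None,
) -> DiversityReport:
    """Apply the estimator battery per sample for each requested scope.

    Scopes: ``total`` (whole library), ``vent_specific`` (restricted to the
    sample's enriched OTU set, requires ``vent_sets`` keyed by region from
    :func:`ventflow.enrichment.subtract_background`), ``domain`` (Bacteria
    and Archaea sub-libraries, requires ``tax``).  When a tree is supplied,
    rarefied phylogenetic diversity is reported for rows with
    ``N >= pd_subsample``.
    """
    rows = []
    domain_tables = {}
    if "domain" in scopes:
        if tax is None:
            raise ValidationError("domain scope requires a taxonomy map")
        for dom in ("Bacteria", "Archaea"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                domain_tables[dom] = restrict_by_domain(table, tax, dom)
    sample_enriched = {}
    if vent_sets is not None:
        for vset in vent_sets.values():
            sample_enriched.update(vset.per_sample)
    rng = np.random.default_rng(seed)
    for sample in table.sample_ids:
        subsets = {}
        if "total" in scopes:
            subsets[("total", "all")] = table.data.loc[sample]
        if "vent_specific" in scopes and sample in sample_enriched:
            otus = sorted(sample_enriched[sample])
            counts = table.data.loc[sample, otus] if otus else pd.Series(dtype=np.int64)
            subsets[("vent_specific", "all")] = counts
            if tax is not None:
                for dom in ("Bacteria", "Archaea"):
                    dom_otus = [o for o in otus if tax.domain_of(o) == dom]
                    subsets[("vent_specific", dom)] = table.data.loc[sample, dom_otus]
        if "domain" in scopes:
            for dom, dtab in domain_tables.items():
                subsets[("total", dom)] = dtab.data.loc[sample]
        for (scope, dom), counts in subsets.items():
            counts = counts[counts > 0] if len(counts) else counts
            v = AbundanceVector(counts.to_numpy() if len(counts) else np.array([], dtype=np.int64))
            row = {"sample_id": sample, "scope": scope, "domain": dom}
            row.update(summarize_vector(v))
            if tree is not None and v.N >= pd_subsample:
                pd_mean, pd_se = phylo_diversity(
                    tree, counts, m=pd_subsample, reps=pd_reps,
                    seed=rng.integers(2**31),
                )
                row.update(phylo_diversity_mean=pd_mean, phylo_diversity_se=pd_se)
            else:
                row.update(phylo_diversity_mean=np.nan, phylo_diversity_se=np.nan)
            rows.append(row)
    return DiversityReport(pd.DataFrame(rows))
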