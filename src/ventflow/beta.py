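"""Community comparison: dissimilarity matrices, clustering, NMDS, vector fitting, BIOENV.

Distances are Yue–Clayton theta (1 - theta_YC) or Bray–Curtis on relative
abundances.  Nonmetric multidimensional scaling minimises Kruskal stress-1
by iterative majorization (SMACOF) with monotone regression of the
configuration distances on the dissimilarities; the BIOENV search
exhaustively scores environmental-variable subsets by the Spearman rank
correlation between community dissimilarity and environmental Euclidean
distance.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr
from sklearn.isotonic import IsotonicRegression
from skbio import DistanceMatrix

from .errors import ValidationError
from .io_model import OtuTable

logger = logging.getLogger("ventflow")

_SUM_TOL = 1e-9


def _check_composition(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    total = a.sum()
    if total <= 0:
        raise ValidationError(f"{name}: zero-sum relative-abundance vector")
    if abs(total - 1.0) > _SUM_TOL:
        raise ValidationError(f"{name}: relative abundances must sum to 1 (got {total})")
    return a


def theta_yc(a, b) -> float:
    """Yue–Clayton similarity between two relative-abundance vectors.

    theta = sum(a_i b_i) / (sum a_i^2 + sum b_i^2 - sum a_i b_i); equals 1
    iff the compositions are identical and 0 for disjoint supports.
    """
    a = _check_composition(a, "a")
    b = _check_composition(b, "b")
    if a.shape != b.shape:
        raise ValidationError("vectors must share one OTU index")
    cross = float(np.dot(a, b))
    denom = float(np.dot(a, a) + np.dot(b, b)) - cross
    return cross / denom


def bray_curtis(a, b) -> float:
    """Bray–Curtis similarity: 1 - sum|a_i - b_i| / sum(a_i + b_i)."""
    a = _check_composition(a, "a")
    b = _check_composition(b, "b")
    if a.shape != b.shape:
        raise ValidationError("vectors must share one OTU index")
    return 1.0 - float(np.abs(a - b).sum() / (a + b).sum())


METRICS = {"thetayc": theta_yc, "braycurtis": bray_curtis}


def distance_matrix(table: OtuTable, metric: str = "thetayc",
                    sample_ids=None) -> DistanceMatrix:
    """Pairwise dissimilarity (1 - similarity) matrix over samples."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {sorted(METRICS)}, got {metric!r}")
    sim = METRICS[metric]
    if sample_ids is not None:
        table = table.select_samples(sample_ids)
    rel = table.relative_abundance().to_numpy()
    ids = table.sample_ids
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = 1.0 - sim(rel[i], rel[j])
    return DistanceMatrix(out, ids)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative clustering result: scipy linkage matrix over sorted ids."""

    ids: list[str]
    linkage: np.ndarray
    method: str

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hier_cluster(dm: DistanceMatrix, method: str = "average") -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    Samples are pre-sorted lexicographically so that tie-breaking is
    deterministic and independent of input order.
    """
    if method not in ("average", "complete", "single"):
        raise ValueError(f"linkage must be average/complete/single, got {method!r}")
    if dm.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 samples")
    ids = sorted(dm.ids)
    sub = dm.filter(ids)
    condensed = squareform(sub.data, checks=False)
    Z = scipy_linkage(condensed, method=method)
    return Dendrogram(ids=ids, linkage=Z, method=method)


# ---------------------------------------------------------------------------
# nonmetric multidimensional scaling
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """NMDS sample coordinates with stress and (optionally) fitted vectors."""

    coordinates: pd.DataFrame  # samples x axes, centered, principal-axis rotated
    stress: float  # Kruskal stress-1
    n_restarts: int
    converged: bool
    stress_path: np.ndarray | None = None  # per-iteration stress of the best restart
    vectors: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)


def kruskal_stress(dist: np.ndarray, disparities: np.ndarray) -> float:
    denom = float(np.sum(dist**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - disparities) ** 2) / denom))


def _classical_mds(full: np.ndarray, k: int) -> np.ndarray:
    # principal-coordinates start: double-centred squared distances
    n = full.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (full**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _smacof_once(d: np.ndarray, X: np.ndarray, max_iter: int, tol: float):
    n = X.shape[0]
    iso = IsotonicRegression(out_of_bounds="clip")
    path = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        dist = pdist(X)
        # monotone regression of configuration distances on dissimilarities;
        # exact ties in d are pooled (primary approach to ties)
        disparities = iso.fit_transform(d, dist)
        stress = kruskal_stress(dist, disparities)
        path.append(stress)
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, disparities / dist, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
    dist = pdist(X)
    disparities = iso.fit_transform(d, dist)
    final = kruskal_stress(dist, disparities)
    path.append(final)
    return X, final, np.asarray(path), converged


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed=None,
) -> OrdinationResult:
    """Nonmetric MDS of a dissimilarity matrix into ``k`` dimensions.

    Runs a principal-coordinates-initialised fit plus ``restarts - 1``
    random initialisations and keeps the configuration with the lowest
    Kruskal stress-1.  Coordinates are centred and rotated to principal
    axes.  If no restart converges the best configuration found is
    returned flagged ``converged=False``.
    """
    n = dm.shape[0]
    if n < k + 1:
        raise ValidationError(f"NMDS in {k} dimensions needs at least {k + 1} samples")
    rng = np.random.default_rng(seed)
    d = squareform(dm.data, checks=False)
    inits = [_classical_mds(dm.data, k)]
    scale = max(d.max(), 1e-12)
    for _ in range(max(0, restarts - 1)):
        inits.append(rng.normal(scale=scale, size=(n, k)))
    best = None
    for X0 in inits:
        X, stress, path, conv = _smacof_once(d, X0.copy(), max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, path, conv)
    X, stress, path, conv = best
    X = X - X.mean(axis=0)
    # principal-axis rotation
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    coords = pd.DataFrame(X, index=dm.ids, columns=[f"axis{i+1}" for i in range(k)])
    if not conv:
        logger.warning("NMDS did not converge in any restart; best stress %.4g", stress)
    return OrdinationResult(
        coordinates=coords, stress=stress, n_restarts=len(inits),
        converged=conv, stress_path=path,
    )


# ---------------------------------------------------------------------------
# vector fitting
# ---------------------------------------------------------------------------

def log_transform_chemistry(chem: pd.DataFrame, exempt=("pH",)) -> pd.DataFrame:
    """ln(value + pseudocount) per variable; pH (already logarithmic) exempt.

    The pseudocount is each variable's smallest positive observed value,
    guarding against zeros in concentration measurements.
    """
    out = chem.copy().astype(float)
    for col in out.columns:
        if col in exempt:
            continue
        vals = out[col]
        positive = vals[vals > 0]
        if positive.empty or (vals + positive.min() <= 0).any():
            warnings.warn(f"chemistry variable {col!r} is not positive; left untransformed")
            continue
        out[col] = np.log(vals + positive.min())
    return out


def fit_vectors(
    ordination: OrdinationResult,
    variables: pd.DataFrame,
    kind: str = "environment",
    otu_totals: pd.Series | None = None,
    r_threshold: float | None = None,
    min_sequences: int = 200,
    transform: bool = True,
) -> pd.DataFrame:
    """Correlate per-sample variables with NMDS axes (biplot vectors).

    Per-axis Pearson r_j and the magnitude r = sqrt(sum r_j^2) are
    computed for every variable.  Retention follows the kind-specific
    filters: OTU vectors need r >= 0.6 and at least ``min_sequences``
    total reads; environmental vectors need r >= 0.2 and are
    log-transformed first (pH exempt).  Constant variables are excluded
    with a warning.
    """
    if kind not in ("otu", "environment"):
        raise ValueError(f"kind must be 'otu' or 'environment', got {kind!r}")
    if r_threshold is None:
        r_threshold = 0.6 if kind == "otu" else 0.2
    coords = ordination.coordinates
    variables = variables.reindex(coords.index)
    if variables.isna().any().any():
        bad = variables.columns[variables.isna().any()].tolist()
        variables = variables.drop(columns=bad)
        warnings.warn(f"dropping variable(s) with missing values: {bad}")
    if kind == "environment" and transform:
        variables = log_transform_chemistry(variables)
    rows = []
    for col in variables.columns:
        vec = variables[col].to_numpy(dtype=float)
        if np.ptp(vec) == 0:
            warnings.warn(f"variable {col!r} is constant; correlation undefined, excluded")
            continue
        r_axes = [float(pearsonr(vec, coords[ax]).statistic) for ax in coords.columns]
        magnitude = float(np.sqrt(np.sum(np.square(r_axes))))
        retained = magnitude >= r_threshold
        if kind == "otu":
            total = int(otu_totals[col]) if otu_totals is not None else 0
            retained = retained and total >= min_sequences
        row = {"variable": col, **{f"r_{ax}": r for ax, r in zip(coords.columns, r_axes)},
               "r": magnitude, "retained": bool(retained)}
        if kind == "otu":
            row["total_sequences"] = int(otu_totals[col]) if otu_totals is not None else np.nan
        rows.append(row)
    frame = pd.DataFrame(rows)
    ordination.vectors = frame
    return frame


# ---------------------------------------------------------------------------
# BIOENV
# ---------------------------------------------------------------------------

@dataclass
class BioenvResult:
    """Best environmental-variable subset per size and overall."""

    per_size: dict = field(default_factory=dict)  # size -> (variables tuple, rho)
    best_subset: tuple = ()
    best_rho: float = np.nan
    variables_used: list = field(default_factory=list)


def bioenv(
    dm: DistanceMatrix,
    chemistry: pd.DataFrame,
    max_subset_size: int | None = None,
    transform: bool = True,
) -> BioenvResult:
    """Exhaustive BIOENV search for the chemistry subset tracking community structure.

    Variables are log-transformed (pH exempt) and z-scored; for every
    non-empty subset up to ``max_subset_size``, inter-sample Euclidean
    distances are rank-correlated (Spearman) with the community
    dissimilarities.  Variables with missing values are dropped with a
    warning; at least 4 complete samples are required.
    """
    chem = chemistry.reindex(list(dm.ids)).astype(float)
    incomplete = chem.columns[chem.isna().any()].tolist()
    if incomplete:
        warnings.warn(f"bioenv dropping variable(s) with missing values: {incomplete}")
        chem = chem.drop(columns=incomplete)
    constant = chem.columns[chem.nunique() <= 1].tolist()
    if constant:
        warnings.warn(f"bioenv dropping constant variable(s): {constant}")
        chem = chem.drop(columns=constant)
    if chem.shape[1] == 0:
        raise ValidationError("bioenv: no usable chemistry variables")
    if chem.shape[0] < 4:
        raise ValidationError("bioenv requires at least 4 samples with complete values")
    if transform:
        chem = log_transform_chemistry(chem)
    chem = (chem - chem.mean()) / chem.std(ddof=1)
    d_comm = squareform(dm.data, checks=False)
    variables = sorted(chem.columns)
    max_size = max_subset_size or len(variables)
    result = BioenvResult(variables_used=variables)
    for size in range(1, min(max_size, len(variables)) + 1):
        best_for_size = None
        for subset in itertools.combinations(variables, size):
            d_env = pdist(chem[list(subset)].to_numpy())
            rho = spearmanr(d_comm, d_env).statistic
            if np.isnan(rho):
                continue
            if best_for_size is None or rho > best_for_size[1]:
                best_for_size = (subset, float(rho))
        if best_for_size is not None:
            result.per_size[size] = best_for_size
    if not result.per_size:
        raise ValidationError("bioenv: no subset produced a defined correlation")
    best = max(result.per_size.values(), key=lambda t: t[1])
    result.best_subset, result.best_rho = best
    return result
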