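"""Domain types and readers/writers for the tabular and tree formats the pipeline touches.

The central container is :class:`OtuTable`, a samples x OTUs matrix of
non-negative integer read counts.  Counts are always stored as integers;
relative frequencies are derived lazily and never stored rounded, so that
downstream statistics are computed from exact library bookkeeping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger("ventflow")

REGIONS = ("EPR", "GUAYMAS")
HABITATS = ("diffuse_flow", "off_axis")
DOMAINS = ("Bacteria", "Archaea")
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: metadata columns that are never treated as chemistry measurements
RESERVED_METADATA_COLUMNS = frozenset(
    {"sample_id", "region", "habitat", "macrofauna", "temperature"}
)


@dataclass(frozen=True)
class AbundanceVector:
    """Read counts for one sample (or one domain-restricted sub-sample).

    Exposes the summary statistics every nonparametric diversity
    estimator consumes: library size ``N``, observed richness ``sobs``,
    and the singleton/doubleton counts ``n1``/``n2``.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 1:
            raise ValidationError("abundance vector must be one-dimensional")
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("abundance vector must hold integer counts")
            arr = np.round(arr).astype(np.int64)
        if np.any(arr < 0):
            raise ValidationError("abundance vector holds a negative count")
        object.__setattr__(self, "counts", arr.astype(np.int64, copy=False))

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def sobs(self) -> int:
        return int(np.count_nonzero(self.counts))

    @property
    def n1(self) -> int:
        return int(np.count_nonzero(self.counts == 1))

    @property
    def n2(self) -> int:
        return int(np.count_nonzero(self.counts == 2))

    def nonzero(self) -> np.ndarray:
        return self.counts[self.counts > 0]


class OtuTable:
    """Samples x OTUs non-negative integer count matrix.

    Parameters
    ----------
    counts
        DataFrame with sample ids as index and OTU ids as columns, or
        anything :func:`pandas.DataFrame` accepts together with
        ``sample_ids``/``otu_ids``.
    drop_empty_otus
        Drop all-zero OTU columns on construction (logged).  This is the
        behaviour of the file readers; set to ``False`` to keep columns
        when slicing an existing validated table.
    """

    def __init__(self, counts, sample_ids=None, otu_ids=None, *, drop_empty_otus=True):
        if isinstance(counts, pd.DataFrame):
            df = counts.copy()
        else:
            df = pd.DataFrame(np.asarray(counts), index=sample_ids, columns=otu_ids)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dupes}")
        values = df.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                fractional = ~np.isclose(values.astype(float) % 1.0, 0.0)
                if fractional.any():
                    r, c = np.argwhere(fractional)[0]
                    raise ValidationError(
                        f"non-integer count at sample {df.index[r]!r}, OTU {df.columns[c]!r}"
                    )
            if (values < 0).any():
                r, c = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"negative count at sample {df.index[r]!r}, OTU {df.columns[c]!r}"
                )
        df = df.astype(np.int64)
        if drop_empty_otus:
            empty = df.columns[(df.to_numpy() == 0).all(axis=0)]
            if len(empty):
                logger.warning(
                    "dropping %d all-zero OTU column(s): %s",
                    len(empty),
                    ", ".join(map(str, empty[:10])),
                )
                df = df.drop(columns=empty)
        self._df = df

    # -- basic accessors -------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample total reads N_s."""
        return self._df.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self._df.shape[0]

    @property
    def n_otus(self) -> int:
        return self._df.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised frequencies p_i = n_i / N (computed lazily, never stored)."""
        totals = self.library_sizes.replace(0, 1)
        return self._df.div(totals, axis=0)

    def sample_counts(self, sample_id: str) -> AbundanceVector:
        if sample_id not in self._df.index:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return AbundanceVector(self._df.loc[sample_id].to_numpy())

    def select_samples(self, sample_ids) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self._df.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return OtuTable(self._df.loc[list(sample_ids)], drop_empty_otus=False)

    def select_otus(self, otu_ids) -> "OtuTable":
        missing = [o for o in otu_ids if o not in self._df.columns]
        if missing:
            raise KeyError(f"unknown OTU ids: {missing}")
        return OtuTable(self._df[list(otu_ids)], drop_empty_otus=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, OtuTable) and self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"OtuTable({self.n_samples} samples x {self.n_otus} OTUs)"


@dataclass
class SampleRecord:
    """Metadata for one sample: design labels plus chemistry measurements."""

    sample_id: str
    region: str
    habitat: str
    macrofauna: bool | None = None
    temperature: float | None = None
    chemistry: dict = field(default_factory=dict)


class SampleMetadata:
    """Collection of per-sample design labels and chemistry measurements.

    Chemistry columns are auto-detected as any numeric column outside the
    reserved set (sample_id, region, habitat, macrofauna, temperature);
    missing values are allowed and preserved as NaN.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        required = {"sample_id", "region", "habitat"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"metadata is missing required column(s): {sorted(missing)}")
        frame["sample_id"] = frame["sample_id"].astype(str)
        if frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        frame["region"] = frame["region"].astype(str).str.upper()
        bad_region = set(frame["region"]) - set(REGIONS)
        if bad_region:
            raise ValidationError(
                f"unknown region value(s) {sorted(bad_region)}; expected one of {REGIONS}"
            )
        frame["habitat"] = frame["habitat"].astype(str)
        bad_habitat = set(frame["habitat"]) - set(HABITATS)
        if bad_habitat:
            raise ValidationError(
                f"unknown habitat value(s) {sorted(bad_habitat)}; expected one of {HABITATS}"
            )
        if "macrofauna" in frame.columns:
            frame["macrofauna"] = frame["macrofauna"].map(_parse_bool)
        frame = frame.set_index("sample_id", drop=False)
        self._df = frame

    @property
    def data(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def chemistry_variables(self) -> list[str]:
        out = []
        for col in self._df.columns:
            if col in RESERVED_METADATA_COLUMNS:
                continue
            series = pd.to_numeric(self._df[col], errors="coerce")
            if series.notna().any():
                out.append(col)
        return out

    def chemistry(self) -> pd.DataFrame:
        """Numeric chemistry table (samples x variables), NaN for missing."""
        cols = self.chemistry_variables
        return self._df[cols].apply(pd.to_numeric, errors="coerce")

    def record(self, sample_id: str) -> SampleRecord:
        if sample_id not in self._df.index:
            raise KeyError(f"unknown sample id {sample_id!r}")
        row = self._df.loc[sample_id]
        chem = {
            v: (float(row[v]) if pd.notna(pd.to_numeric(row[v], errors="coerce")) else None)
            for v in self.chemistry_variables
        }
        temp = row.get("temperature")
        return SampleRecord(
            sample_id=sample_id,
            region=row["region"],
            habitat=row["habitat"],
            macrofauna=row.get("macrofauna"),
            temperature=float(temp) if pd.notna(temp) else None,
            chemistry=chem,
        )

    def samples_in(self, region: str, habitat: str | None = None) -> list[str]:
        mask = self._df["region"] == region.upper()
        if habitat is not None:
            mask &= self._df["habitat"] == habitat
        return list(self._df.index[mask])

    def off_axis_sample(self, region: str) -> str:
        """The unique background (off-axis) sample for a region.

        Raised at pairing time, not read time: a metadata file without an
        off-axis sample is readable, it just cannot drive a subtraction.
        """
        hits = self.samples_in(region, "off_axis")
        if len(hits) != 1:
            raise ConfigurationError(
                f"region {region!r} must have exactly one off_axis sample, found {len(hits)}"
            )
        return hits[0]

    def require_matching(self, table: OtuTable) -> None:
        missing = set(self._df.index) - set(table.sample_ids)
        if missing:
            raise ValidationError(
                f"metadata sample(s) missing from OTU table: {sorted(missing)}"
            )


def _parse_bool(value):
    if pd.isna(value):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"y", "yes", "true", "1"}:
        return True
    if text in {"n", "no", "false", "0"}:
        return False
    raise ValidationError(f"cannot interpret macrofauna flag {value!r}")


class TaxonomyMap:
    """otu_id -> ranked lineage (domain; phylum; ...; genus) with optional confidences."""

    def __init__(self, lineages: pd.DataFrame, confidences: pd.DataFrame | None = None):
        lineages = lineages.copy()
        lineages.index = lineages.index.astype(str)
        for rank in TAXONOMY_RANKS:
            if rank not in lineages.columns:
                lineages[rank] = "unclassified"
        lineages = lineages[list(TAXONOMY_RANKS)].fillna("unclassified")
        bad = set(lineages["domain"]) - set(DOMAINS) - {"unclassified"}
        if bad:
            raise ValidationError(
                f"domain rank must be Bacteria, Archaea or unclassified; got {sorted(bad)}"
            )
        self._df = lineages
        self._conf = confidences

    @property
    def data(self) -> pd.DataFrame:
        return self._df

    @property
    def otu_ids(self) -> list[str]:
        return list(self._df.index)

    def domain_of(self, otu_id: str) -> str:
        if otu_id not in self._df.index:
            raise KeyError(f"no taxonomy record for OTU {otu_id!r}")
        return self._df.loc[otu_id, "domain"]

    def lineage_of(self, otu_id: str) -> tuple[str, ...]:
        if otu_id not in self._df.index:
            raise KeyError(f"no taxonomy record for OTU {otu_id!r}")
        return tuple(self._df.loc[otu_id, list(TAXONOMY_RANKS)])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

MOTHUR_SHARED_PREFIX = ("label", "Group", "numOtus")


def read_otu_table(path, dialect: str = "plain_wide") -> OtuTable:
    """Read an OTU count table from a TSV file.

    Two dialects are supported: ``plain_wide`` (first column is the
    sample id, remaining columns are OTU counts) and ``mothur_shared``
    (leading label/Group/numOtus columns; Group becomes the sample id).
    """
    if dialect not in ("plain_wide", "mothur_shared"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.columns.size == 0 or df.columns.str.startswith("Unnamed").all():
        raise FormatError(f"{path}: missing header row")
    if dialect == "mothur_shared":
        expected = list(MOTHUR_SHARED_PREFIX)
        if list(df.columns[:3]) != expected:
            raise FormatError(
                f"{path}: mothur shared header must start with {expected}, "
                f"got {list(df.columns[:3])}"
            )
        sample_ids = df["Group"].astype(str)
        body = df.drop(columns=expected)
    else:
        sample_ids = df.iloc[:, 0].astype(str)
        body = df.iloc[:, 1:]
    try:
        numeric = body.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric count value ({exc})") from exc
    numeric.index = sample_ids
    return OtuTable(numeric)


def write_otu_table(table: OtuTable, path, dialect: str = "plain_wide") -> None:
    df = table.data
    if dialect == "plain_wide":
        out = df.copy()
        out.insert(0, "sample_id", df.index)
        out.to_csv(path, sep="\t", index=False)
    elif dialect == "mothur_shared":
        out = df.copy()
        out.insert(0, "label", "0.03")
        out.insert(1, "Group", df.index)
        out.insert(2, "numOtus", table.n_otus)
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_metadata(path) -> SampleMetadata:
    """Read a sample metadata + chemistry TSV (columns sample_id, region, habitat, ...)."""
    df = pd.read_csv(path, sep="\t", header=0)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyMap:
    """Read mothur constaxonomy-style assignments.

    Expected columns: OTU, (optional Size), Taxonomy, where Taxonomy is a
    ';'-separated lineage whose levels may carry '(confidence)' suffixes.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "otu" not in cols or "taxonomy" not in cols:
        raise FormatError(f"{path}: taxonomy file needs OTU and Taxonomy columns")
    lineages = {}
    confidences = {}
    for _, row in df.iterrows():
        otu = str(row[cols["otu"]])
        ranks, confs = _parse_lineage(str(row[cols["taxonomy"]]))
        lineages[otu] = ranks
        confidences[otu] = confs
    lin = pd.DataFrame.from_dict(lineages, orient="index", columns=list(TAXONOMY_RANKS))
    conf = pd.DataFrame.from_dict(confidences, orient="index", columns=list(TAXONOMY_RANKS))
    return TaxonomyMap(lin, conf)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    rows = []
    for otu in tax.otu_ids:
        lineage = ";".join(tax.lineage_of(otu)) + ";"
        rows.append({"OTU": otu, "Taxonomy": lineage})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _parse_lineage(text: str) -> tuple[list[str], list[float]]:
    ranks: list[str] = []
    confs: list[float] = []
    for level in text.strip().rstrip(";").split(";"):
        level = level.strip()
        if not level:
            continue
        if level.endswith(")") and "(" in level:
            name, conf = level.rsplit("(", 1)
            ranks.append(name.strip())
            try:
                confs.append(float(conf.rstrip(")")))
            except ValueError:
                confs.append(np.nan)
        else:
            ranks.append(level)
            confs.append(np.nan)
    ranks = (ranks + ["unclassified"] * len(TAXONOMY_RANKS))[: len(TAXONOMY_RANKS)]
    confs = (confs + [np.nan] * len(TAXONOMY_RANKS))[: len(TAXONOMY_RANKS)]
    return ranks, confs


def read_newick(path) -> skbio.TreeNode:
    """Read a single rooted newick tree whose leaves are OTU ids.

    Missing branch lengths default to 0 with a warning; unlabeled internal
    nodes are allowed.  Leaves are *not* checked against any OTU table
    here — downstream operations report unresolvable leaves.
    """
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise FormatError(f"cannot parse newick file {path}: {exc}") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        warnings.warn(
            f"{n_missing} branch(es) had no length in {path}; defaulting to 0",
            stacklevel=2,
        )
        logger.warning("%d branch(es) without length in %s set to 0", n_missing, path)
    return tree


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def restrict_by_domain(
    table: OtuTable, tax: TaxonomyMap, domain: str, *, unclassified: str = "drop"
) -> OtuTable:
    """Restrict an OTU table to one domain (Bacteria or Archaea).

    OTUs whose domain rank is ``unclassified`` are excluded from both
    domain tables by default; ``unclassified={'bacteria','archaea'}``
    reassigns them to one domain instead.
    """
    if domain not in DOMAINS:
        raise ValueError(f"domain must be one of {DOMAINS}, got {domain!r}")
    if unclassified not in ("drop", "bacteria", "archaea"):
        raise ValueError(f"unclassified must be drop/bacteria/archaea, got {unclassified!r}")
    missing = [o for o in table.otu_ids if o not in tax.data.index]
    if missing:
        raise ValidationError(f"OTU(s) without taxonomy record: {missing[:10]}")
    keep = []
    for otu in table.otu_ids:
        d = tax.domain_of(otu)
        if d == "unclassified" and unclassified != "drop":
            d = unclassified.capitalize()
        if d == domain:
            keep.append(otu)
    if not keep:
        warnings.warn(f"no OTUs assigned to domain {domain}", stacklevel=2)
    return OtuTable(table.data[keep], drop_empty_otus=False)
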