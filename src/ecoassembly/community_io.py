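"""Community tables, sample metadata, rarefaction, filtering and alpha diversity.

The central container is :class:`CommunityTable`, an integer taxa × samples
count matrix with optional phylum-level taxonomy labels. Counts are kept as
integers because the null models downstream operate on individuals
(reads), not on relative abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CommunityTable",
    "SampleTable",
    "read_community",
    "write_community",
    "read_tree",
    "rarefy",
    "prevalence_filter",
    "shannon",
    "chao1",
    "alpha_diversity",
    "env_variation",
]

#: Default rarefaction depth (reads per sample), the depth used for the
#: field dataset this pipeline was designed around.
DEFAULT_RAREFACTION_DEPTH = 20_515

# Greengenes-style rank prefixes
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

# Proteobacterial classes conventionally reported at the phylum level
_PROTEO_CLASSES = {
    "Alphaproteobacteria",
    "Betaproteobacteria",
    "Gammaproteobacteria",
    "Deltaproteobacteria",
    "Epsilonproteobacteria",
    "Zetaproteobacteria",
}


@dataclass
class CommunityTable:
    """Integer count matrix (taxa × samples) with optional taxonomy labels.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, rows indexed by taxon ids, columns by
        sample ids. Ids must be unique.
    taxonomy : pandas.Series, optional
        Phylum (or class, for Proteobacteria) label per taxon, indexed like
        ``counts``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups[:5]}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = counts.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("counts must be finite")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at taxon {counts.index[r]!r}, sample {counts.columns[c]!r}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValueError(
                    "counts must be integers (null models operate on individuals); "
                    f"non-integer value at taxon {counts.index[r]!r}, "
                    f"sample {counts.columns[c]!r}"
                )
            self.counts = counts.astype(np.int64)
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.index)

    # -- convenience accessors -------------------------------------------------

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        sums = self.counts.sum(axis=0)
        if (sums == 0).any():
            empty = sums.index[sums == 0].tolist()
            raise ValueError(f"samples with zero total count: {empty}")
        return self.counts / sums

    def subset_samples(self, sample_ids) -> "CommunityTable":
        missing = set(sample_ids) - set(self.counts.columns)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        return CommunityTable(self.counts[list(sample_ids)].copy(), self.taxonomy)

    def subset_taxa(self, taxon_ids) -> "CommunityTable":
        missing = set(taxon_ids) - set(self.counts.index)
        if missing:
            raise KeyError(f"unknown taxon ids: {sorted(missing)}")
        tax = self.taxonomy.loc[list(taxon_ids)] if self.taxonomy is not None else None
        return CommunityTable(self.counts.loc[list(taxon_ids)].copy(), tax)

    def drop_empty_taxa(self) -> "CommunityTable":
        keep = self.counts.sum(axis=1) > 0
        return self.subset_taxa(self.counts.index[keep])


@dataclass
class SampleTable:
    """Sample metadata: depth layer, treatment, and numeric environment."""

    meta: pd.DataFrame
    layer_col: str = "layer"
    treatment_col: str = "treatment"

    def __post_init__(self) -> None:
        if self.meta.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        if self.layer_col not in self.meta.columns:
            raise ValueError(f"missing layer column {self.layer_col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def layer(self) -> pd.Series:
        return self.meta[self.layer_col]

    @property
    def env(self) -> pd.DataFrame:
        """Numeric environmental variables (everything except categoricals)."""
        drop = [c for c in (self.layer_col, self.treatment_col) if c in self.meta.columns]
        env = self.meta.drop(columns=drop).select_dtypes(include=[np.number])
        if not np.isfinite(env.to_numpy(dtype=float)).all():
            raise ValueError("environmental variables contain non-finite values")
        return env

    def groups(self) -> dict[str, list[str]]:
        """Sample ids keyed by layer, in layer order of first appearance."""
        out: dict[str, list[str]] = {}
        for sid, lay in self.layer.items():
            out.setdefault(lay, []).append(sid)
        return out


# -- taxonomy parsing ----------------------------------------------------------


def parse_taxonomy_label(tax_string: str) -> str:
    """Extract a phylum-level label from a semicolon-delimited lineage.

    Accepts Greengenes-style prefixes (``k__;p__Chloroflexi;...``) or plain
    rank lists. Proteobacterial classes are promoted to the phylum slot,
    matching common phylum/class reporting. Falls back to the raw string
    when no phylum can be identified.
    """
    if not isinstance(tax_string, str) or not tax_string.strip():
        return "unclassified"
    parts = [p.strip() for p in tax_string.split(";")]
    ranks: dict[str, str] = {}
    plain: list[str] = []
    for part in parts:
        matched = False
        for pref in _RANK_PREFIXES:
            if part.lower().startswith(pref):
                val = part[len(pref):].strip().strip("[]")
                if val:
                    ranks[pref[0]] = val
                matched = True
                break
        if not matched and part:
            plain.append(part.strip("[]"))
    phylum = ranks.get("p")
    cls = ranks.get("c")
    if phylum is None and plain:
        # plain lineage: kingdom;phylum;class;...
        phylum = plain[1] if len(plain) > 1 else plain[0]
        cls = plain[2] if len(plain) > 2 else None
    if cls in _PROTEO_CLASSES:
        return cls
    if phylum == "Proteobacteria" and cls:
        return cls
    return phylum if phylum else tax_string.strip()


# -- readers / writers ---------------------------------------------------------


def read_community(path, format: str = "tsv") -> CommunityTable:
    """Read a taxa × samples TSV count table.

    First column holds taxon ids, header row sample ids; a trailing
    ``taxonomy`` column (case-insensitive, or any ``k__;p__;...`` strings)
    is parsed into phylum labels. Lines starting with ``#`` are ignored,
    except a leading ``#OTU ID`` header (BIOM TSV convention).
    """
    if format not in {"tsv", "biom-tsv"}:
        raise ValueError(f"unknown format {format!r}")
    with open(path) as fh:  # pandas mangles duplicate headers, so check first
        for line in fh:
            if line.strip() and not (line.startswith("#") and "\t" not in line):
                header = line.rstrip("\n").split("\t")[1:]
                if len(header) != len(set(header)):
                    raise ValueError(f"duplicate sample ids in header of {path}")
                break
    df = pd.read_csv(
        path, sep="\t", index_col=0, comment=None, dtype=str,
        skiprows=lambda i: False, header=0, skip_blank_lines=True,
    )
    # pandas keeps '#' lines because BIOM TSVs start with '#OTU ID'; drop pure
    # comment rows (index starting with '#') but keep a '#OTU ID' header.
    df = df[~df.index.astype(str).str.startswith("#")]
    taxonomy = None
    tax_cols = [c for c in df.columns if str(c).strip().lower() in {"taxonomy", "taxon"}]
    if tax_cols:
        taxonomy = df[tax_cols[0]].map(parse_taxonomy_label)
        df = df.drop(columns=tax_cols)
    try:
        counts = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric count in {path}: {exc}") from exc
    counts.index.name = None
    counts.columns.name = None
    return CommunityTable(counts, taxonomy)


def write_community(table: CommunityTable, path) -> None:
    out = table.counts.copy()
    if table.taxonomy is not None:
        out["taxonomy"] = table.taxonomy
    out.to_csv(path, sep="\t", index_label="otu_id")


def read_tree(path, strict: bool = False) -> TreeNode:
    """Parse a rooted Newick tree with branch lengths.

    Missing branch lengths are treated as 0 (warning); negative lengths are
    an error. Tip labels must be unique.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise ValueError(f"unparseable Newick in {path}: {exc}") from exc
    return validate_tree(tree, strict=strict)


def validate_tree(tree: TreeNode, strict: bool = False) -> TreeNode:
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValueError(f"negative branch length on node {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        msg = f"{n_missing} branch lengths missing; treated as 0"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate tip labels in tree")
    return tree


# -- rarefaction and filtering -------------------------------------------------


def rarefy(
    table: CommunityTable,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int | np.random.Generator | None = None,
) -> CommunityTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Uses the multivariate hypergeometric distribution, i.e. an exact draw of
    ``depth`` reads from each sample's observed reads. Reproducible under
    ``seed``; taxa left with zero total count are retained (drop with
    :meth:`CommunityTable.drop_empty_taxa` if undesired).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    sums = table.sample_sums()
    shallow = sums.index[sums < depth].tolist()
    if shallow:
        raise ValueError(
            f"samples shallower than depth {depth}: {shallow}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    arr = table.counts.to_numpy()
    for j in range(arr.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(arr[:, j], depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return CommunityTable(counts, table.taxonomy)


def prevalence_filter(
    table: CommunityTable,
    group_samples=None,
    min_fraction: float = 0.75,
) -> CommunityTable:
    """Keep taxa present in strictly more than ``min_fraction`` of the group.

    With the default 0.75 and 12 samples, a taxon must be detected in more
    than 9 samples (i.e. ≥10) to be retained — the "more than three-fourths"
    rule used for network construction.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    if group_samples is None:
        group_samples = table.sample_ids
    group_samples = list(group_samples)
    if not group_samples:
        raise ValueError("empty sample group")
    sub = table.counts[group_samples]
    presence = (sub > 0).sum(axis=1)
    keep = presence > min_fraction * len(group_samples)
    if min_fraction == 0:
        keep = presence > 0
    return CommunityTable(sub.loc[keep].copy(),
                          table.taxonomy.loc[keep.index[keep]] if table.taxonomy is not None else None)


# -- alpha diversity -----------------------------------------------------------


def shannon(counts) -> float:
    """Shannon entropy H = −Σ p_i ln p_i (nats) over nonzero proportions."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate.

    Bias-corrected form (default): S_obs + F1(F1−1)/(2(F2+1)), defined even
    when there are no doubletons. Classic form: S_obs + F1²/(2 F2).
    """
    x = np.asarray(counts, dtype=float)
    if x.sum() <= 0:
        raise ValueError("all-zero count vector")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0  # classic form's F2=0 limit
    return s_obs + f1 * f1 / (2.0 * f2)


def alpha_diversity(table: CommunityTable, bias_corrected: bool = True) -> pd.DataFrame:
    """Shannon (nats) and Chao1 per sample."""
    rows = {
        sid: {
            "shannon": shannon(table.counts[sid]),
            "chao1": chao1(table.counts[sid], bias_corrected=bias_corrected),
        }
        for sid in table.sample_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index")


# -- environmental variation ---------------------------------------------------


def env_variation(samples: SampleTable) -> dict:
    """Per-layer summaries of overall environmental variation.

    Variables are z-scored on the full dataset; per layer the function
    reports the trace of the within-layer variance–covariance matrix of the
    z-scored variables (``dispersion``), each sample's squared distance to
    the layer centroid in z-space (``sq_dist_to_centroid``, suitable for a
    box plot), and the raw-scale coefficient of variation per variable
    (``cv``). Variables constant across the full dataset are excluded with
    a warning.
    """
    env = samples.env
    sd = env.std(axis=0, ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        warnings.warn(f"constant environmental variables excluded: {constant}")
        env = env.drop(columns=constant)
        sd = sd.drop(constant)
    if env.shape[1] == 0:
        raise ValueError("no varying environmental variables")
    z = (env - env.mean(axis=0)) / sd
    out: dict[str, dict] = {}
    for layer, sids in samples.groups().items():
        if len(sids) < 2:
            raise ValueError(f"layer {layer!r} has fewer than 2 samples")
        zl = z.loc[sids]
        cov = np.cov(zl.to_numpy(dtype=float), rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        centroid = zl.mean(axis=0)
        sq = ((zl - centroid) ** 2).sum(axis=1)
        raw = env.loc[sids]
        mean = raw.mean(axis=0)
        cv = raw.std(axis=0, ddof=1) / mean.where(mean != 0, np.nan)
        out[layer] = {
            "dispersion": float(np.trace(cov)),
            "sq_dist_to_centroid": sq,
            "cv": cv,
        }
    return out
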