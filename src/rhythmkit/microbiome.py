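"""Circadian analysis of 16S-style taxon count tables.

A sample×taxon count table (with a semicolon-delimited taxonomy lineage per
taxon and per-sample group / time-of-day metadata) is aggregated to a
taxonomic rank (genus, phylum, …), converted to relative abundances, and fed
through the same per-feature cosinor machinery used for host measurements:
per-taxon, per-group single-cosinor fits, zero-amplitude tests, and
two-group parameter comparisons with Benjamini–Hochberg correction across
taxa.  Community-level differences are tested with PERMANOVA (Anderson's
pseudo-F over a permutation null) on Bray–Curtis dissimilarities.

Proportions are analysed on the raw proportion scale by default (published
microbiome MESORs are proportions); an arcsine-square-root variance
stabilization is available but off by default.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .cosinor import DEFAULT_PERIOD_H, InvalidArgumentError, TestResult
from .pipeline import CohortAnalysis, CohortTable, SchemaError, analyze_cohort

__all__ = [
    "RANKS",
    "TaxaTable",
    "DistanceMatrix",
    "load_taxa",
    "write_taxa",
    "aggregate_rank",
    "relative_abundance",
    "bray_curtis",
    "permanova",
    "taxa_rhythms",
]

logger = logging.getLogger(__name__)

#: Ordered taxonomy ranks expected in a lineage string (semicolon-separated).
RANKS = ["kingdom", "phylum", "class", "order", "family", "genus"]

METADATA_COLUMNS = ["sample_id", "group", "time_h"]


@dataclass
class TaxaTable:
    """Sample×taxon abundance table with taxonomy and sample metadata.

    ``counts`` rows are samples, columns are taxa; nonnegative integers in
    ``"counts"`` mode, rows summing to 1 in ``"proportions"`` mode.
    ``taxonomy`` maps taxon id -> semicolon-separated lineage string
    (kingdom;phylum;class;order;family;genus).  ``metadata`` is indexed by
    sample id with columns ``group`` and ``time_h``.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str]
    metadata: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "proportions"):
            raise InvalidArgumentError(f"unknown mode {self.mode!r}")
        if (self.counts.to_numpy() < 0).any():
            raise InvalidArgumentError("abundances must be nonnegative")
        missing_meta = [s for s in self.counts.index if s not in self.metadata.index]
        if missing_meta:
            raise InvalidArgumentError(
                f"samples missing metadata: {missing_meta}"
            )
        missing_tax = [t for t in self.counts.columns if t not in self.taxonomy]
        if missing_tax:
            raise InvalidArgumentError(f"taxa missing taxonomy: {missing_tax}")
        if self.mode == "proportions":
            totals = self.counts.sum(axis=1).to_numpy()
            if not np.allclose(totals, 1.0, atol=1e-9):
                raise InvalidArgumentError("proportion rows must sum to 1 (±1e-9)")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric pairwise dissimilarity matrix in [0, 1]."""

    matrix: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise InvalidArgumentError("distance matrix shape/id mismatch")
        if not np.allclose(m, m.T):
            raise InvalidArgumentError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise InvalidArgumentError("distance matrix diagonal must be zero")
        if np.nanmin(m) < -1e-12 or np.nanmax(m) > 1.0 + 1e-12:
            raise InvalidArgumentError("dissimilarities must lie in [0, 1]")


def load_taxa(counts_path, taxonomy_path, metadata_path) -> TaxaTable:
    """Load a taxon count table with taxonomy and metadata.

    ``counts_path``: TSV, taxa as rows, first column the taxon id, remaining
    columns one per sample.  ``taxonomy_path``: TSV with columns
    ``taxon_id`` and ``lineage`` (semicolon-separated ranks).
    ``metadata_path``: TSV with ``sample_id``, ``group``, ``time_h``.
    Samples present in counts but absent from metadata are a hard error;
    extra metadata rows and unmatched taxonomy entries are reported and
    ignored.
    """
    counts_raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts = counts_raw.T  # samples × taxa
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    counts = counts.rename_axis(index=None, columns=None)

    tax_df = pd.read_csv(taxonomy_path, sep="\t", dtype=str, keep_default_na=False)
    if not {"taxon_id", "lineage"}.issubset(tax_df.columns):
        raise SchemaError(f"{taxonomy_path}: needs columns taxon_id, lineage")
    taxonomy = dict(zip(tax_df["taxon_id"], tax_df["lineage"]))

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"{metadata_path}: missing columns {missing}")
    meta = meta.set_index("sample_id")

    orphan_samples = [s for s in counts.index if s not in meta.index]
    if orphan_samples:
        raise InvalidArgumentError(
            f"samples in counts without metadata: {orphan_samples}"
        )
    extra_meta = [s for s in meta.index if s not in counts.index]
    if extra_meta:
        logger.info("metadata rows without counts (ignored): %s", extra_meta)
    orphan_taxa = [t for t in counts.columns if t not in taxonomy]
    if orphan_taxa:
        raise InvalidArgumentError(f"taxa in counts without taxonomy: {orphan_taxa}")

    meta = meta.loc[counts.index]
    return TaxaTable(counts=counts, taxonomy=taxonomy, metadata=meta, mode="counts")


def write_taxa(table: TaxaTable, counts_path, taxonomy_path, metadata_path) -> None:
    """Write a TaxaTable back to the three-file TSV layout."""
    table.counts.T.rename_axis("taxon_id").to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"taxon_id": list(table.taxonomy), "lineage": list(table.taxonomy.values())}
    ).to_csv(taxonomy_path, sep="\t", index=False)
    table.metadata.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def _lineage_at_rank(lineage: str, rank_idx: int) -> str:
    """Label of a lineage at a rank; blanks bucket as unclassified_<parent>."""
    parts = [p.strip() for p in lineage.split(";")]
    parts += [""] * (len(RANKS) - len(parts))
    label = parts[rank_idx]
    if label:
        return label
    # walk up to the nearest assigned ancestor
    for j in range(rank_idx - 1, -1, -1):
        if parts[j]:
            return f"unclassified_{parts[j]}"
    return "unclassified_unassigned"


def aggregate_rank(table: TaxaTable, rank: str) -> TaxaTable:
    """Sum abundances over taxa sharing the same label at ``rank``.

    Per-sample totals are conserved exactly (integer arithmetic in counts
    mode).  Taxa with a blank label at the rank are bucketed as
    ``unclassified_<nearest assigned ancestor>``.
    """
    if rank not in RANKS:
        raise InvalidArgumentError(f"unknown rank {rank!r}; expected one of {RANKS}")
    rank_idx = RANKS.index(rank)
    labels = {t: _lineage_at_rank(table.taxonomy[t], rank_idx) for t in table.taxa}
    agg = table.counts.T.groupby(table.counts.columns.map(labels)).sum().T
    # truncated lineage for the aggregated units
    new_tax: dict[str, str] = {}
    for t in table.taxa:
        lab = labels[t]
        if lab not in new_tax:
            parts = [p.strip() for p in table.taxonomy[t].split(";")][: rank_idx + 1]
            parts += [""] * (rank_idx + 1 - len(parts))
            parts[rank_idx] = lab
            new_tax[lab] = ";".join(parts)
    return TaxaTable(
        counts=agg, taxonomy=new_tax, metadata=table.metadata, mode=table.mode
    )


def relative_abundance(table: TaxaTable) -> TaxaTable:
    """Convert counts to per-sample proportions (rows sum to 1)."""
    if table.mode != "counts":
        raise InvalidArgumentError("relative_abundance expects a counts-mode table")
    totals = table.counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise InvalidArgumentError(
            f"samples with zero total count: {list(zero.index)}"
        )
    props = table.counts.div(totals, axis=0)
    return TaxaTable(
        counts=props, taxonomy=table.taxonomy, metadata=table.metadata,
        mode="proportions",
    )


def bray_curtis(table: TaxaTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between samples:
    BC(u, v) = sum|u_i - v_i| / sum(u_i + v_i)."""
    X = table.counts.to_numpy(dtype=float)
    row_sums = X.sum(axis=1)
    if (row_sums == 0).sum() >= 1 and len(X) > 1:
        zero_ids = [s for s, tot in zip(table.samples, row_sums) if tot == 0]
        raise InvalidArgumentError(
            f"Bray–Curtis undefined for all-zero samples: {zero_ids}"
        )
    mat = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(matrix=mat, ids=tuple(table.samples))


def _pseudo_f(sq_dist: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's PERMANOVA pseudo-F from a squared-dissimilarity matrix."""
    n = len(labels)
    groups, inverse = np.unique(labels, return_inverse=True)
    a = len(groups)
    ss_total = sq_dist[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(a):
        idx = np.flatnonzero(inverse == g)
        if len(idx) > 1:
            sub = sq_dist[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> TestResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    Pseudo-F compares among-group to within-group sums of squared
    dissimilarities; the p-value is ``(1 + #{F_perm >= F_obs}) / (1 +
    n_perm)`` under random relabelling, so it is never exactly 0.  The
    permutation stream is fully determined by ``seed``.
    """
    labels = np.asarray(labels)
    if len(labels) != len(dist.ids):
        raise InvalidArgumentError("labels length must match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise InvalidArgumentError("PERMANOVA needs at least 2 groups")
    small = [str(u) for u, c in zip(uniq, counts) if c < 2]
    if small:
        raise InvalidArgumentError(f"groups with fewer than 2 samples: {small}")
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")

    sq = dist.matrix**2
    f_obs = _pseudo_f(sq, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _pseudo_f(sq, rng.permutation(labels)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    n = len(labels)
    return TestResult(
        kind="permanova",
        statistic=float(f_obs),
        df1=len(uniq) - 1,
        df2=n - len(uniq),
        p=float(p),
    )


def permanova_exact(dist: DistanceMatrix, labels) -> tuple[float, float]:
    """Exhaustively enumerate all distinct label assignments (small n only).

    Returns (pseudo-F, exact permutation p) where p is the fraction of all
    ``n!/(n1!…nk!)``-equivalent arrangements — enumerated as permutations of
    the label vector — whose pseudo-F is >= the observed one.  This is the
    ``n_perm -> inf`` limit of :func:`permanova` without the +1 correction.
    """
    labels = np.asarray(labels)
    sq = dist.matrix**2
    f_obs = _pseudo_f(sq, labels)
    total = 0
    hits = 0
    for perm in set(itertools.permutations(labels.tolist())):
        total += 1
        if _pseudo_f(sq, np.asarray(perm)) >= f_obs - 1e-12:
            hits += 1
    return f_obs, hits / total


def taxa_rhythms(
    table: TaxaTable,
    period_h: float = DEFAULT_PERIOD_H,
    alpha: float = 0.01,
    arcsine_sqrt: bool = False,
) -> CohortAnalysis:
    """Per-taxon circadian rhythm analysis on relative abundances.

    Each taxon becomes a feature in a long-format cohort (one row per
    sample), and the standard per-feature pipeline runs: per-group cosinor
    fit, zero-amplitude test, two-group comparisons, BH correction across
    taxa within each test family.  Requires a proportions-mode table;
    ``arcsine_sqrt=True`` applies the arcsin(sqrt(p)) transform first.
    ``alpha`` (default 0.01 on adjusted p) is the flagging threshold used
    by downstream reporting.
    """
    if table.mode != "proportions":
        raise InvalidArgumentError(
            "taxa_rhythms expects proportions; call relative_abundance first"
        )
    values = table.counts
    if arcsine_sqrt:
        values = np.arcsin(np.sqrt(values))
    long = values.stack().rename("value").reset_index()
    long.columns = ["subject_id", "feature", "value"]
    meta = table.metadata.loc[long["subject_id"]]
    long["group"] = meta["group"].to_numpy()
    long["time_h"] = meta["time_h"].to_numpy(dtype=float)
    cohort = CohortTable(data=long[["subject_id", "group", "time_h", "feature", "value"]])
    return analyze_cohort(cohort, period_h=period_h, alpha=alpha)
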