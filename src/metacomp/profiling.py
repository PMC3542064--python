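"""Count matrices, taxonomic composition, assignment rates and CAZy tallies.

These are the descriptive summaries of an annotated metagenome: how many
occurrences each protein family has per sample (the x's and n's of the
enrichment statistic), what fraction of gene models fall in each taxonomic
domain, what fraction of predicted genes received a functional assignment at
all, and how the carbohydrate-active enzyme (CAZy) families split into
glycoside hydrolases (GH), carbohydrate-binding modules (CBM) and glycosyl
transferases (GT).

Denominator conventions
-----------------------
Two different denominators are in play and are easy to confuse:

* :func:`domain_composition` percentages divide by the *assigned pool* — the
  sum of the six domain counts (Archaea, Bacteria, Eukarya, Plasmid, Virus,
  Unassigned).  This is the convention under which published
  domain-composition tables are internally consistent even when their header
  says "% of total CDSs".
* :func:`assignment_rate` divides by the *total CDS count* of the sample,
  which may be larger than the assigned pool.

Both are documented on the functions and checked in the test suite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_up
from .annotations import SampleTable, VALID_DOMAINS

__all__ = [
    "FunctionCountMatrix",
    "DomainCompositionTable",
    "AbundanceProfile",
    "build_count_matrix",
    "domain_composition",
    "assignment_rate",
    "class_abundance",
    "cazy_tally",
]

DOMAIN_ORDER = ["Archaea", "Bacteria", "Eukarya", "Plasmid", "Virus", "Unassigned"]

_CAZY_CLASS_RE = re.compile(r"^(GH|CBM|GT)([1-9][0-9]*)$")


@dataclass
class FunctionCountMatrix:
    """Occurrence counts of protein families (rows) per sample (columns).

    ``sample_totals[j]`` is the total number of annotation occurrences of
    sample *j* in this namespace — the ``n`` of the D-score.  When the matrix
    was built on a family subset with ``subset_mode="global"`` the totals
    still span the whole namespace, so subset analyses share the same n as
    the full analysis.
    """

    counts: pd.DataFrame
    sample_totals: pd.Series
    namespace: str
    subset_mode: str = "global"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        nz = self.counts.sum(axis=1) > 0
        self.counts = self.counts.loc[nz]
        self.sample_totals = self.sample_totals.astype(int)

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def column(self, sample_id: str) -> tuple[np.ndarray, int]:
        """Counts vector and total n for one sample."""
        return self.counts[sample_id].to_numpy(), int(self.sample_totals[sample_id])

    def to_tsv(self, path) -> None:
        out = self.counts.sort_index()
        out.index.name = "family_id"
        out.to_csv(path, sep="\t", lineterminator="\n")


@dataclass
class DomainCompositionTable:
    """Per-sample gene counts and percentages for the six taxonomic domains.

    Percentages use the assigned pool (sum of the six domain counts) as
    denominator, rounded half-away-from-zero to two decimals; the total CDS
    count of the sample is carried separately.
    """

    counts: pd.DataFrame          # domain x sample, gene counts
    percentages: pd.DataFrame     # domain x sample, 2-decimal percents
    assigned_pool: pd.Series      # per sample
    total_cds: pd.Series          # per sample (0 where unknown)

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, dict[str, int]] | pd.DataFrame,
        total_cds: dict[str, int] | None = None,
    ) -> "DomainCompositionTable":
        """Build from explicit domain counts (e.g. a published summary table).

        ``counts`` maps sample -> {domain -> gene count}.
        """
        frame = pd.DataFrame(counts).reindex(DOMAIN_ORDER).fillna(0).astype(int)
        pool = frame.sum(axis=0)
        if (pool == 0).any():
            empty = list(pool.index[pool == 0])
            raise ValueError(f"sample(s) with zero genes: {empty}")
        pct = frame.div(pool, axis=1) * 100.0
        pct = pct.map(round_half_up)
        cds = pd.Series(total_cds or {}, dtype=float).reindex(frame.columns).fillna(0).astype(int)
        return cls(counts=frame, percentages=pct, assigned_pool=pool.astype(int), total_cds=cds)

    def percent(self, domain: str, sample_id: str) -> float:
        return float(self.percentages.loc[domain, sample_id])

    def to_tsv(self, path) -> None:
        out = self.counts.astype(str) + " (" + self.percentages.map(lambda v: f"{v:.2f}") + ")"
        out.index.name = "taxon_domain"
        out.to_csv(path, sep="\t", lineterminator="\n")


@dataclass
class AbundanceProfile:
    """Relative abundance (percent of classified gene models) per taxon and sample.

    ``display_cap`` is the percent value at which a heatmap colour scale
    saturates; it affects rendering only, never the stored values.
    """

    values: pd.DataFrame          # taxon x sample, percent
    level: str = "class"
    display_cap: float = 5.0

    def __post_init__(self) -> None:
        if self.display_cap <= 0:
            raise ValueError("display_cap must be positive")

    def capped(self) -> pd.DataFrame:
        """Values with the display cap applied (for rendering)."""
        return self.values.clip(upper=self.display_cap)

    def to_tsv(self, path) -> None:
        out = self.values.sort_index()
        out.index.name = f"taxon_{self.level}"
        out.to_csv(path, sep="\t", float_format="%.6f", lineterminator="\n")

    def to_long_tsv(self, path) -> None:
        long = (
            self.values.rename_axis(index="taxon", columns="sample_id")
            .stack()
            .rename("percent")
            .reset_index()
            .sort_values(["taxon", "sample_id"], kind="mergesort")
        )
        long.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def build_count_matrix(
    table: SampleTable,
    namespace: str,
    subset: list[str] | None = None,
    subset_mode: str = "global",
) -> FunctionCountMatrix:
    """Tally annotation occurrences per (family, sample) in one namespace.

    Parameters
    ----------
    subset
        Optional family-id whitelist (e.g. the PTS or defense gene sets).
    subset_mode
        ``"global"`` (default): sample totals span the whole namespace, so a
        subset matrix shares its n's with the full analysis.  ``"local"``:
        totals are recomputed over the subset only.
    """
    if subset_mode not in ("global", "local"):
        raise ValueError(f"unknown subset_mode {subset_mode!r}")
    rows = table.subset(namespace)
    if rows.empty:
        raise ValueError(f"no records in namespace {namespace!r}")
    full = (
        rows.groupby(["family_id", "sample_id"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=sorted(rows["sample_id"].unique()), fill_value=0)
    )
    if subset is not None:
        counts = full.loc[full.index.intersection(subset)]
        totals = counts.sum(axis=0) if subset_mode == "local" else full.sum(axis=0)
    else:
        counts = full
        totals = full.sum(axis=0)
    return FunctionCountMatrix(
        counts=counts.astype(int),
        sample_totals=totals.astype(int),
        namespace=namespace,
        subset_mode=subset_mode,
    )


def _genes(table: SampleTable) -> pd.DataFrame:
    """Deduplicate occurrences to one row per (sample, gene)."""
    cols = ["sample_id", "gene_id", "taxon_domain", "taxon_class"]
    genes = table.frame[cols].drop_duplicates(["sample_id", "gene_id"], keep="first")
    conflicts = (
        table.frame[["sample_id", "gene_id", "taxon_domain"]]
        .drop_duplicates()
        .groupby(["sample_id", "gene_id"])
        .size()
    )
    if (conflicts > 1).any():
        bad = conflicts.index[conflicts > 1][0]
        raise ValueError(f"gene {bad[1]!r} in sample {bad[0]!r} has conflicting taxon_domain values")
    return genes


def domain_composition(
    table: SampleTable, total_cds: dict[str, int] | None = None
) -> DomainCompositionTable:
    """Gene counts and percentages per taxonomic domain per sample.

    Occurrences are deduplicated to genes first; each gene must carry a single
    domain.  Percentages divide by the assigned pool (see module docstring).
    """
    genes = _genes(table)
    counts = (
        genes.groupby(["taxon_domain", "sample_id"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(DOMAIN_ORDER, fill_value=0)
    return DomainCompositionTable.from_counts(counts, total_cds=total_cds)


def assignment_rate(table: SampleTable, namespace: str, total_cds: int) -> float:
    """Percent of predicted genes with at least one assignment in a namespace.

    The denominator is the sample's total CDS count, not the assigned pool;
    returns a 2-decimal percent.  Works on single-sample tables (pass a
    per-sample slice for multi-sample data).
    """
    if total_cds <= 0:
        raise ValueError("total_cds must be positive")
    rows = table.subset(namespace)
    n_genes = rows[["sample_id", "gene_id"]].drop_duplicates().shape[0]
    if n_genes > total_cds:
        raise ValueError(
            f"{n_genes} assigned genes exceed total_cds={total_cds}"
        )
    return round_half_up(100.0 * n_genes / total_cds)


def class_abundance(
    table: SampleTable, level: str = "class", display_cap: float = 5.0
) -> AbundanceProfile:
    """Relative abundance of taxa from classified gene models.

    Per sample, the percent of classified gene models assigned to each taxon
    label in the ``taxon_class`` column (whatever rank the annotation pipeline
    put there; ``level`` is recorded as metadata).  Unclassified genes (empty
    label) are excluded from the denominator, so each column sums to 100
    within rounding.
    """
    genes = _genes(table)
    classified = genes[genes["taxon_class"] != ""]
    if classified.empty:
        raise ValueError("no classified records (taxon_class empty everywhere)")
    counts = (
        classified.groupby(["taxon_class", "sample_id"]).size().unstack(fill_value=0)
    )
    pct = counts.div(counts.sum(axis=0), axis=1) * 100.0
    return AbundanceProfile(values=pct, level=level, display_cap=display_cap)


@dataclass
class CazyTally:
    """Per-class (GH/CBM/GT) count matrices and distinct-family counts."""

    matrices: dict[str, FunctionCountMatrix]
    distinct_families: pd.DataFrame  # class x sample, number of distinct families

    def matrix(self, cazy_class: str) -> FunctionCountMatrix:
        return self.matrices[cazy_class]


def cazy_tally(table: SampleTable) -> CazyTally:
    """Split CAZy occurrences into GH / CBM / GT matrices with family richness.

    Distinct-family counts per sample per class mirror the "number of
    different GH families" style of summary and are invariant to occurrence
    multiplicities.
    """
    rows = table.subset("CAZY")
    if rows.empty:
        raise ValueError("no records in namespace 'CAZY'")
    bad = [f for f in rows["family_id"].unique() if not _CAZY_CLASS_RE.match(f)]
    if bad:
        raise ValueError(f"malformed CAZy id(s): {sorted(bad)}")
    full = build_count_matrix(table, "CAZY")
    matrices: dict[str, FunctionCountMatrix] = {}
    distinct = {}
    samples = full.samples
    for cls in ("GH", "CBM", "GT"):
        members = [f for f in full.families
                   if _CAZY_CLASS_RE.match(f).group(1) == cls]
        sub = full.counts.loc[members] if members else full.counts.iloc[0:0]
        matrices[cls] = FunctionCountMatrix(
            counts=sub.copy(),
            sample_totals=full.sample_totals.copy(),
            namespace="CAZY",
            subset_mode="global",
        )
        distinct[cls] = (sub > 0).sum(axis=0) if members else pd.Series(0, index=samples)
    frame = pd.DataFrame(distinct).T.reindex(columns=samples, fill_value=0).astype(int)
    frame.index.name = "cazy_class"
    return CazyTally(matrices=matrices, distinct_families=frame)


# re-export for convenience in error messages / validation
assert set(DOMAIN_ORDER) == VALID_DOMAINS
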