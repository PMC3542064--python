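"""Data model and TSV I/O for annotated metagenomes.

The unit of analysis throughout the package is the *annotation occurrence*:
one functional (COG / KEGG / CAZy) or taxonomic assignment of one predicted
gene in one sample.  A gene with three COG hits contributes three rows; all
downstream frequencies are computed over occurrences, not genes, except where
a function documents otherwise (gene-level deduplication in taxonomic
composition and assignment rates).

Files are plain UTF-8 TSV with a header and no quoting, matching the shape of
IMG/M-style annotation exports without binding to any proprietary dialect.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "VALID_DOMAINS",
    "VALID_NAMESPACES",
    "AnnotationRecord",
    "CategoryMap",
    "SampleTable",
    "FormatError",
    "read_annotations",
    "write_annotations",
    "read_category_map",
]

#: Taxonomic domains recognised in the ``taxon_domain`` column.  Anything
#: else is remapped to ``"Unassigned"`` at load time and counted in the
#: load report.
VALID_DOMAINS = frozenset(
    {"Archaea", "Bacteria", "Eukarya", "Plasmid", "Virus", "Unassigned"}
)

#: Functional annotation namespaces.  The empty string marks a purely
#: taxonomic record (a gene with no functional assignment).
VALID_NAMESPACES = frozenset({"COG", "KO", "KEGG_PATHWAY", "CAZY", ""})

#: Canonical column order of the annotation TSV.
COLUMNS = ["sample_id", "gene_id", "taxon_domain", "taxon_class", "namespace", "family_id"]

MANDATORY_COLUMNS = ["sample_id", "gene_id", "taxon_domain"]

_CAZY_RE = re.compile(r"^(GH|CBM|GT)[1-9][0-9]*$")


class FormatError(ValueError):
    """Raised when an input file violates the documented TSV contract."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotation occurrence of one gene in one sample."""

    sample_id: str
    gene_id: str
    taxon_domain: str
    taxon_class: str = ""
    namespace: str = ""
    family_id: str = ""

    def __post_init__(self) -> None:
        if self.taxon_domain not in VALID_DOMAINS:
            raise ValueError(f"unknown taxon_domain {self.taxon_domain!r}")
        if self.namespace not in VALID_NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r}")
        if self.namespace == "CAZY" and not _CAZY_RE.match(self.family_id):
            raise ValueError(
                f"malformed CAZy family id {self.family_id!r} "
                "(expected GH/CBM/GT + positive integer)"
            )
        if self.namespace and not self.family_id:
            raise ValueError("functional record needs a family_id")


@dataclass
class CategoryMap:
    """Assignment of protein families to functional categories.

    Each family maps to exactly one category (the COG convention of a single
    one-letter functional class per cluster).  ``K`` — the total number of
    categories — is the normalising constant of the D-rank statistic.
    """

    entries: dict[str, str]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("category map is empty")
        used = set(self.entries.values())
        orphan = set(self.labels) - used
        if orphan:
            raise ValueError(f"labelled categories never used: {sorted(orphan)}")

    @property
    def K(self) -> int:
        """Total number of distinct categories."""
        return len(set(self.entries.values()))

    @property
    def categories(self) -> list[str]:
        return sorted(set(self.entries.values()))

    def members(self, category_id: str) -> list[str]:
        return sorted(f for f, c in self.entries.items() if c == category_id)

    def label(self, category_id: str) -> str:
        return self.labels.get(category_id, category_id)

    def __contains__(self, family_id: str) -> bool:
        return family_id in self.entries

    def __getitem__(self, family_id: str) -> str:
        return self.entries[family_id]


class SampleTable:
    """An ordered collection of annotation occurrences across samples.

    Internally a pandas DataFrame with the canonical column set; duplicate
    rows are preserved (they are distinct occurrences, not a set).
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = "") -> None:
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"missing columns: {missing}")
        self.frame = frame[COLUMNS].reset_index(drop=True).astype(str)
        self.provenance = provenance
        self.load_report: dict[str, int] = {}

    @classmethod
    def from_records(
        cls, records: list[AnnotationRecord], provenance: str = ""
    ) -> "SampleTable":
        frame = pd.DataFrame(
            [(r.sample_id, r.gene_id, r.taxon_domain, r.taxon_class, r.namespace, r.family_id)
             for r in records],
            columns=COLUMNS,
        )
        return cls(frame, provenance=provenance)

    @property
    def records(self) -> list[AnnotationRecord]:
        return [AnnotationRecord(*row) for row in self.frame.itertuples(index=False)]

    @property
    def sample_ids(self) -> list[str]:
        # first-appearance order, unique
        return list(dict.fromkeys(self.frame["sample_id"]))

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleTable):
            return NotImplemented
        a = self.frame.sort_values(COLUMNS, kind="mergesort").reset_index(drop=True)
        b = other.frame.sort_values(COLUMNS, kind="mergesort").reset_index(drop=True)
        return a.equals(b)

    def subset(self, namespace: str) -> pd.DataFrame:
        """Rows carrying an assignment in the given namespace."""
        return self.frame[self.frame["namespace"] == namespace]


def read_annotations(path, dialect: str = "tsv") -> SampleTable:
    """Read an annotation TSV into a :class:`SampleTable`.

    Rows whose ``taxon_domain`` is not one of the recognised domains are
    remapped to ``"Unassigned"``; the table's ``load_report`` records how many
    rows were read, kept verbatim and remapped
    (``records_read == records_kept + records_remapped``).
    """
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    if frame.empty:
        raise FormatError(f"{path}: no data rows")
    for col in COLUMNS:
        if col not in frame.columns:
            frame[col] = ""
    unknown = ~frame["taxon_domain"].isin(VALID_DOMAINS)
    n_remapped = int(unknown.sum())
    frame.loc[unknown, "taxon_domain"] = "Unassigned"
    bad_ns = ~frame["namespace"].isin(VALID_NAMESPACES)
    if bad_ns.any():
        offending = sorted(frame.loc[bad_ns, "namespace"].unique())
        raise FormatError(f"{path}: unknown namespace value(s) {offending}")
    cazy = frame["namespace"] == "CAZY"
    bad_cazy = cazy & ~frame["family_id"].str.match(_CAZY_RE)
    if bad_cazy.any():
        offending = sorted(frame.loc[bad_cazy, "family_id"].unique())
        raise FormatError(f"{path}: malformed CAZy id(s) {offending}")
    table = SampleTable(frame, provenance=f"read from {path}")
    table.load_report = {
        "records_read": len(frame),
        "records_kept": len(frame) - n_remapped,
        "records_remapped": n_remapped,
    }
    return table


def write_annotations(table: SampleTable, path) -> None:
    """Write a table as deterministic TSV.

    Rows are sorted by (sample_id, gene_id, namespace, family_id) so two
    writes of equal tables are byte-identical; the record multiset is
    preserved, only presentation order is normalised.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty table")
    out = table.frame.sort_values(
        ["sample_id", "gene_id", "namespace", "family_id"], kind="mergesort"
    )
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_category_map(path) -> CategoryMap:
    """Read a family→category TSV (columns family_id, category_id[, category_label])."""
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    for col in ("family_id", "category_id"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing mandatory column(s) ['{col}']")
    entries: dict[str, str] = {}
    labels: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        fam, cat = row.family_id, row.category_id
        if fam in entries and entries[fam] != cat:
            raise FormatError(
                f"{path}: family {fam!r} listed under two categories "
                f"({entries[fam]!r} and {cat!r})"
            )
        entries[fam] = cat
        if "category_label" in frame.columns and getattr(row, "category_label", ""):
            labels[cat] = row.category_label
    return CategoryMap(entries=entries, labels=labels)
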