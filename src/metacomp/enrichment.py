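"""Two-sample enrichment statistics for annotation count profiles.

The core statistic compares the frequency of a protein family between a
*query* and a *reference* metagenome.  With x1 occurrences of the family out
of n1 total annotation occurrences in the query, and x2 of n2 in the
reference, the per-family **D-score** is the pooled two-proportion
z-statistic

    d = (f1 - f2) / sqrt(p * q * (1/n1 + 1/n2)),

where f1 = x1/n1, f2 = x2/n2, p = (x1 + x2)/(n1 + n2) and q = 1 - p.  Under
the null hypothesis that the family has the same occurrence probability in
both communities, d is asymptotically standard normal, so |d| > 1.96
corresponds to a two-sided P < 0.05.

Family-level scores aggregate to the category-level **D-rank**: the sum of
the D-scores of all families assigned to a functional category, normalised
by the square root of the total number of categories K,

    d_rank(c) = sum_{family in c} d_family / sqrt(K).

Because a category with m_c member families sums m_c approximately-standard-
normal scores, its null standard deviation is sqrt(m_c)/sqrt(K); the default
significance threshold is therefore z_{1-alpha/2} * sqrt(m_c / K).  A seeded
permutation null (re-drawing both samples' family counts from the pooled
multinomial) is available as the assumption-free alternative.

The module is organised around a model/results pair: build a
:class:`FunctionalEnrichment` model from a count matrix and a category map,
call :meth:`~FunctionalEnrichment.fit`, and read the per-family and
per-category tables off the returned :class:`EnrichmentResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import CategoryMap, SampleTable
from .profiling import FunctionCountMatrix, build_count_matrix

__all__ = [
    "EnrichmentConfig",
    "DScoreEntry",
    "DRankEntry",
    "FunctionalEnrichment",
    "EnrichmentResults",
    "ComparisonReport",
    "d_score",
    "d_score_table",
    "d_rank_table",
    "compare_categories",
]

UNCATEGORIZED = "uncategorized"


@dataclass(frozen=True)
class EnrichmentConfig:
    """Knobs of the enrichment analysis.

    alpha
        Two-sided significance level for both family calls and category
        thresholds (default 0.05).
    null_mode
        ``"normal"`` — asymptotic standard-normal reference (default);
        ``"permutation"`` — empirical null from pooled-multinomial re-draws.
    n_permutations
        Number of re-draws in permutation mode.
    seed
        Seed of the permutation RNG; fixed seed means byte-identical reports.
    multiple_testing
        ``"none"`` (raw P values, the convention of most comparative
        metagenome reports) or ``"BH"`` (Benjamini-Hochberg FDR).
    k_mode
        ``"total"`` — D-ranks divide by sqrt(K) with K the total number of
        categories in the map; ``"per_category_families"`` — divide each
        category by the square root of its own member count instead, which
        standardises every category to unit null variance.
    """

    alpha: float = 0.05
    null_mode: str = "normal"
    n_permutations: int = 10_000
    seed: int = 0
    multiple_testing: str = "none"
    k_mode: str = "total"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.null_mode not in ("normal", "permutation"):
            raise ValueError(f"unknown null_mode {self.null_mode!r}")
        if self.multiple_testing not in ("none", "BH"):
            raise ValueError(f"unknown multiple_testing {self.multiple_testing!r}")
        if self.k_mode not in ("total", "per_category_families"):
            raise ValueError(f"unknown k_mode {self.k_mode!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")


@dataclass(frozen=True)
class DScoreEntry:
    """Per-family enrichment statistic with all intermediate quantities."""

    family_id: str
    x1: int
    x2: int
    n1: int
    n2: int
    f1: float
    f2: float
    p: float
    q: float
    d: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class DRankEntry:
    """Per-category aggregate of member-family D-scores."""

    category_id: str
    member_families: tuple[str, ...]
    sum_d: float
    K: int
    d_rank: float
    threshold: float
    enriched: bool
    under_represented: bool


def _d_vector(x1, n1, x2, n2):
    """Vectorised D-score: degenerate pooled p (0 or 1) maps to d = 0."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    f1 = x1 / n1
    f2 = x2 / n2
    p = (x1 + x2) / (n1 + n2)
    q = 1.0 - p
    var = p * q * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(var > 0.0, (f1 - f2) / np.sqrt(var), 0.0)
    return f1, f2, p, q, d


def d_score(x1: int, n1: int, x2: int, n2: int, alpha: float = 0.05) -> DScoreEntry:
    """D-score of one family between a query (x1/n1) and a reference (x2/n2).

    Degenerate pooled probabilities (p = 0 or p = 1, where the denominator
    vanishes but also f1 = f2) return d = 0: the statistic carries no
    information there and 0/0 is avoided.  The two-sided P value is the
    standard-normal tail probability of |d|.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample totals n1 and n2 must be positive")
    if not (0 <= x1 <= n1) or not (0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    f1, f2, p, q, d = _d_vector(x1, n1, x2, n2)
    d = float(d)
    p_value = float(2.0 * stats.norm.sf(abs(d)))
    return DScoreEntry(
        family_id="",
        x1=int(x1), x2=int(x2), n1=int(n1), n2=int(n2),
        f1=float(f1), f2=float(f2), p=float(p), q=float(q),
        d=d, p_value=p_value, significant=p_value < alpha,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


class FunctionalEnrichment:
    """Model of differential family abundance between two metagenomes.

    Built from a :class:`~metacomp.profiling.FunctionCountMatrix` (or a raw
    :class:`~metacomp.annotations.SampleTable` via :meth:`from_table`), a
    query/reference sample pair and optionally a
    :class:`~metacomp.annotations.CategoryMap`.  :meth:`fit` computes the
    per-family D-score table, and — when a category map is present — the
    per-category D-rank table with significance thresholds.
    """

    def __init__(
        self,
        matrix: FunctionCountMatrix,
        query: str,
        reference: str,
        category_map: CategoryMap | None = None,
        config: EnrichmentConfig | None = None,
    ) -> None:
        if query == reference:
            raise ValueError("query and reference must differ")
        for s in (query, reference):
            if s not in matrix.samples:
                raise ValueError(f"sample {s!r} not in matrix (has {matrix.samples})")
        self.matrix = matrix
        self.query = query
        self.reference = reference
        self.category_map = category_map
        self.config = config or EnrichmentConfig()

    @classmethod
    def from_table(
        cls,
        table: SampleTable,
        namespace: str,
        query: str,
        reference: str,
        category_map: CategoryMap | None = None,
        config: EnrichmentConfig | None = None,
    ) -> "FunctionalEnrichment":
        matrix = build_count_matrix(table, namespace)
        return cls(matrix, query=query, reference=reference,
                   category_map=category_map, config=config)

    # ---- fitting ---------------------------------------------------------

    def fit(self) -> "EnrichmentResults":
        cfg = self.config
        x1, n1 = self.matrix.column(self.query)
        x2, n2 = self.matrix.column(self.reference)
        families = np.array(self.matrix.families)
        keep = (x1 + x2) > 0
        families, x1, x2 = families[keep], x1[keep], x2[keep]
        if families.size == 0:
            raise ValueError("no family has a nonzero count in either sample")

        f1, f2, p, q, d = _d_vector(x1, n1, x2, n2)
        p_value = 2.0 * stats.norm.sf(np.abs(d))
        p_adj = _bh_adjust(p_value) if cfg.multiple_testing == "BH" else p_value

        dscores = pd.DataFrame(
            {
                "family_id": families,
                "x1": x1.astype(int), "x2": x2.astype(int),
                "n1": n1, "n2": n2,
                "f1": f1, "f2": f2, "p": p, "q": q,
                "d": d, "p_value": p_value, "p_adjusted": p_adj,
                "significant": p_adj < cfg.alpha,
            }
        )
        # deterministic report order: |d| descending, ties lexicographic
        dscores = dscores.sort_values(
            ["family_id"], kind="mergesort"
        ).sort_values("d", key=lambda s: -s.abs(), kind="mergesort")
        dscores = dscores.reset_index(drop=True)

        dranks = None
        if self.category_map is not None:
            dranks = self._fit_dranks(dscores)
        return EnrichmentResults(model=self, dscores=dscores, dranks=dranks)

    def _fit_dranks(self, dscores: pd.DataFrame) -> pd.DataFrame:
        return _compute_dranks(dscores, self.category_map, self.config)


def _compute_dranks(
    dscores: pd.DataFrame, cmap: CategoryMap, cfg: EnrichmentConfig
) -> pd.DataFrame:
    """Aggregate per-family D-scores into category D-ranks with thresholds.

    ``dscores`` needs columns family_id, x1, x2, n1, n2, d.  The ``d`` column
    is used as given, so pre-computed score tables aggregate exactly.
    """
    cat = dscores["family_id"].map(lambda f: cmap.entries.get(f, UNCATEGORIZED))
    grouped = dscores.assign(category_id=cat).groupby("category_id")
    sum_d = grouped["d"].sum()
    m_c = grouped["d"].size()
    members = grouped["family_id"].apply(lambda s: tuple(sorted(s)))
    K = cmap.K
    if cfg.k_mode == "total":
        denom = pd.Series(np.sqrt(K), index=m_c.index)
    else:
        denom = np.sqrt(m_c.astype(float))
    d_rank = sum_d / denom

    if cfg.null_mode == "normal":
        z = stats.norm.ppf(1.0 - cfg.alpha / 2.0)
        threshold = z * np.sqrt(m_c.astype(float)) / denom
    else:
        threshold = _permutation_thresholds(dscores, cat, denom, cfg)

    out = pd.DataFrame(
        {
            "category_id": sum_d.index,
            "n_families": m_c.values,
            "sum_d": sum_d.values,
            "K": K,
            "d_rank": d_rank.values,
            "threshold": np.asarray(threshold),
            "enriched": d_rank.values > np.asarray(threshold),
            "under_represented": d_rank.values < -np.asarray(threshold),
        }
    )
    out["member_families"] = members.loc[out["category_id"]].values
    out["label"] = out["category_id"].map(cmap.label)
    out.loc[out["category_id"] == UNCATEGORIZED, "label"] = UNCATEGORIZED
    out = out.sort_values(
        ["category_id"], kind="mergesort"
    ).sort_values("d_rank", key=lambda s: -s.abs(), kind="mergesort")
    return out.reset_index(drop=True)


def _permutation_thresholds(
    dscores: pd.DataFrame, cat: pd.Series, denom: pd.Series, cfg: EnrichmentConfig
) -> pd.Series:
    """Per-category (1 - alpha) empirical quantile of |d_rank| under the
    pooled two-sample multinomial null.

    Both samples' family counts are re-drawn from the pooled frequency
    vector, conditioning on the observed totals n1 and n2; for a symmetric
    null this two-sided threshold matches the normal z_{1-alpha/2}
    construction.
    """
    x1 = dscores["x1"].to_numpy()
    x2 = dscores["x2"].to_numpy()
    n1 = int(dscores["n1"].iloc[0])
    n2 = int(dscores["n2"].iloc[0])
    pooled = (x1 + x2).astype(float)
    # occurrences outside the tested families (e.g. a subset matrix) are
    # folded into one extra cell so the re-drawn totals stay honest
    rest = max(n1 + n2 - int(pooled.sum()), 0)
    pvals = np.append(pooled, rest) / (n1 + n2)
    rng = np.random.default_rng(cfg.seed)
    F = len(pooled)
    X1 = rng.multinomial(n1, pvals, size=cfg.n_permutations)[:, :F]
    X2 = rng.multinomial(n2, pvals, size=cfg.n_permutations)[:, :F]
    _, _, _, _, D = _d_vector(X1, n1, X2, n2)
    cats = pd.Categorical(cat)
    onehot = np.zeros((F, len(cats.categories)))
    onehot[np.arange(F), cats.codes] = 1.0
    sums = D @ onehot  # (P, C)
    ranks = np.abs(sums / denom.loc[list(cats.categories)].to_numpy())
    thr = np.quantile(ranks, 1.0 - cfg.alpha, axis=0)
    return pd.Series(thr, index=list(cats.categories))


@dataclass
class ComparisonReport:
    """Full enrichment output for several ordered sample pairs."""

    pairs: list[tuple[str, str]]
    results: dict[tuple[str, str], "EnrichmentResults"]
    wide: pd.DataFrame  # category x pair -> d_rank and significance flag

    def to_tsv(self, path) -> None:
        out = self.wide.sort_index()
        out.index.name = "category_id"
        out.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")


class EnrichmentResults:
    """Fitted enrichment tables plus report formatting.

    Attributes
    ----------
    dscores : pandas.DataFrame
        One row per family with x1, x2, n1, n2, f1, f2, p, q, d, p_value,
        p_adjusted and the significance flag; ordered by |d| descending.
    dranks : pandas.DataFrame or None
        One row per category with n_families, sum_d, K, d_rank, threshold
        and enriched / under_represented flags (None without a category map).
    """

    def __init__(self, model: FunctionalEnrichment, dscores: pd.DataFrame,
                 dranks: pd.DataFrame | None) -> None:
        self.model = model
        self.dscores = dscores
        self.dranks = dranks

    # ---- spec-level accessors -------------------------------------------

    def dscore_entries(self) -> list[DScoreEntry]:
        return [
            DScoreEntry(
                family_id=r.family_id, x1=r.x1, x2=r.x2, n1=r.n1, n2=r.n2,
                f1=r.f1, f2=r.f2, p=r.p, q=r.q, d=r.d,
                p_value=r.p_value, significant=bool(r.significant),
            )
            for r in self.dscores.itertuples(index=False)
        ]

    def drank_entries(self) -> list[DRankEntry]:
        if self.dranks is None:
            raise ValueError("model was fitted without a category map")
        return [
            DRankEntry(
                category_id=r.category_id,
                member_families=tuple(r.member_families),
                sum_d=r.sum_d, K=int(r.K), d_rank=r.d_rank,
                threshold=r.threshold, enriched=bool(r.enriched),
                under_represented=bool(r.under_represented),
            )
            for r in self.dranks.itertuples(index=False)
        ]

    @property
    def n_significant_families(self) -> int:
        return int(self.dscores["significant"].sum())

    def summary(self) -> str:
        m = self.model
        cfg = m.config
        lines = [
            "Functional enrichment (two-proportion D-score)",
            "=" * 54,
            f"query:      {m.query}  (n1 = {int(self.dscores['n1'].iloc[0])})",
            f"reference:  {m.reference}  (n2 = {int(self.dscores['n2'].iloc[0])})",
            f"namespace:  {m.matrix.namespace}   families tested: {len(self.dscores)}",
            f"alpha: {cfg.alpha}   null: {cfg.null_mode}   "
            f"multiple testing: {cfg.multiple_testing}",
            f"significant families: {self.n_significant_families}",
            "",
            "Top families by |d|",
            "-" * 54,
        ]
        head = self.dscores.head(10)
        lines.append(f"{'family':<14}{'x1':>6}{'x2':>6}{'d':>10}{'P':>12}")
        for r in head.itertuples(index=False):
            lines.append(
                f"{r.family_id:<14}{r.x1:>6}{r.x2:>6}{r.d:>10.3f}{r.p_value:>12.3e}"
            )
        if self.dranks is not None:
            lines += ["", "Category D-ranks", "-" * 54,
                      f"{'category':<14}{'m_c':>5}{'d_rank':>10}{'thresh':>9}  call"]
            for r in self.dranks.itertuples(index=False):
                call = ("enriched" if r.enriched
                        else "under-represented" if r.under_represented else "")
                lines.append(
                    f"{r.category_id:<14}{r.n_families:>5}{r.d_rank:>10.3f}"
                    f"{r.threshold:>9.3f}  {call}"
                )
        return "\n".join(lines)

    def dscores_to_tsv(self, path) -> None:
        self.dscores.to_csv(path, sep="\t", index=False,
                            float_format="%.10g", lineterminator="\n")

    def dranks_to_tsv(self, path) -> None:
        if self.dranks is None:
            raise ValueError("model was fitted without a category map")
        out = self.dranks.drop(columns=["member_families"])
        out.to_csv(path, sep="\t", index=False,
                   float_format="%.10g", lineterminator="\n")


# ---- spec-level functional wrappers -------------------------------------


def d_score_table(
    matrix: FunctionCountMatrix,
    query: str,
    reference: str,
    config: EnrichmentConfig | None = None,
) -> list[DScoreEntry]:
    """Per-family D-scores for one ordered sample pair (see the model class)."""
    model = FunctionalEnrichment(matrix, query=query, reference=reference,
                                 config=config)
    return model.fit().dscore_entries()


def d_rank_table(
    entries: list[DScoreEntry],
    cmap: CategoryMap,
    config: EnrichmentConfig | None = None,
) -> list[DRankEntry]:
    """Aggregate a D-score table into category D-ranks.

    Families absent from the map are collected into an ``uncategorized``
    bucket (reported like any category; K counts only mapped categories).
    """
    if not entries:
        raise ValueError("empty D-score table")
    cfg = config or EnrichmentConfig()
    frame = pd.DataFrame(
        {
            "family_id": [e.family_id for e in entries],
            "x1": [e.x1 for e in entries], "x2": [e.x2 for e in entries],
            "n1": [e.n1 for e in entries], "n2": [e.n2 for e in entries],
            "d": [e.d for e in entries],
        }
    )
    dranks = _compute_dranks(frame, cmap, cfg)
    return [
        DRankEntry(
            category_id=r.category_id,
            member_families=tuple(r.member_families),
            sum_d=r.sum_d, K=int(r.K), d_rank=r.d_rank,
            threshold=r.threshold, enriched=bool(r.enriched),
            under_represented=bool(r.under_represented),
        )
        for r in dranks.itertuples(index=False)
    ]


def compare_categories(
    table: SampleTable,
    cmap: CategoryMap,
    pairs: list[tuple[str, str]] | None = None,
    namespace: str = "COG",
    config: EnrichmentConfig | None = None,
    mode: str = "all_pairs",
) -> ComparisonReport:
    """Run the enrichment model over several ordered sample pairs.

    If ``pairs`` is None they are generated from the table's samples:
    ``mode="all_pairs"`` takes every unordered pair once (lexicographic query
    first); ``mode="vs_reference:<sample>"`` compares every other sample
    against the named reference.
    """
    cfg = config or EnrichmentConfig()
    matrix = build_count_matrix(table, namespace)
    samples = matrix.samples
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    if pairs is None:
        if mode == "all_pairs":
            pairs = [(a, b) for i, a in enumerate(samples) for b in samples[i + 1:]]
        elif mode.startswith("vs_reference:"):
            ref = mode.split(":", 1)[1]
            if ref not in samples:
                raise ValueError(f"unknown reference sample {ref!r}")
            pairs = [(s, ref) for s in samples if s != ref]
        else:
            raise ValueError(f"unknown mode {mode!r}")
    for q, r in pairs:
        for s in (q, r):
            if s not in samples:
                raise ValueError(f"unknown sample {s!r} in pairs")
    results: dict[tuple[str, str], EnrichmentResults] = {}
    cols: dict[str, pd.Series] = {}
    for q, r in pairs:
        res = FunctionalEnrichment(
            matrix, query=q, reference=r, category_map=cmap, config=cfg
        ).fit()
        results[(q, r)] = res
        dr = res.dranks.set_index("category_id")
        tag = f"{q}_vs_{r}"
        cols[f"{tag}.d_rank"] = dr["d_rank"]
        cols[f"{tag}.flag"] = np.where(
            dr["enriched"], "enriched",
            np.where(dr["under_represented"], "under_represented", ""),
        )
        cols[f"{tag}.flag"] = pd.Series(cols[f"{tag}.flag"], index=dr.index)
    wide = pd.DataFrame(cols)
    return ComparisonReport(pairs=list(pairs), results=results, wide=wide)
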