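"""Synthetic annotation tables with known ground truth, plus calibration and
power experiments for the enrichment statistic.

The generative model mirrors the structure the analysis assumes: each
sample's family occurrence counts are one multinomial draw of fixed size n_j
(so sample totals are exact, matching the fixed-n conditioning implicit in
the frequency definitions f = x/n), over a shared base frequency vector π.
Differential abundance is injected by multiplying selected entries of π by a
per-sample fold change and renormalising — a simple, invertible ground
truth.  Per-gene taxonomy (domain and class labels) is drawn from
configurable mixtures, independent of function.

Defaults mirror the scale of a two-sample insect-gut study: two samples of
roughly 9,000 and 11,300 functional occurrences out of ~22,000–25,000
predicted genes, ~2,000 families grouped into K = 25 categories, and a
Zipf-like abundance spectrum.  Everything is reproducible from a single
integer seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import CategoryMap, SampleTable
from .enrichment import _d_vector

__all__ = [
    "SampleSpec",
    "SyntheticConfig",
    "ExperimentResult",
    "simulate_table",
    "type1_experiment",
    "power_experiment",
]

COG_LETTERS = list("JAKLBDYVTMNZWUOCGEFHIPQRS")  # 25 one-letter categories

DEFAULT_DOMAIN_PROBS = {
    # proportions of the assigned pool in a grass-feeding insect gut
    "Archaea": 0.0017, "Bacteria": 0.2610, "Eukarya": 0.2132,
    "Plasmid": 0.0024, "Virus": 0.0179, "Unassigned": 0.5038,
}

DEFAULT_CLASS_PROBS = {
    # dominant classes of insect-gut communities; "" = unclassified
    "γ-proteobacteria": 0.25, "Bacilli": 0.10, "Clostridia": 0.04,
    "Erysipelotrichi": 0.035, "Bacteroidia": 0.03, "Spirochaetes": 0.02,
    "": 0.525,
}


@dataclass(frozen=True)
class SampleSpec:
    """Scale of one simulated sample."""

    label: str
    n_occurrences: int
    total_cds: int = 0  # 0 means "equal to n_occurrences"

    def __post_init__(self) -> None:
        if self.n_occurrences <= 0:
            raise ValueError("n_occurrences must be positive")
        cds = self.total_cds or self.n_occurrences
        if cds < self.n_occurrences:
            raise ValueError("total_cds cannot be below n_occurrences")


@dataclass
class SyntheticConfig:
    """Full generative specification of a simulated annotation table.

    effects
        Per-sample log2 fold changes on the base frequencies:
        ``{sample_label: {family_id: log2fc}}``.  The adjusted vector is
        renormalised, so effects are relative enrichments.
    """

    samples: list[SampleSpec]
    family_ids: list[str]
    base_freqs: np.ndarray
    namespace: str = "COG"
    categories: CategoryMap | None = None
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    domain_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DOMAIN_PROBS))
    class_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    seed: int = 0

    def __post_init__(self) -> None:
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if len(self.base_freqs) != len(self.family_ids):
            raise ValueError("base_freqs and family_ids lengths differ")
        if (self.base_freqs < 0).any():
            raise ValueError("negative base frequency")
        total = self.base_freqs.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"base frequencies sum to {total}, not 1")
        self.base_freqs = self.base_freqs / total
        known = set(self.family_ids)
        labels = {s.label for s in self.samples}
        for sample, fam_effects in self.effects.items():
            if sample not in labels:
                raise ValueError(f"effect on unknown sample {sample!r}")
            unknown = set(fam_effects) - known
            if unknown:
                raise ValueError(f"effect on unknown family(ies) {sorted(unknown)}")

    # ---- constructors ----------------------------------------------------

    @classmethod
    def study_like(cls, seed: int = 0) -> "SyntheticConfig":
        """Two-sample configuration at the scale of an insect-gut study.

        2,000 families with a Zipf-like (rank^-0.9) abundance spectrum,
        25 categories assigned round-robin, occurrence totals of 8,954 and
        11,317 against 22,335 and 25,208 predicted genes.
        """
        n_fam = 2000
        family_ids = [f"COG{i:04d}" for i in range(1, n_fam + 1)]
        ranks = np.arange(1, n_fam + 1, dtype=float)
        freqs = ranks ** -0.9
        freqs /= freqs.sum()
        entries = {f: COG_LETTERS[i % len(COG_LETTERS)]
                   for i, f in enumerate(family_ids)}
        cmap = CategoryMap(entries=entries)
        return cls(
            samples=[
                SampleSpec("GH", n_occurrences=8954, total_cds=22335),
                SampleSpec("CW", n_occurrences=11317, total_cds=25208),
            ],
            family_ids=family_ids,
            base_freqs=freqs,
            categories=cmap,
            seed=seed,
        )

    @classmethod
    def null_two_sample(
        cls,
        n_families: int = 200,
        n_occurrences: int = 10_000,
        n_categories: int = 25,
        uniform: bool = True,
        seed: int = 0,
    ) -> "SyntheticConfig":
        """Minimal two-sample null (no effects) for calibration experiments."""
        family_ids = [f"F{i:04d}" for i in range(1, n_families + 1)]
        if uniform:
            freqs = np.full(n_families, 1.0 / n_families)
        else:
            ranks = np.arange(1, n_families + 1, dtype=float)
            freqs = ranks ** -0.9
            freqs /= freqs.sum()
        n_categories = min(n_categories, n_families)
        cats = [f"C{i:02d}" for i in range(1, n_categories + 1)]
        entries = {f: cats[i % n_categories] for i, f in enumerate(family_ids)}
        return cls(
            samples=[
                SampleSpec("Q", n_occurrences=n_occurrences),
                SampleSpec("R", n_occurrences=n_occurrences),
            ],
            family_ids=family_ids,
            base_freqs=freqs,
            categories=CategoryMap(entries=entries),
            seed=seed,
        )

    # ---- derived quantities ---------------------------------------------

    def adjusted_freqs(self, sample_label: str) -> np.ndarray:
        """Base frequencies with the sample's effects applied, renormalised."""
        pi = self.base_freqs.copy()
        fam_effects = self.effects.get(sample_label, {})
        if fam_effects:
            index = {f: i for i, f in enumerate(self.family_ids)}
            for fam, lfc in fam_effects.items():
                pi[index[fam]] *= 2.0 ** lfc
            pi = pi / pi.sum()
        return pi

    def with_effects(self, effects: dict[str, dict[str, float]]) -> "SyntheticConfig":
        return replace(self, effects=effects)


def _draw_counts(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """One multinomial draw per sample; returns families x samples counts."""
    cols = [
        rng.multinomial(s.n_occurrences, config.adjusted_freqs(s.label))
        for s in config.samples
    ]
    return np.stack(cols, axis=1)


def simulate_table(config: SyntheticConfig) -> SampleTable:
    """Draw one full annotation table from the generative model.

    Each functional occurrence becomes one record with its own gene id;
    genes beyond the annotated pool (up to the sample's total CDS count)
    are emitted as purely taxonomic records, so gene-level summaries
    (domain composition, assignment rates) behave like real tables.
    """
    rng = np.random.default_rng(config.seed)
    counts = _draw_counts(config, rng)
    domains = list(config.domain_probs)
    dprobs = np.array([config.domain_probs[d] for d in domains], dtype=float)
    dprobs = dprobs / dprobs.sum()
    classes = list(config.class_probs)
    cprobs = np.array([config.class_probs[c] for c in classes], dtype=float)
    cprobs = cprobs / cprobs.sum()

    frames = []
    fam_arr = np.array(config.family_ids)
    for j, spec in enumerate(config.samples):
        total_cds = spec.total_cds or spec.n_occurrences
        fams = np.repeat(fam_arr, counts[:, j])
        n_func = len(fams)
        gene_ids = np.array([f"{spec.label}_g{i:06d}" for i in range(1, total_cds + 1)])
        gdom = rng.choice(domains, size=total_cds, p=dprobs)
        gcls = rng.choice(classes, size=total_cds, p=cprobs)
        # unclassified domains carry no class label
        gcls = np.where(gdom == "Unassigned", "", gcls)
        func = pd.DataFrame(
            {
                "sample_id": spec.label,
                "gene_id": gene_ids[:n_func],
                "taxon_domain": gdom[:n_func],
                "taxon_class": gcls[:n_func],
                "namespace": config.namespace,
                "family_id": fams,
            }
        )
        frames.append(func)
        if total_cds > n_func:
            taxonly = pd.DataFrame(
                {
                    "sample_id": spec.label,
                    "gene_id": gene_ids[n_func:],
                    "taxon_domain": gdom[n_func:],
                    "taxon_class": gcls[n_func:],
                    "namespace": "",
                    "family_id": "",
                }
            )
            frames.append(taxonly)
    table = SampleTable(
        pd.concat(frames, ignore_index=True),
        provenance=f"simulated (seed={config.seed})",
    )
    return table


@dataclass
class ExperimentResult:
    """Rejection/recovery rates from a Monte-Carlo experiment.

    ``mc_errors`` holds the binomial approximation sqrt(r(1-r)/replicates);
    ``empirical_se`` the standard error of the per-replicate rates, which
    additionally reflects within-replicate correlation.
    """

    rates: dict[str, float]
    mc_errors: dict[str, float]
    empirical_se: dict[str, float]
    replicates: int
    config: SyntheticConfig

    def __post_init__(self) -> None:
        for k, r in self.rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {k}={r} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rate": pd.Series(self.rates),
                "mc_error": pd.Series(self.mc_errors),
                "empirical_se": pd.Series(self.empirical_se),
            }
        ).rename_axis("quantity")


def _binom_se(r: float, n: int) -> float:
    return float(np.sqrt(r * (1.0 - r) / n))


def _category_machinery(config: SyntheticConfig):
    cmap = config.categories
    cats = cmap.categories
    code = {c: i for i, c in enumerate(cats)}
    codes = np.array([code[cmap[f]] for f in config.family_ids])
    m_c = np.bincount(codes, minlength=len(cats)).astype(float)
    K = cmap.K
    return cats, codes, m_c, K


def _replicate_stats(config, rng, z, codes, m_c, K, n_perm=0, alpha=0.05):
    """One replicate: family |d|>z flags and category d_rank/threshold."""
    counts = _draw_counts(config, rng)
    n1 = config.samples[0].n_occurrences
    n2 = config.samples[1].n_occurrences
    x1, x2 = counts[:, 0], counts[:, 1]
    _, _, _, _, d = _d_vector(x1, n1, x2, n2)
    tested = (x1 + x2) > 0
    # >= so the alpha -> 1 limit (z = 0) rejects everything, ties included;
    # at conventional alpha the boundary has probability zero
    fam_reject = np.abs(d) >= z
    sums = np.bincount(codes, weights=d, minlength=len(m_c))
    d_rank = sums / np.sqrt(K)
    if n_perm:
        pooled = (x1 + x2).astype(float)
        pvals = pooled / pooled.sum()
        X1 = rng.multinomial(n1, pvals, size=n_perm)
        X2 = rng.multinomial(n2, pvals, size=n_perm)
        _, _, _, _, D = _d_vector(X1, n1, X2, n2)
        onehot = np.zeros((len(codes), len(m_c)))
        onehot[np.arange(len(codes)), codes] = 1.0
        perm_ranks = np.abs((D @ onehot) / np.sqrt(K))
        threshold = np.quantile(perm_ranks, 1.0 - alpha, axis=0)
    else:
        threshold = z * np.sqrt(m_c / K)
    cat_flag = np.abs(d_rank) > threshold
    return tested, fam_reject, cat_flag, d


def type1_experiment(
    config: SyntheticConfig, replicates: int, alpha: float = 0.05
) -> ExperimentResult:
    """Empirical type-I error of family D-scores and category D-ranks.

    Requires a two-sample configuration with no effects (a true null).
    Reports the fraction of tested families with |d| > z(alpha) and of
    categories beyond the normal D-rank threshold, pooled over replicates.
    """
    if replicates < 10:
        raise ValueError("need at least 10 replicates")
    if config.effects:
        raise ValueError("type-I experiment requires a zero-effect config")
    if len(config.samples) != 2:
        raise ValueError("experiment needs exactly two samples")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    _, codes, m_c, K = _category_machinery(config)
    rng = np.random.default_rng(config.seed)
    fam_rates, cat_rates = [], []
    for _ in range(replicates):
        tested, fam_reject, cat_flag, _ = _replicate_stats(
            config, rng, z, codes, m_c, K, alpha=alpha
        )
        fam_rates.append(fam_reject[tested].mean())
        cat_rates.append(cat_flag.mean())
    fam_rates = np.array(fam_rates)
    cat_rates = np.array(cat_rates)
    rates = {
        "family_rejection_rate": float(fam_rates.mean()),
        "category_rejection_rate": float(cat_rates.mean()),
    }
    return ExperimentResult(
        rates=rates,
        mc_errors={k: _binom_se(v, replicates) for k, v in rates.items()},
        empirical_se={
            "family_rejection_rate": float(fam_rates.std(ddof=1) / np.sqrt(replicates)),
            "category_rejection_rate": float(cat_rates.std(ddof=1) / np.sqrt(replicates)),
        },
        replicates=replicates,
        config=config,
    )


def power_experiment(
    config: SyntheticConfig,
    fold_changes: list[float],
    replicates: int,
    alpha: float = 0.05,
    null_mode: str = "normal",
    n_permutations: int = 1000,
) -> ExperimentResult:
    """Detection power of the statistic across fold changes.

    ``config.effects`` designates which families are enriched in the first
    (query) sample; the listed fold changes override the effect magnitude one
    at a time.  For each fold change the experiment reports power over the
    effect families, the type-I rate over null families, and — for
    categories whose every member carries the effect — the category-level
    recovery rate (fraction of replicates flagged enriched).
    """
    if not fold_changes:
        raise ValueError("fold_changes is empty")
    if replicates < 10:
        raise ValueError("need at least 10 replicates")
    if len(config.samples) != 2:
        raise ValueError("experiment needs exactly two samples")
    query = config.samples[0].label
    effect_fams = sorted(config.effects.get(query, {}))
    if not effect_fams:
        raise ValueError(f"config designates no effect families on query {query!r}")
    fam_index = {f: i for i, f in enumerate(config.family_ids)}
    eff_idx = np.array([fam_index[f] for f in effect_fams])
    null_mask = np.ones(len(config.family_ids), dtype=bool)
    null_mask[eff_idx] = False

    cats, codes, m_c, K = _category_machinery(config)
    cmap = config.categories
    full_effect_cats = [
        i for i, c in enumerate(cats)
        if set(cmap.members(c)) and set(cmap.members(c)) <= set(effect_fams)
    ]
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    n_perm = n_permutations if null_mode == "permutation" else 0

    rates: dict[str, float] = {}
    ses: dict[str, float] = {}
    rng = np.random.default_rng(config.seed)
    for fc in fold_changes:
        lfc = float(np.log2(fc))
        cfg_fc = config.with_effects({query: {f: lfc for f in effect_fams}})
        power_r, type1_r, recov_r = [], [], []
        for _ in range(replicates):
            tested, fam_reject, cat_flag, d = _replicate_stats(
                cfg_fc, rng, z, codes, m_c, K, n_perm=n_perm, alpha=alpha
            )
            power_r.append(fam_reject[eff_idx].mean())
            type1_r.append(fam_reject[null_mask & tested].mean())
            if full_effect_cats:
                # recovery requires the right sign, not just exceedance
                sums = np.bincount(codes, weights=d, minlength=len(m_c))
                d_rank = sums / np.sqrt(K)
                recov_r.append(
                    np.mean(cat_flag[full_effect_cats] & (d_rank[full_effect_cats] > 0))
                )
        for name, vals in (
            (f"power@fc={fc:g}", power_r),
            (f"type1@fc={fc:g}", type1_r),
            (f"category_recovery@fc={fc:g}", recov_r),
        ):
            if vals:
                arr = np.array(vals)
                rates[name] = float(arr.mean())
                ses[name] = float(arr.std(ddof=1) / np.sqrt(replicates))
    return ExperimentResult(
        rates=rates,
        mc_errors={k: _binom_se(v, replicates) for k, v in rates.items()},
        empirical_se=ses,
        replicates=replicates,
        config=config,
    )


assert len(COG_LETTERS) == 25 and len(set(COG_LETTERS)) == 25
assert set(COG_LETTERS) <= set(string.ascii_uppercase)
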