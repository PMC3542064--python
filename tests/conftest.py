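import numpy as np
import pandas as pd
import pytest

from metacomp.annotations import COLUMNS, AnnotationRecord, CategoryMap, SampleTable

DOMAINS = ["Archaea", "Bacteria", "Eukarya", "Plasmid", "Virus", "Unassigned"]
CLASSES = ["Bacilli", "Clostridia", "γ-proteobacteria", "Erysipelotrichi", ""]


def random_table(
    n_rows: int,
    seed: int,
    n_samples: int = 2,
    n_families: int = 30,
    namespace: str = "COG",
) -> SampleTable:
    """A random but valid annotation table for property tests."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(1, n_samples + 1)]
    fams = [f"COG{i:04d}" for i in range(1, n_families + 1)]
    # draw a gene pool with fixed per-gene taxonomy, then sample occurrences
    # from it so repeated genes never carry conflicting labels
    pool = max(n_rows // 2, 1)
    gene_domain = rng.choice(DOMAINS, size=pool)
    gene_class = rng.choice(CLASSES, size=pool)
    idx = rng.integers(0, pool, size=n_rows)
    frame = pd.DataFrame(
        {
            "sample_id": rng.choice(samples, size=n_rows),
            "gene_id": [f"g{i:05d}" for i in idx],
            "taxon_domain": gene_domain[idx],
            "taxon_class": gene_class[idx],
            "namespace": namespace,
            "family_id": rng.choice(fams, size=n_rows),
        }
    )
    return SampleTable(frame[COLUMNS])


@pytest.fixture
def toy_records() -> list[AnnotationRecord]:
    return [
        AnnotationRecord("S1", "g1", "Bacteria", "Bacilli", "COG", "COG0039"),
        AnnotationRecord("S1", "g2", "Bacteria", "Bacilli", "COG", "COG0039"),
        AnnotationRecord("S1", "g3", "Bacteria", "Clostridia", "COG", "COG1131"),
        AnnotationRecord("S2", "g1", "Eukarya", "", "COG", "COG0039"),
        AnnotationRecord("S2", "g2", "Bacteria", "Bacilli", "COG", "COG1131"),
        AnnotationRecord("S2", "g3", "Unassigned", "", "", ""),
    ]


@pytest.fixture
def toy_table(toy_records) -> SampleTable:
    return SampleTable.from_records(toy_records)


@pytest.fixture
def toy_cmap() -> CategoryMap:
    return CategoryMap(
        entries={"COG0039": "C", "COG0538": "C", "COG1131": "V"},
        labels={"C": "Energy production and conversion", "V": "Defense mechanisms"},
    )


@pytest.fixture
def cog_map_path():
    from importlib.resources import files

    return files("metacomp") / "data" / "cog_categories.tsv"
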