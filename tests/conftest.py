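import numpy as np
import pandas as pd
import pytest

from streamcom.containers import (
    CountTable,
    Phylogeny,
    validate_metadata,
    validate_taxonomy,
)


@pytest.fixture
def toy_table() -> CountTable:
    """4 samples x 6 taxa integer table used across preprocessing tests."""
    data = pd.DataFrame(
        [
            [10, 0, 4, 2, 1, 30],
            [8, 1, 0, 5, 2, 25],
            [12, 0, 6, 0, 3, 28],
            [9, 2, 5, 3, 0, 33],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=[f"t{i}" for i in range(1, 7)],
    )
    return CountTable(data)


@pytest.fixture
def toy_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1.5,D:0.5):0.5);")


@pytest.fixture
def toy_metadata() -> pd.DataFrame:
    rows = []
    coords = [(44.90, 15.60), (44.91, 15.61), (44.95, 15.62), (44.99, 15.63)]
    types = ["tributary", "tributary", "interlake", "korana"]
    for i, ((lat, lon), st) in enumerate(zip(coords, types), start=1):
        rows.append(
            {
                "sample_id": f"s{i}",
                "site_id": f"site{i}",
                "stream_type": st,
                "season": "spring",
                "year": 2019,
                "latitude": lat,
                "longitude": lon,
                "temperature": 10.0 + i,
                "O2": 9.0,
                "DOC": 2.0 + 0.1 * i,
            }
        )
    return validate_metadata(pd.DataFrame(rows))


@pytest.fixture
def toy_taxonomy() -> pd.DataFrame:
    rows = []
    for i in range(1, 7):
        rows.append(
            {
                "taxon_id": f"t{i}",
                "domain": "Bacteria",
                "phylum": f"P{i}",
                "class": "",
                "order": "",
                "family": "",
                "genus": "",
            }
        )
    return validate_taxonomy(pd.DataFrame(rows))


def random_count_table(rng: np.random.Generator, n_samples: int, n_taxa: int) -> CountTable:
    counts = rng.integers(0, 50, size=(n_samples, n_taxa))
    # guarantee nonempty samples
    counts[:, 0] += 1
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        )
    )
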