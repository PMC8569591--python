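import numpy as np
import pandas as pd
import pytest

from phosol import quant as qt
from phosol.charge import ProteinRecord
from phosol.simulate import SimulationParams, generate_fixture, write_fixture

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int, pid: str = "P1") -> ProteinRecord:
    return ProteinRecord(pid, "".join(rng.choice(list(AA), size=length)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The default synthetic study: 500 proteins, 16 samples, seed 7."""
    bundle = generate_fixture(SimulationParams(seed=7))
    out = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(out, bundle)
    return bundle, paths


@pytest.fixture(scope="session")
def preprocessed(default_fixture):
    bundle, paths = default_fixture
    qm = qt.read_protein_groups(paths["protein_groups"], bundle.design)
    filtered, report = qt.filter_matrix(qm)
    imputed, _ = qt.impute_missing(qt.log2_transform(filtered), seed=7)
    return bundle, qm, filtered, report, imputed


def toy_protein_groups(tmp_path, design, values, peptides=None, flags=None,
                       ids=None):
    """Write a small proteinGroups-style TSV and return its path.

    ``values``: 2D array-like (proteins x samples), 0 = missing.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ids = ids or [f"P{i + 1}" for i in range(n)]
    peptides = peptides if peptides is not None else [3] * n
    flags = flags or {}
    df = pd.DataFrame({"Protein IDs": ids, "Razor + unique peptides": peptides})
    for key, col in (("reverse", "Reverse"), ("contaminant", "Potential contaminant"),
                     ("site_only", "Only identified by site")):
        df[col] = ["+" if i in flags.get(key, ()) else "" for i in range(n)]
    for j, sid in enumerate(design.sample_ids):
        df[f"LFQ intensity {sid}"] = values[:, j]
    path = tmp_path / "proteinGroups.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path
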