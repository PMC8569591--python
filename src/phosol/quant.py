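"""Label-free quant preprocessing: proteinGroups ingest, filtering, log2,
and shifted-normal imputation of detection-limit missing values.

The intensity table follows the MaxQuant proteinGroups dialect: one row per
protein group, ``LFQ intensity <sample>`` columns, a razor+unique peptide
count, and ``+``-flagged Reverse / Potential contaminant / Only identified by
site columns. Zero intensities are treated as missing (the MaxQuant
convention for undetected proteins).

Filtering removes flagged rows, then rows missing in more than half of the
design samples, then single-peptide identifications. Missing values are
imputed per sample column with draws from a normal distribution centred
``downshift`` column standard deviations below the observed column mean and
scaled to ``width`` of the observed column SD — the standard proteomics
treatment of missing-not-at-random (left-censored) intensities.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .io import PathLike

FRACTIONS = ("soluble", "pellet")
CONDITIONS = ("mock", "cip")

DEFAULT_COLUMN_MAP = {
    "id": "Protein IDs",
    "peptides": "Razor + unique peptides",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "site_only": "Only identified by site",
    "intensity_pattern": "LFQ intensity {sample_id}",
}


class SchemaError(ValueError):
    """Input table does not match the expected proteinGroups layout."""


@dataclass(frozen=True)
class SampleDesign:
    """Sample sheet: one row per MS run with fraction/condition/replicate."""

    table: pd.DataFrame  # columns: sample_id, fraction, condition, replicate

    def __post_init__(self) -> None:
        df = self.table
        required = {"sample_id", "fraction", "condition", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"design missing columns {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design")
        triples = df[["fraction", "condition", "replicate"]]
        if triples.duplicated().any():
            raise ValueError("duplicate (fraction, condition, replicate) triples")
        bad_frac = set(df["fraction"]) - set(FRACTIONS)
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_frac or bad_cond:
            raise ValueError(
                f"unknown fraction/condition labels: {sorted(bad_frac | bad_cond)}"
            )

    @classmethod
    def from_csv(cls, path: PathLike) -> "SampleDesign":
        df = pd.read_csv(path, dtype={"sample_id": str, "fraction": str, "condition": str})
        df["replicate"] = df["replicate"].astype(int)
        return cls(df)

    @classmethod
    def full_factorial(cls, replicates: int = 4) -> "SampleDesign":
        rows = [
            (f"{cond}_{frac}_r{rep}", frac, cond, rep)
            for cond in CONDITIONS
            for frac in FRACTIONS
            for rep in range(1, replicates + 1)
        ]
        return cls(pd.DataFrame(rows, columns=["sample_id", "fraction", "condition", "replicate"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def replicates(self) -> list[int]:
        return sorted(self.table["replicate"].unique())

    def is_full_factorial(self) -> bool:
        expected = len(FRACTIONS) * len(CONDITIONS) * len(self.replicates)
        return len(self.table) == expected and not self.table[
            ["fraction", "condition", "replicate"]
        ].duplicated().any()

    def sample_for(self, fraction: str, condition: str, replicate: int) -> str:
        df = self.table
        m = (
            (df["fraction"] == fraction)
            & (df["condition"] == condition)
            & (df["replicate"] == replicate)
        )
        hit = df.loc[m, "sample_id"]
        if len(hit) != 1:
            raise KeyError(f"no unique sample for ({fraction}, {condition}, {replicate})")
        return str(hit.iloc[0])

    def to_csv(self, path: PathLike) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class QuantMatrix:
    """Protein x sample intensity matrix with flags and peptide counts."""

    data: pd.DataFrame  # index: protein id; columns: sample ids; NaN = missing
    peptide_counts: pd.Series
    flags: pd.DataFrame  # boolean columns: reverse, contaminant, site_only
    design: SampleDesign
    scale: str = "linear"  # or "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if set(self.data.columns) != set(self.design.sample_ids):
            raise ValueError("matrix columns do not match design sample ids")
        if self.scale == "linear":
            vals = self.data.to_numpy()
            if np.nanmin(vals, initial=np.inf) <= 0:
                raise ValueError("linear-scale intensities must be positive")

    @property
    def n_proteins(self) -> int:
        return len(self.data)

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            self.data.copy(), self.peptide_counts.copy(), self.flags.copy(),
            self.design, self.scale,
        )


@dataclass
class FilterReport:
    """Row-removal audit trail, one count per rule."""

    input_rows: int
    removed_flagged: int
    removed_missing: int
    removed_peptides: int
    output_rows: int

    def as_dict(self) -> dict[str, int]:
        return {
            "input_rows": self.input_rows,
            "removed_flagged": self.removed_flagged,
            "removed_missing": self.removed_missing,
            "removed_single_peptide": self.removed_peptides,
            "output_rows": self.output_rows,
        }


def read_protein_groups(
    path: PathLike,
    design: SampleDesign,
    column_map: Optional[dict[str, str]] = None,
) -> QuantMatrix:
    """Read a proteinGroups-style TSV into a linear-scale QuantMatrix.

    Zeros become missing; ``+`` flag columns are parsed into booleans. A
    design sample whose intensity column is absent raises a SchemaError
    naming the sample.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype={cmap["id"]: str})
    if cmap["id"] not in df.columns:
        raise SchemaError(f"id column {cmap['id']!r} not found")
    ids = df[cmap["id"]]
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].tolist()
        raise SchemaError(f"duplicate protein ids: {dups[:5]}")
    intensity_cols = {}
    for sid in design.sample_ids:
        col = cmap["intensity_pattern"].format(sample_id=sid)
        if col not in df.columns:
            raise SchemaError(f"intensity column for sample {sid!r} not found ({col!r})")
        intensity_cols[sid] = col
    if cmap["peptides"] not in df.columns:
        raise SchemaError(f"peptide-count column {cmap['peptides']!r} not found")

    data = df[[intensity_cols[s] for s in design.sample_ids]].astype(float)
    data.columns = design.sample_ids
    data.index = ids
    if (data.to_numpy() < 0).any():
        raise SchemaError("negative intensities are not allowed")
    data = data.replace(0.0, np.nan)

    flags = pd.DataFrame(index=ids)
    for key in ("reverse", "contaminant", "site_only"):
        col = cmap[key]
        if col in df.columns:
            flags[key] = (df[col].fillna("").astype(str).str.strip() == "+").to_numpy()
        else:
            flags[key] = False
    peptides = pd.Series(df[cmap["peptides"]].astype(int).to_numpy(), index=ids,
                         name="peptides")
    return QuantMatrix(data, peptides, flags, design, scale="linear")


def filter_matrix(
    qm: QuantMatrix,
    drop_flagged: bool = True,
    max_missing_fraction: float = 0.5,
    min_peptides: int = 2,
) -> tuple[QuantMatrix, FilterReport]:
    """Apply the row filters in order: flags, missingness, peptide count.

    The missingness denominator is the full design sample count, so with 16
    samples a protein observed in exactly 8 sits on the <=50% boundary and is
    retained.
    """
    n0 = qm.n_proteins
    data, flags, peptides = qm.data, qm.flags, qm.peptide_counts
    if drop_flagged:
        keep = ~flags.any(axis=1)
    else:
        keep = pd.Series(True, index=data.index)
    n_flagged = int((~keep).sum())
    data, flags, peptides = data[keep], flags[keep], peptides[keep]

    missing_frac = data.isna().mean(axis=1)
    keep = missing_frac <= max_missing_fraction
    n_missing = int((~keep).sum())
    data, flags, peptides = data[keep], flags[keep], peptides[keep]

    keep = peptides >= min_peptides
    n_pep = int((~keep).sum())
    data, flags, peptides = data[keep], flags[keep], peptides[keep]

    if len(data) == 0:
        raise ValueError("all proteins removed by filtering")
    out = QuantMatrix(data, peptides, flags, qm.design, qm.scale)
    return out, FilterReport(n0, n_flagged, n_missing, n_pep, len(data))


def log2_transform(qm: QuantMatrix) -> QuantMatrix:
    """Log2 of present intensities; missing cells stay missing."""
    if qm.scale != "linear":
        raise ValueError("log2_transform expects a linear-scale matrix")
    data = np.log2(qm.data)
    return QuantMatrix(data, qm.peptide_counts.copy(), qm.flags.copy(), qm.design, "log2")


def delog2(qm: QuantMatrix) -> QuantMatrix:
    """Back to linear scale (inverse of log2_transform)."""
    if qm.scale != "log2":
        raise ValueError("delog2 expects a log2-scale matrix")
    data = np.power(2.0, qm.data)
    return QuantMatrix(data, qm.peptide_counts.copy(), qm.flags.copy(), qm.design, "linear")


def _column_rng(seed: int, column: str) -> np.random.Generator:
    # stable per-column substream: draws do not depend on column order
    digest = hashlib.sha256(column.encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass
class ImputationReport:
    seed: int
    width: float
    downshift: float
    per_column: pd.DataFrame  # column, n_observed, n_imputed, mean, sd

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "width": self.width,
            "downshift": self.downshift,
            "per_column": self.per_column.to_dict(orient="records"),
        }


def impute_missing(
    qm: QuantMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
) -> tuple[QuantMatrix, ImputationReport]:
    """Impute missing log2 intensities column by column.

    Each missing cell in column c is drawn from
    ``Normal(mean_c - downshift * sd_c, (width * sd_c)**2)`` where mean_c and
    sd_c are the observed mean and SD of that column, computed before any
    imputation. Observed cells are untouched; the same seed gives
    bit-identical output regardless of column order.
    """
    if qm.scale != "log2":
        raise ValueError("impute_missing expects a log2-scale matrix")
    data = qm.data.copy()
    records = []
    # column statistics are frozen up front: no leakage from imputed values
    stats = {}
    for col in data.columns:
        observed = data[col].dropna()
        if len(observed) < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        stats[col] = (float(observed.mean()), float(observed.std(ddof=1)), len(observed))
    for col in data.columns:
        mean, sd, n_obs = stats[col]
        mask = data[col].isna()
        n_miss = int(mask.sum())
        if n_miss:
            rng = _column_rng(seed, str(col))
            draws = rng.normal(loc=mean - downshift * sd, scale=width * sd, size=n_miss)
            data.loc[mask, col] = draws
        records.append((str(col), n_obs, n_miss, mean, sd))
    report = ImputationReport(
        seed, width, downshift,
        pd.DataFrame(records, columns=["column", "n_observed", "n_imputed", "mean", "sd"]),
    )
    out = QuantMatrix(data, qm.peptide_counts.copy(), qm.flags.copy(), qm.design, "log2")
    return out, report


def write_matrix(path: PathLike, qm: QuantMatrix) -> None:
    out = qm.data.copy()
    out.insert(0, "peptides", qm.peptide_counts)
    out.to_csv(path, sep="\t", index_label="protein_id")
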