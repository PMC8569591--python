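"""Synthetic fixtures with ground truth for the full analysis chain.

The generator emulates the downstream structure of a detergent-solubility
fractionation LFQ experiment: 2 fractions x 2 conditions x 4 biological
replicates (16 runs), log-normal protein abundances, multiplicative
measurement noise, and detection-limit (missing-not-at-random) dropout that
grows at low intensity. Three sequence classes are planted:

* ``rs_like`` — arginine/serine-rich sequences (>= 25% R and S each) with
  strongly positive net charge, whose insolubility rises after the
  dephosphorylation ("cip") perturbation (default true log2 FI shift +2);
* ``acidic`` — aspartate/glutamate-rich sequences with strongly negative net
  charge and a mild solubility increase (default shift -0.5);
* ``background`` — typical-composition sequences with no true shift.

Class labels, per-protein baseline fraction insolubility, true shifts and
base abundances are emitted as a truth table, so recovery statistics
(sensitivity, false-positive rate, group-mean ordering, planted-set
enrichment) can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .charge import PHOSPHO_ACCEPTORS, PhosphoSiteSet, ProteinRecord
from .io import PathLike, ensure_dir, write_fasta, write_phosphosites
from .quant import SampleDesign

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

# Background composition: roughly typical proteome residue frequencies.
BACKGROUND_COMPOSITION = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047, "G": 0.074,
    "H": 0.029, "I": 0.068, "K": 0.058, "L": 0.099, "M": 0.025, "N": 0.045,
    "P": 0.039, "Q": 0.034, "R": 0.042, "S": 0.057, "T": 0.051, "V": 0.073,
    "W": 0.013, "Y": 0.039,
}

# RS-like: R and S each >= 25%, depleted acidics -> expected NCPR ~ +0.30.
RS_LIKE_COMPOSITION = {
    "A": 0.030, "C": 0.005, "D": 0.010, "E": 0.010, "F": 0.010, "G": 0.060,
    "H": 0.020, "I": 0.010, "K": 0.050, "L": 0.020, "M": 0.005, "N": 0.020,
    "P": 0.060, "Q": 0.020, "R": 0.270, "S": 0.250, "T": 0.050, "V": 0.020,
    "W": 0.005, "Y": 0.075,
}

# Acidic: D/E-rich, depleted basics -> expected NCPR ~ -0.30.
ACIDIC_COMPOSITION = {
    "A": 0.080, "C": 0.010, "D": 0.170, "E": 0.170, "F": 0.030, "G": 0.080,
    "H": 0.010, "I": 0.040, "K": 0.020, "L": 0.070, "M": 0.020, "N": 0.040,
    "P": 0.050, "Q": 0.040, "R": 0.020, "S": 0.050, "T": 0.040, "V": 0.040,
    "W": 0.010, "Y": 0.010,
}

DEFAULT_COMPOSITIONS = {
    "rs_like": RS_LIKE_COMPOSITION,
    "acidic": ACIDIC_COMPOSITION,
    "background": BACKGROUND_COMPOSITION,
}

DEFAULT_TRUE_DELTA = {"rs_like": 2.0, "acidic": -0.5, "background": 0.0}
DEFAULT_OCCUPANCY = {"rs_like": 0.5, "acidic": 0.1, "background": 0.1}
# Baseline fraction insolubility is drawn log-uniformly between the class
# bounds: a scale quantity whose spread covers orders of magnitude, as in
# real fractionation data where many proteins are nearly fully soluble.
# Mock-condition (phosphorylated) SR-like proteins are mostly soluble
# (densitometry puts their insolubility near 0.3), and the +2 log2 shift
# must keep FI_cip below 1, so the planted class sits in (0.10, 0.22).
DEFAULT_BASELINE_FI = {
    "rs_like": (0.10, 0.22),
    "acidic": (0.20, 0.50),
    "background": (0.03, 0.60),
}


@dataclass
class SimulationParams:
    """Study-condition defaults for the synthetic fixture."""

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"rs_like": 50, "acidic": 50, "background": 400}
    )
    length_range: tuple[int, int] = (150, 450)
    replicates: int = 4
    noise_cv: float = 0.2
    base_abundance_mean: float = 26.0  # log2 LFQ intensity
    base_abundance_sd: float = 1.5
    replicate_sd: float = 0.25  # biological replicate spread, log2
    detection_midpoint: float = 21.5  # log2 intensity of 50% detection
    detection_slope: float = 0.15  # sharp limit: dropout consistent across replicates
    occupancy: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_OCCUPANCY))
    true_delta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_DELTA))
    baseline_fi: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_FI)
    )
    n_decoys: int = 5  # planted Reverse and contaminant rows, each
    seed: int = 0


@dataclass
class FixtureBundle:
    records: list[ProteinRecord]
    sites: dict[str, PhosphoSiteSet]
    truth: pd.DataFrame
    design: SampleDesign
    protein_groups: pd.DataFrame
    params: SimulationParams


def _validate_composition(comp: Mapping[str, float]) -> np.ndarray:
    probs = np.array([comp.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-6):
        raise ValueError("composition must be a probability vector over the 20 residues")
    return probs / probs.sum()


def generate_sequences(
    n_per_class: Mapping[str, int],
    length_range: tuple[int, int],
    compositions: Optional[Mapping[str, Mapping[str, float]]] = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Draw i.i.d.-residue sequences per class; returns records + truth skeleton."""
    compositions = compositions or DEFAULT_COMPOSITIONS
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range {length_range!r}")
    records, rows = [], []
    idx = 0
    for cls in sorted(n_per_class):
        probs = _validate_composition(compositions[cls])
        for _ in range(int(n_per_class[cls])):
            idx += 1
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(AMINO_ACIDS, size=length, p=probs))
            pid = f"SYN{idx:04d}"
            records.append(ProteinRecord(pid, seq))
            rows.append({"id": pid, "class": cls, "length": length})
    truth = pd.DataFrame(rows).set_index("id")
    return records, truth


def assign_phosphosites(
    records: list[ProteinRecord],
    truth: pd.DataFrame,
    occupancy: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> dict[str, PhosphoSiteSet]:
    """Include each S/T/Y independently with its class occupancy."""
    occupancy = occupancy or DEFAULT_OCCUPANCY
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    sites = {}
    for rec in records:
        occ = float(occupancy[truth.loc[rec.id, "class"]])
        if not 0.0 <= occ <= 1.0:
            raise ValueError(f"occupancy must be in [0, 1], got {occ}")
        sty = sorted(rec.sty_positions())
        chosen = [p for p in sty if rng.random() < occ]
        sites[rec.id] = PhosphoSiteSet(rec.id, frozenset(chosen))
    return sites


def _complete_truth(
    truth: pd.DataFrame, params: SimulationParams, rng: np.random.Generator
) -> pd.DataFrame:
    truth = truth.copy()
    fi, delta, abundance = [], [], []
    for pid, row in truth.iterrows():
        cls = row["class"]
        lo, hi = params.baseline_fi[cls]
        base_fi = float(2.0 ** rng.uniform(np.log2(lo), np.log2(hi)))
        d = float(params.true_delta[cls])
        fi_cip = base_fi * 2.0**d
        if not 0.0 < fi_cip < 1.0:
            raise ValueError(
                f"{pid}: true_delta {d} pushes FI_cip = {fi_cip:.3f} outside (0, 1)"
            )
        fi.append(base_fi)
        delta.append(d)
        abundance.append(float(rng.normal(params.base_abundance_mean,
                                          params.base_abundance_sd)))
    truth["baseline_fi"] = fi
    truth["true_delta"] = delta
    truth["base_abundance_log2"] = abundance
    return truth


def simulate_quant(
    truth: pd.DataFrame,
    design: SampleDesign,
    params: SimulationParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a proteinGroups-style table from the completed truth.

    Per protein and replicate the total linear abundance is log-normal around
    the base abundance; it is split into pellet/soluble by the condition's
    true FI, perturbed by multiplicative noise with the given CV, and dropped
    to zero when a Bernoulli detection draw at logistic(log2 intensity)
    fails. Peptide counts scale with abundance; a few planted Reverse and
    contaminant decoy rows carry the corresponding ``+`` flags.
    """
    if not design.is_full_factorial():
        raise ValueError("design must be full-factorial")
    required = {"baseline_fi", "true_delta", "base_abundance_log2"}
    if not required <= set(truth.columns):
        raise ValueError("truth table incomplete; run _complete_truth first")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    sigma = np.sqrt(np.log1p(params.noise_cv**2))  # lognormal sigma for given CV

    sample_ids = design.sample_ids
    rows = []
    for pid, row in truth.iterrows():
        intensities = {}
        for rep in design.replicates:
            total_log2 = rng.normal(row["base_abundance_log2"], params.replicate_sd)
            total = 2.0**total_log2
            for cond in ("mock", "cip"):
                fi = row["baseline_fi"] if cond == "mock" else (
                    row["baseline_fi"] * 2.0 ** row["true_delta"]
                )
                for frac, share in (("pellet", fi), ("soluble", 1.0 - fi)):
                    value = total * share
                    if params.noise_cv > 0:
                        value *= float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
                    sid = design.sample_for(frac, cond, rep)
                    # MNAR dropout: detection probability is logistic in log2 intensity
                    x = np.log2(value)
                    p_detect = 1.0 / (1.0 + np.exp(
                        -(x - params.detection_midpoint) / params.detection_slope
                    ))
                    intensities[sid] = value if rng.random() < p_detect else 0.0
        peptides = max(1, int(rng.poisson(
            max(1.0, (row["base_abundance_log2"] - 20.0) * 2.0)
        )))
        rows.append({"Protein IDs": pid, "Razor + unique peptides": peptides,
                     "Reverse": "", "Potential contaminant": "",
                     "Only identified by site": "",
                     **{f"LFQ intensity {s}": intensities[s] for s in sample_ids}})

    # planted decoy rows, removed by the flag filter downstream
    for i in range(params.n_decoys):
        for flag, prefix in (("Reverse", "REV"), ("Potential contaminant", "CON")):
            vals = {
                f"LFQ intensity {s}": float(2.0 ** rng.normal(24.0, 1.0))
                for s in sample_ids
            }
            rows.append({"Protein IDs": f"{prefix}__{i + 1}",
                         "Razor + unique peptides": int(rng.integers(1, 6)),
                         "Reverse": "+" if flag == "Reverse" else "",
                         "Potential contaminant": "+" if flag == "Potential contaminant" else "",
                         "Only identified by site": "", **vals})
    return pd.DataFrame(rows)


def generate_fixture(params: Optional[SimulationParams] = None,
                     seed: Optional[int] = None) -> FixtureBundle:
    """End-to-end fixture generation under one root seed."""
    params = params or SimulationParams()
    if seed is not None:
        params.seed = int(seed)
    records, truth = generate_sequences(
        params.n_per_class, params.length_range, seed=params.seed
    )
    sites = assign_phosphosites(records, truth, params.occupancy, seed=params.seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 4]))
    truth = _complete_truth(truth, params, rng)
    design = SampleDesign.full_factorial(params.replicates)
    pg = simulate_quant(truth, design, params, seed=params.seed)
    return FixtureBundle(records, sites, truth, design, pg, params)


def _params_to_jsonable(params: SimulationParams) -> dict:
    d = asdict(params)
    d["n_per_class"] = dict(d["n_per_class"])
    d["baseline_fi"] = {k: list(v) for k, v in d["baseline_fi"].items()}
    d["length_range"] = list(d["length_range"])
    return d


def write_fixture(output_dir: PathLike, bundle: FixtureBundle) -> dict[str, str]:
    """Write FASTA, phosphosites, proteinGroups, design, truth and manifest."""
    out = ensure_dir(output_dir)
    paths = {
        "fasta": str(out / "proteins.fasta"),
        "phosphosites": str(out / "phosphosites.tsv"),
        "protein_groups": str(out / "proteinGroups.tsv"),
        "design": str(out / "design.csv"),
        "truth": str(out / "truth.tsv"),
        "manifest": str(out / "manifest.json"),
    }
    by_id = {r.id: r for r in bundle.records}
    write_fasta(paths["fasta"], bundle.records)
    write_phosphosites(paths["phosphosites"], bundle.sites, by_id)
    bundle.protein_groups.to_csv(paths["protein_groups"], sep="\t", index=False)
    bundle.design.to_csv(paths["design"])
    bundle.truth.to_csv(paths["truth"], sep="\t")
    manifest = {"seed": bundle.params.seed, "params": _params_to_jsonable(bundle.params),
                "files": {k: Path(v).name for k, v in paths.items()}}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
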