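"""Configuration-driven end-to-end pipeline.

Stages: simulate (or ingest) -> preprocess (filter, log2, impute) -> charge
summary -> solubility statistics -> enrichment -> network modules -> report.
All randomness flows from one root seed; a fixed config + seed reproduces
the report byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import charge as chg
from . import enrichment as enr
from . import io as pio
from . import network as net
from . import quant as qt
from . import simulate as sim
from . import solubility as sol

log = logging.getLogger("phosol")

_NUMERIC_RANGES = {
    ("preprocessing", "max_missing_fraction"): (0.0, 1.0),
    ("preprocessing", "min_peptides"): (0, 1000),
    ("preprocessing", "width"): (0.0, 10.0),
    ("preprocessing", "downshift"): (0.0, 10.0),
    ("charge", "window"): (1, 10001),
    ("charge", "min_length"): (1, 100000),
    ("solubility", "log2_fc_threshold"): (0.0, 100.0),
    ("solubility", "alpha"): (0.0, 1.0),
    ("solubility", "epsilon"): (0.0, 0.5),
    ("network", "beta"): (1.0, 100.0),
    ("network", "min_size"): (2, 100000),
    ("network", "cut_height"): (0.0, 1.0),
    ("network", "merge_height"): (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    """Validated, defaults-filled pipeline configuration."""

    inputs: dict = field(default_factory=dict)  # fasta/phosphosites/protein_groups/design/candidate_sets
    simulate: Optional[dict] = None  # simulation params; used when inputs absent
    preprocessing: dict = field(
        default_factory=lambda: {
            "max_missing_fraction": 0.5,
            "min_peptides": 2,
            "width": 0.3,
            "downshift": 1.8,
            "impute_before_solubility": True,
        }
    )
    charge: dict = field(
        default_factory=lambda: {"window": 21, "state": "hypo", "min_length": 1}
    )
    solubility: dict = field(
        default_factory=lambda: {"log2_fc_threshold": 1.0, "alpha": 0.05,
                                 "epsilon": 1e-6}
    )
    network: dict = field(
        default_factory=lambda: {"beta": 20.0, "min_size": 15,
                                 "cut_height": 0.995, "merge_height": 0.07}
    )
    seed: int = 0
    output_dir: str = "phosol_out"

    def as_dict(self) -> dict:
        return asdict(self)


_SECTION_DEFAULTS = {
    "preprocessing": PipelineConfig().preprocessing,
    "charge": PipelineConfig().charge,
    "solubility": PipelineConfig().solubility,
    "network": PipelineConfig().network,
}
_TOP_KEYS = {"inputs", "simulate", "preprocessing", "charge", "solubility",
             "network", "seed", "output_dir"}


class ConfigError(ValueError):
    """One or more configuration problems, all reported at once."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


def validate_config(path_or_dict) -> PipelineConfig:
    """Load, default-fill and validate a YAML config (or dict).

    Unknown keys are rejected; all type/range/file-existence violations are
    collected and reported together.
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict or {})
    problems: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown top-level keys: {sorted(unknown)}")

    cfg = PipelineConfig()
    for section, defaults in _SECTION_DEFAULTS.items():
        user = raw.get(section) or {}
        bad = set(user) - set(defaults)
        if bad:
            problems.append(f"unknown keys in {section}: {sorted(bad)}")
        merged = {**defaults, **{k: v for k, v in user.items() if k in defaults}}
        setattr(cfg, section, merged)
    cfg.inputs = raw.get("inputs") or {}
    cfg.simulate = raw.get("simulate")
    cfg.seed = int(raw.get("seed", 0))
    cfg.output_dir = str(raw.get("output_dir", cfg.output_dir))

    for (section, key), (lo, hi) in _NUMERIC_RANGES.items():
        val = getattr(cfg, section).get(key)
        try:
            v = float(val)
        except (TypeError, ValueError):
            problems.append(f"{section}.{key} must be numeric, got {val!r}")
            continue
        if not (lo <= v <= hi):
            problems.append(f"{section}.{key}={val} outside [{lo}, {hi}]")
    if cfg.charge["window"] % 2 == 0:
        problems.append("charge.window must be odd")

    if cfg.inputs:
        for key in ("fasta", "protein_groups", "design"):
            p = cfg.inputs.get(key)
            if not p:
                problems.append(f"inputs.{key} is required when ingesting data")
            elif not Path(p).exists():
                problems.append(f"inputs.{key}: file not found: {p}")
        for key in ("phosphosites", "candidate_sets"):
            p = cfg.inputs.get(key)
            if p and not Path(p).exists():
                problems.append(f"inputs.{key}: file not found: {p}")
    elif cfg.simulate is None:
        problems.append("either an inputs block or a simulate block is required")

    if problems:
        raise ConfigError(problems)
    return cfg


def _simulation_params(cfg: PipelineConfig) -> sim.SimulationParams:
    block = dict(cfg.simulate or {})
    params = sim.SimulationParams(seed=cfg.seed)
    for key, val in block.items():
        if not hasattr(params, key):
            raise ConfigError([f"unknown simulate key {key!r}"])
        if key == "length_range":
            val = tuple(val)
        setattr(params, key, val)
    params.seed = int(block.get("seed", cfg.seed))
    return params


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle; returns the summary."""
    out = pio.ensure_dir(cfg.output_dir)
    summary: dict = {"config": cfg.as_dict(), "stages": {}}
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "input"
    try:
        truth = None
        candidate_sets: dict[str, set[str]] = {}
        if cfg.inputs:
            records = pio.read_fasta(cfg.inputs["fasta"])
            by_id = {r.id: r for r in records}
            sites = (
                pio.read_phosphosites(cfg.inputs["phosphosites"], by_id)
                if cfg.inputs.get("phosphosites") else {}
            )
            design = qt.SampleDesign.from_csv(cfg.inputs["design"])
            qm = qt.read_protein_groups(cfg.inputs["protein_groups"], design)
            if cfg.inputs.get("candidate_sets"):
                candidate_sets = pio.read_candidate_set(cfg.inputs["candidate_sets"])
        else:
            bundle = sim.generate_fixture(_simulation_params(cfg))
            fixture_dir = out / "fixture"
            sim.write_fixture(fixture_dir, bundle)
            records, sites, truth = bundle.records, bundle.sites, bundle.truth
            design = bundle.design
            qm = qt.read_protein_groups(
                fixture_dir / "proteinGroups.tsv", design
            )
            candidate_sets = {
                "rs_like_planted": set(truth.index[truth["class"] == "rs_like"])
            }
        summary["stages"]["input"] = {"n_proteins": qm.n_proteins,
                                      "n_samples": len(design.sample_ids)}
        log.info("input: %d proteins x %d samples", qm.n_proteins,
                 len(design.sample_ids))

        stage = "preprocess"
        pp = cfg.preprocessing
        filtered, freport = qt.filter_matrix(
            qm, max_missing_fraction=pp["max_missing_fraction"],
            min_peptides=pp["min_peptides"],
        )
        logged = qt.log2_transform(filtered)
        imputed, ireport = qt.impute_missing(
            logged, width=pp["width"], downshift=pp["downshift"], seed=cfg.seed
        )
        qt.write_matrix(out / "matrix_imputed.tsv", imputed)
        summary["stages"]["preprocess"] = {
            "filters": freport.as_dict(),
            "imputation": {"seed": cfg.seed, "width": pp["width"],
                           "downshift": pp["downshift"],
                           "n_imputed": int(ireport.per_column["n_imputed"].sum())},
        }
        log.info("preprocess: %s", freport.as_dict())

        stage = "charge"
        cc = cfg.charge
        state = chg.PhosphoState(cc["state"])
        quantified = [r for r in records if r.id in imputed.data.index]
        summary_chg = chg.proteome_charge_summary(
            quantified, min_length=cc["min_length"], state=state, sites=sites
        )
        pio.write_sgraph(out / "sgraph.tsv", summary_chg)
        summary["stages"]["charge"] = {
            "n_proteins": len(summary_chg.table),
            "mean_ncpr": summary_chg.mean_ncpr,
            "sd_ncpr": summary_chg.sd_ncpr,
            "low_threshold": summary_chg.low_threshold,
            "high_threshold": summary_chg.high_threshold,
            "group_counts": summary_chg.counts(),
        }

        stage = "solubility"
        sp = cfg.solubility
        linear = qt.delog2(imputed) if pp["impute_before_solubility"] else filtered
        fi = sol.fraction_insoluble(linear, design)
        deltas = sol.delta_insolubility(fi, epsilon=sp["epsilon"])
        volcano = sol.paired_volcano(
            deltas, log2_fc_threshold=sp["log2_fc_threshold"], alpha=sp["alpha"]
        )
        volcano.table.to_csv(out / "volcano.tsv", sep="\t", index_label="protein_id")
        groups = summary_chg.groups()
        comparison = sol.group_compare(volcano, groups, deltas)
        comparison.to_csv(out / "group_comparison.tsv", sep="\t", index=False)
        gmeans = sol.group_means(volcano, groups)
        class_counts = volcano.table["class"].value_counts().to_dict()
        summary["stages"]["solubility"] = {
            "class_counts": {k: int(v) for k, v in class_counts.items()},
            "group_mean_delta": {k: float(v) for k, v in gmeans.items()},
        }

        stage = "enrichment"
        universe = set(imputed.data.index)
        hits = volcano.hits("more_insoluble")
        enrich_rows = []
        if hits:
            for name, cand in sorted(candidate_sets.items()):
                res = enr.hypergeom_enrichment(universe, hits, cand, label=name)
                enrich_rows.append(res)
            if enrich_rows:
                qs = enr.bh_adjust([r.p for r in enrich_rows])
                for r, q in zip(enrich_rows, qs):
                    r.q = float(q)
        set_table = pd.DataFrame([r.as_dict() for r in enrich_rows])
        set_table.to_csv(out / "set_enrichment.tsv", sep="\t", index=False)
        summary["stages"]["enrichment"] = {
            "n_hits": len(hits),
            "sets": {r.label: {"k": r.overlap_k, "p": r.p, "q": r.q}
                     for r in enrich_rows},
        }

        stage = "network"
        np_ = cfg.network
        adj = net.signed_adjacency(imputed, beta=np_["beta"])
        tom = net.tom_similarity(adj)
        modules = net.detect_modules(tom, min_size=int(np_["min_size"]),
                                     cut_height=np_["cut_height"])
        if modules.module_labels():
            modules = net.merge_close_modules(modules, imputed,
                                              merge_height=np_["merge_height"])
            mod_enr = enr.module_hit_enrichment(
                modules.member_map(), universe, hits
            ) if hits else pd.DataFrame()
            msummary = net.module_summary(modules, volcano.table, summary_chg.table)
        else:
            mod_enr, msummary = pd.DataFrame(), pd.DataFrame()
        assign = pd.DataFrame({"module": modules.labels})
        if not modules.kme.empty:
            own = [
                modules.kme.loc[pid, lab] if lab != 0 else np.nan
                for pid, lab in modules.labels.items()
            ]
            assign["kme_own"] = own
        assign.to_csv(out / "modules.tsv", sep="\t", index_label="protein_id")
        modules.eigenproteins.to_csv(out / "eigenproteins.tsv", sep="\t")
        msummary.to_csv(out / "module_summary.tsv", sep="\t", index=False)
        mod_enr.to_csv(out / "module_enrichment.tsv", sep="\t", index=False)
        summary["stages"]["network"] = {
            "n_modules": len(modules.module_labels()),
            "module_sizes": {f"M{k}": v for k, v in modules.sizes().items()},
            "n_unassigned": int((modules.labels == 0).sum()),
        }

        if truth is not None:
            stage = "truth_scoring"
            summary["stages"]["recovery"] = score_recovery(volcano, truth)
    except Exception as exc:
        failed_marker.write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return summary


def score_recovery(volcano: sol.SolubilityTable, truth: pd.DataFrame) -> dict:
    """Sensitivity / FPR of more_insoluble calls against planted truth,
    plus class-wise mean deltas."""
    common = volcano.table.index.intersection(truth.index)
    called = volcano.table.loc[common, "class"] == "more_insoluble"
    true_pos_set = truth.loc[common, "true_delta"] >= volcano.log2_fc_threshold
    tp = int((called & true_pos_set).sum())
    fn = int((~called & true_pos_set).sum())
    fp = int((called & ~true_pos_set).sum())
    tn = int((~called & ~true_pos_set).sum())
    class_means = (
        volcano.table.loc[common, "mean_delta"]
        .groupby(truth.loc[common, "class"])
        .mean()
        .to_dict()
    )
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "fpr": fp / (fp + tn) if fp + tn else float("nan"),
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "class_mean_delta": {k: float(v) for k, v in class_means.items()},
    }
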