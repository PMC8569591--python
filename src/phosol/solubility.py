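"""Fraction insolubility and the paired dephosphorylation solubility statistic.

For each protein, fraction insolubility FI = pellet / (pellet + soluble)
within a matched (condition, replicate) pair of runs. The per-replicate
statistic is the paired log2 delta

    delta_r = log2 FI[cip, r] - log2 FI[mock, r]

and the per-protein test is a two-tailed one-sample t test of the deltas
against zero (identical to the paired two-sample t on the condition
vectors). A protein is called more insoluble after dephosphorylation when
mean delta >= +1 (twofold) with p < 0.05, more soluble when mean delta <= -1
with p < 0.05, otherwise unchanged. Charge-group comparisons use Welch
unpaired t tests between the low/mid/high NCPR strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import QuantMatrix, SampleDesign

DEFAULT_EPSILON = 1e-6

STAR_TIERS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    for cut, stars in STAR_TIERS:
        if p < cut:
            return stars
    return "ns"


def fraction_insoluble(qm: QuantMatrix, design: Optional[SampleDesign] = None) -> pd.DataFrame:
    """Per-protein fraction insolubility for every (condition, replicate).

    Expects a linear-scale matrix (de-logged after imputation). Pairs with a
    missing pellet or soluble intensity get NaN (undefined, flagged by
    absence). Columns are a MultiIndex (condition, replicate).
    """
    design = design or qm.design
    if qm.scale != "linear":
        raise ValueError("fraction_insoluble expects a linear-scale matrix")
    if not design.is_full_factorial():
        raise ValueError("design must be full-factorial over fractions x conditions x replicates")
    cols = {}
    for cond in ("mock", "cip"):
        for rep in design.replicates:
            s = qm.data[design.sample_for("soluble", cond, rep)]
            p = qm.data[design.sample_for("pellet", cond, rep)]
            cols[(cond, rep)] = p / (p + s)
    fi = pd.DataFrame(cols)
    fi.columns = pd.MultiIndex.from_tuples(fi.columns, names=["condition", "replicate"])
    return fi


def delta_insolubility(
    fi: pd.DataFrame, epsilon: float = DEFAULT_EPSILON
) -> pd.DataFrame:
    """Paired log2 FI deltas (+CIP minus mock) per replicate, plus their mean.

    FI values are clamped to [epsilon, 1 - epsilon] before taking logs so
    that degenerate 0/1 fractions give large finite deltas instead of
    infinities; clamping is reported with a warning.
    """
    conditions = fi.columns.get_level_values("condition")
    if not {"mock", "cip"} <= set(conditions):
        raise ValueError("FI table must contain both mock and cip conditions")
    vals = fi.to_numpy()
    n_clamped = int(((vals < epsilon) | (vals > 1 - epsilon)).sum())
    if n_clamped:
        warnings.warn(f"{n_clamped} FI values clamped to [{epsilon}, {1 - epsilon}]",
                      stacklevel=2)
    clamped = fi.clip(lower=epsilon, upper=1 - epsilon)
    reps = sorted(set(fi.columns.get_level_values("replicate")))
    deltas = pd.DataFrame(
        {
            rep: np.log2(clamped[("cip", rep)]) - np.log2(clamped[("mock", rep)])
            for rep in reps
        }
    )
    deltas.columns.name = "replicate"
    deltas["mean_delta"] = deltas[reps].mean(axis=1)
    return deltas


@dataclass
class SolubilityTable:
    """Per-protein paired-delta test results with volcano classification."""

    table: pd.DataFrame  # id index; mean_delta, t, p, bh_q, class, degenerate
    log2_fc_threshold: float
    alpha: float

    def classes(self) -> pd.Series:
        return self.table["class"]

    def hits(self, direction: str = "more_insoluble") -> set[str]:
        return set(self.table.index[self.table["class"] == direction])


def paired_volcano(
    deltas: pd.DataFrame,
    log2_fc_threshold: float = 1.0,
    alpha: float = 0.05,
    classify_degenerate_by_threshold: bool = False,
) -> SolubilityTable:
    """One-sample two-tailed t test of per-replicate deltas against zero.

    Classification combines the fold-change threshold with raw p < alpha
    (BH-adjusted q values are reported alongside but do not gate the class).
    Zero-variance delta vectors cannot produce a meaningful p value; they are
    flagged degenerate with p = NaN and classified by the threshold rule only
    when explicitly requested.
    """
    rep_cols = [c for c in deltas.columns if c != "mean_delta"]
    if len(rep_cols) < 2:
        raise ValueError("need >= 2 replicates for the paired t test")
    arr = deltas[rep_cols].to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    n = arr.shape[1]
    degenerate = sd == 0.0
    t = np.full(len(arr), np.nan)
    p = np.full(len(arr), np.nan)
    ok = ~degenerate
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)

    q = np.full(len(arr), np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]

    cls = np.full(len(arr), "unchanged", dtype=object)
    sig = ok & (p < alpha)
    cls[sig & (mean >= log2_fc_threshold)] = "more_insoluble"
    cls[sig & (mean <= -log2_fc_threshold)] = "more_soluble"
    if classify_degenerate_by_threshold:
        cls[degenerate & (mean >= log2_fc_threshold)] = "more_insoluble"
        cls[degenerate & (mean <= -log2_fc_threshold)] = "more_soluble"

    table = pd.DataFrame(
        {
            "mean_delta": mean,
            "t": t,
            "p": p,
            "bh_q": q,
            "class": cls,
            "degenerate": degenerate,
        },
        index=deltas.index,
    )
    return SolubilityTable(table, log2_fc_threshold, alpha)


def group_compare(
    solubility: SolubilityTable,
    groups: pd.Series,
    deltas: Optional[pd.DataFrame] = None,
    use_pooled_replicates: bool = False,
) -> pd.DataFrame:
    """Compare mean log2 insolubility deltas between NCPR groups.

    By default each protein contributes its across-replicate mean delta;
    ``use_pooled_replicates`` instead pools every per-replicate delta into
    the group sample. Pairwise Welch (unequal-variance) two-sided t tests
    over all group pairs, with star annotations at the usual tiers. Groups
    with fewer than 2 members are skipped with a warning.
    """
    common = solubility.table.index.intersection(groups.index)
    groups = groups.loc[common]
    if use_pooled_replicates:
        if deltas is None:
            raise ValueError("pooled-replicate comparison needs the delta table")
        rep_cols = [c for c in deltas.columns if c != "mean_delta"]
        samples = {
            g: deltas.loc[groups.index[groups == g], rep_cols].to_numpy().ravel()
            for g in groups.unique()
        }
    else:
        values = solubility.table.loc[common, "mean_delta"]
        samples = {g: values[groups == g].to_numpy() for g in groups.unique()}

    order = [g for g in ("low", "mid", "high") if g in samples]
    order += [g for g in samples if g not in order]
    rows = []
    for a, b in combinations(order, 2):
        xa, xb = samples[a], samples[b]
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(f"group comparison {a} vs {b} skipped (<2 members)",
                          stacklevel=2)
            continue
        if np.array_equal(np.sort(xa), np.sort(xb)):
            t, p = 0.0, 1.0  # identical samples: no evidence of difference
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(xa),
                "n_b": len(xb),
                "mean_a": float(np.mean(xa)),
                "mean_b": float(np.mean(xb)),
                "t": float(t),
                "p": float(p),
                "stars": significance_stars(float(p)),
            }
        )
    return pd.DataFrame(rows)


def group_means(solubility: SolubilityTable, groups: pd.Series) -> pd.Series:
    """Per-group mean of per-protein mean deltas."""
    common = solubility.table.index.intersection(groups.index)
    values = solubility.table.loc[common, "mean_delta"]
    return values.groupby(groups.loc[common]).mean()
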