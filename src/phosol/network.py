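"""Simplified signed weighted-correlation network with topological overlap.

A signed adjacency a_ij = ((1 + cor(x_i, x_j)) / 2)^beta is soft-thresholded
at a high power (default beta = 20) so anticorrelated proteins contribute no
edge weight. Neighborhood sharing is summarized by the topological overlap
matrix (TOM) and proteins are clustered by average linkage on 1 - TOM with a
static cut: a deliberately simple, fully deterministic stand-in for dynamic
hybrid tree cutting. Clusters below the minimum size stay unassigned
(label 0); modules are ranked by decreasing size (M1 largest). Each module is
summarized by its eigenprotein — the first principal component of the
member x sample matrix after per-protein standardization — and every
protein's module membership strength kME is its correlation with each
eigenprotein. Modules whose eigenproteins are nearly collinear
(1 - cor < merge height) are merged iteratively to a fixpoint.

This stage is intentionally a simplified variant of the full WGCNA
blockwiseModules procedure: deep splitting, medoid partitioning and
significance-based reassignment are not reproduced, so module counts on real
data will differ from a WGCNA run with otherwise identical parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .quant import QuantMatrix

DEFAULT_BETA = 20.0
DEFAULT_MIN_SIZE = 15
DEFAULT_CUT_HEIGHT = 0.995
DEFAULT_MERGE_HEIGHT = 0.07


@dataclass
class AdjacencyMatrix:
    values: np.ndarray  # square, symmetric, [0, 1], unit diagonal
    ids: list[str]
    beta: float

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(v, v.T):
            raise ValueError("adjacency must be symmetric")


def signed_adjacency(expr: QuantMatrix, beta: float = DEFAULT_BETA) -> AdjacencyMatrix:
    """Signed soft-thresholded adjacency from Pearson correlations.

    Requires a complete (imputed) log2 matrix with at least 4 samples.
    """
    data = expr.data
    if data.isna().any().any():
        raise ValueError("expression matrix must have no missing values")
    if data.shape[1] < 4:
        raise ValueError("need >= 4 samples for correlation network")
    sds = data.std(axis=1, ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(f"zero-variance protein(s): {list(zero.index[:5])}")
    cor = np.corrcoef(data.to_numpy())
    adj = np.power((1.0 + cor) / 2.0, beta)
    np.fill_diagonal(adj, 1.0)
    adj = np.clip(adj, 0.0, 1.0)
    adj = (adj + adj.T) / 2.0  # exact symmetry against float asymmetry
    return AdjacencyMatrix(adj, list(data.index), beta)


def tom_similarity(adj: AdjacencyMatrix) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu, and TOM_ii = 1.
    """
    a = adj.values
    k = a.sum(axis=0) - 1.0  # diagonal is 1 by construction
    shared = a @ a - 2.0 * a  # removes the u=i and u=j terms (a_ii = a_jj = 1)
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.ids, columns=adj.ids)


@dataclass
class ModuleSet:
    """Module labels (0 = unassigned), eigenproteins, kME and parameters."""

    labels: pd.Series  # protein id -> int label, 0 unassigned
    eigenproteins: pd.DataFrame = field(default_factory=pd.DataFrame)  # module x sample
    kme: pd.DataFrame = field(default_factory=pd.DataFrame)  # protein x module
    params: dict = field(default_factory=dict)

    def members(self, label: int) -> set[str]:
        return set(self.labels.index[self.labels == label])

    def module_labels(self) -> list[int]:
        return sorted(l for l in self.labels.unique() if l != 0)

    def member_map(self) -> dict[int, set[str]]:
        return {l: self.members(l) for l in self.module_labels()}

    def sizes(self) -> dict[int, int]:
        return {l: int((self.labels == l).sum()) for l in self.module_labels()}


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != 0].value_counts()
    # largest first; ties broken by old label for determinism
    order = sorted(sizes.index, key=lambda l: (-sizes[l], l))
    remap = {old: new for new, old in enumerate(order, start=1)}
    remap[0] = 0
    return labels.map(remap)


def detect_modules(
    tom: pd.DataFrame,
    min_size: int = DEFAULT_MIN_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> ModuleSet:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Clusters smaller than ``min_size`` are unassigned (label 0); surviving
    clusters are labelled 1..M by decreasing size. Purely deterministic.
    """
    if not (0.0 < cut_height < 1.0):
        raise ValueError("cut_height must lie in (0, 1)")
    dist = 1.0 - tom.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=tom.index, name="module")
    sizes = labels.value_counts()
    small = sizes[sizes < min_size].index
    labels[labels.isin(small)] = 0
    if (labels == 0).all():
        warnings.warn("no cluster reached min_size; all proteins unassigned",
                      stacklevel=2)
    labels = _relabel_by_size(labels)
    return ModuleSet(labels, params={"min_size": min_size, "cut_height": cut_height})


def _standardize(rows: pd.DataFrame) -> np.ndarray:
    x = rows.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("degenerate (zero-variance) member profile")
    return (x - mu) / sd


def eigenproteins(expr: QuantMatrix, modules: ModuleSet) -> ModuleSet:
    """First-principal-component eigenprotein of each module, plus kME.

    Each eigenprotein is unit-norm over samples and sign-oriented so that
    the mean correlation of the module's own members with it is positive
    (ties resolved toward a positive first-sample loading). kME is the
    Pearson correlation of every network protein with every eigenprotein.
    """
    data = expr.data
    eig = {}
    for label in modules.module_labels():
        members = sorted(modules.members(label))
        if len(members) < 2:
            raise ValueError(f"module {label} has fewer than 2 members")
        X = _standardize(data.loc[members])
        if not np.any(X):
            raise ValueError(f"module {label} is rank-0")
        # first right singular vector of the member x sample matrix
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        e = vt[0]
        member_cor = np.array([np.corrcoef(x, e)[0, 1] for x in X])
        mean_cor = member_cor.mean()
        if mean_cor < 0 or (mean_cor == 0 and e[0] < 0):
            e = -e
        eig[label] = e
    eig_df = pd.DataFrame(eig, index=data.columns).T
    eig_df.index.name = "module"

    expr_z = _standardize(data)
    kme = pd.DataFrame(index=data.index, columns=eig_df.index, dtype=float)
    for label in eig_df.index:
        e = eig_df.loc[label].to_numpy()
        ez = (e - e.mean()) / e.std(ddof=1)
        kme[label] = expr_z @ ez / (len(e) - 1)
    return ModuleSet(modules.labels.copy(), eig_df, kme, dict(modules.params))


def variance_explained(expr: QuantMatrix, modules: ModuleSet, label: int) -> float:
    """Fraction of standardized member variance carried by the eigenprotein."""
    members = sorted(modules.members(label))
    X = _standardize(expr.data.loc[members])
    e = modules.eigenproteins.loc[label].to_numpy()
    proj = X @ e
    return float((proj**2).sum() / (X**2).sum())


def merge_close_modules(
    modules: ModuleSet,
    expr: QuantMatrix,
    merge_height: float = DEFAULT_MERGE_HEIGHT,
) -> ModuleSet:
    """Merge modules whose eigenproteins are closer than the merge height.

    Repeatedly merges the closest pair with 1 - cor(E_a, E_b) < merge_height,
    recomputing eigenproteins after each merge, until no pair qualifies;
    then relabels by size.
    """
    labels = modules.labels.copy()
    current = eigenproteins(expr, ModuleSet(labels, params=dict(modules.params)))
    while True:
        mods = current.module_labels()
        if len(mods) < 2:
            break
        E = current.eigenproteins
        best: Optional[tuple[float, int, int]] = None
        for i, a in enumerate(mods):
            for b in mods[i + 1 :]:
                diss = 1.0 - float(np.corrcoef(E.loc[a], E.loc[b])[0, 1])
                if diss < merge_height and (best is None or diss < best[0]):
                    best = (diss, a, b)
        if best is None:
            break
        _, a, b = best
        labels[labels == b] = a
        current = eigenproteins(expr, ModuleSet(labels, params=dict(current.params)))
        labels = current.labels

    labels = _relabel_by_size(labels)
    merged = eigenproteins(expr, ModuleSet(labels, params=dict(current.params)))
    merged.params["merge_height"] = merge_height
    return merged


def module_summary(
    modules: ModuleSet,
    solubility_table: pd.DataFrame,
    charge_table: pd.DataFrame,
    n_hubs: int = 10,
) -> pd.DataFrame:
    """Per-module insolubility heat, mean member NCPR and hub proteins.

    ``solubility_table`` must carry ``mean_delta`` indexed by protein id;
    ``charge_table`` must carry id/ncpr columns. Hubs are the module members
    with the highest own-module kME (ties broken by id). Proteins missing
    from either table are skipped; the skipped count is reported per module.
    """
    ncpr_by_id = charge_table.set_index("id")["ncpr"] if "id" in charge_table else charge_table["ncpr"]
    rows = []
    for label in modules.module_labels():
        members = sorted(modules.members(label))
        deltas = solubility_table["mean_delta"].reindex(members)
        ncprs = ncpr_by_id.reindex(members)
        skipped = int(deltas.isna().sum() + ncprs.isna().sum())
        kme_own = modules.kme.loc[members, label]
        hubs = kme_own.sort_values(ascending=False, kind="mergesort")
        hubs = sorted(hubs.index[:n_hubs], key=lambda i: (-hubs[i], i))
        rows.append(
            {
                "module": f"M{label}",
                "size": len(members),
                "mean_delta": float(deltas.mean()),
                "mean_ncpr": float(ncprs.mean()),
                "hubs": ";".join(hubs),
                "skipped_members": skipped,
            }
        )
    return pd.DataFrame(rows)


def eigenprotein_long_table(modules: ModuleSet, design) -> pd.DataFrame:
    """Eigenprotein values joined with sample fraction/condition labels
    (the box-plot data behind per-module solubility profiles)."""
    df = modules.eigenproteins.reset_index().melt(
        id_vars="module", var_name="sample_id", value_name="eigenprotein"
    )
    return df.merge(design.table, on="sample_id", how="left")


def edge_list(tom: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Thresholded TOM edge list for graph export (id1, id2, tom)."""
    ids = list(tom.index)
    vals = tom.to_numpy()
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if vals[i, j] >= threshold:
                rows.append((ids[i], ids[j], float(vals[i, j])))
    return pd.DataFrame(rows, columns=["id1", "id2", "tom"])
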