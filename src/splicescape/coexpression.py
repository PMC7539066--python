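"""Simplified signed weighted coexpression network analysis.

The pipeline mirrors the standard weighted-network recipe: a soft power
is picked by the scale-free-topology fit criterion, a signed adjacency

    a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta

is raised to that power, the topological overlap measure

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

(with k_i the connectivity excluding the diagonal) converts shared
neighborhoods into a similarity, modules are cut from an average-linkage
tree on 1 - TOM, and the top fraction of genes by within-module weighted
degree are reported as hubs. The dynamic tree cut of the reference R
implementation is replaced by a static height cut (auto-calibrated to
the largest gap between merge heights) followed by a minimum-size
filter; small clusters fall into the unassigned label 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import linregress

__all__ = [
    "CoexpressionResult",
    "pick_soft_threshold",
    "signed_adjacency",
    "tom_similarity",
    "detect_modules",
    "hub_genes",
    "coexpression_analysis",
]


def _row_correlation(x: np.ndarray) -> np.ndarray:
    c = np.corrcoef(x)
    return np.clip(c, -1.0, 1.0)


def signed_adjacency(values: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Signed soft-thresholded adjacency a_ij = ((1 + cor) / 2) ** beta.

    Zero-variance rows have undefined correlations and are dropped with a
    warning. The diagonal is 1 by convention.
    """
    x = values.values.astype(float)
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(values.index[~keep])
        warnings.warn(
            f"dropping {len(dropped)} zero-variance rows from the network "
            f"(e.g. {dropped[:3]})"
        )
        values = values.loc[keep]
        x = x[keep]
    if len(values) < 2:
        raise ValueError("need at least 2 variable rows for a network")
    a = ((1.0 + _row_correlation(x)) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2.0
    return pd.DataFrame(a, index=values.index, columns=values.index)


def pick_soft_threshold(
    values: pd.DataFrame,
    powers: Sequence[float] = tuple(range(1, 21)),
    r2_cut: float = 0.80,
    n_bins: int = 10,
    override: Optional[float] = None,
) -> Tuple[float, pd.DataFrame]:
    """Soft power by the scale-free-topology fit criterion.

    For each candidate power the connectivity distribution is binned and
    log10(frequency) regressed on log10(mean connectivity); the fit index
    is R^2 signed against the slope (a scale-free network has a negative
    slope). The smallest power reaching ``r2_cut`` wins, else the argmax;
    an explicit ``override`` (e.g. a previously published choice) skips
    the selection but the fit table is still returned.
    """
    if len(powers) < 2:
        raise ValueError("need at least 2 candidate powers")
    rows = []
    for beta in powers:
        adj = signed_adjacency(values, beta).values
        k = adj.sum(axis=0) - 1.0
        r2, slope, mean_k = _scale_free_fit(k, n_bins)
        rows.append(
            {"power": beta, "sft_r2": r2, "slope": slope, "mean_connectivity": mean_k}
        )
    table = pd.DataFrame(rows)
    if override is not None:
        return float(override), table
    ok = table[table["sft_r2"] >= r2_cut]
    if not ok.empty:
        beta = float(ok.iloc[0]["power"])
    else:
        beta = float(table.loc[table["sft_r2"].idxmax(), "power"])
    return beta, table


def _scale_free_fit(k: np.ndarray, n_bins: int) -> Tuple[float, float, float]:
    """Signed R^2 of log10 p(k) vs log10 k over connectivity bins."""
    mean_k = float(k.mean())
    kmax, kmin = k.max(), k.min()
    if kmax <= kmin:
        return 0.0, 0.0, mean_k
    edges = np.linspace(kmin, kmax + 1e-9, n_bins + 1)
    idx = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        kb = k[sel].mean()
        if kb <= 0:
            continue
        xs.append(math.log10(kb))
        ys.append(math.log10(sel.sum() / len(k)))
    if len(xs) < 3:
        return 0.0, 0.0, mean_k
    fit = linregress(xs, ys)
    r2 = fit.rvalue**2
    # signed fit: a positive slope is the opposite of scale-free
    signed = r2 if fit.slope < 0 else -r2
    return float(signed), float(fit.slope), mean_k


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a [0,1] adjacency with unit diagonal.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with k_i = sum_{u != i} a_iu; the diagonal is 1.
    """
    a = adjacency.values.astype(float)
    n = a.shape[0]
    k = a.sum(axis=0) - 1.0
    prod = a @ a
    # remove diagonal contributions a_ii * a_ij and a_ij * a_jj from the sum
    shared = prod - a * np.diag(a)[:, None] - a * np.diag(a)[None, :]
    num = shared + a
    kmin = np.minimum(k[:, None], k[None, :])
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / denom
    tom = np.clip(np.nan_to_num(tom, nan=0.0), 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    tom = (tom + tom.T) / 2.0
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def _auto_cut_height(link: np.ndarray) -> float:
    """Cut height at the midpoint of the largest gap between successive
    merge heights — a deterministic stand-in for dynamic tree cutting."""
    heights = np.sort(link[:, 2])
    if float(heights[-1] - heights[0]) <= 1e-9:
        # degenerate tree (e.g. identical rows): everything is one cluster
        return float(heights[-1]) + 1e-6
    gaps = np.diff(heights)
    i = int(np.argmax(gaps))
    return float((heights[i] + heights[i + 1]) / 2.0)


def detect_modules(
    tom: pd.DataFrame, min_size: int, cut_height: Optional[float] = None
) -> pd.Series:
    """Module labels from average-linkage clustering of 1 - TOM.

    The tree is cut at ``cut_height`` (auto-calibrated to the largest
    merge-height gap when None); clusters smaller than ``min_size`` are
    relabeled 0 (unassigned) and the rest renumbered 1, 2, ... by
    descending size, ties broken by first member id.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    d = 1.0 - tom.values
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = average(squareform(d, checks=False))
    h = _auto_cut_height(link) if cut_height is None else cut_height
    raw = fcluster(link, t=h, criterion="distance")
    labels = pd.Series(raw, index=tom.index)
    sizes = labels.value_counts()
    keep = [lab for lab in sizes.index if sizes[lab] >= min_size]
    # renumber by size descending, deterministic tie-break on first member
    keep.sort(key=lambda lab: (-sizes[lab], str(labels[labels == lab].index[0])))
    mapping = {lab: i + 1 for i, lab in enumerate(keep)}
    return labels.map(lambda lab: mapping.get(lab, 0))


def hub_genes(
    labels: pd.Series, adjacency: pd.DataFrame, fraction: float = 0.10
) -> pd.DataFrame:
    """Per-module hubs: the top ceil(fraction * size) genes by weighted
    within-module degree (adjacency to same-module genes, self excluded).
    Ties are broken by gene id."""
    rows = []
    for module in sorted(labels.unique()):
        if module == 0:
            continue
        members = list(labels.index[labels == module])
        sub = adjacency.loc[members, members].values.copy()
        np.fill_diagonal(sub, 0.0)
        degree = sub.sum(axis=1)
        n_hubs = math.ceil(fraction * len(members))
        order = sorted(range(len(members)), key=lambda i: (-degree[i], members[i]))
        hubs = {members[i] for i in order[:n_hubs]}
        for i, gid in enumerate(members):
            rows.append(
                {
                    "gene_id": gid,
                    "module": module,
                    "degree": float(degree[i]),
                    "hub": gid in hubs,
                }
            )
    if not rows:
        return pd.DataFrame(columns=["gene_id", "module", "degree", "hub"]).set_index(
            "gene_id"
        )
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class CoexpressionResult:
    """Bundle of the network stages for one expression matrix."""

    power: float
    fit_table: pd.DataFrame
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    modules: pd.Series
    hubs: pd.DataFrame


def coexpression_analysis(
    values: pd.DataFrame,
    power: Optional[float] = None,
    min_module_size: int = 300,
    hub_fraction: float = 0.10,
    cut_height: Optional[float] = None,
    powers: Sequence[float] = tuple(range(1, 21)),
) -> CoexpressionResult:
    """Run the full network stage: power selection (unless given),
    adjacency, TOM, modules, hubs."""
    beta, table = pick_soft_threshold(values, powers=powers, override=power)
    adj = signed_adjacency(values, beta)
    tom = tom_similarity(adj)
    modules = detect_modules(tom, min_size=min_module_size, cut_height=cut_height)
    hubs = hub_genes(modules, adj, fraction=hub_fraction)
    return CoexpressionResult(
        power=beta, fit_table=table, adjacency=adj, tom=tom, modules=modules, hubs=hubs
    )
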