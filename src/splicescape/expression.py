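"""FPKM expression matrices: transforms, presence calls, variance
filtering, and hierarchical clustering.

Samples are tissue x replicate columns; the tissue map assigns every
column to exactly one tissue. Presence in a tissue means the mean of
that tissue's replicate FPKM values reaches a threshold (default 1),
matching a per-tissue minimum-expression filter with pooled replicates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

__all__ = [
    "ExpressionMatrix",
    "log_transform",
    "tissue_presence",
    "variance_top_fraction",
    "hierarchical_cluster",
    "read_fpkm",
    "read_tissue_map",
]


@dataclass
class ExpressionMatrix:
    """Rows (transcripts or genes) x samples FPKM table with tissue groups."""

    values: pd.DataFrame
    tissue_map: Dict[str, str]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = [c for c in self.values.columns if c not in self.tissue_map]
        if missing:
            raise ValueError(f"samples without a tissue assignment: {missing}")

    @property
    def tissues(self) -> List[str]:
        seen: List[str] = []
        for c in self.values.columns:
            t = self.tissue_map[c]
            if t not in seen:
                seen.append(t)
        return seen

    def tissue_columns(self, tissue: str) -> List[str]:
        return [c for c in self.values.columns if self.tissue_map[c] == tissue]

    def log_transform(self) -> pd.DataFrame:
        return log_transform(self.values)

    def tissue_means(self) -> pd.DataFrame:
        """Row x tissue matrix of replicate-mean FPKM."""
        cols = {t: self.tissue_columns(t) for t in self.tissues}
        return pd.DataFrame(
            {t: self.values[c].mean(axis=1) for t, c in cols.items()},
            index=self.values.index,
        )

    def tissue_presence(self, min_fpkm: float = 1.0) -> pd.DataFrame:
        return self.tissue_means() >= min_fpkm

    def to_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", index_label="id")


def log_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log10(FPKM + 1)."""
    if (values.values < 0).any():
        raise ValueError("negative value in expression matrix")
    return np.log10(values + 1.0)


def tissue_presence(m: ExpressionMatrix, min_fpkm: float = 1.0) -> pd.DataFrame:
    """Boolean row x tissue presence table (mean replicate FPKM >= threshold)."""
    return m.tissue_presence(min_fpkm=min_fpkm)


def variance_top_fraction(
    m: ExpressionMatrix, fraction: float = 0.60
) -> List[str]:
    """Row ids in the top ``fraction`` of the variance ranking.

    Variance is taken across all samples; ceil(fraction * n) rows are
    kept. Ties in variance are broken by row id so the retained set is
    deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    var = m.values.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda rid: (-var[rid], rid))
    k = math.ceil(fraction * len(order))
    return order[:k]


def _correlation_distance(logged: pd.DataFrame) -> np.ndarray:
    """1 - Pearson row-correlation; zero-variance rows sit at distance 1."""
    x = logged.values.astype(float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    d = 1.0 - c
    degenerate = sd == 0
    d[degenerate, :] = 1.0
    d[:, degenerate] = 1.0
    np.fill_diagonal(d, 0.0)
    # numerical cleanup: clamp to [0, 2] and symmetrize
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return d


def hierarchical_cluster(
    m: ExpressionMatrix, log: bool = True
) -> Tuple[List[str], np.ndarray]:
    """Average-linkage clustering of rows on 1 - Pearson correlation of
    log10(FPKM + 1) values.

    Returns (row ids in leaf order, scipy linkage matrix). Zero-variance
    rows are placed at distance 1 from everything.
    """
    if len(m.values) < 2:
        raise ValueError("need at least 2 rows to cluster")
    data = m.log_transform() if log else m.values
    d = _correlation_distance(data)
    link = average(squareform(d, checks=False))
    order = [m.values.index[i] for i in leaves_list(link)]
    return order, link


def read_fpkm(path: str, tissue_map: Optional[Dict[str, str]] = None) -> ExpressionMatrix:
    """Read a rows x samples FPKM TSV (header = sample ids).

    Without an explicit tissue map, sample names of the form
    ``<tissue>_<replicate>`` are split on the final underscore.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if tissue_map is None:
        tissue_map = {c: c.rsplit("_", 1)[0] for c in df.columns}
    return ExpressionMatrix(values=df, tissue_map=tissue_map)


def read_tissue_map(path: str) -> Dict[str, str]:
    """Tissue-map config: YAML or JSON mapping sample id -> tissue."""
    with open(path) as fh:
        if path.endswith(".json"):
            data = json.load(fh)
        else:
            data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: tissue map must be a mapping")
    return {str(k): str(v) for k, v in data.items()}
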