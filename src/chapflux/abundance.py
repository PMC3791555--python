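"""Cross-dataset protein-abundance harmonisation and comparison.

Proteome-wide abundance datasets come in parts-per-million of total protein
molecules (PaxDB convention) or directly in copies per cell.  Under a
60-million-molecule cell, 1 ppm corresponds to 60 cpc.  Datasets are
compared by Spearman rank correlation on their shared proteins and
clustered by average linkage on 1 - rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.stats import spearmanr

TOTAL_COPIES_PER_CELL = 6.0e7


@dataclass
class AbundanceDataset:
    """One protein-abundance dataset keyed by systematic ORF name."""

    name: str
    unit: str  # "ppm" or "cpc"
    values: dict[str, float]
    total_copies_assumption: float = TOTAL_COPIES_PER_CELL

    def __post_init__(self) -> None:
        if self.unit not in ("ppm", "cpc"):
            raise ValueError(f"unit must be 'ppm' or 'cpc', got {self.unit!r}")
        if any(v < 0 for v in self.values.values()):
            raise ValueError("abundances must be >= 0")

    def in_cpc(self) -> dict[str, float]:
        if self.unit == "cpc":
            return dict(self.values)
        return {k: ppm_to_cpc(v, self.total_copies_assumption) for k, v in self.values.items()}

    def in_ppm(self) -> dict[str, float]:
        if self.unit == "ppm":
            return dict(self.values)
        return {k: cpc_to_ppm(v, self.total_copies_assumption) for k, v in self.values.items()}


@dataclass
class ComparisonResult:
    names: list[str]
    rho_matrix: np.ndarray  # dataset x dataset Spearman rho, NaN where overlap too small
    n_common: np.ndarray    # pairwise overlap counts

    linkage: np.ndarray | None = field(default=None)


def ppm_to_cpc(ppm: float, total_copies: float = TOTAL_COPIES_PER_CELL) -> float:
    """ppm of total protein molecules → copies per cell (1 ppm ≅ 60 cpc)."""
    if ppm < 0 or total_copies <= 0:
        raise ValueError("ppm must be >= 0 and total_copies > 0")
    return ppm * total_copies * 1e-6


def cpc_to_ppm(cpc: float, total_copies: float = TOTAL_COPIES_PER_CELL) -> float:
    """Exact inverse of :func:`ppm_to_cpc`."""
    if cpc < 0 or total_copies <= 0:
        raise ValueError("cpc must be >= 0 and total_copies > 0")
    return cpc * 1e6 / total_copies


def correlation_matrix(
    datasets: list[AbundanceDataset], min_overlap: int = 10
) -> ComparisonResult:
    """Pairwise Spearman correlations on pairwise-complete ORF intersections.

    Each pair is correlated on the proteins present (non-missing) in both
    datasets; pairs with fewer than ``min_overlap`` shared proteins get a
    NaN rho.  Spearman is rank-based, so ppm/cpc unit differences and any
    monotone transform are immaterial.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    names = [d.name for d in datasets]
    if len(set(names)) != len(names):
        raise ValueError("dataset names must be unique")
    k = len(datasets)
    rho = np.eye(k)
    n_common = np.zeros((k, k), dtype=int)
    maps = [d.values for d in datasets]
    for i in range(k):
        n_common[i, i] = len(maps[i])
        for j in range(i + 1, k):
            shared = sorted(set(maps[i]) & set(maps[j]))
            n_common[i, j] = n_common[j, i] = len(shared)
            if len(shared) < min_overlap:
                rho[i, j] = rho[j, i] = np.nan
                continue
            x = [maps[i][o] for o in shared]
            y = [maps[j][o] for o in shared]
            r = spearmanr(x, y).statistic
            rho[i, j] = rho[j, i] = r
    return ComparisonResult(names=names, rho_matrix=rho, n_common=n_common)


def cluster_datasets(comparison: ComparisonResult) -> ComparisonResult:
    """Average-linkage agglomerative tree on distance d = 1 - rho.

    Datasets are ordered by name before clustering so the tree is invariant
    to input order; missing correlations are an error (impute or drop
    upstream).
    """
    rho = comparison.rho_matrix
    if np.isnan(rho).any():
        raise ValueError("rho matrix has missing entries; impute or drop first")
    order = np.argsort(np.asarray(comparison.names))
    names = [comparison.names[i] for i in order]
    d = 1.0 - rho[np.ix_(order, order)]
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    condensed = d[np.triu_indices_from(d, k=1)]
    z = hierarchy.linkage(condensed, method="average")
    return ComparisonResult(
        names=names,
        rho_matrix=rho[np.ix_(order, order)],
        n_common=comparison.n_common[np.ix_(order, order)],
        linkage=z,
    )


def linkage_to_newick(z: np.ndarray, names: list[str]) -> str:
    """Serialise a scipy linkage matrix over labelled leaves as Newick text."""
    tree = hierarchy.to_tree(z)

    def render(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{names[node.id]}:{parent_height:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    inner = f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)})"
    return inner + ";"


def complex_cv(dataset: AbundanceDataset, members: list[str]) -> float:
    """Coefficient of variation (sample SD / mean) across complex members.

    A fixed-stoichiometry complex (e.g. the octameric CCT/TRiC ring) should
    show a low CV across its subunits in a well-calibrated dataset.
    """
    vals = [dataset.values[m] for m in members if m in dataset.values]
    if len(vals) < 2:
        raise ValueError("need at least two quantified members")
    arr = np.asarray(vals, dtype=float)
    mean = arr.mean()
    if mean == 0:
        raise ValueError("mean abundance is zero")
    return float(arr.std(ddof=1) / mean)
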