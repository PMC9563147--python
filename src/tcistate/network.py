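"""Signed driver -> DEG regulatory matrix and its biclusters.

Each retained causal edge is signed by the point-biserial correlation
between the target's continuous expression and the driver's dichotomous
status (alteration status by default, inferred activation state on
request): +1 activating, -1 repressing, 0 kept but unsigned. Modules of
co-regulated drivers/DEGs are then found with an iterative signature
algorithm (ISA): from a random gene-set seed, alternate z-scored
row-scoring and column-scoring with thresholding until a fixed point;
fixed points recurring across random restarts form consensus biclusters,
each annotated with the fraction of runs reproducing it (stability).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["point_biserial", "sign_edges", "Bicluster", "isa_biclusters",
           "signed_edge_list", "to_networkx"]


def point_biserial(values, groups) -> float:
    """Point-biserial correlation between a continuous and a 0/1 vector.

    Computed from the classical formula

        r_pb = (M1 - M0) / s_n * sqrt(n1 * n0 / n^2)

    with s_n the population SD of ``values``; algebraically identical to
    the Pearson correlation of the two vectors. Degenerate inputs (a
    single group, or constant values) return 0 with a warning.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if x.shape != g.shape or x.ndim != 1:
        raise ValueError("values and groups must be 1-d vectors of equal length")
    if not set(np.unique(g)) <= {0, 1}:
        raise ValueError("groups must be binary 0/1")
    n = x.size
    n1 = int(g.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        warnings.warn("single-group input: point-biserial undefined, returning 0")
        return 0.0
    s = x.std()
    if s == 0:
        warnings.warn("constant values: point-biserial undefined, returning 0")
        return 0.0
    m1 = x[g == 1].mean()
    m0 = x[g == 0].mean()
    return float((m1 - m0) / s * np.sqrt(n1 * n0 / n**2))


def _pb_pvalue(r: float, n: int) -> float:
    """Two-sided p-value via the t-approximation with n - 2 dof."""
    if n <= 2 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 else 1.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def sign_edges(catalog, expression: pd.DataFrame, binary: pd.DataFrame,
               sign_threshold: float = 0.0, alpha: float = 0.05) -> pd.DataFrame:
    """Sign every retained driver -> DEG edge.

    Parameters
    ----------
    catalog : DriverCatalog
    expression : DataFrame
        Continuous tumors x genes matrix (targets must be present).
    binary : DataFrame
        Dichotomous driver status per tumor — the SGA matrix, or the
        inferred activation-state matrix.
    sign_threshold, alpha : float
        An edge receives sign(r) only when |r| >= ``sign_threshold`` and
        the correlation's two-sided p (t-approximation) < ``alpha``;
        otherwise it stays 0 (kept but unsigned).

    Returns the r x c signed regulatory matrix (drivers x target DEGs,
    entries in {-1, 0, 1}); entries outside the retained edge set are 0.
    """
    drivers = catalog.driver_genes
    targets = catalog.target_genes
    m = pd.DataFrame(0, index=drivers, columns=targets, dtype=np.int8)
    n = len(expression.index)
    for drv, tgt in catalog.edge_set:
        r = point_biserial(expression[tgt].to_numpy(),
                           binary.loc[expression.index, drv].to_numpy())
        if abs(r) >= sign_threshold and _pb_pvalue(r, n) < alpha and r != 0:
            m.loc[drv, tgt] = 1 if r > 0 else -1
    m.index.name = "driver"
    return m


def signed_edge_list(signed: pd.DataFrame) -> pd.DataFrame:
    """Two-column edge list with a sign attribute (graph-loadable)."""
    rows = [
        (d, t, int(signed.loc[d, t]))
        for d in signed.index for t in signed.columns if signed.loc[d, t] != 0
    ]
    return pd.DataFrame(rows, columns=["driver", "target", "sign"])


def to_networkx(signed: pd.DataFrame):
    """Signed regulatory matrix as a directed networkx graph."""
    import networkx as nx

    g = nx.DiGraph()
    for _, row in signed_edge_list(signed).iterrows():
        g.add_edge(row["driver"], row["target"], sign=row["sign"])
    return g


@dataclass(frozen=True)
class Bicluster:
    """A recurring driver-subset x DEG-subset module."""

    drivers: frozenset
    targets: frozenset
    stability: float

    def jaccard(self, other: "Bicluster") -> float:
        a = {("r", d) for d in self.drivers} | {("c", t) for t in self.targets}
        b = {("r", d) for d in other.drivers} | {("c", t) for t in other.targets}
        return len(a & b) / len(a | b)


def _zscore(v: np.ndarray) -> np.ndarray | None:
    s = v.std()
    if s == 0:
        return None
    return (v - v.mean()) / s


def _isa_fixed_point(m: np.ndarray, cols: np.ndarray, t_rows: float,
                     t_cols: float, max_iter: int) -> tuple[np.ndarray, np.ndarray] | None:
    """Iterate row/column thresholded scoring from a column seed.

    Returns (row mask, column mask) at the fixed point, or None when no
    fixed point is reached (empty selection, degenerate scores, or the
    iteration cap)."""
    rows = np.zeros(m.shape[0], dtype=bool)
    for _ in range(max_iter):
        if not cols.any():
            return None
        rs = _zscore(m[:, cols].mean(axis=1))
        if rs is None:
            return None
        new_rows = rs >= t_rows
        if not new_rows.any():
            return None
        cs = _zscore(m[new_rows, :].mean(axis=0))
        if cs is None:
            return None
        new_cols = cs >= t_cols
        if not new_cols.any():
            return None
        if (new_rows == rows).all() and (new_cols == cols).all():
            return rows, cols
        rows, cols = new_rows, new_cols
    return None


def isa_biclusters(signed: pd.DataFrame, n_runs: int = 100, t_rows: float = 1.5,
                   t_cols: float = 1.5, seed: int | None = None,
                   seed_col_prob: float = 0.5, jaccard_cutoff: float = 0.8,
                   stability_cutoff: float = 0.5,
                   max_iter: int = 100) -> list[Bicluster]:
    """Consensus ISA biclusters of a (signed) regulatory matrix.

    ``n_runs`` random column seeds each iterate to a fixed point; fixed
    points are merged greedily at Jaccard >= ``jaccard_cutoff`` (over the
    union of row and column members) and a merged bicluster's stability
    is the fraction of all runs reproducing it. Only biclusters with
    stability >= ``stability_cutoff`` are returned, ordered by stability.
    Runs without a fixed point are discarded (logged).
    """
    if signed.shape[0] == 0 or signed.shape[1] == 0:
        raise ValueError("empty matrix")
    m = signed.to_numpy(float)
    rng = np.random.default_rng(seed)
    found: list[tuple[np.ndarray, np.ndarray, int]] = []  # row mask, col mask, count
    n_discarded = 0
    for _ in range(n_runs):
        cols = rng.random(m.shape[1]) < seed_col_prob
        fp = _isa_fixed_point(m, cols, t_rows, t_cols, max_iter)
        if fp is None:
            n_discarded += 1
            continue
        rows, cols = fp
        for i, (r0, c0, cnt) in enumerate(found):
            inter = (rows & r0).sum() + (cols & c0).sum()
            union = (rows | r0).sum() + (cols | c0).sum()
            if union and inter / union >= jaccard_cutoff:
                found[i] = (r0, c0, cnt + 1)
                break
        else:
            found.append((rows, cols, 1))
    if n_discarded:
        log.info("%d of %d ISA starts reached no fixed point", n_discarded, n_runs)
    out = [
        Bicluster(
            drivers=frozenset(signed.index[r0]),
            targets=frozenset(signed.columns[c0]),
            stability=cnt / n_runs,
        )
        for r0, c0, cnt in found
        if cnt / n_runs >= stability_cutoff
    ]
    return sorted(out, key=lambda b: -b.stability)


def biclusters_to_json(biclusters: list[Bicluster], path: str | Path) -> None:
    payload = [
        {"drivers": sorted(b.drivers), "targets": sorted(b.targets),
         "stability": b.stability}
        for b in biclusters
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
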