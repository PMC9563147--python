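"""Consensus subtyping of tumors plus survival and covariate association.

Tumors are clustered on any numeric feature matrix (SGA status of
retained drivers, binary DEG indicators, expression of retained target
DEGs, or inferred activation states). Because agglomerative clustering
is deterministic, stability is probed by repeated subsampling: each of
``n_resamples`` draws clusters a random 80% of tumors (Euclidean
distance, average linkage) and the consensus matrix records how often
each tumor pair lands in the same cluster among the draws containing
both. The cluster number K is chosen from the growth of the area under
the consensus-entry CDF, and final labels come from re-clustering the
consensus-derived distance 1 - consensus.

Survival differences between subtypes are assessed by Kaplan-Meier
curves and the multi-group log-rank test, with follow-up administratively
capped (default 2500 days). Covariate association runs a contingency
chi-square (or Fisher for sparse 2x2, Kruskal-Wallis for continuous
covariates) against labels, or — for an activation-state matrix and a
binary covariate — tabulates per-driver SGA frequency versus inferred
activation rate in each covariate group, flagging drivers whose
activation among genomically unaltered tumors differs between groups.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

__all__ = ["ConsensusResult", "consensus_cluster", "SurvivalComparison",
           "compare_survival", "associate_with_covariate"]


@dataclass
class ConsensusResult:
    """Consensus matrix, CDF-area curve, selected K and final labels."""

    consensus: pd.DataFrame = field(repr=False)
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    selected_k: int
    labels: pd.Series = field(repr=False)
    consensus_per_k: dict[int, pd.DataFrame] = field(default_factory=dict, repr=False)

    def summary(self) -> str:
        lines = ["Consensus clustering",
                 f"  tumors:     {len(self.labels)}",
                 f"  selected K: {self.selected_k}",
                 "  K   CDF area   relative gain"]
        for k in sorted(self.cdf_area):
            lines.append(f"  {k:<3} {self.cdf_area[k]:<10.4f} {self.delta_area[k]:.4f}")
        sizes = self.labels.value_counts().sort_index()
        lines.append("  cluster sizes: " + ", ".join(f"{k}: {v}" for k, v in sizes.items()))
        return "\n".join(lines)

    def plot_consensus(self, ax=None):
        """Consensus heatmap ordered by cluster label (presentation only)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = self.labels.sort_values(kind="stable").index
        ax.imshow(self.consensus.loc[order, order].to_numpy(), cmap="Blues",
                  vmin=0, vmax=1, interpolation="nearest")
        ax.set_title(f"consensus matrix (K = {self.selected_k})")
        ax.set_xticks([])
        ax.set_yticks([])
        return ax

    def plot_feature_heatmap(self, features: pd.DataFrame, ax=None):
        """Feature heatmap with a subtype sidebar (presentation only)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = self.labels.sort_values(kind="stable").index
        ax.imshow(features.loc[order].to_numpy(), aspect="auto",
                  cmap="coolwarm", interpolation="nearest")
        bounds = np.flatnonzero(np.diff(self.labels.loc[order].to_numpy()))
        for b in bounds:
            ax.axhline(b + 0.5, color="black", lw=0.8)
        ax.set_xlabel("features")
        ax.set_ylabel("tumors (by subtype)")
        return ax


def _cdf_area(entries: np.ndarray, bins: int = 100) -> float:
    """Area under the empirical CDF of consensus entries over [0, 1]."""
    hist, edges = np.histogram(entries, bins=bins, range=(0.0, 1.0))
    cdf = np.cumsum(hist) / max(len(entries), 1)
    return float(np.sum(cdf * np.diff(edges)))


def consensus_cluster(
    features: pd.DataFrame,
    k_range: tuple[int, int] = (2, 6),
    n_resamples: int = 100,
    subsample_frac: float = 0.8,
    linkage_method: str = "average",
    seed: int | None = None,
    force_k: int | None = None,
    rel_gain_threshold: float = 0.1,
) -> ConsensusResult:
    """Subsampled hierarchical consensus clustering with CDF-area K selection.

    ``k_range`` is inclusive. K is the largest value whose relative gain
    in CDF area over K-1 is at least ``rel_gain_threshold`` (the smallest
    K when no gain qualifies); ``force_k`` overrides the selection.
    """
    n = len(features.index)
    if n < 2:
        raise ValueError("need at least 2 tumors")
    ks = list(range(k_range[0], k_range[1] + 1))
    if ks[-1] > n:
        raise ValueError(f"K up to {ks[-1]} exceeds the number of tumors {n}")
    if force_k is not None and not (2 <= force_k <= n):
        raise ValueError(f"force_k={force_k} out of range")

    rng = np.random.default_rng(seed)
    x = features.to_numpy(float)
    m = max(2, int(np.floor(subsample_frac * n)))
    together = {k: np.zeros((n, n)) for k in ks}
    co_sampled = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        co_sampled[np.ix_(idx, idx)] += 1
        z = linkage(x[idx], method=linkage_method, metric="euclidean")
        for k in ks:
            lab = fcluster(z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            together[k][np.ix_(idx, idx)] += same

    iu = np.triu_indices(n, k=1)
    never = int((co_sampled[iu] == 0).sum())
    if never:
        log.warning("%d tumor pairs were never co-sampled; their consensus "
                    "entries are set to 0", never)
    denom = np.where(co_sampled > 0, co_sampled, 1.0)
    consensus_per_k = {}
    cdf_area: dict[int, float] = {}
    for k in ks:
        c = together[k] / denom
        np.fill_diagonal(c, 1.0)
        c = (c + c.T) / 2.0
        consensus_per_k[k] = pd.DataFrame(c, index=features.index,
                                          columns=features.index)
        cdf_area[k] = _cdf_area(c[iu])

    delta: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = cdf_area[k]
        else:
            prev = cdf_area[ks[i - 1]]
            delta[k] = (cdf_area[k] - prev) / prev if prev > 0 else 0.0

    if force_k is not None:
        selected = force_k
    else:
        qualifying = [k for k in ks[1:] if delta[k] >= rel_gain_threshold]
        selected = max(qualifying) if qualifying else ks[0]

    cons = consensus_per_k.get(selected)
    if cons is None:  # force_k outside the scanned range
        cons_mat = np.zeros((n, n))
        z = linkage(x, method=linkage_method, metric="euclidean")
        lab = fcluster(z, t=selected, criterion="maxclust")
        cons_mat[:] = (lab[:, None] == lab[None, :]).astype(float)
        cons = pd.DataFrame(cons_mat, index=features.index, columns=features.index)

    dist = 1.0 - cons.to_numpy()
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    labels = pd.Series(fcluster(z, t=selected, criterion="maxclust"),
                       index=features.index, name="subtype")
    return ConsensusResult(consensus=cons, cdf_area=cdf_area, delta_area=delta,
                           selected_k=selected, labels=labels,
                           consensus_per_k=consensus_per_k)


@dataclass
class SurvivalComparison:
    """Kaplan-Meier curves per group and the multi-group log-rank test."""

    statistic: float
    p_value: float
    n_per_group: dict
    km_curves: dict = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "logrank_statistic": self.statistic,
            "p_value": self.p_value,
            "n_per_group": {str(k): int(v) for k, v in self.n_per_group.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def summary(self) -> str:
        lines = [
            "Survival comparison (multi-group log-rank)",
            f"  statistic: {self.statistic:.4f}",
            f"  p-value:   {self.p_value:.3g}",
            "  group sizes: "
            + ", ".join(f"{k}: {v}" for k, v in sorted(self.n_per_group.items())),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for grp, curve in sorted(self.km_curves.items()):
            ax.step(curve.index, curve.iloc[:, 0], where="post", label=f"group {grp}")
        ax.set_xlabel("time (days)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        ax.set_title(f"log-rank p = {self.p_value:.2g}")
        return ax


def compare_survival(labels: pd.Series, clinical: pd.DataFrame,
                     max_time: float = 2500.0) -> SurvivalComparison:
    """Kaplan-Meier + multi-group log-rank over subtype labels.

    ``clinical`` needs columns tumor_id (or an index of tumor ids),
    time_days and event; follow-up is administratively censored at
    ``max_time`` days.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    clin = clinical.set_index("tumor_id") if "tumor_id" in clinical.columns else clinical
    missing = labels.index.difference(clin.index)
    if len(missing):
        raise ValueError(f"{len(missing)} labeled tumors lack clinical rows")
    if labels.nunique() < 2:
        raise ValueError("need at least 2 groups to compare survival")
    clin = clin.loc[labels.index]
    time = clin["time_days"].astype(float).clip(upper=max_time)
    event = clin["event"].astype(int).where(clin["time_days"] <= max_time, 0)

    for grp, ev in event.groupby(labels):
        if ev.sum() == 0:
            warnings.warn(f"group {grp} has zero observed events")

    res = multivariate_logrank_test(time, labels, event)
    curves = {}
    for grp in sorted(labels.unique()):
        mask = labels == grp
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(grp))
        curves[grp] = kmf.survival_function_
    return SurvivalComparison(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n_per_group=labels.value_counts().to_dict(),
        km_curves=curves,
    )


@dataclass
class CovariateAssociation:
    """Association of subtype labels with a clinical covariate."""

    method: str
    statistic: float
    p_value: float
    table: pd.DataFrame = field(repr=False)

    def summary(self) -> str:
        return (f"Covariate association ({self.method}): statistic = "
                f"{self.statistic:.4f}, p = {self.p_value:.3g}")


def _associate_labels(labels: pd.Series, covariate: pd.Series) -> CovariateAssociation:
    cov = covariate.loc[labels.index]
    if pd.api.types.is_numeric_dtype(cov) and cov.nunique() > 10:
        groups = [cov[labels == g].to_numpy() for g in sorted(labels.unique())]
        stat, p = stats.kruskal(*groups)
        table = cov.groupby(labels).describe()
        return CovariateAssociation("kruskal-wallis", float(stat), float(p), table)
    table = pd.crosstab(labels, cov)
    chi2, p, _, expected = stats.chi2_contingency(table)
    if (expected < 5).any():
        if table.shape == (2, 2):
            odds, p = stats.fisher_exact(table)
            return CovariateAssociation("fisher-exact", float(odds), float(p), table)
        warnings.warn("expected counts below 5; chi-square approximation is rough")
    return CovariateAssociation("chi-square", float(chi2), float(p), table)


def _associate_states(states: pd.DataFrame, covariate: pd.Series,
                      sga: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-driver SGA frequency vs inferred activation rate by covariate group.

    The flag tests, among tumors *without* the driver's SGA, whether the
    inferred activation rate differs between the two covariate groups
    (Fisher exact, Bonferroni-corrected) — the signature of a covariate
    driving activation through crosstalk rather than genome alteration.
    """
    cov = covariate.loc[states.index]
    vals = sorted(cov.unique())
    if len(vals) != 2:
        raise ValueError("state-matrix association needs a binary covariate")
    g0, g1 = vals
    rows = []
    n_drivers = states.shape[1]
    for d in states.columns:
        s = sga.loc[states.index, d]
        a = states[d]
        rec = {"driver": d}
        for name, grp in (("g0", cov == g0), ("g1", cov == g1)):
            rec[f"sga_freq_{name}"] = float(s[grp].mean())
            rec[f"activation_rate_{name}"] = float(a[grp].mean())
            rec[f"gap_{name}"] = rec[f"activation_rate_{name}"] - rec[f"sga_freq_{name}"]
        # crosstalk test among SGA-free tumors
        free = s == 0
        tab = pd.crosstab(cov[free], a[free])
        tab = tab.reindex(index=vals, columns=[0, 1], fill_value=0)
        _, p = stats.fisher_exact(tab)
        rec["crosstalk_p"] = float(p)
        rec["flagged"] = bool(p * n_drivers < alpha)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("driver")
    out.attrs["group_levels"] = {"g0": g0, "g1": g1}
    return out


def associate_with_covariate(labels_or_states, covariate: pd.Series,
                             sga: pd.DataFrame | None = None, alpha: float = 0.05):
    """Associate subtype labels (Series) or an activation-state matrix
    (DataFrame, requires ``sga``) with a clinical covariate."""
    if isinstance(labels_or_states, pd.DataFrame):
        if sga is None:
            raise ValueError("state-matrix association requires the SGA matrix")
        return _associate_states(labels_or_states, covariate, sga, alpha=alpha)
    return _associate_labels(labels_or_states, covariate)
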