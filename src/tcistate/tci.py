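"""Tumor-specific causal inference (TCI) of SGA -> DEG arcs.

For each tumor t and each differentially expressed gene E_i observed in
it, the candidate causes are the somatic genome alterations present in
that tumor plus a catch-all non-specific cause A0. Each candidate arc
A_h -> E_i is scored by its posterior probability

    P(A_h -> E_i | D)  propto  P(A_h -> E_i) * P(D | A_h -> E_i),

normalised over the tumor's candidate set. The marginal likelihood
P(D | A_h -> E_i) is the Dirichlet-multinomial (BDeu-style) score of the
two-state cause/two-state effect contingency table counted over the whole
cohort:

    prod_j Gamma(a_j)/Gamma(a_j + N_j) * prod_k Gamma(a_jk + N_jk)/Gamma(a_jk)

with j indexing the cause state, k the effect state, and a_jk Dirichlet
pseudo-counts. A0's marginal likelihood is the same score with a single
cause block (the effect's marginal multinomial over all tumors), so the
Bayesian Occam factor lets A0 absorb effects unexplained by any SGA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

log = logging.getLogger(__name__)

A0 = "A0"

ARC_COLUMNS = ["tumor_id", "cause", "effect", "prior", "log_ml", "posterior", "edge_p"]

__all__ = ["A0", "log_marginal_likelihood", "TumorCausalModel", "TCIResults",
           "score_tumor", "score_cohort"]


def log_marginal_likelihood(counts, alpha=1.0) -> float:
    """Dirichlet-multinomial log marginal likelihood of a count table.

    Parameters
    ----------
    counts : array-like, shape (q, r)
        N_jk — tumors with cause state j and effect state k. A single-row
        table scores the cause-absent (A0) model.
    alpha : float or array-like broadcastable to ``counts``
        Dirichlet pseudo-counts a_jk (> 0). Scalar means uniform.

    Computed entirely in log space via ``gammaln``; an empty table scores
    0 (probability 1).
    """
    n = np.atleast_2d(np.asarray(counts, dtype=float))
    if (n < 0).any():
        raise ValueError("counts must be non-negative")
    a = np.broadcast_to(np.asarray(alpha, dtype=float), n.shape)
    if (a <= 0).any():
        raise ValueError("alpha must be positive")
    a_j = a.sum(axis=1)
    n_j = n.sum(axis=1)
    return float(
        np.sum(gammaln(a_j) - gammaln(a_j + n_j))
        + np.sum(gammaln(a + n) - gammaln(a))
    )


def _pair_log_ml(S: np.ndarray, D: np.ndarray, alpha: float) -> np.ndarray:
    """Log marginal likelihood for every (SGA gene, DEG gene) pair.

    Contingency counts are computed once over the whole cohort; returns a
    (n_sga_genes, n_deg_genes) array.
    """
    n = S.shape[0]
    n11 = S.T.astype(np.int64) @ D.astype(np.int64)
    s1 = S.sum(axis=0, dtype=np.int64)[:, None]
    d1 = D.sum(axis=0, dtype=np.int64)[None, :]
    n10 = s1 - n11
    n01 = d1 - n11
    n00 = n - s1 - d1 + n11

    def block(a, b):
        return (
            gammaln(2 * alpha) - gammaln(2 * alpha + a + b)
            + gammaln(alpha + a) + gammaln(alpha + b) - 2 * gammaln(alpha)
        )

    return block(n00, n01) + block(n10, n11)


def _a0_log_ml(D: np.ndarray, alpha: float) -> np.ndarray:
    """Cause-absent model per DEG gene: one multinomial block over all tumors."""
    n = D.shape[0]
    d1 = D.sum(axis=0, dtype=np.int64)
    return (
        gammaln(2 * alpha) - gammaln(2 * alpha + n)
        + gammaln(alpha + n - d1) + gammaln(alpha + d1) - 2 * gammaln(alpha)
    )


class TumorCausalModel:
    """Per-tumor Bayesian competition among SGAs (plus A0) to explain DEGs.

    Parameters
    ----------
    sga, deg : DataFrame
        Binary tumors x genes matrices sharing the same tumor set.
    prior : {"uniform", "frequency"}
        Population-level arc prior. "uniform" spreads mass evenly over
        {A0} + the tumor's SGAs; "frequency" weights each SGA by its
        cohort alteration frequency, with A0 given ``a0_mass``.
    a0_mass : float, optional
        Prior mass of A0 in "frequency" mode; default 1/(|SGA_t| + 1).
    alpha : float
        Dirichlet pseudo-count a_jk (uniform), default 1.
    """

    def __init__(self, sga: pd.DataFrame, deg: pd.DataFrame,
                 prior: str = "uniform", a0_mass: float | None = None,
                 alpha: float = 1.0):
        if prior not in ("uniform", "frequency"):
            raise ValueError(f"unknown prior mode {prior!r}")
        if set(sga.index) != set(deg.index):
            raise ValueError("SGA and DEG matrices must share the same tumor set")
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        # sort gene columns so argmax tie-breaks are lexicographic
        self.sga = sga.reindex(columns=sorted(sga.columns)).astype(np.int8)
        self.deg = deg.loc[sga.index].reindex(columns=sorted(deg.columns)).astype(np.int8)
        self.prior_mode = prior
        self.a0_mass = a0_mass
        self.alpha = float(alpha)
        self._S = self.sga.to_numpy()
        self._D = self.deg.to_numpy()
        self._L = None  # (p, q) pair log-ML cache
        self._a0 = None

    @property
    def tumor_ids(self) -> pd.Index:
        return self.sga.index

    def _ensure_scores(self) -> None:
        if self._L is None:
            self._L = _pair_log_ml(self._S, self._D, self.alpha)
            self._a0 = _a0_log_ml(self._D, self.alpha)

    def _priors(self, n_candidates: int, sga_cols: np.ndarray) -> np.ndarray:
        """Prior vector over [A0, sorted SGAs of the tumor]."""
        if self.prior_mode == "uniform":
            return np.full(n_candidates, 1.0 / n_candidates)
        freqs = self._S[:, sga_cols].mean(axis=0).astype(float)
        a0 = self.a0_mass if self.a0_mass is not None else 1.0 / n_candidates
        if not 0 < a0 < 1:
            raise ValueError("a0_mass must be in (0, 1)")
        w = freqs / freqs.sum() * (1.0 - a0) if freqs.sum() > 0 else freqs
        return np.concatenate([[a0], w])

    def _score_one(self, t_idx: int) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Winner rows and full candidate table for one tumor."""
        self._ensure_scores()
        tumor = self.tumor_ids[t_idx]
        deg_cols = np.flatnonzero(self._D[t_idx])
        if deg_cols.size == 0:
            empty = pd.DataFrame(columns=ARC_COLUMNS)
            return empty, empty
        sga_cols = np.flatnonzero(self._S[t_idx])
        effects = self.deg.columns[deg_cols]
        if sga_cols.size == 0:
            log.info("tumor %s has no SGA; all DEGs assigned to %s", tumor, A0)
            win = pd.DataFrame({
                "tumor_id": tumor, "cause": A0, "effect": effects,
                "prior": 1.0, "log_ml": self._a0[deg_cols],
                "posterior": 1.0, "edge_p": 0.0,
            })
            return win, win.copy()

        causes = [A0] + list(self.sga.columns[sga_cols])
        lml = np.vstack([self._a0[deg_cols], self._L[np.ix_(sga_cols, deg_cols)]])
        priors = self._priors(len(causes), sga_cols)
        logpost = np.log(priors)[:, None] + lml
        posts = np.exp(logpost - logsumexp(logpost, axis=0, keepdims=True))

        # ties resolved to the first (lexicographically smallest, A0 first)
        winners = posts.argmax(axis=0)
        win = pd.DataFrame({
            "tumor_id": tumor,
            "cause": np.asarray(causes, dtype=object)[winners],
            "effect": effects,
            "prior": priors[winners],
            "log_ml": lml[winners, np.arange(deg_cols.size)],
            "posterior": posts[winners, np.arange(deg_cols.size)],
        })
        win["edge_p"] = 1.0 - win["posterior"]
        full = pd.DataFrame({
            "tumor_id": tumor,
            "cause": np.repeat(causes, deg_cols.size),
            "effect": np.tile(effects, len(causes)),
            "prior": np.repeat(priors, deg_cols.size),
            "log_ml": lml.ravel(),
            "posterior": posts.ravel(),
        })
        full["edge_p"] = 1.0 - full["posterior"]
        return win, full

    def fit(self, pvalue_mode: str = "posterior", permutations: int = 0,
            seed: int | None = None) -> "TCIResults":
        """Score every tumor; returns per-tumor winning arcs.

        ``pvalue_mode="posterior"`` (default) sets edge_p = 1 - posterior.
        ``pvalue_mode="permutation"`` additionally calibrates edge_p
        against an empirical null of winning posteriors obtained by
        shuffling each SGA column across tumors ``permutations`` times.
        """
        self._ensure_scores()
        winners = [self._score_one(t)[0] for t in range(len(self.tumor_ids))]
        arcs = pd.concat([w for w in winners if len(w)], ignore_index=True) \
            if any(len(w) for w in winners) else pd.DataFrame(columns=ARC_COLUMNS)
        if pvalue_mode == "permutation":
            if permutations < 1:
                raise ValueError("permutation mode needs permutations >= 1")
            null = self._permutation_null(permutations, seed)
            obs = arcs["posterior"].to_numpy()
            # empirical p: how often a null winning posterior beats the observed
            n_ge = len(null) - np.searchsorted(null, obs, side="left")
            arcs["edge_p"] = (1 + n_ge) / (1 + len(null))
        elif pvalue_mode != "posterior":
            raise ValueError(f"unknown pvalue_mode {pvalue_mode!r}")
        return TCIResults(model=self, arcs=arcs)

    def _permutation_null(self, b: int, seed: int | None) -> np.ndarray:
        rng = np.random.default_rng(seed)
        null = []
        for _ in range(b):
            perm = np.empty_like(self._S)
            for j in range(self._S.shape[1]):
                perm[:, j] = self._S[rng.permutation(self._S.shape[0]), j]
            m = TumorCausalModel(
                pd.DataFrame(perm, index=self.sga.index, columns=self.sga.columns),
                self.deg, prior=self.prior_mode, a0_mass=self.a0_mass,
                alpha=self.alpha)
            res = m.fit()
            null.append(res.arcs.loc[res.arcs["cause"] != A0, "posterior"].to_numpy())
        return np.sort(np.concatenate(null)) if null else np.array([])


@dataclass
class TCIResults:
    """Per-tumor winning SGA -> DEG arcs and their posteriors."""

    model: TumorCausalModel
    arcs: pd.DataFrame = field(repr=False)

    def candidate_table(self, tumor_id) -> pd.DataFrame:
        """Full candidate-by-DEG posterior table for one tumor."""
        t_idx = self.model.tumor_ids.get_loc(tumor_id)
        return self.model._score_one(t_idx)[1]

    def tumor_arcs(self, tumor_id) -> pd.DataFrame:
        return self.arcs[self.arcs["tumor_id"] == tumor_id]

    def driver_catalog(self, min_edges: int = 5, p_cutoff: float = 0.05,
                       rate_cutoff: float = 0.5):
        """Aggregate arcs into the cohort driver/target-DEG catalog."""
        from .catalog import build_catalog

        return build_catalog(self.arcs, self.model.sga, self.model.deg,
                             min_edges=min_edges, p_cutoff=p_cutoff,
                             rate_cutoff=rate_cutoff)

    def to_tsv(self, path) -> None:
        self.arcs.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        n_t = len(self.model.tumor_ids)
        by_cause = self.arcs[self.arcs["cause"] != A0]["cause"].value_counts()
        lines = [
            "Tumor-specific causal inference",
            f"  tumors scored:        {n_t}",
            f"  winning arcs:         {len(self.arcs)}",
            f"  arcs won by A0:       {int((self.arcs['cause'] == A0).sum())}",
            f"  distinct SGA winners: {len(by_cause)}",
            "  top SGA winners (arcs won):",
        ]
        for gene, cnt in by_cause.head(10).items():
            lines.append(f"    {gene:<12} {cnt}")
        return "\n".join(lines)


def score_tumor(tumor_id, sga: pd.DataFrame, deg: pd.DataFrame,
                prior: str = "uniform", a0_mass: float | None = None,
                alpha: float = 1.0, full: bool = False) -> pd.DataFrame:
    """Score one tumor's DEGs against its candidate causes.

    Convenience wrapper over :class:`TumorCausalModel`; with
    ``full=True`` returns the complete candidate table instead of the
    per-DEG winners.
    """
    model = TumorCausalModel(sga, deg, prior=prior, a0_mass=a0_mass, alpha=alpha)
    win, table = model._score_one(model.tumor_ids.get_loc(tumor_id))
    return table if full else win


def score_cohort(sga: pd.DataFrame, deg: pd.DataFrame, prior: str = "uniform",
                 a0_mass: float | None = None, alpha: float = 1.0) -> TCIResults:
    """Score every tumor in the cohort (functional form of ``fit``)."""
    return TumorCausalModel(sga, deg, prior=prior, a0_mass=a0_mass,
                            alpha=alpha).fit()
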