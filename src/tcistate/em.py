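"""EM inference of latent driver-protein activation states.

A driver protein can be functionally active in a tumor even without a
somatic alteration of its gene (pathway crosstalk), so the activation
state PRO_jt of driver j in tumor t is treated as a hidden Bernoulli
variable. Evidence comes from the continuous log2 expression E_jkt of the
driver's target DEGs, modelled as Gaussian with state-conditional
parameters (mu_jk1, sigma_jk1) / (mu_jk0, sigma_jk0):

    P(PRO_jt = 1 | targets) =
        P(PRO_j=1) * prod_k N(E_jkt; mu_jk1, sigma_jk1)
        -----------------------------------------------------------
        sum_{s in {0,1}} P(PRO_j=s) * prod_k N(E_jkt; mu_jks, sigma_jks)

The chain is initialised from the SGA matrix (state = alteration status),
the per-driver prior is the mean state, and EM alternates the posterior
computation with parameter re-estimation. The default follows the
hard-EM procedure — posteriors are discretised at 0.5 (ties map to
active) before the M-step — with a soft-EM option whose observed-data
log-likelihood is guaranteed non-decreasing. Convergence is declared
when the largest absolute posterior change over all (driver, tumor)
pairs drops below ``tol``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))

__all__ = ["DriverActivationModel", "ActivationResults"]


class DriverActivationModel:
    """Two-state Gaussian-emission model of driver activation.

    Parameters
    ----------
    expression : DataFrame
        Continuous tumors x genes log2 expression matrix. The binary DEG
        matrix plays no role here beyond having defined the catalog's
        target sets.
    catalog : DriverCatalog
        Retained drivers and their retained target DEGs; each driver's
        emission product runs over exactly these targets. A DEG retained
        for several drivers contributes to each driver independently.
    sga : DataFrame
        Binary alteration matrix covering the catalog drivers; supplies
        the initial states.
    mode : {"hard", "soft"}
        Hard EM discretises posteriors before the M-step (the default
        procedure); soft EM uses posterior-weighted moments.
    tol : float
        Convergence threshold on max |change in posterior|.
    max_iter : int
        E-step budget; non-convergence is reported, not fatal.
    sigma_min : float
        Floor on emission standard deviations.
    """

    def __init__(self, expression: pd.DataFrame, catalog, sga: pd.DataFrame,
                 mode: str = "hard", tol: float = 1e-4, max_iter: int = 500,
                 sigma_min: float = 1e-3):
        if mode not in ("hard", "soft"):
            raise ValueError(f"unknown mode {mode!r}")
        if tol <= 0:
            raise ValueError("tol must be positive")
        self.mode = mode
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        self.sigma_min = float(sigma_min)

        self.drivers = list(catalog.driver_genes)
        if not self.drivers:
            raise ValueError("catalog has no retained drivers")
        missing = [d for d in self.drivers if d not in sga.columns]
        if missing:
            raise ValueError(f"drivers absent from the SGA matrix: {missing}")
        self.tumor_ids = expression.index
        self._sga = sga.loc[self.tumor_ids, self.drivers].to_numpy(float)

        self._targets: list[list[str]] = []
        self._X: list[np.ndarray] = []
        for d in self.drivers:
            tg = [g for g in catalog.targets_of(d) if g in expression.columns]
            if not tg:
                raise ValueError(
                    f"driver {d} has no retained target in the expression matrix")
            self._targets.append(tg)
            self._X.append(expression[tg].to_numpy(float))

        # fitted state (set by initialize / the EM loop)
        self.priors_: np.ndarray | None = None
        self._mu1: list[np.ndarray] = []
        self._sd1: list[np.ndarray] = []
        self._mu0: list[np.ndarray] = []
        self._sd0: list[np.ndarray] = []
        self.posteriors_: np.ndarray | None = None
        self.states_: np.ndarray | None = None

    # -- parameter estimation ------------------------------------------------

    def _moments(self, x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
        """Weighted per-column mean/SD with pooled fallback when the
        effective count on a side is below 2."""
        n_eff = w.sum()
        if n_eff < 2.0:
            mu = x.mean(axis=0)
            sd = np.maximum(x.std(axis=0), self.sigma_min)
            return mu, sd, True
        mu = (w[:, None] * x).sum(axis=0) / n_eff
        var = (w[:, None] * (x - mu) ** 2).sum(axis=0) / n_eff
        return mu, np.maximum(np.sqrt(var), self.sigma_min), False

    def _estimate(self, weights: np.ndarray) -> None:
        """Per-driver priors (mean weight) and two-state emission moments."""
        self.priors_ = weights.mean(axis=0)
        self._mu1, self._sd1, self._mu0, self._sd0 = [], [], [], []
        fell_back = []
        for j, x in enumerate(self._X):
            w = weights[:, j]
            mu1, sd1, f1 = self._moments(x, w)
            mu0, sd0, f0 = self._moments(x, 1.0 - w)
            if f1 or f0:
                fell_back.append(self.drivers[j])
            self._mu1.append(mu1)
            self._sd1.append(sd1)
            self._mu0.append(mu0)
            self._sd0.append(sd0)
        if fell_back:
            log.warning("degenerate state partition for %d drivers "
                        "(pooled-moment fallback): %s", len(fell_back), fell_back)

    def initialize(self) -> "DriverActivationModel":
        """Start from the alteration status: PRO := SGA."""
        self.posteriors_ = self._sga.copy()
        self.states_ = self._sga.copy()
        self._estimate(self._sga)
        return self

    # -- EM steps ------------------------------------------------------------

    def _log_ratio(self, j: int) -> np.ndarray:
        """Sum over targets of log N(x; mu1, sd1) - log N(x; mu0, sd0)."""
        x = self._X[j]
        l1 = -np.log(self._sd1[j]) - 0.5 * ((x - self._mu1[j]) / self._sd1[j]) ** 2
        l0 = -np.log(self._sd0[j]) - 0.5 * ((x - self._mu0[j]) / self._sd0[j]) ** 2
        return (l1 - l0).sum(axis=1)

    def e_step(self) -> np.ndarray:
        """Posterior activation probabilities; discretised at >= 0.5."""
        if self.priors_ is None:
            raise RuntimeError("call initialize() first")
        n = self._sga.shape[0]
        post = np.empty((n, len(self.drivers)))
        for j in range(len(self.drivers)):
            p = self.priors_[j]
            if p <= 0.0:
                post[:, j] = 0.0
            elif p >= 1.0:
                post[:, j] = 1.0
            else:
                logit = np.log(p / (1.0 - p)) + self._log_ratio(j)
                post[:, j] = 1.0 / (1.0 + np.exp(-logit))
        if not np.isfinite(post).all():
            raise AssertionError("non-finite activation posterior")
        self.posteriors_ = post
        self.states_ = (post >= 0.5).astype(float)
        return post

    def m_step(self) -> "DriverActivationModel":
        """Re-estimate priors and emissions from the current states
        (hard mode) or posteriors (soft mode)."""
        w = self.states_ if self.mode == "hard" else self.posteriors_
        self._estimate(w)
        return self

    def loglik(self) -> float:
        """Observed-data log-likelihood under the current parameters."""
        total = 0.0
        for j in range(len(self.drivers)):
            x = self._X[j]
            l1 = (-np.log(self._sd1[j]) - 0.5 * _LOG2PI
                  - 0.5 * ((x - self._mu1[j]) / self._sd1[j]) ** 2).sum(axis=1)
            l0 = (-np.log(self._sd0[j]) - 0.5 * _LOG2PI
                  - 0.5 * ((x - self._mu0[j]) / self._sd0[j]) ** 2).sum(axis=1)
            p = np.clip(self.priors_[j], 1e-300, 1.0 - 1e-16)
            total += float(np.logaddexp(np.log(p) + l1, np.log1p(-p) + l0).sum())
        return total

    def fit(self) -> "ActivationResults":
        """Alternate E/M until the posteriors stabilise."""
        self.initialize()
        prev = self.posteriors_
        loglik_path: list[float] = []
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            post = self.e_step()
            loglik_path.append(self.loglik())
            if np.max(np.abs(post - prev)) < self.tol:
                converged = True
                break
            prev = post
            self.m_step()
        if not converged:
            log.warning("EM did not converge within %d iterations", self.max_iter)
        return ActivationResults(
            model=self,
            states_prob=pd.DataFrame(self.posteriors_, index=self.tumor_ids,
                                     columns=self.drivers),
            states=pd.DataFrame(self.states_.astype(np.int8), index=self.tumor_ids,
                                columns=self.drivers),
            priors=pd.Series(self.priors_, index=self.drivers, name="prior"),
            emissions=self._emissions_frame(),
            n_iterations=n_iter,
            converged=converged,
            loglik_path=loglik_path,
        )

    def _emissions_frame(self) -> pd.DataFrame:
        rows = []
        for j, d in enumerate(self.drivers):
            for k, g in enumerate(self._targets[j]):
                rows.append((d, g, self._mu1[j][k], self._sd1[j][k],
                             self._mu0[j][k], self._sd0[j][k]))
        return pd.DataFrame(rows, columns=["driver", "target", "mu1", "sigma1",
                                           "mu0", "sigma0"])


@dataclass
class ActivationResults:
    """Fitted activation states and emission parameters."""

    model: DriverActivationModel
    states_prob: pd.DataFrame = field(repr=False)
    states: pd.DataFrame = field(repr=False)
    priors: pd.Series = field(repr=False)
    emissions: pd.DataFrame = field(repr=False)
    n_iterations: int = 0
    converged: bool = False
    loglik_path: list[float] = field(default_factory=list, repr=False)

    @property
    def activation_rate(self) -> pd.Series:
        """Fraction of tumors in which each driver is inferred active."""
        return self.states.mean(axis=0)

    def to_tsv(self, prob_path: str | Path, binary_path: str | Path) -> None:
        self.states_prob.to_csv(prob_path, sep="\t", index_label="tumor_id")
        self.states.to_csv(binary_path, sep="\t", index_label="tumor_id")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.model.mode,
            "priors": {d: float(p) for d, p in self.priors.items()},
            "emissions": self.emissions.to_dict(orient="records"),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "loglik_path": self.loglik_path,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def summary(self) -> str:
        rate = self.activation_rate
        sga_rate = pd.Series(self.model._sga.mean(axis=0), index=self.states.columns)
        lines = [
            f"Driver activation states ({self.model.mode} EM)",
            f"  tumors:      {self.states.shape[0]}",
            f"  drivers:     {self.states.shape[1]}",
            f"  iterations:  {self.n_iterations} "
            f"({'converged' if self.converged else 'NOT converged'})",
            "  driver       SGA freq  activation rate",
        ]
        for d in self.states.columns:
            lines.append(f"    {d:<12} {sga_rate[d]:>6.3f}   {rate[d]:>6.3f}")
        return "\n".join(lines)
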