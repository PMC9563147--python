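"""Synthetic tumor cohorts with planted causal structure.

Every inference stage of the pipeline (causal arc scoring, driver
cataloguing, EM activation inference, subtyping, survival analysis) can be
tested against a cohort whose ground truth is known: a sparse planted
driver -> target-DEG bipartite graph, hidden per-tumor protein activation
states (SGA OR pathway crosstalk), state-conditional Gaussian expression,
and group-structured censored survival.

The generator emulates the structure of a TCGA-style cohort — a binary
tumors x genes somatic-genome-alteration (SGA) matrix, a continuous
tumors x genes log2 expression matrix, a matched normal-tissue expression
matrix, and a clinical table — without any real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "truth_catalog",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate a single-tissue TCGA-scale study: a few hundred
    tumors, a modest set of recurrent drivers each regulating a fixed
    number of target genes, a larger background of passenger alterations
    and unregulated noise genes, four molecular subtypes with distinct
    driver-frequency profiles, and exponential survival whose scale
    depends on subtype only (so subtype recovery and survival separation
    are independently testable).

    Parameters
    ----------
    n_tumors, n_drivers, n_passenger_sgas, n_target_degs_per_driver,
    n_noise_genes : int
        Cohort and gene-universe sizes. Target genes are disjoint across
        drivers, so the planted bipartite graph has exactly
        ``n_drivers * n_target_degs_per_driver`` edges.
    sga_freq_range : (float, float)
        Each altered gene draws its marginal cohort alteration frequency
        uniformly from this interval.
    crosstalk_rate : float
        Probability that a driver protein is active in a tumor lacking
        its SGA (pathway crosstalk), i.i.d. per tumor-driver.
    effect_size : float
        Standardised mean shift Delta(mu)/sigma of a target gene between
        the driver's active and inactive states.
    repress_frac : float
        Fraction of planted edges that are repressing (negative shift);
        the rest are activating.
    deg_sigma : float
        Emission standard deviation of every expression gene (log2 units).
    n_subtypes : int
        Number of planted molecular subtypes (equiprobable).
    subtype_assoc_strength : float in [0, 1]
        How strongly driver alteration frequency is concentrated in the
        driver's own subtype. 0 gives homogeneous Bernoulli(f_g) SGAs;
        the default 1 concentrates alterations maximally, giving each
        subtype a characteristic driver set (distinct activation-state
        profiles). The mixture preserves each gene's marginal frequency
        f_g exactly at any strength.
    survival_scale_per_subtype : tuple of float
        Exponential survival scale (days) per subtype; survival depends
        on the true subtype, not on activation states.
    censor_rate : float
        Probability a tumor's survival time is right-censored (censored
        times are drawn uniformly below the event time).
    n_normals : int
        Number of normal-tissue samples in the reference matrix.
    hpv_positive_frac : float
        Fraction of tumors carrying a binary clinical covariate
        (modelled on HPV status). When > 0 together with
        ``hpv_tied_drivers`` > 0, the crosstalk rate of the first
        ``hpv_tied_drivers`` drivers is raised to ``hpv_crosstalk_rate``
        in covariate-positive tumors — the "latent factor" mode in which
        a clinical factor activates driver proteins without altering
        their genes.
    seed : int
        Seed of the single numpy Generator; identical seeds give
        bit-identical cohorts.
    """

    n_tumors: int = 500
    n_drivers: int = 20
    n_passenger_sgas: int = 50
    n_target_degs_per_driver: int = 10
    n_noise_genes: int = 200
    sga_freq_range: tuple[float, float] = (0.2, 0.4)
    crosstalk_rate: float = 0.2
    effect_size: float = 2.0
    repress_frac: float = 0.3
    deg_sigma: float = 1.0
    n_subtypes: int = 4
    subtype_assoc_strength: float = 1.0
    survival_scale_per_subtype: tuple[float, ...] = (400.0, 400.0, 800.0, 1200.0)
    censor_rate: float = 0.2
    n_normals: int = 100
    hpv_positive_frac: float = 0.0
    hpv_tied_drivers: int = 0
    hpv_crosstalk_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumors", "n_drivers", "n_target_degs_per_driver",
                     "n_subtypes", "n_normals"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_passenger_sgas", "n_noise_genes", "hpv_tied_drivers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("crosstalk_rate", "censor_rate", "repress_frac",
                     "subtype_assoc_strength", "hpv_positive_frac",
                     "hpv_crosstalk_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        lo, hi = self.sga_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"invalid sga_freq_range {self.sga_freq_range}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.deg_sigma <= 0:
            raise ValueError("deg_sigma must be > 0")
        if len(self.survival_scale_per_subtype) != self.n_subtypes:
            raise ValueError("survival_scale_per_subtype length must equal n_subtypes")
        if any(s <= 0 for s in self.survival_scale_per_subtype):
            raise ValueError("survival scales must be positive")
        if self.hpv_tied_drivers > self.n_drivers:
            raise ValueError("hpv_tied_drivers cannot exceed n_drivers")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``true_protein_states`` satisfies state = SGA OR crosstalk, so every
    tumor with the driver's SGA has state 1. ``emission_params`` maps
    (driver, target) to the two-state Gaussian (mu0, mu1, sigma).
    """

    true_edges: set[tuple[str, str]]
    true_protein_states: pd.DataFrame
    true_subtype: pd.Series
    emission_params: dict[tuple[str, str], dict[str, float]]
    baseline_means: pd.Series = field(default=None)
    deg_sigma: float = 1.0

    @property
    def drivers(self) -> list[str]:
        return list(self.true_protein_states.columns)


class SyntheticCohort(NamedTuple):
    sga: pd.DataFrame
    expression: pd.DataFrame
    normals: pd.DataFrame
    clinical: pd.DataFrame
    truth: SyntheticTruth


def _subtype_freqs(f: float, k: int, strength: float) -> tuple[float, float]:
    """Per-tumor SGA probabilities (own-subtype, other-subtype) for a driver.

    Mixture preserves the marginal: pi*f_own + (1-pi)*f_other = f with
    pi = 1/k. ``strength`` in [0, 1] scales the contrast up to the largest
    delta keeping both probabilities in [0, 1].
    """
    if k == 1 or strength == 0.0:
        return f, f
    pi = 1.0 / k
    delta = strength * min((1.0 - f) / (1.0 - pi), f / pi)
    return f + (1.0 - pi) * delta, f - pi * delta


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one synthetic cohort. Deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_tumors

    tumor_ids = [f"T{i:04d}" for i in range(n)]
    drivers = [f"DRV{j:02d}" for j in range(cfg.n_drivers)]
    passengers = [f"PAS{j:02d}" for j in range(cfg.n_passenger_sgas)]
    targets = [f"TGT{j:03d}" for j in range(cfg.n_drivers * cfg.n_target_degs_per_driver)]
    noise = [f"NSE{j:03d}" for j in range(cfg.n_noise_genes)]
    expr_genes = targets + noise

    subtype = rng.integers(0, cfg.n_subtypes, size=n)

    lo, hi = cfg.sga_freq_range
    n_sga_genes = cfg.n_drivers + cfg.n_passenger_sgas
    freqs = rng.uniform(lo, hi, size=n_sga_genes)

    sga = np.zeros((n, n_sga_genes), dtype=np.int8)
    for j in range(cfg.n_drivers):
        own = j % cfg.n_subtypes
        f_own, f_other = _subtype_freqs(freqs[j], cfg.n_subtypes,
                                        cfg.subtype_assoc_strength)
        p = np.where(subtype == own, f_own, f_other)
        sga[:, j] = rng.random(n) < p
    for j in range(cfg.n_drivers, n_sga_genes):
        sga[:, j] = rng.random(n) < freqs[j]

    # clinical covariate (HPV-like), possibly tied to crosstalk below
    hpv_pos = rng.random(n) < cfg.hpv_positive_frac

    # protein state = SGA OR crosstalk
    cross_p = np.full((n, cfg.n_drivers), cfg.crosstalk_rate)
    if cfg.hpv_tied_drivers > 0 and cfg.hpv_positive_frac > 0:
        cross_p[hpv_pos, : cfg.hpv_tied_drivers] = cfg.hpv_crosstalk_rate
    crosstalk = rng.random((n, cfg.n_drivers)) < cross_p
    states = (sga[:, : cfg.n_drivers].astype(bool) | crosstalk).astype(np.int8)

    # expression: baseline means heterogeneous across genes
    mu0 = rng.normal(0.0, 1.0, size=len(expr_genes))
    sigma = cfg.deg_sigma
    edge_sign = np.where(rng.random(len(targets)) < cfg.repress_frac, -1.0, 1.0)

    expr = mu0[None, :] + rng.normal(0.0, sigma, size=(n, len(expr_genes)))
    true_edges: set[tuple[str, str]] = set()
    emission: dict[tuple[str, str], dict[str, float]] = {}
    m = cfg.n_target_degs_per_driver
    for j, drv in enumerate(drivers):
        cols = np.arange(j * m, (j + 1) * m)
        shift = edge_sign[cols] * cfg.effect_size * sigma
        expr[:, cols] += states[:, j][:, None] * shift[None, :]
        for c in cols:
            g = expr_genes[c]
            true_edges.add((drv, g))
            emission[(drv, g)] = {
                "mu0": float(mu0[c]),
                "mu1": float(mu0[c] + edge_sign[c] * cfg.effect_size * sigma),
                "sigma": float(sigma),
            }

    normals = mu0[None, :] + rng.normal(0.0, sigma, size=(cfg.n_normals, len(expr_genes)))

    # survival from the true subtype
    scales = np.asarray(cfg.survival_scale_per_subtype)[subtype]
    event_time = rng.exponential(scales)
    censored = rng.random(n) < cfg.censor_rate
    obs_time = np.where(censored, rng.uniform(0.0, event_time), event_time)
    event = (~censored).astype(int)

    t_index = pd.Index(tumor_ids, name="tumor_id")
    sga_df = pd.DataFrame(sga, index=t_index, columns=drivers + passengers)
    expr_df = pd.DataFrame(expr, index=t_index, columns=expr_genes)
    normals_df = pd.DataFrame(
        normals,
        index=pd.Index([f"N{i:04d}" for i in range(cfg.n_normals)], name="sample_id"),
        columns=expr_genes,
    )
    clinical = pd.DataFrame(
        {
            "tumor_id": tumor_ids,
            "time_days": obs_time,
            "event": event,
            "hpv_status": np.where(hpv_pos, "positive", "negative"),
        }
    )
    truth = SyntheticTruth(
        true_edges=true_edges,
        true_protein_states=pd.DataFrame(states, index=t_index, columns=drivers),
        true_subtype=pd.Series(subtype + 1, index=t_index, name="subtype"),
        emission_params=emission,
        baseline_means=pd.Series(mu0, index=expr_genes, name="mean"),
        deg_sigma=sigma,
    )
    return SyntheticCohort(sga_df, expr_df, normals_df, clinical, truth)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort as TSV matrices + clinical CSV + truth JSON.

    Round-trips exactly through :func:`read_cohort`.
    """
    if len(cohort.sga.index) == 0:
        raise ValueError("refusing to write an empty cohort (0 tumors)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sga": out / "sga.tsv",
        "expression": out / "expression.tsv",
        "normals": out / "normals.tsv",
        "clinical": out / "clinical.csv",
        "truth": out / "truth.json",
    }
    cohort.sga.to_csv(paths["sga"], sep="\t", index_label="tumor_id")
    cohort.expression.to_csv(paths["expression"], sep="\t", index_label="tumor_id")
    cohort.normals.to_csv(paths["normals"], sep="\t", index_label="sample_id")
    cohort.clinical.to_csv(paths["clinical"], index=False)
    t = cohort.truth
    payload = {
        "true_edges": sorted(list(e) for e in t.true_edges),
        "drivers": list(t.true_protein_states.columns),
        "tumor_ids": list(t.true_protein_states.index),
        "true_protein_states": t.true_protein_states.values.astype(int).tolist(),
        "true_subtype": t.true_subtype.astype(int).tolist(),
        "emission_params": {f"{d}->{g}": p for (d, g), p in t.emission_params.items()},
        "baseline_means": {g: float(v) for g, v in t.baseline_means.items()},
        "deg_sigma": t.deg_sigma,
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths


def read_cohort(out_dir: str | Path) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    out = Path(out_dir)
    sga = pd.read_csv(out / "sga.tsv", sep="\t", index_col="tumor_id")
    expr = pd.read_csv(out / "expression.tsv", sep="\t", index_col="tumor_id")
    normals = pd.read_csv(out / "normals.tsv", sep="\t", index_col="sample_id")
    clinical = pd.read_csv(out / "clinical.csv")
    payload = json.loads((out / "truth.json").read_text())
    states = pd.DataFrame(
        np.asarray(payload["true_protein_states"], dtype=np.int8),
        index=pd.Index(payload["tumor_ids"], name="tumor_id"),
        columns=payload["drivers"],
    )
    truth = SyntheticTruth(
        true_edges={tuple(e) for e in payload["true_edges"]},
        true_protein_states=states,
        true_subtype=pd.Series(payload["true_subtype"], index=payload["tumor_ids"],
                               name="subtype"),
        emission_params={
            tuple(k.split("->")): v for k, v in payload["emission_params"].items()
        },
        baseline_means=pd.Series(payload["baseline_means"], name="mean"),
        deg_sigma=payload["deg_sigma"],
    )
    return SyntheticCohort(sga, expr, normals, clinical, truth)


def truth_catalog(truth: SyntheticTruth, sga: pd.DataFrame | None = None):
    """Build a :class:`~tcistate.catalog.DriverCatalog` from planted edges.

    Lets the EM activation stage (and downstream stages) run against the
    known regulatory structure, isolating them from causal-discovery error.
    """
    from .catalog import DriverCatalog

    drivers = truth.drivers
    targets = sorted({g for _, g in truth.true_edges})
    n_host = (
        sga[drivers].sum(axis=0).astype(int)
        if sga is not None
        else pd.Series(0, index=drivers)
    )
    drv_df = pd.DataFrame(
        {
            "n_hosting": [int(n_host[d]) for d in drivers],
            "n_called": [int(n_host[d]) for d in drivers],
            "call_rate": 1.0,
        },
        index=pd.Index(drivers, name="gene"),
    )
    deg_df = pd.DataFrame(
        {"n_deg": 0, "n_targeted": 0, "call_rate": 1.0},
        index=pd.Index(targets, name="gene"),
    )
    edges = pd.DataFrame(
        sorted(truth.true_edges), columns=["driver", "target"]
    )
    edges["support"] = 0
    return DriverCatalog(drivers=drv_df, target_degs=deg_df, retained_edges=edges)
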