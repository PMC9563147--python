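"""Cohort-level driver and target-DEG catalog from per-tumor causal arcs.

An SGA is designated a driver *in a tumor* when it is the posterior-
winning cause of at least ``min_edges`` DEGs, each with edge p-value at
or below ``p_cutoff``. Cohort-level retention then applies two call-rate
filters: the driver call rate (fraction of SGA-hosting tumors in which
the gene was designated a driver) and, against the already-retained
driver set, the DEG call rate (fraction of DEG-hosting tumors in which
the gene was a retained driver's winning target). Both default to the
inclusive >= 0.5 cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .tci import A0

__all__ = ["DriverCatalog", "designate_tumor_drivers", "build_catalog"]


@dataclass
class DriverCatalog:
    """Retained drivers, retained target DEGs, and the edges between them.

    ``drivers`` and ``target_degs`` are DataFrames indexed by gene with
    hosting/called counts and call rates; ``retained_edges`` has columns
    driver, target, support (number of tumors in which the pair was a
    qualifying winning arc).
    """

    drivers: pd.DataFrame
    target_degs: pd.DataFrame
    retained_edges: pd.DataFrame

    @property
    def driver_genes(self) -> list[str]:
        return list(self.drivers.index)

    @property
    def target_genes(self) -> list[str]:
        return list(self.target_degs.index)

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.retained_edges["driver"], self.retained_edges["target"]))

    def targets_of(self, driver: str) -> list[str]:
        e = self.retained_edges
        return sorted(e.loc[e["driver"] == driver, "target"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "drivers": self.drivers.reset_index().to_dict(orient="records"),
            "target_degs": self.target_degs.reset_index().to_dict(orient="records"),
            "retained_edges": self.retained_edges.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DriverCatalog":
        payload = json.loads(Path(path).read_text())
        drivers = pd.DataFrame(payload["drivers"]).set_index("gene")
        degs = pd.DataFrame(payload["target_degs"]).set_index("gene")
        edges = pd.DataFrame(payload["retained_edges"],
                             columns=["driver", "target", "support"])
        return cls(drivers=drivers, target_degs=degs, retained_edges=edges)

    def to_tsv(self, drivers_path: str | Path, degs_path: str | Path,
               edges_path: str | Path) -> None:
        self.drivers.to_csv(drivers_path, sep="\t", index_label="gene")
        self.target_degs.to_csv(degs_path, sep="\t", index_label="gene")
        self.retained_edges.to_csv(edges_path, sep="\t", index=False)

    def summary(self) -> str:
        return "\n".join([
            "Driver catalog",
            f"  retained drivers:     {len(self.drivers)}",
            f"  retained target DEGs: {len(self.target_degs)}",
            f"  retained edges:       {len(self.retained_edges)}",
        ])


def designate_tumor_drivers(tumor_arcs: pd.DataFrame, min_edges: int = 5,
                            p_cutoff: float = 0.05) -> set[str]:
    """Driver designations for one tumor's winning-arc table.

    A gene qualifies iff it wins >= ``min_edges`` arcs with
    edge_p <= ``p_cutoff`` in that tumor; A0 never qualifies.
    """
    q = tumor_arcs[(tumor_arcs["edge_p"] <= p_cutoff) & (tumor_arcs["cause"] != A0)]
    counts = q["cause"].value_counts()
    return set(counts.index[counts >= min_edges])


def build_catalog(arcs: pd.DataFrame, sga: pd.DataFrame, deg: pd.DataFrame,
                  min_edges: int = 5, p_cutoff: float = 0.05,
                  rate_cutoff: float = 0.5) -> DriverCatalog:
    """Apply the call-rate filters to a cohort's winning arcs.

    Two-pass: drivers are retained first (driver call rate >=
    ``rate_cutoff`` among hosting tumors); DEG call rates are then
    computed against that retained driver set only.
    """
    qualifying = arcs[(arcs["edge_p"] <= p_cutoff) & (arcs["cause"] != A0)]

    # pass 1: per-tumor driver designation, then the driver call rate
    per_tumor = qualifying.groupby(["tumor_id", "cause"]).size()
    called = per_tumor[per_tumor >= min_edges].reset_index(name="n_arcs")
    n_called = called.groupby("cause").size()
    n_hosting = sga.sum(axis=0).astype(int)

    rows = []
    for gene, n_c in n_called.items():
        host = int(n_hosting.get(gene, 0))
        if host == 0:  # never hosted: cannot enter the catalog
            continue
        rows.append((gene, host, int(n_c), n_c / host))
    drv = pd.DataFrame(rows, columns=["gene", "n_hosting", "n_called", "call_rate"])
    drv = drv[drv["call_rate"] >= rate_cutoff].sort_values("gene").set_index("gene")

    # pass 2: DEG call rate against retained drivers only
    retained = set(drv.index)
    driver_arcs = qualifying[qualifying["cause"].isin(retained)]

    n_deg = deg.sum(axis=0).astype(int)
    n_targeted = driver_arcs.groupby("effect")["tumor_id"].nunique()
    rows = []
    for gene, n_t in n_targeted.items():
        denom = int(n_deg.get(gene, 0))
        if denom == 0:
            continue
        rows.append((gene, denom, int(n_t), n_t / denom))
    degs = pd.DataFrame(rows, columns=["gene", "n_deg", "n_targeted", "call_rate"])
    degs = degs[degs["call_rate"] >= rate_cutoff].sort_values("gene").set_index("gene")

    kept_degs = set(degs.index)
    edges = (
        driver_arcs[driver_arcs["effect"].isin(kept_degs)]
        .groupby(["cause", "effect"]).size().reset_index(name="support")
        .rename(columns={"cause": "driver", "effect": "target"})
        .sort_values(["driver", "target"], ignore_index=True)
    )
    return DriverCatalog(drivers=drv, target_degs=degs, retained_edges=edges)
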