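"""Building and reading the pipeline's matrices.

The binary somatic-genome-alteration (SGA) matrix merges a mutation call
table with thresholded copy-number calls (a gene is altered in a tumor if
it carries a mutation event and/or a copy-number event). Differentially
expressed genes (DEGs) are called per tumor against a per-gene Gaussian
null estimated from normal tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

VALID_CN_CALLS = {-2, -1, 0, 1, 2}
DEFAULT_ALTERATION_CALLS = frozenset({-2, 2})

__all__ = [
    "NormalReference",
    "build_sga_matrix",
    "call_degs",
    "read_matrix",
    "write_matrix",
    "read_maf",
    "read_gistic",
]


def read_matrix(path: str | Path, index_col: str = "tumor_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "tumor_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_maf(path: str | Path, variant_filter: dict[str, set] | None = None) -> pd.DataFrame:
    """Read a MAF-like TSV into a (tumor, gene) mutation table.

    Requires columns ``Tumor_Sample_Barcode`` and ``Hugo_Symbol``; all
    other columns are ignored unless named in ``variant_filter``, a
    mapping column -> allowed values applied as a row filter (e.g.
    restricting ``Variant_Classification`` to non-silent classes).
    """
    maf = pd.read_csv(path, sep="\t", comment="#", low_memory=False)
    for col in ("Tumor_Sample_Barcode", "Hugo_Symbol"):
        if col not in maf.columns:
            raise ValueError(f"MAF file {path} lacks required column {col!r}")
    if variant_filter:
        for col, allowed in variant_filter.items():
            maf = maf[maf[col].isin(allowed)]
    return maf.rename(
        columns={"Tumor_Sample_Barcode": "tumor", "Hugo_Symbol": "gene"}
    )[["tumor", "gene"]]


def read_gistic(path: str | Path) -> pd.DataFrame:
    """Read a GISTIC2 'all_thresholded.by_genes'-style TSV (genes x samples)
    into a long (tumor, gene, call) table."""
    wide = pd.read_csv(path, sep="\t", index_col=0)
    # drop non-sample annotation columns GISTIC2 emits
    for col in ("Locus ID", "Cytoband", "Gene ID"):
        if col in wide.columns:
            wide = wide.drop(columns=col)
    long = wide.reset_index(names="gene").melt(
        id_vars="gene", var_name="tumor", value_name="call"
    )
    long["call"] = long["call"].astype(int)
    return long[["tumor", "gene", "call"]]


def build_sga_matrix(
    mutations: pd.DataFrame,
    cn_calls: pd.DataFrame,
    alteration_calls: set[int] | frozenset[int] = DEFAULT_ALTERATION_CALLS,
) -> pd.DataFrame:
    """Merge mutation events and copy-number events into a binary SGA matrix.

    Parameters
    ----------
    mutations : DataFrame with columns ``tumor``, ``gene``
        One row per somatic mutation event (duplicates are fine).
    cn_calls : DataFrame with columns ``tumor``, ``gene``, ``call``
        GISTIC2-thresholded integer calls in {-2, -1, 0, 1, 2}.
    alteration_calls : set of int
        Which calls count as a copy-number alteration event. The default
        {-2, 2} keeps only deep deletions and high-level amplifications.

    Returns
    -------
    DataFrame of 0/1 over the union of tumors and genes; an entry is 1
    iff the gene has a mutation event or a qualifying copy-number event
    in that tumor.
    """
    if len(mutations) == 0 and len(cn_calls) == 0:
        raise ValueError("both input tables are empty")
    if not set(alteration_calls) <= VALID_CN_CALLS:
        raise ValueError(f"alteration_calls must be within {sorted(VALID_CN_CALLS)}")
    bad = set(cn_calls["call"].unique()) - VALID_CN_CALLS
    if bad:
        raise ValueError(f"unknown copy-number call values: {sorted(bad)}")

    cn_events = cn_calls[cn_calls["call"].isin(alteration_calls)]
    tumors = sorted(set(mutations["tumor"]).union(cn_calls["tumor"]))
    genes = sorted(set(mutations["gene"]).union(cn_calls["gene"]))

    only_mut = set(mutations["tumor"]) - set(cn_calls["tumor"])
    only_cn = set(cn_calls["tumor"]) - set(mutations["tumor"])
    if len(cn_calls) and only_mut:
        log.info("%d tumors present only in the mutation table (zeros elsewhere)",
                 len(only_mut))
    if len(mutations) and only_cn:
        log.info("%d tumors present only in the copy-number table (zeros elsewhere)",
                 len(only_cn))

    mat = pd.DataFrame(0, index=tumors, columns=genes, dtype=np.int8)
    for table in (mutations[["tumor", "gene"]], cn_events[["tumor", "gene"]]):
        if len(table):
            t_idx = mat.index.get_indexer(table["tumor"])
            g_idx = mat.columns.get_indexer(table["gene"])
            mat.values[t_idx, g_idx] = 1
    mat.index.name = "tumor_id"
    return mat


@dataclass
class NormalReference:
    """Per-gene Gaussian null of log2 expression in normal tissue."""

    means: pd.Series
    sds: pd.Series
    sigma_floor: float = 1e-6
    floored_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = self.means.astype(float)
        sds = self.sds.astype(float)
        low = sds < self.sigma_floor
        if low.any():
            self.floored_genes = list(sds.index[low])
            log.warning("flooring SD of %d genes to %g", int(low.sum()),
                        self.sigma_floor)
            sds = sds.clip(lower=self.sigma_floor)
        self.sds = sds

    @classmethod
    def from_normal_matrix(cls, normals: pd.DataFrame,
                           sigma_floor: float = 1e-6) -> "NormalReference":
        """Estimate per-gene mean/SD from a normal-sample expression matrix."""
        return cls(means=normals.mean(axis=0), sds=normals.std(axis=0, ddof=1),
                   sigma_floor=sigma_floor)

    @property
    def genes(self) -> pd.Index:
        return self.means.index


def call_degs(
    tumors: pd.DataFrame,
    ref: NormalReference,
    p_threshold: float = 0.005,
) -> pd.DataFrame:
    """Call per-tumor differentially expressed genes against the normal null.

    An entry is 1 iff the two-sided Gaussian tail probability of the
    tumor's log2 value under Normal(mean_g, sd_g) is strictly below
    ``p_threshold``. Both over- and under-expression qualify. Genes
    absent from the reference are dropped with a warning.
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    missing = tumors.columns.difference(ref.genes)
    if len(missing):
        log.warning("dropping %d tumor genes absent from the normal reference",
                    len(missing))
    genes = tumors.columns.intersection(ref.genes)
    x = tumors[genes].to_numpy(float)
    z = (x - ref.means[genes].to_numpy()) / ref.sds[genes].to_numpy()
    p = 2.0 * stats.norm.sf(np.abs(z))
    deg = pd.DataFrame((p < p_threshold).astype(np.int8),
                       index=tumors.index, columns=genes)
    deg.index.name = "tumor_id"
    return deg
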