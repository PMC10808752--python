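"""cis-instrument selection: window filter, p-value threshold, LD clumping.

Instruments for a protein are cis-SNPs within a fixed window of the encoding
gene, associated with protein level below a p-value threshold, and pruned to
approximate pairwise independence by greedy LD clumping (keep the smallest-p
variant, remove its LD partners, repeat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import GeneAnnotation

log = logging.getLogger(__name__)

CIS_WINDOW_BP = 1_000_000
P_THRESHOLD = 1e-5
R2_THRESHOLD = 0.01
CLUMP_WINDOW_BP = 10_000_000


@dataclass
class LDMatrix:
    """Pairwise Pearson correlations of allele dosages for an ordered set
    of variants (symmetric, unit diagonal, entries in [-1, 1])."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match "
                             f"{k} variant ids")
        if k and not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if k and not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal is not 1")
        if k and (np.abs(self.r) > 1 + 1e-8).any():
            raise ValueError("LD entries outside [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)

    def subset(self, ids: list[str]) -> "LDMatrix":
        idx = [self._index[v] for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(float))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r, index=self.variant_ids,
                     columns=self.variant_ids).to_csv(path, sep="\t",
                                                      float_format="%.10g")


def ld_from_genotypes(G: np.ndarray, variant_ids: list[str]) -> LDMatrix:
    """Pearson-correlation LD from a samples x variants dosage matrix.

    Raises on monomorphic columns (zero variance), naming the variant.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("need a 2-D dosage matrix with >= 2 samples")
    if G.shape[1] != len(variant_ids):
        raise ValueError("variant_ids length does not match matrix columns")
    sd = G.std(axis=0)
    mono = np.flatnonzero(sd == 0)
    if mono.size:
        names = [variant_ids[i] for i in mono[:5]]
        raise ValueError(f"monomorphic variant(s) in LD reference: {names}")
    r = np.corrcoef(G, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(list(variant_ids), r)


def read_genotype_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a samples x variants dosage TSV (header = variant ids)."""
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(float), [str(c) for c in df.columns]


def cis_filter(table: pd.DataFrame, gene: GeneAnnotation,
               window_bp: int = CIS_WINDOW_BP) -> pd.DataFrame:
    """Keep variants on the gene's chromosome within gene body +/- window."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    keep = ((table["chrom"].astype(str) == str(gene.chrom))
            & (table["pos"] >= gene.start - window_bp)
            & (table["pos"] <= gene.end + window_bp))
    return table[keep].reset_index(drop=True)


def pvalue_filter(table: pd.DataFrame, p_threshold: float = P_THRESHOLD,
                  col: str = "pval") -> pd.DataFrame:
    """Keep rows with p strictly below the threshold."""
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    return table[table[col] < p_threshold].reset_index(drop=True)


def restrict_to_ld(table: pd.DataFrame, ld: LDMatrix) -> pd.DataFrame:
    """Drop variants absent from the LD reference, with a logged warning.

    Assuming independence for unseen variants would be anti-conservative, so
    they are removed before clumping.
    """
    present = table["variant_id"].map(lambda v: v in ld)
    n_miss = int((~present).sum())
    if n_miss:
        log.warning("restrict_to_ld: dropped %d variant(s) absent from the "
                    "LD reference", n_miss)
    return table[present].reset_index(drop=True)


@dataclass
class InstrumentSet:
    """Post-clumping independent instruments for one protein."""

    protein_id: str
    table: pd.DataFrame
    ld: LDMatrix
    selection_log: list[dict] = field(default_factory=list)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["variant_id"])

    def __len__(self) -> int:
        return len(self.table)


def clump(table: pd.DataFrame, ld: LDMatrix,
          r2_threshold: float = R2_THRESHOLD,
          window_bp: int = CLUMP_WINDOW_BP,
          protein_id: str = "", pval_col: str = "pval") -> InstrumentSet:
    """Greedy LD clumping by ascending p-value.

    Repeatedly keep the smallest-p remaining variant (ties broken by
    lexicographic variant_id) and remove all others within ``window_bp``
    whose r^2 with it is >= ``r2_threshold``.  Pairs farther apart than the
    window are never pruned regardless of r^2.

    Every variant in ``table`` must be present in ``ld`` (use
    :func:`restrict_to_ld` first to drop unknowns); a missing variant raises.
    """
    missing = [v for v in table["variant_id"] if v not in ld]
    if missing:
        raise KeyError(f"variant(s) missing from LD matrix: {missing[:5]}")

    order = table.sort_values([pval_col, "variant_id"],
                              kind="mergesort").reset_index(drop=True)
    removed: set[str] = set()
    kept: list[str] = []
    sel_log: list[dict] = []
    pos = dict(zip(order["variant_id"], order["pos"]))

    for row in order.itertuples(index=False):
        v = row.variant_id
        if v in removed:
            continue
        kept.append(v)
        sel_log.append({"variant_id": v, "action": "keep",
                        "index_variant": v, "r2": 1.0})
        for other in order["variant_id"]:
            if other == v or other in removed or other in kept:
                continue
            if abs(pos[other] - pos[v]) > window_bp:
                continue
            r2 = ld.r2(v, other)
            if r2 >= r2_threshold:
                removed.add(other)
                sel_log.append({"variant_id": other, "action": "remove",
                                "index_variant": v, "r2": r2})

    kept_tab = (table[table["variant_id"].isin(kept)]
                .sort_values([pval_col, "variant_id"], kind="mergesort")
                .reset_index(drop=True))
    result = InstrumentSet(protein_id, kept_tab, ld.subset(kept), sel_log)

    # Postcondition: all pairwise r^2 among kept in-window variants below
    # threshold.
    sub = result.ld.r ** 2
    kpos = kept_tab["pos"].to_numpy()
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            if abs(int(kpos[i]) - int(kpos[j])) <= window_bp:
                assert sub[i, j] < r2_threshold, (
                    f"clump postcondition violated for "
                    f"{kept[i]}/{kept[j]}: r2={sub[i, j]}")
    return result
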