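"""GWAS/pQTL summary-statistics I/O and allele harmonization.

A summary-statistics table is a :class:`pandas.DataFrame` with one row per
variant and the canonical columns in :data:`COLUMNS`.  ``eaf``, ``n``,
``ncase`` and ``ncontrol`` are optional (NaN where unknown).  Effects are per
copy of ``effect_allele``: log-odds for binary traits, SD units for
standardized quantitative traits.  Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Canonical column order.  The first nine are mandatory on read
#: (``eaf`` may be empty but the column must exist after dialect mapping
#: unless listed in the dialect as absent).
COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "ncase", "ncontrol",
]

MANDATORY = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
             "beta", "se", "pval"]

OPTIONAL = ["eaf", "n", "ncase", "ncontrol"]

#: Built-in column-name dialects, mapping canonical -> file column name.
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {c: c for c in COLUMNS},
    "finngen-like": {
        "variant_id": "rsids", "chrom": "#chrom", "pos": "pos",
        "effect_allele": "alt", "other_allele": "ref", "eaf": "af_alt",
        "beta": "beta", "se": "sebeta", "pval": "pval",
    },
    "decode-like": {
        "variant_id": "Name", "chrom": "Chrom", "pos": "Pos",
        "effect_allele": "effectAllele", "other_allele": "otherAllele",
        "eaf": "ImpFreq", "beta": "Beta", "se": "SE", "pval": "Pval",
        "n": "N",
    },
}

_PALINDROMES = {frozenset("AT"), frozenset("CG")}


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic footprint of the gene encoding a protein (1-based inclusive)."""

    gene_id: str
    protein_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}")


def read_gene_annotations(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a BED-like (but 1-based, inclusive) gene annotation TSV.

    Columns: gene_id, protein_id, chrom, start, end, strand.
    Returns a mapping protein_id -> :class:`GeneAnnotation`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        g = GeneAnnotation(str(row.gene_id), str(row.protein_id),
                           str(row.chrom), int(row.start), int(row.end),
                           str(getattr(row, "strand", "+")))
        out[g.protein_id] = g
    return out


def write_gene_annotations(genes: Mapping[str, GeneAnnotation],
                           path: str | Path) -> None:
    rows = [(g.gene_id, g.protein_id, g.chrom, g.start, g.end, g.strand)
            for g in genes.values()]
    pd.DataFrame(rows, columns=["gene_id", "protein_id", "chrom", "start",
                                "end", "strand"]).to_csv(
        path, sep="\t", index=False)


def _resolve_dialect(dialect: str | Mapping[str, str]) -> Mapping[str, str]:
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise ValueError(
                f"unknown dialect {dialect!r}; built-ins: {sorted(DIALECTS)}"
            ) from None
    return dialect


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce types and drop rows violating the record invariants.

    Dropped rows are counted per reason in ``result.attrs['drop_reasons']``
    (a Counter) and logged.  Invariants: se > 0, 0 < pval <= 1, pos >= 1,
    effect_allele != other_allele, eaf (when present) strictly in (0, 1).
    """
    df = df.copy()
    for c in OPTIONAL:
        if c not in df.columns:
            df[c] = np.nan
    for c in ["pos", "eaf", "beta", "se", "pval", "n", "ncase", "ncontrol"]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper()

    reasons = Counter()

    def _flag(mask: pd.Series, reason: str) -> pd.Series:
        n = int(mask.sum())
        if n:
            reasons[reason] += n
        return mask

    bad = _flag(df[["pos", "beta", "se", "pval"]].isna().any(axis=1),
                "unparseable_numeric")
    bad |= _flag(~bad & (df["se"] <= 0), "nonpositive_se")
    bad |= _flag(~bad & ((df["pval"] <= 0) | (df["pval"] > 1)),
                 "pval_out_of_range")
    bad |= _flag(~bad & (df["pos"] < 1), "nonpositive_pos")
    bad |= _flag(~bad & (df["effect_allele"] == df["other_allele"]),
                 "identical_alleles")
    bad |= _flag(~bad & df["eaf"].notna() & ~df["eaf"].between(
        0, 1, inclusive="neither"), "eaf_out_of_range")

    clean = df.loc[~bad, COLUMNS].reset_index(drop=True)
    clean["pos"] = clean["pos"].astype(np.int64)
    for c in ["eaf", "beta", "se", "pval", "n", "ncase", "ncontrol"]:
        clean[c] = clean[c].astype(float)
    clean.attrs["n_dropped"] = int(bad.sum())
    clean.attrs["drop_reasons"] = reasons
    if bad.any():
        log.info("validate_sumstats: dropped %d/%d rows (%s)",
                 bad.sum(), len(df), dict(reasons))
    return clean


def read_sumstats(path: str | Path,
                  dialect: str | Mapping[str, str] = "generic"
                  ) -> pd.DataFrame:
    """Read a delimited summary-statistics file into the canonical frame.

    ``dialect`` maps canonical column names to the file's column names
    (string presets: "generic", "finngen-like", "decode-like").  gzip is
    handled transparently by pandas via the file extension.

    Raises :class:`KeyError` if a mandatory mapped column is missing.
    Rows failing the record invariants are dropped and counted
    (``df.attrs['n_dropped']``).
    """
    mapping = _resolve_dialect(dialect)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [mapping[c] for c in MANDATORY
               if c in mapping and mapping[c] not in raw.columns]
    if missing:
        raise KeyError(f"{path}: missing mandatory column(s) {missing}")
    renamed = raw.rename(columns={v: k for k, v in mapping.items()
                                  if v in raw.columns})
    return validate_sumstats(renamed)


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical frame as TSV (gzip by extension).

    Floats use repr-level precision so that read∘write is the identity on
    valid tables.
    """
    out = df.reindex(columns=COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    """A/T and C/G allele pairs cannot be strand-resolved from labels."""
    pairs = [frozenset((a, b)) for a, b in zip(ea, oa)]
    return pd.Series([p in _PALINDROMES for p in pairs], index=ea.index)


PAIR_COLUMNS = [
    "variant_id", "chrom", "pos", "aligned_allele", "other_allele",
    "beta_exp", "se_exp", "pval_exp", "eaf_exp",
    "beta_out", "se_out", "pval_out", "eaf_out",
    "flipped", "palindromic",
]


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindromic_policy: str = "drop",
              eaf_ambiguous_band: tuple[float, float] = (0.42, 0.58),
              ) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele per variant.

    Returns one row per variant present in both tables with reconcilable
    alleles.  When the outcome's effect/other alleles are swapped relative to
    the exposure, ``beta_out`` is negated, ``eaf_out`` reflected, and
    ``flipped`` set.  Palindromic (A/T, C/G) variants are dropped under
    policy ``"drop"`` (default); under ``"keep_if_eaf_informative"`` they are
    kept and oriented by allele frequency if both eafs lie outside the
    ambiguous band, else dropped.

    An empty intersection returns an empty frame with a logged warning.
    """
    if palindromic_policy not in ("drop", "keep_if_eaf_informative"):
        raise ValueError(f"unknown palindromic policy {palindromic_policy!r}")
    lo, hi = eaf_ambiguous_band

    m = exposure.merge(outcome, on="variant_id", suffixes=("_exp", "_out"))
    if m.empty:
        log.warning("harmonize: no shared variants between exposure and "
                    "outcome tables")
        return pd.DataFrame(columns=PAIR_COLUMNS)

    ea_e, oa_e = m["effect_allele_exp"], m["other_allele_exp"]
    ea_o, oa_o = m["effect_allele_out"], m["other_allele_out"]
    same = (ea_e == ea_o) & (oa_e == oa_o)
    swapped = (ea_e == oa_o) & (oa_e == ea_o) & ~same
    pal = is_palindromic(ea_e, oa_e)

    keep = (same | swapped).to_numpy(bool)
    beta_out = np.where(swapped, -m["beta_out"], m["beta_out"])
    eaf_out = np.where(swapped, 1.0 - m["eaf_out"], m["eaf_out"])
    flipped = swapped.to_numpy(bool).copy()

    if palindromic_policy == "drop":
        keep &= ~pal.to_numpy(bool)
    else:
        # For palindromic variants the allele labels are strand-ambiguous:
        # re-orient purely from eaf concordance after the label alignment.
        eaf_e = m["eaf_exp"].to_numpy(float)
        informative = (np.isfinite(eaf_e) & np.isfinite(eaf_out)
                       & ((eaf_e < lo) | (eaf_e > hi))
                       & ((eaf_out < lo) | (eaf_out > hi)))
        discordant = ((eaf_e < lo) & (eaf_out > hi)) | \
                     ((eaf_e > hi) & (eaf_out < lo))
        palv = pal.to_numpy(bool)
        keep &= ~palv | informative
        refl = palv & informative & discordant
        beta_out = np.where(refl, -beta_out, beta_out)
        eaf_out = np.where(refl, 1.0 - eaf_out, eaf_out)
        flipped ^= refl

    n_irrec = int((~(same | swapped)).sum())
    if n_irrec:
        log.info("harmonize: %d variant(s) with irreconcilable alleles "
                 "excluded", n_irrec)

    out = pd.DataFrame({
        "variant_id": m["variant_id"],
        "chrom": m["chrom_exp"],
        "pos": m["pos_exp"],
        "aligned_allele": ea_e,
        "other_allele": oa_e,
        "beta_exp": m["beta_exp"].astype(float),
        "se_exp": m["se_exp"].astype(float),
        "pval_exp": m["pval_exp"].astype(float),
        "eaf_exp": m["eaf_exp"].astype(float),
        "beta_out": beta_out.astype(float),
        "se_out": m["se_out"].astype(float),
        "pval_out": m["pval_out"].astype(float),
        "eaf_out": eaf_out.astype(float),
        "flipped": flipped,
        "palindromic": pal.to_numpy(bool),
    })[keep].reset_index(drop=True)
    if out.empty:
        log.warning("harmonize: no harmonizable variants remained")
    return out
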