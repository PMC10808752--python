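"""Discovery -> FDR -> replication -> sensitivity -> colocalization -> tiers.

The study design: screen every protein in a pQTL panel against the outcome
with IVW cis-MR, control the family with Benjamini-Hochberg FDR (< 0.05),
re-estimate the significant proteins from an independent replication panel
with four estimators, run heterogeneity/pleiotropy sensitivity tests,
colocalize each significant protein's region with the outcome, and grade
targets:

* Tier 1 — replication-consistent, PPH4 > 0.75, and no significant
  heterogeneity or pleiotropy (inapplicable tests are non-disqualifying);
* Tier 2 — PPH4 > 0.75 but some Tier-1 condition unmet;
* Tier 3 — everything else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import instruments as ins
from . import mr
from .coloc import ColocPriors, coloc_abf, PPH4_HIGH
from .sensitivity import sensitivity_analysis
from .sumstats import GeneAnnotation, harmonize

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cis_window_bp: int = ins.CIS_WINDOW_BP
    p_threshold: float = ins.P_THRESHOLD
    r2_threshold: float = ins.R2_THRESHOLD
    clump_window_bp: int = ins.CLUMP_WINDOW_BP
    fdr_threshold: float = 0.05
    alpha: float = 0.05
    palindromic_policy: str = "drop"
    ivw_mode: str = "multiplicative_random"
    n_boot: int = 1000
    seed: int = 0
    # BH family: by default only proteins with >= 1 instrument; set True to
    # count instrument-less proteins in the FDR denominator as well.
    count_zero_instrument_proteins: bool = False
    pph4_high: float = PPH4_HIGH


def bh_fdr(pvals, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg q-values, preserving input order.

    ``m_total`` optionally inflates the family size beyond ``len(pvals)``
    (used when counting proteins that produced no test).  Raises if any p
    lies outside (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if m_total is not None:
        if m_total < p.size:
            raise ValueError("m_total cannot be below the number of tests")
        q = np.minimum(q * (m_total / p.size), 1.0)
    return q


@dataclass
class TargetReport:
    """One protein x one outcome evidence row."""

    protein_id: str
    outcome_id: str
    discovery: mr.MRResult | None = None
    discovery_fdr: float | None = None
    n_instruments_discovery: int = 0
    replication: dict[str, mr.MRResult] = field(default_factory=dict)
    replication_consistent: bool | None = None
    n_instruments_replication: int = 0
    q_pval: float | None = None
    intercept_pval: float | None = None
    pph4: float | None = None
    tier: int | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return (self.discovery_fdr is not None
                and self.discovery_fdr < 0.05)


def select_instruments(exposure: pd.DataFrame, outcome: pd.DataFrame,
                       gene: GeneAnnotation, ld: ins.LDMatrix,
                       cfg: PipelineConfig, protein_id: str = ""
                       ) -> tuple[pd.DataFrame, ins.InstrumentSet] | None:
    """cis filter -> p filter -> LD restriction -> clump -> harmonize.

    Returns (harmonized pairs, instrument set) or None if no instrument
    survives.
    """
    cis = ins.cis_filter(exposure, gene, cfg.cis_window_bp)
    sig = ins.pvalue_filter(cis, cfg.p_threshold)
    if sig.empty:
        return None
    avail = ins.restrict_to_ld(sig, ld)
    if avail.empty:
        return None
    iset = ins.clump(avail, ld, cfg.r2_threshold, cfg.clump_window_bp,
                     protein_id=protein_id)
    pairs = harmonize(iset.table, outcome, cfg.palindromic_policy)
    if pairs.empty:
        return None
    return pairs, iset


def run_discovery(pqtl_panel: Mapping[str, pd.DataFrame],
                  outcome: pd.DataFrame,
                  genes: Mapping[str, GeneAnnotation],
                  ld_provider: Callable[[str], ins.LDMatrix],
                  cfg: PipelineConfig | None = None,
                  outcome_id: str = "outcome") -> list[TargetReport]:
    """IVW screen of every protein, then BH FDR across the panel.

    Proteins without instruments are reported with a note and excluded from
    the FDR family (unless ``cfg.count_zero_instrument_proteins``); other
    per-protein failures are logged and skipped, never fatal.
    """
    cfg = cfg or PipelineConfig()
    reports: list[TargetReport] = []
    tested: list[TargetReport] = []
    for pid in sorted(pqtl_panel):
        rep = TargetReport(pid, outcome_id)
        reports.append(rep)
        try:
            sel = select_instruments(pqtl_panel[pid], outcome, genes[pid],
                                     ld_provider(pid), cfg, pid)
            if sel is None:
                rep.notes.append("no_instruments")
                log.info("%s: no instruments after selection; skipped", pid)
                continue
            pairs, _ = sel
            rep.n_instruments_discovery = len(pairs)
            rep.discovery = mr.ivw(pairs, cfg.ivw_mode, protein_id=pid,
                                   outcome_id=outcome_id)
            tested.append(rep)
        except Exception as exc:   # per-protein robustness
            rep.notes.append(f"discovery_failed: {exc}")
            log.warning("%s: discovery failed (%s)", pid, exc)
    if tested:
        m_total = len(reports) if cfg.count_zero_instrument_proteins \
            else None
        q = bh_fdr([r.discovery.pval for r in tested], m_total)
        for rep, qv in zip(tested, q):
            rep.discovery_fdr = float(qv)
    log.info("discovery: %d/%d proteins tested, %d significant at "
             "FDR<%g", len(tested), len(reports),
             sum(r.significant for r in tested), cfg.fdr_threshold)
    return reports


def _protein_seed(base: int, protein_id: str) -> int:
    import zlib
    return (base + zlib.crc32(protein_id.encode())) % (2 ** 31 - 1)


def run_replication(reports: list[TargetReport],
                    replication_panel: Mapping[str, pd.DataFrame],
                    outcome: pd.DataFrame,
                    genes: Mapping[str, GeneAnnotation],
                    ld_provider: Callable[[str], ins.LDMatrix],
                    cfg: PipelineConfig | None = None
                    ) -> list[TargetReport]:
    """Four-estimator replication plus sensitivity for significant proteins.

    Replication is "consistent" iff the primary estimator (IVW; Wald when a
    single instrument remains) has p < alpha with the same effect sign as
    discovery.  Proteins absent from the replication panel get NA.
    """
    cfg = cfg or PipelineConfig()
    for rep in reports:
        if not rep.significant:
            continue
        pid = rep.protein_id
        if pid not in replication_panel:
            rep.notes.append("absent_from_replication_panel")
            log.info("%s: absent from replication panel", pid)
            continue
        sel = select_instruments(replication_panel[pid], outcome,
                                 genes[pid], ld_provider(pid), cfg, pid)
        if sel is None:
            rep.notes.append("no_replication_instruments")
            continue
        pairs, _ = sel
        rep.n_instruments_replication = len(pairs)
        seed = _protein_seed(cfg.seed, pid)
        primary = mr.ivw(pairs, cfg.ivw_mode, protein_id=pid,
                         outcome_id=rep.outcome_id)
        rep.replication = {
            "ivw": primary,
            "egger": mr.egger(pairs, protein_id=pid,
                              outcome_id=rep.outcome_id),
            "weighted_median": mr.weighted_median(
                pairs, cfg.n_boot, seed, protein_id=pid,
                outcome_id=rep.outcome_id),
            "weighted_mode": mr.weighted_mode(
                pairs, 1.0, cfg.n_boot, seed + 1, protein_id=pid,
                outcome_id=rep.outcome_id),
        }
        sens = sensitivity_analysis(pairs)
        rep.q_pval = sens.q_pval
        rep.intercept_pval = sens.intercept_pval
        rep.replication_consistent = bool(
            primary.pval < cfg.alpha
            and np.sign(primary.beta) == np.sign(rep.discovery.beta))
    return reports


def run_coloc(reports: list[TargetReport],
              pqtl_panel: Mapping[str, pd.DataFrame],
              outcome: pd.DataFrame,
              genes: Mapping[str, GeneAnnotation],
              cfg: PipelineConfig | None = None,
              priors: ColocPriors | None = None,
              trait_types: tuple[str, str] = ("quant", "cc")
              ) -> list[TargetReport]:
    """Regional colocalization for significant proteins.

    Region = the same cis window used for instrument selection, with *no*
    p-value filter (colocalization needs the full regional signal).
    """
    cfg = cfg or PipelineConfig()
    for rep in reports:
        if not rep.significant:
            continue
        pid = rep.protein_id
        region = ins.cis_filter(pqtl_panel[pid], genes[pid],
                                cfg.cis_window_bp)
        pairs = harmonize(region, outcome, cfg.palindromic_policy)
        if pairs.empty:
            rep.notes.append("coloc_no_shared_region")
            continue
        r1 = pairs.rename(columns={"beta_exp": "beta", "se_exp": "se"})
        r2 = pairs.rename(columns={"beta_out": "beta", "se_out": "se"})
        res = coloc_abf(r1[["variant_id", "beta", "se"]],
                        r2[["variant_id", "beta", "se"]],
                        priors, trait_types)
        rep.pph4 = res.pph4
    return reports


def tier_from_evidence(discovery_fdr: float,
                       replication_pval: float | None,
                       q_pval: float | None,
                       intercept_pval: float | None,
                       pph4: float | None,
                       sign_consistent: bool | None = None,
                       alpha: float = 0.05,
                       pph4_high: float = PPH4_HIGH) -> int | None:
    """Tier grade from the evidence-table quantities.

    Returns None when the protein does not pass discovery FDR < 0.05 (tiers
    are defined only for discovered targets).  NA sensitivity tests are
    non-disqualifying; a missing PPH4 is treated as not-high (Tier 3 path).
    ``sign_consistent=None`` means sign information is unavailable and the
    replication gate is the p-value alone.
    """
    if discovery_fdr is None or not discovery_fdr < 0.05:
        return None
    repl_ok = (replication_pval is not None
               and np.isfinite(replication_pval)
               and replication_pval < alpha
               and sign_consistent is not False)
    sens_ok = ((q_pval is None or not np.isfinite(q_pval)
                or q_pval >= alpha)
               and (intercept_pval is None or not np.isfinite(intercept_pval)
                    or intercept_pval >= alpha))
    coloc_high = (pph4 is not None and np.isfinite(pph4)
                  and pph4 > pph4_high)
    if repl_ok and coloc_high and sens_ok:
        return 1
    if coloc_high:
        return 2
    return 3


def assign_tier(report: TargetReport, cfg: PipelineConfig | None = None
                ) -> int | None:
    cfg = cfg or PipelineConfig()
    if not report.significant:
        return None
    if report.pph4 is None:
        log.info("%s: missing PPH4, graded on the Tier-3 path",
                 report.protein_id)
    repl_p = None
    if report.replication.get("ivw") is not None:
        repl_p = report.replication["ivw"].pval
    return tier_from_evidence(
        report.discovery_fdr, repl_p, report.q_pval, report.intercept_pval,
        report.pph4,
        sign_consistent=report.replication_consistent,
        alpha=cfg.alpha, pph4_high=cfg.pph4_high)


def run_study(discovery_panel: Mapping[str, pd.DataFrame],
              outcome_discovery: pd.DataFrame,
              replication_panel: Mapping[str, pd.DataFrame],
              outcome_replication: pd.DataFrame,
              genes: Mapping[str, GeneAnnotation],
              ld_discovery: Callable[[str], ins.LDMatrix],
              ld_replication: Callable[[str], ins.LDMatrix],
              cfg: PipelineConfig | None = None,
              priors: ColocPriors | None = None,
              outcome_id: str = "outcome") -> list[TargetReport]:
    """The full study design, end to end."""
    cfg = cfg or PipelineConfig()
    reports = run_discovery(discovery_panel, outcome_discovery, genes,
                            ld_discovery, cfg, outcome_id)
    run_replication(reports, replication_panel, outcome_replication, genes,
                    ld_replication, cfg)
    run_coloc(reports, discovery_panel, outcome_discovery, genes, cfg,
              priors)
    for rep in reports:
        rep.tier = assign_tier(rep, cfg)
    return reports


REPORT_COLUMNS = ["Disease", "Protein", "Discovery", "Replication",
                  "Heterogeneity", "Pleiotropy", "Colocalization", "Targets"]


def _fmt_p(p: float | None) -> str:
    return "NA" if p is None or not np.isfinite(p) else f"{p:.2E}"


def render_report(reports: list[TargetReport],
                  significant_only: bool = True) -> pd.DataFrame:
    """Evidence table in the canonical column order, sorted by outcome then
    ascending discovery FDR.  Re-rendering is byte-identical."""
    rows = []
    for r in reports:
        if significant_only and not r.significant:
            continue
        repl = r.replication.get("ivw")
        rows.append({
            "Disease": r.outcome_id,
            "Protein": r.protein_id,
            "Discovery": _fmt_p(r.discovery_fdr),
            "Replication": _fmt_p(repl.pval if repl is not None else None),
            "Heterogeneity": _fmt_p(r.q_pval),
            "Pleiotropy": _fmt_p(r.intercept_pval),
            "Colocalization": "NA" if r.pph4 is None
            else f"{100 * r.pph4:.1f}%",
            "Targets": f"Tier {r.tier} Target" if r.tier else "NA",
            "_fdr": np.inf if r.discovery_fdr is None else r.discovery_fdr,
        })
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS + ["_fdr"])
    df = df.sort_values(["Disease", "_fdr", "Protein"],
                        kind="mergesort").drop(columns="_fdr")
    return df.reset_index(drop=True)


def evidence_table_tiers(df: pd.DataFrame, alpha: float = 0.05,
                         pph4_high: float = PPH4_HIGH) -> pd.DataFrame:
    """Apply the tier rule to a precomputed evidence table.

    Expected columns: disease, protein, discovery_fdr, replication_pval,
    q_pval, intercept_pval, pph4 ("94.4%" strings or fractions; "NA"
    allowed anywhere).  Optional discovery/replication CI columns
    (``discovery_ci_lo``/``_hi``, ``replication_ci_lo``/``_hi``) supply the
    effect signs for the consistency check.
    """
    def _num(x):
        if pd.isna(x):
            return None
        if isinstance(x, str):
            x = x.strip()
            if x.upper() == "NA":
                return None
            if x.endswith("%"):
                return float(x[:-1]) / 100.0
        return float(x)

    out = df.copy()
    tiers, labels = [], []
    for _, row in out.iterrows():
        pph4 = _num(row["pph4"])
        if pph4 is not None and pph4 > 1:
            pph4 /= 100.0
        sign_ok = None
        if {"discovery_ci_lo", "discovery_ci_hi", "replication_ci_lo",
                "replication_ci_hi"} <= set(out.columns):
            d_lo, d_hi = _num(row["discovery_ci_lo"]), \
                _num(row["discovery_ci_hi"])
            r_lo, r_hi = _num(row["replication_ci_lo"]), \
                _num(row["replication_ci_hi"])
            if None not in (d_lo, d_hi, r_lo, r_hi):
                sign_ok = (np.sign(d_lo + d_hi) == np.sign(r_lo + r_hi))
        t = tier_from_evidence(_num(row["discovery_fdr"]),
                               _num(row["replication_pval"]),
                               _num(row["q_pval"]),
                               _num(row["intercept_pval"]),
                               pph4, sign_ok, alpha, pph4_high)
        tiers.append(t)
        labels.append(f"Tier {t} Target" if t else "NA")
    out["tier"] = tiers
    out["target_label"] = labels
    return out


def manhattan(reports: list[TargetReport],
              genes: Mapping[str, GeneAnnotation],
              path: str | Path,
              fdr_threshold: float = 0.05) -> None:
    """Minimal Manhattan-style scatter of -log10(FDR) by gene position."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs, ys, sig = [], [], []
    x0 = 0.0
    for i, rep in enumerate(r for r in reports
                            if r.discovery_fdr is not None):
        g = genes[rep.protein_id]
        xs.append(x0 + i)
        ys.append(-np.log10(max(rep.discovery_fdr, 1e-300)))
        sig.append(rep.discovery_fdr < fdr_threshold)
    fig, ax = plt.subplots(figsize=(8, 3))
    colors = ["#c0392b" if s else "#7f8c8d" for s in sig]
    ax.scatter(xs, ys, c=colors, s=12)
    ax.axhline(-np.log10(fdr_threshold), ls="--", lw=0.8, color="k")
    ax.set_xlabel("protein (gene order)")
    ax.set_ylabel("-log10 FDR")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
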