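"""Synthetic two-sample summary statistics with known ground truth.

Emulates the statistical structure of a proteome-wide cis-MR study: a
genomic region with autoregressive LD, a standardized plasma protein driven
by a few cis-SNPs, and an independent case-control cohort whose disease
liability depends on the protein (and optionally on direct per-SNP
pleiotropic effects).  Three disjoint samples are drawn per region — an LD
reference panel, the exposure (protein GWAS) cohort, and the outcome GWAS
cohort — so exposure and outcome errors are independent by construction.

Everything is driven by a :class:`SimConfig` whose seed makes outputs fully
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy import stats

from .instruments import LDMatrix, ld_from_genotypes
from .sumstats import GeneAnnotation, write_sumstats, write_gene_annotations


@dataclass
class SimConfig:
    """Study-scale simulation settings.

    Desk-scale defaults: 5,000 individuals per cohort, 200 SNPs per region,
    a 500-sample LD reference, adjacent-haplotype allele-copy probability
    0.9, three causal cis-SNPs explaining 15% of protein variance, and a
    10% case fraction (an enriched case-control design).  ``theta`` is the
    true causal log-odds of disease per 1-SD protein increase.
    """

    n_ref: int = 500
    n_exp: int = 5000
    n_out: int = 5000
    n_cases_frac: float = 0.10
    m_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.9
    n_causal_exp: int = 3
    h2_protein: float = 0.15
    theta: float = 0.0
    pleiotropy: str = "none"            # none | balanced | directional
    pleiotropy_mag: float = 0.05
    shared_causal: bool = True
    coloc_log_or: float = 0.8           # causal-SNP log-OR in coloc pairs
    seed: int = 0
    chrom: str = "1"
    region_start: int = 1_000_000
    snp_spacing_bp: int = 5_000
    outcome_model: str = "logistic"     # logistic | linear

    def __post_init__(self) -> None:
        if not 0 <= self.h2_protein < 1:
            raise ValueError("h2_protein must be in [0, 1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range bounds must be in (0, 0.5]")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")


@dataclass
class SimTruth:
    """Ground truth recorded for every generated dataset."""

    theta: float
    gamma: np.ndarray                   # per-SNP effect on the protein (SD)
    causal_idx_exp: np.ndarray
    causal_idx_out: np.ndarray          # SNPs with direct outcome effects
    delta: np.ndarray                   # per-SNP direct log-odds effects
    causal_variant_ids_exp: list[str] = field(default_factory=list)
    causal_variant_ids_out: list[str] = field(default_factory=list)


def _variant_meta(cfg: SimConfig, rng: np.random.Generator,
                  tag: str = "") -> pd.DataFrame:
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.m_snps)
    pos = cfg.region_start + cfg.snp_spacing_bp * np.arange(cfg.m_snps)
    ids = [f"rs{tag}{cfg.chrom}_{int(x)}" for x in pos]
    return pd.DataFrame({"variant_id": ids, "chrom": cfg.chrom,
                         "pos": pos.astype(np.int64), "maf": p})


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator,
                       n: int, meta: pd.DataFrame) -> np.ndarray:
    """Dosages for ``n`` diploid individuals under a first-order
    allele-copy haplotype model.

    Each haplotype copies the previous SNP's allele with probability
    ``ld_rho``, else draws fresh at that SNP's MAF; adjacent-SNP
    correlation therefore decays geometrically with distance.
    Monomorphic columns (possible at small n) are redrawn independently.
    """
    p = meta["maf"].to_numpy()
    m = cfg.m_snps
    H = np.empty((2 * n, m), dtype=np.int8)
    H[:, 0] = rng.random(2 * n) < p[0]
    for j in range(1, m):
        copy = rng.random(2 * n) < cfg.ld_rho
        fresh = rng.random(2 * n) < p[j]
        H[:, j] = np.where(copy, H[:, j - 1], fresh)
    G = (H[0::2] + H[1::2]).astype(np.float64)
    for j in np.flatnonzero(G.std(axis=0) == 0):
        while G[:, j].std() == 0:
            G[:, j] = rng.binomial(2, p[j], n)
    return G


def _spaced_causal_indices(cfg: SimConfig, rng: np.random.Generator,
                           k: int) -> np.ndarray:
    """k causal indices spread across the region (jittered even spacing),
    so that post-clumping instruments stay mutually independent."""
    m, half = cfg.m_snps, cfg.m_snps / (2 * k)
    centers = (np.arange(k) + 0.5) * (m / k)
    jitter = rng.integers(-int(half / 2), int(half / 2) + 1, k)
    return np.clip(np.round(centers + jitter).astype(int), 0, m - 1)


def _linear_gwas(G: np.ndarray, y: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP simple linear regression, vectorized (beta, se, p)."""
    n = G.shape[0]
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    ssx = (Gc ** 2).sum(axis=0)
    beta = Gc.T @ yc / ssx
    rss = (yc ** 2).sum() - beta ** 2 * ssx
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / ssx)
    pval = 2 * stats.t.sf(np.abs(beta / se), n - 2)
    return beta, se, np.clip(pval, np.nextafter(0, 1), 1.0)


def _logistic_gwas(G: np.ndarray, y: np.ndarray, max_iter: int = 40,
                   tol: float = 1e-10
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP marginal logistic regression (intercept + dosage), fitted by
    Newton-Raphson batched across SNPs.  Returns MLE log-odds, Wald SE, p."""
    n, m = G.shape
    yv = y.astype(float)[:, None]
    a = np.full(m, logit(max(min(y.mean(), 1 - 1e-9), 1e-9)))
    b = np.zeros(m)
    H11 = H12 = H22 = np.ones(m)
    for _ in range(max_iter):
        eta = a[None, :] + G * b[None, :]
        mu = expit(eta)
        resid = yv - mu
        s = mu * (1.0 - mu)
        U1 = resid.sum(axis=0)
        U2 = (G * resid).sum(axis=0)
        H11 = s.sum(axis=0)
        H12 = (s * G).sum(axis=0)
        H22 = (s * G * G).sum(axis=0)
        det = H11 * H22 - H12 ** 2
        da = (H22 * U1 - H12 * U2) / det
        db = (H11 * U2 - H12 * U1) / det
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < tol:
            break
    se = np.sqrt(H11 / (H11 * H22 - H12 ** 2))
    pval = 2 * stats.norm.sf(np.abs(b / se))
    return b, se, np.clip(pval, np.nextafter(0, 1), 1.0)


def _to_sumstats(meta: pd.DataFrame, G: np.ndarray, beta, se, pval,
                 n: int, ncase=np.nan, ncontrol=np.nan) -> pd.DataFrame:
    eaf = G.mean(axis=0) / 2.0
    return pd.DataFrame({
        "variant_id": meta["variant_id"], "chrom": meta["chrom"],
        "pos": meta["pos"], "effect_allele": "A", "other_allele": "G",
        "eaf": eaf, "beta": beta, "se": se, "pval": pval,
        "n": float(n), "ncase": ncase, "ncontrol": ncontrol,
    })


def simulate_protein_gwas(G: np.ndarray, meta: pd.DataFrame, cfg: SimConfig,
                          rng: np.random.Generator,
                          truth: SimTruth | None = None
                          ) -> tuple[pd.DataFrame, SimTruth, np.ndarray]:
    """Protein levels and their per-SNP GWAS on the exposure cohort.

    X = sum_c gamma_c G_c + eps with Var(X) = 1 by construction
    (gamma_c^2 Var(G_c) summing to h2, eps ~ N(0, 1-h2)); per-SNP simple
    regression gives beta/se/p in SD units.  Returns (sumstats, truth, X).
    """
    n = G.shape[0]
    if truth is None:
        causal = _spaced_causal_indices(cfg, rng, cfg.n_causal_exp) \
            if cfg.h2_protein > 0 and cfg.n_causal_exp > 0 else \
            np.empty(0, dtype=int)
        gamma = np.zeros(cfg.m_snps)
        if causal.size:
            var_g = G[:, causal].var(axis=0)
            gamma[causal] = np.sqrt(cfg.h2_protein
                                    / (causal.size * var_g))
        truth = SimTruth(
            theta=cfg.theta, gamma=gamma, causal_idx_exp=causal,
            causal_idx_out=causal.copy(), delta=np.zeros(cfg.m_snps),
            causal_variant_ids_exp=list(meta["variant_id"].iloc[causal]))
    eps_sd = np.sqrt(max(1.0 - cfg.h2_protein, 0.0)) \
        if truth.causal_idx_exp.size else 1.0
    X = G @ truth.gamma + rng.normal(0.0, eps_sd, n)
    beta, se, pval = _linear_gwas(G, X)
    return _to_sumstats(meta, G, beta, se, pval, n), truth, X


def _pleiotropy_deltas(cfg: SimConfig, rng: np.random.Generator,
                       idx: np.ndarray) -> np.ndarray:
    delta = np.zeros(cfg.m_snps)
    if cfg.pleiotropy == "balanced":
        delta[idx] = rng.choice([-1.0, 1.0], idx.size) * cfg.pleiotropy_mag
    elif cfg.pleiotropy == "directional":
        delta[idx] = cfg.pleiotropy_mag
    return delta


def simulate_outcome_gwas(G: np.ndarray, meta: pd.DataFrame,
                          truth: SimTruth, cfg: SimConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Case-control GWAS on an independent outcome cohort.

    Disease liability: logit P(case) = alpha + theta * X + sum_j delta_j G_j,
    with alpha set so the expected case fraction is ``n_cases_frac`` and X
    regenerated from the same genetic architecture (two-sample design).
    Per-SNP marginal logistic regression by default; ``outcome_model =
    "linear"`` uses a fast linear-probability fit rescaled to the log-odds
    scale (beta / ybar(1-ybar)).
    """
    n = G.shape[0]
    eps_sd = np.sqrt(max(1.0 - cfg.h2_protein, 0.0)) \
        if truth.causal_idx_exp.size else 1.0
    X = G @ truth.gamma + rng.normal(0.0, eps_sd, n)
    delta = truth.delta
    eta = logit(cfg.n_cases_frac) + truth.theta * X + G @ delta
    eta -= truth.theta * X.mean() + (G @ delta).mean()
    y = (rng.random(n) < expit(eta)).astype(np.int8)
    if y.sum() in (0, n):           # degenerate draw at tiny n
        y[rng.integers(0, n)] = 1 - y[0]
    if cfg.outcome_model == "logistic":
        beta, se, pval = _logistic_gwas(G, y)
    else:
        beta, se, pval = _linear_gwas(G, y.astype(float))
        scale = y.mean() * (1.0 - y.mean())
        beta, se = beta / scale, se / scale
        pval = 2 * stats.norm.sf(np.abs(beta / se))
    ncase = int(y.sum())
    return _to_sumstats(meta, G, beta, se, pval, n, float(ncase),
                        float(n - ncase))


@dataclass
class RegionData:
    """One protein region: sumstats for both samples, LD, gene, truth."""

    protein_id: str
    exposure: pd.DataFrame
    outcome: pd.DataFrame
    gene: GeneAnnotation
    ld: LDMatrix
    truth: SimTruth
    ref_genotypes: np.ndarray


def _gene_for_region(cfg: SimConfig, protein_id: str) -> GeneAnnotation:
    center = cfg.region_start + cfg.snp_spacing_bp * cfg.m_snps // 2
    return GeneAnnotation(gene_id=f"GENE_{protein_id}",
                          protein_id=protein_id, chrom=cfg.chrom,
                          start=center - 5_000, end=center + 5_000)


def simulate_two_sample(cfg: SimConfig, protein_id: str = "P1",
                        seed: int | None = None) -> RegionData:
    """Full two-sample dataset for one protein region."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    meta = _variant_meta(cfg, rng)
    g_ref = simulate_genotypes(cfg, rng, cfg.n_ref, meta)
    g_exp = simulate_genotypes(cfg, rng, cfg.n_exp, meta)
    g_out = simulate_genotypes(cfg, rng, cfg.n_out, meta)
    exposure, truth, _ = simulate_protein_gwas(g_exp, meta, cfg, rng)
    truth.delta = _pleiotropy_deltas(cfg, rng, truth.causal_idx_exp)
    truth.causal_idx_out = truth.causal_idx_exp.copy()
    outcome = simulate_outcome_gwas(g_out, meta, truth, cfg, rng)
    ld = ld_from_genotypes(g_ref, list(meta["variant_id"]))
    return RegionData(protein_id, exposure, outcome,
                      _gene_for_region(cfg, protein_id), ld, truth, g_ref)


def simulate_coloc_pair(cfg: SimConfig, scenario: str | None = None,
                        seed: int | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Regional sumstats for a quantitative trait and a binary trait.

    ``scenario``: "shared" (one causal SNP drives both traits), "distinct"
    (two causal SNPs with reference r^2 < 0.01), or "null" (no association
    for either trait).  Defaults to cfg.shared_causal -> shared/distinct.
    """
    if scenario is None:
        scenario = "shared" if cfg.shared_causal else "distinct"
    if scenario not in ("shared", "distinct", "null"):
        raise ValueError(f"unknown coloc scenario {scenario!r}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    meta = _variant_meta(cfg, rng)
    g1 = simulate_genotypes(cfg, rng, cfg.n_exp, meta)
    g2 = simulate_genotypes(cfg, rng, cfg.n_out, meta)

    m = cfg.m_snps
    idx1 = m // 3
    if scenario == "distinct":
        # place the second causal SNP far enough that AR-decay LD is ~0
        lag = max(int(np.ceil(np.log(0.05) / np.log(max(cfg.ld_rho, 1e-9)))),
                  25)
        idx2 = min(idx1 + lag, m - 1)
    else:
        idx2 = idx1

    gamma = np.zeros(m)
    delta = np.zeros(m)
    if scenario != "null":
        gamma[idx1] = np.sqrt(cfg.h2_protein / g1[:, idx1].var())
        delta[idx2] = cfg.coloc_log_or
    truth = SimTruth(theta=0.0, gamma=gamma,
                     causal_idx_exp=np.array([idx1] if scenario != "null"
                                             else [], dtype=int),
                     causal_idx_out=np.array([idx2] if scenario != "null"
                                             else [], dtype=int),
                     delta=delta,
                     causal_variant_ids_exp=[meta["variant_id"][idx1]]
                     if scenario != "null" else [],
                     causal_variant_ids_out=[meta["variant_id"][idx2]]
                     if scenario != "null" else [])

    X = g1 @ gamma + rng.normal(
        0.0, np.sqrt(1 - cfg.h2_protein) if scenario != "null" else 1.0,
        cfg.n_exp)
    b1, s1, p1 = _linear_gwas(g1, X)
    trait1 = _to_sumstats(meta, g1, b1, s1, p1, cfg.n_exp)

    eta = logit(cfg.n_cases_frac) + g2 @ delta - (g2 @ delta).mean()
    y = (rng.random(cfg.n_out) < expit(eta)).astype(np.int8)
    b2, s2, p2 = _logistic_gwas(g2, y)
    trait2 = _to_sumstats(meta, g2, b2, s2, p2, cfg.n_out,
                          float(y.sum()), float(cfg.n_out - int(y.sum())))
    return trait1, trait2, truth


@dataclass
class SimStudy:
    """A panel of protein regions sharing one outcome definition."""

    exposure_panel: dict[str, pd.DataFrame]
    replication_panel: dict[str, pd.DataFrame]
    outcome_discovery: pd.DataFrame
    outcome_replication: pd.DataFrame
    genes: dict[str, GeneAnnotation]
    ld: dict[str, LDMatrix]
    ld_replication: dict[str, LDMatrix]
    truths: dict[str, SimTruth]
    causal_proteins: list[str]


def simulate_study(cfg: SimConfig, n_proteins: int = 50,
                   n_causal_proteins: int = 3,
                   theta_causal: float = 0.4,
                   with_replication: bool = True) -> SimStudy:
    """A proteome-scale panel: each protein gets its own region (labelled
    with its own synthetic chromosome) and cohorts; ``n_causal_proteins``
    of them truly affect the outcome with log-odds ``theta_causal``.

    Outcome summary statistics are produced per region (regions are on
    distinct chromosomes, hence independent) and concatenated into a single
    outcome table.
    """
    rng = np.random.default_rng(cfg.seed)
    causal = [f"P{i + 1:03d}" for i in range(n_causal_proteins)]
    exposure_panel, replication_panel = {}, {}
    ld_disc, ld_repl, truths, genes = {}, {}, {}, {}
    out_disc, out_repl = [], []
    for i in range(n_proteins):
        pid = f"P{i + 1:03d}"
        theta = theta_causal if pid in causal else 0.0
        region_cfg = SimConfig(**{**asdict(cfg), "theta": theta,
                                  "chrom": str(i + 1),
                                  "seed": cfg.seed})
        seed_i = int(rng.integers(0, 2 ** 31 - 1))
        region = simulate_two_sample(region_cfg, pid, seed=seed_i)
        exposure_panel[pid] = region.exposure
        out_disc.append(region.outcome)
        genes[pid] = region.gene
        ld_disc[pid] = region.ld
        truths[pid] = region.truth
        if with_replication:
            seed_r = int(rng.integers(0, 2 ** 31 - 1))
            region_r = simulate_two_sample(region_cfg, pid, seed=seed_r)
            replication_panel[pid] = region_r.exposure
            out_repl.append(region_r.outcome)
            ld_repl[pid] = region_r.ld
    return SimStudy(
        exposure_panel, replication_panel,
        pd.concat(out_disc, ignore_index=True),
        pd.concat(out_repl, ignore_index=True) if out_repl
        else pd.DataFrame(),
        genes, ld_disc, ld_repl, truths, causal)


def write_study(study: SimStudy, out_dir: str | Path) -> None:
    """Write a simulated study as the file layout the CLI pipeline reads."""
    out = Path(out_dir)
    for sub in ("discovery", "replication", "ld_discovery",
                "ld_replication"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for pid, df in study.exposure_panel.items():
        write_sumstats(df, out / "discovery" / f"{pid}.tsv")
        study.ld[pid].write_tsv(out / "ld_discovery" / f"{pid}.tsv")
    for pid, df in study.replication_panel.items():
        write_sumstats(df, out / "replication" / f"{pid}.tsv")
        study.ld_replication[pid].write_tsv(
            out / "ld_replication" / f"{pid}.tsv")
    write_sumstats(study.outcome_discovery, out / "outcome_discovery.tsv")
    if len(study.outcome_replication):
        write_sumstats(study.outcome_replication,
                       out / "outcome_replication.tsv")
    write_gene_annotations(study.genes, out / "genes.tsv")
    truth = {pid: {"theta": t.theta,
                   "causal_variants": t.causal_variant_ids_exp}
             for pid, t in study.truths.items()}
    truth["_causal_proteins"] = study.causal_proteins
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
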