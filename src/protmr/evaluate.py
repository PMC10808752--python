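"""Seeded evaluation harnesses: calibration, coverage, discrimination.

These drive many independent replicates of the synthetic generator through
the same selection/estimation code paths the pipeline uses, and summarize
operating characteristics (type-I error, CI coverage, colocalization
discrimination, clumping validity).  Region replicates default to a
reduced problem size (100 SNPs, 4,000-individual cohorts) so that
hundreds of replicates run in seconds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .instruments import clump
from .mr import ivw
from .pipeline import PipelineConfig, select_instruments
from .sensitivity import cochran_q
from .simulate import SimConfig, simulate_coloc_pair, simulate_two_sample
from .coloc import coloc_abf

#: Region-replicate problem size used by the calibration harnesses.
REPLICATE_SIZES = dict(m_snps=100, n_exp=4000, n_out=4000, n_ref=400)


def replicate_config(theta: float = 0.0, seed: int = 0,
                     **overrides) -> SimConfig:
    kw = {**REPLICATE_SIZES, "theta": theta, "seed": seed, **overrides}
    return SimConfig(**kw)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, n)]


@dataclass
class MRCalibration:
    theta: float
    n_reps: int
    estimates: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray
    covered: np.ndarray
    q_pvals: np.ndarray
    n_instruments: np.ndarray
    n_failed: int = 0

    @property
    def rejection_rate(self) -> float:
        return float((self.pvals < 0.05).mean())

    @property
    def coverage(self) -> float:
        return float(self.covered.mean())

    @property
    def mean_estimate(self) -> float:
        return float(self.estimates.mean())


def mr_operating_characteristics(theta: float, n_reps: int, seed: int,
                                 cfg: SimConfig | None = None,
                                 pcfg: PipelineConfig | None = None
                                 ) -> MRCalibration:
    """IVW over ``n_reps`` independently simulated two-sample regions.

    Each replicate runs the full selection path (cis window, p < 1e-5,
    LD restriction, clumping) and the IVW estimate; replicates yielding no
    instrument are counted as failed and skipped.
    """
    pcfg = pcfg or PipelineConfig()
    base = cfg or replicate_config(theta=theta, seed=seed)
    seeds = _spawn_seeds(seed, n_reps)
    est, ses, pv, cov, qp, ks = [], [], [], [], [], []
    n_failed = 0
    for s in seeds:
        rcfg = SimConfig(**{**asdict(base), "theta": theta, "seed": s})
        region = simulate_two_sample(rcfg, seed=s)
        sel = select_instruments(region.exposure, region.outcome,
                                 region.gene, region.ld, pcfg)
        if sel is None:
            n_failed += 1
            continue
        pairs, _ = sel
        res = ivw(pairs, pcfg.ivw_mode)
        est.append(res.beta)
        ses.append(res.se)
        pv.append(res.pval)
        cov.append(res.ci_low <= theta <= res.ci_high)
        ks.append(res.n_snps)
        sens = cochran_q(pairs)
        qp.append(sens.q_pval if sens.applicable_q else np.nan)
    return MRCalibration(theta, n_reps, np.array(est), np.array(ses),
                         np.array(pv), np.array(cov, dtype=bool),
                         np.array(qp, dtype=float), np.array(ks),
                         n_failed)


@dataclass
class ColocDiscrimination:
    n_reps: int
    pph4_shared: np.ndarray = field(default_factory=lambda: np.array([]))
    pph3_distinct: np.ndarray = field(default_factory=lambda: np.array([]))
    max_sum_err: float = 0.0

    @property
    def shared_rate(self) -> float:
        return float((self.pph4_shared > 0.75).mean())

    @property
    def distinct_rate(self) -> float:
        return float((self.pph3_distinct > 0.75).mean())


def coloc_discrimination(n_reps: int, seed: int,
                         cfg: SimConfig | None = None
                         ) -> ColocDiscrimination:
    """PPH4/PPH3 over shared- and distinct-causal regional simulations."""
    base = cfg or replicate_config(seed=seed)
    seeds = _spawn_seeds(seed, 2 * n_reps)
    pph4, pph3 = [], []
    max_err = 0.0
    for i, scenario in enumerate(("shared", "distinct")):
        vals = []
        for s in seeds[i * n_reps:(i + 1) * n_reps]:
            rcfg = SimConfig(**{**asdict(base), "seed": s})
            t1, t2, _ = simulate_coloc_pair(rcfg, scenario, seed=s)
            res = coloc_abf(t1, t2)
            max_err = max(max_err,
                          abs(sum(res.pp.values()) - 1.0))
            vals.append(res.pp["pph4" if scenario == "shared" else "pph3"])
        (pph4 if scenario == "shared" else pph3).extend(vals)
    return ColocDiscrimination(n_reps, np.array(pph4), np.array(pph3),
                               max_err)


def greedy_clump_oracle(variant_ids, pos, pvals, r2_mat, r2_threshold,
                        window_bp) -> list[str]:
    """Reference greedy clumping, written independently of the library
    implementation: explicit loop keeping each best remaining variant and
    discarding in-window partners at or above the r^2 threshold."""
    order = sorted(range(len(variant_ids)),
                   key=lambda i: (pvals[i], variant_ids[i]))
    alive = set(order)
    kept = []
    for i in order:
        if i not in alive:
            continue
        kept.append(i)
        for j in list(alive):
            if j == i or j in kept:
                continue
            if abs(pos[j] - pos[i]) <= window_bp and \
                    r2_mat[i, j] >= r2_threshold:
                alive.discard(j)
    return [variant_ids[i] for i in kept]


def clumping_agreement(n_structures: int, seed: int,
                       m: int = 30, n_ref: int = 300,
                       r2_threshold: float = 0.01,
                       window_bp: int = 10_000_000) -> dict:
    """Compare library clumping with the reference oracle on random LD
    structures; also count pairwise-r^2 violations in kept sets."""
    from .instruments import ld_from_genotypes
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_match, n_viol = 0, 0
    for _ in range(n_structures):
        cfg = SimConfig(m_snps=m, n_ref=n_ref,
                        ld_rho=float(rng.uniform(0.0, 0.97)),
                        seed=int(rng.integers(0, 2 ** 31 - 1)))
        sub = np.random.default_rng(cfg.seed)
        from .simulate import _variant_meta, simulate_genotypes
        meta = _variant_meta(cfg, sub)
        G = simulate_genotypes(cfg, sub, n_ref, meta)
        ld = ld_from_genotypes(G, list(meta["variant_id"]))
        table = pd.DataFrame({
            "variant_id": meta["variant_id"],
            "pos": meta["pos"],
            "pval": sub.uniform(1e-12, 1e-4, m),
        })
        # make some positions far apart so the window rule matters
        if sub.random() < 0.5:
            table.loc[m // 2:, "pos"] += window_bp + 1
        kept = clump(table, ld, r2_threshold, window_bp)
        oracle = greedy_clump_oracle(
            list(table["variant_id"]), table["pos"].to_numpy(),
            table["pval"].to_numpy(), ld.r ** 2, r2_threshold, window_bp)
        if kept.variant_ids == oracle:
            n_match += 1
        r2 = kept.ld.r ** 2
        kpos = kept.table["pos"].to_numpy()
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                if abs(int(kpos[i]) - int(kpos[j])) <= window_bp and \
                        r2[i, j] >= r2_threshold:
                    n_viol += 1
    return {"n_structures": n_structures, "n_match": n_match,
            "n_violations": n_viol,
            "agreement": n_match / n_structures}
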