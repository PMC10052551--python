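"""Cell-proliferation association test for newly predicted driver genes.

A core set of cell-proliferation-related genes (CPRGs) that are strongly
coexpressed is selected; each tumor sample's proliferation activity theta is
the no-intercept least-squares coefficient fitting the core genes' mean
expression vector from that sample's core-gene expression. For a candidate
gene, samples are split into mutated (M) and unmutated (U) groups and the
theta distributions are compared with a two-sided Wilcoxon rank-sum test;
candidates with p < 0.05 are called newly predicted cancer drivers (NPCDs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from drivergnn.io import ExpressionMatrix, MutationTable

logger = logging.getLogger(__name__)


@dataclass
class ProliferationModel:
    core_genes: list[str]
    s_mean: pd.Series  # mean expression of core genes over tumor samples
    theta: pd.Series  # per tumor sample proliferation activity


@dataclass
class ProliferationResult:
    gene: str
    m_size: int
    u_size: int
    median_m: float
    median_u: float
    p_value: float
    is_npcd: bool
    degenerate: bool = False


def select_core_genes(
    expr: ExpressionMatrix,
    cprg: list[str],
    rho_threshold: float = 0.4,
    p_cutoff: float = 1e-3,
    k: int = 20,
) -> ProliferationModel:
    """Select the k most mutually coexpressed CPRGs as core genes.

    A CPRG pair is significantly coexpressed iff |Spearman rho| >=
    rho_threshold and p < p_cutoff over tumor samples. Genes are ranked by
    their count of significant partners (ties broken by mean |rho| over
    significant partners, then lexicographically); the top k become the core
    set, and theta is computed for every tumor sample.
    """
    samples = expr.tumor_samples
    present = [g for g in cprg if g in expr.values.index]
    if len(present) < k:
        raise ValueError(f"need >= {k} CPRGs present in the expression matrix, have {len(present)}")
    sub = expr.values.loc[present, samples].to_numpy(dtype=float)
    rho, p = stats.spearmanr(sub, axis=1)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    np.fill_diagonal(rho, 0.0)
    np.fill_diagonal(p, 1.0)
    sig = (np.abs(rho) >= rho_threshold) & (p < p_cutoff)
    counts = sig.sum(axis=1)
    if (counts > 0).sum() < k:
        raise ValueError(
            "fewer than k CPRGs have a significantly coexpressed partner; "
            "relax rho_threshold or p_cutoff"
        )
    with np.errstate(invalid="ignore"):
        mean_abs = np.where(counts > 0, np.abs(np.where(sig, rho, 0.0)).sum(axis=1) / np.maximum(counts, 1), 0.0)
    order = sorted(
        range(len(present)),
        key=lambda i: (-counts[i], -mean_abs[i], present[i]),
    )
    core = [present[i] for i in order[:k]]
    core_expr = expr.values.loc[core, samples]
    s_mean = core_expr.mean(axis=1)
    theta = pd.Series(
        {s: sample_theta(core_expr[s].to_numpy(), s_mean.to_numpy()) for s in samples},
        name="theta",
    )
    return ProliferationModel(core_genes=core, s_mean=s_mean, theta=theta)


def sample_theta(s: np.ndarray, s_mean: np.ndarray) -> float:
    """No-intercept least-squares coefficient fitting s_mean from s.

    theta = argmin_t sum_i (s_mean_i - t * s_i)^2 = (s . s_mean) / (s . s).
    An all-zero sample vector yields theta = 0 with a warning.
    """
    denom = float(np.dot(s, s))
    if denom == 0.0:
        logger.warning("all-zero core-gene vector; theta set to 0")
        return 0.0
    return float(np.dot(s, s_mean) / denom)


def mutation_association(
    pm: ProliferationModel, muts: MutationTable, gene: str
) -> ProliferationResult:
    """Wilcoxon rank-sum test of theta between mutated and unmutated samples."""
    samples = list(pm.theta.index)
    rec = muts.records
    mutated = set(rec.loc[rec["gene"] == gene, "sample"]) & set(samples)
    m = sorted(mutated)
    u = sorted(set(samples) - mutated)
    theta_m = pm.theta.reindex(m).to_numpy()
    theta_u = pm.theta.reindex(u).to_numpy()
    if len(m) == 0 or len(u) == 0:
        return ProliferationResult(
            gene=gene,
            m_size=len(m),
            u_size=len(u),
            median_m=float(np.median(theta_m)) if len(m) else float("nan"),
            median_u=float(np.median(theta_u)) if len(u) else float("nan"),
            p_value=1.0,
            is_npcd=False,
            degenerate=True,
        )
    # exact null distribution for small groups, normal approximation with
    # tie correction otherwise
    method = "exact" if min(len(m), len(u)) <= 20 else "asymptotic"
    try:
        res = stats.mannwhitneyu(theta_m, theta_u, alternative="two-sided", method=method)
    except ValueError:  # ties force the asymptotic path
        res = stats.mannwhitneyu(theta_m, theta_u, alternative="two-sided", method="asymptotic")
    p = float(res.pvalue)
    return ProliferationResult(
        gene=gene,
        m_size=len(m),
        u_size=len(u),
        median_m=float(np.median(theta_m)),
        median_u=float(np.median(theta_u)),
        p_value=p,
        is_npcd=p < 0.05,
    )


def call_npcds(
    scores: pd.DataFrame,
    known_drivers: list[str],
    pm: ProliferationModel,
    muts: MutationTable,
    top_n: int = 20,
) -> list[ProliferationResult]:
    """Call newly predicted cancer drivers among the top-scoring genes.

    Takes the top_n genes by driver probability, removes known drivers, runs
    the proliferation association on the remainder and flags p < 0.05;
    results are sorted by p-value.
    """
    ranked = scores.sort_values("p_driver", ascending=False)
    top = list(ranked.index[:top_n])
    known = set(known_drivers)
    candidates = [g for g in top if g not in known]
    results = [mutation_association(pm, muts, g) for g in candidates]
    return sorted(results, key=lambda r: (r.p_value, r.gene))


def results_to_frame(results: list[ProliferationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "m_size": r.m_size,
                "u_size": r.u_size,
                "median_m": r.median_m,
                "median_u": r.median_u,
                "p_value": r.p_value,
                "is_npcd": r.is_npcd,
            }
            for r in results
        ]
    )
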