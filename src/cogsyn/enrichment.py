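"""Gene-set enrichment of delta z-score profiles with permutation significance.

The enrichment score of gene set *l* is the plain mean of the delta
z-scores over the set's members bound to the study universe,

    S_l = (1/N_l) * sum_j Z_ij .

Significance is empirical: the gene labels of the z vector are permuted B
times (equivalently, random gene sets of the same size are drawn) and the
two-sided p-value is (#{|S*| >= |S_obs|} + 1) / (B + 1). P-values are
Benjamini-Hochberg adjusted across the collection. Sets whose score falls
inside the non-informative band |S| <= 1.96/sqrt(N) are flagged and removed
from pair scoring regardless of their p-value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import DeltaZProfile
from .genesets import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "enrichment_score",
    "bh_adjust",
    "informative_filter",
    "permutation_pvalues",
]

#: Critical value defining the non-informative band |S| <= Z_CRIT / sqrt(N).
Z_CRIT = 1.96


def enrichment_score(z: np.ndarray, member_idx: np.ndarray) -> float:
    """Mean delta z-score over the bound members of a gene set."""
    if len(member_idx) == 0:
        raise ValueError("gene set has no members bound to the profile")
    return float(np.mean(np.asarray(z, dtype=float)[member_idx]))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def informative_filter(score: float, n: int) -> bool:
    """True iff |score| exceeds the 1.96/sqrt(N) non-informative band."""
    if n < 1:
        raise ValueError("set size must be >= 1")
    return bool(abs(score) > Z_CRIT / np.sqrt(n))


def permutation_pvalues(
    profile: DeltaZProfile,
    coll: GeneSetCollection,
    b_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every gene set of a collection against one delta z profile.

    For each set the null distribution is built from ``b_permutations``
    gene-label permutations of the z vector; permutations are shared across
    sets of equal bound size (each permutation contributes the mean of its
    first N entries, an exchangeable draw of N genes without replacement).
    Sets with no bound member are skipped with a warning.

    Returns a table with columns drug, concentration, set_name, n_bound,
    score, p_raw, p_adj, informative, enriched, where
    enriched = (p_adj < alpha) AND informative.
    """
    if b_permutations < 1:
        raise ValueError("b_permutations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    z = np.asarray(profile.z, dtype=float)
    gene_pos = {g: i for i, g in enumerate(profile.genes)}
    bound: list[tuple[str, np.ndarray]] = []
    for s in coll.sets:
        idx = np.array(sorted(gene_pos[g] for g in s.members if g in gene_pos), dtype=int)
        if idx.size == 0:
            logger.warning("gene set %r has no members in the profile; skipped", s.name)
            continue
        bound.append((s.name, idx))
    if not bound:
        return pd.DataFrame(columns=["drug", "concentration", "set_name", "n_bound",
                                     "score", "p_raw", "p_adj", "informative", "enriched"])

    # B shuffled copies of z; running means give the null score for every size
    perm = np.empty((b_permutations, z.size))
    for b in range(b_permutations):
        perm[b] = rng.permutation(z)
    running_mean = np.cumsum(perm, axis=1) / np.arange(1, z.size + 1)

    rows = []
    for name, idx in bound:
        n = idx.size
        s_obs = float(np.mean(z[idx]))
        null = np.abs(running_mean[:, n - 1])
        abs_obs = abs(s_obs)
        # numerically equal null scores (e.g. a set spanning the whole
        # universe) must count as >=, so ties are detected with a tolerance
        hits = np.count_nonzero((null > abs_obs) | np.isclose(null, abs_obs, rtol=1e-9, atol=1e-12))
        p_raw = (hits + 1) / (b_permutations + 1)
        rows.append((name, n, s_obs, p_raw))

    df = pd.DataFrame(rows, columns=["set_name", "n_bound", "score", "p_raw"])
    df.insert(0, "concentration", profile.concentration)
    df.insert(0, "drug", profile.drug)
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    df["informative"] = [informative_filter(s, n) for s, n in zip(df["score"], df["n_bound"])]
    df["enriched"] = (df["p_adj"] < alpha) & df["informative"]
    return df
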