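"""Evaluation of predicted synergy rankings against an EOB gold standard.

The gold standard gives, for every drug pair, the mean excess over Bliss
(EOB; observed combined inhibition minus the Bliss-independence
expectation) and its standard error (sem). Rankings are compared with:

* the concordance index (c-index): fraction of pair-of-pairs whose relative
  order agrees between predicted ranks v and gold ranks u (ties count 0.5);
* the probabilistic c-index (PC-index): the 0/1 concordance indicator is
  replaced by t' = 1/2 ± 1/2·erf((EOB_q − EOB_r)/sqrt(sem_q² + sem_r²)),
  weighting each comparison by how distinguishable the two EOBs really are;
* the normalized PC-index (PC − PC_min)/(PC_max − PC_min), where PC_max and
  PC_min are the PC-index of the EOB-descending and -ascending orders;
* SNR classification: a pair with |EOB/sem| > 2 is synergistic (EOB > 0) or
  antagonistic (EOB < 0), otherwise additive;
* ROC curves / AUC obtained by calling the top-i predicted pairs positive
  (decreasing score order for synergy, increasing for antagonism), and
  precision at k.

Rank convention everywhere: rank 1 = most synergistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandard",
    "load_gold_standard",
    "c_index",
    "pc_index",
    "pc_extremes",
    "normalize_pc",
    "pc_permutation_pvalue",
    "snr_classify",
    "roc_curve",
    "precision_at_k",
    "evaluate_ranking",
]


@dataclass
class GoldStandard:
    """EOB gold standard: one row per unordered drug pair.

    ``table`` columns: drug_a, drug_b, eob_mean, eob_sem, gold_rank (1 =
    most synergistic, i.e. largest EOB), label (synergistic / antagonistic /
    additive, derived from the SNR rule).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"drug_a", "drug_b", "eob_mean", "eob_sem"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"gold standard lacks columns {sorted(missing)}")
        if (t["eob_sem"] < 0).any():
            raise ValueError("eob_sem must be >= 0")
        pairs = [tuple(sorted(p)) for p in zip(t["drug_a"], t["drug_b"])]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate drug pairs in gold standard")
        if "gold_rank" not in t.columns:
            order = t.sort_values(
                by=["eob_mean", "drug_a", "drug_b"], ascending=[False, True, True],
                kind="mergesort",
            ).index
            t["gold_rank"] = pd.Series(range(1, len(t) + 1), index=order)
        if "label" not in t.columns:
            t["label"] = snr_classify(t)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def class_counts(self) -> dict[str, int]:
        return self.table["label"].value_counts().to_dict()


def load_gold_standard(path: str | Path) -> GoldStandard:
    """Read a TSV with columns drug_a, drug_b, eob_mean, eob_sem."""
    return GoldStandard(pd.read_csv(path, sep="\t"))


def snr_classify(rows: pd.DataFrame) -> pd.Series:
    """Signal-to-noise classification of gold-standard pairs.

    SNR = eob_mean / eob_sem; synergistic iff SNR > 2 (EOB positive),
    antagonistic iff SNR < -2 (EOB negative), otherwise additive.
    """
    eob = rows["eob_mean"].to_numpy(dtype=float)
    sem = rows["eob_sem"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.divide(eob, sem, out=np.full_like(eob, np.inf) * np.sign(eob), where=sem > 0)
    labels = np.where((snr > 2) & (eob > 0), "synergistic",
                      np.where((np.abs(snr) > 2) & (eob < 0), "antagonistic", "additive"))
    return pd.Series(labels, index=rows.index)


def _pairwise_sign(x: np.ndarray) -> np.ndarray:
    """Upper-triangle (q < r) matrix of sign(x_q - x_r)."""
    return np.sign(x[:, None] - x[None, :])


def c_index(u, v) -> float:
    """Concordance between two rankings over all C(n,2) pair-of-pairs.

    A comparison contributes 1 if u and v order the two items the same way,
    0 if oppositely, and 0.5 if either ranking ties them.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("rank vectors must have equal length")
    n = u.size
    if n < 2:
        raise ValueError("need at least two items")
    du = _pairwise_sign(u)
    dv = _pairwise_sign(v)
    prod = du * dv
    t = np.where(prod > 0, 1.0, np.where(prod < 0, 0.0, 0.5))
    iu = np.triu_indices(n, k=1)
    return float(t[iu].mean())


def _t_prime_matrix(eob: np.ndarray, sem: np.ndarray) -> np.ndarray:
    """erf((EOB_q - EOB_r)/sqrt(sem_q^2 + sem_r^2)) for all q, r.

    A zero denominator with equal EOBs gives erf-term 0 (contribution 0.5,
    logged); with distinct EOBs it gives the ±1 step limit.
    """
    diff = eob[:, None] - eob[None, :]
    denom = np.sqrt(sem[:, None] ** 2 + sem[None, :] ** 2)
    zero_div = denom == 0
    if np.any(zero_div & (diff == 0) & ~np.eye(len(eob), dtype=bool)):
        logger.info("zero sem with equal EOBs: concordance contribution set to 0.5")
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = np.where(zero_div, np.sign(diff) * np.inf, diff / np.where(zero_div, 1.0, denom))
    arg = np.where(zero_div & (diff == 0), 0.0, arg)
    return erf(arg)


def pc_index(gold: GoldStandard, v) -> float:
    """Probabilistic c-index of predicted ranks v against the gold standard.

    t'_{q,r} = 1/2 + 1/2·erf(Δ/σ) when v ranks q better (smaller rank) than
    r, and 1/2 − 1/2·erf(Δ/σ) when worse; ties in v contribute 0.5 (the two
    branches averaged). The PC-index is the mean of t' over all unordered
    pair-of-pairs.
    """
    t = gold.table
    v = np.asarray(v, dtype=float)
    if v.size != len(t):
        raise ValueError("predicted ranks must match gold-standard length")
    e = _t_prime_matrix(t["eob_mean"].to_numpy(float), t["eob_sem"].to_numpy(float))
    dv = _pairwise_sign(v)  # dv[q,r] < 0 when v_q < v_r (q predicted better)
    tprime = np.where(dv < 0, 0.5 + 0.5 * e, np.where(dv > 0, 0.5 - 0.5 * e, 0.5))
    iu = np.triu_indices(v.size, k=1)
    return float(tprime[iu].mean())


def pc_extremes(gold: GoldStandard) -> tuple[float, float]:
    """(PC_max, PC_min): PC-index of the EOB-descending / ascending orders."""
    eob = gold.table["eob_mean"].to_numpy(float)
    best = pd.Series(-eob).rank(method="first").to_numpy()
    worst = pd.Series(eob).rank(method="first").to_numpy()
    return pc_index(gold, best), pc_index(gold, worst)


def normalize_pc(pc: float, pc_max: float, pc_min: float) -> float:
    """Rescale a PC-index so the gold standard's own extremes map to 1 and 0."""
    if pc_max <= pc_min:
        raise ValueError("degenerate gold standard: pc_max must exceed pc_min")
    return (pc - pc_min) / (pc_max - pc_min)


def pc_permutation_pvalue(
    gold: GoldStandard,
    v,
    b_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Upper-tail empirical p-value of a PC-index under random rankings.

    Permutes the predicted ranks ``b_permutations`` times; p = (#{PC* >=
    PC_obs} + 1)/(B + 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = np.asarray(v, dtype=float)
    obs = pc_index(gold, v)
    count = 0
    for _ in range(b_permutations):
        if pc_index(gold, rng.permutation(v)) >= obs:
            count += 1
    return (count + 1) / (b_permutations + 1)


def roc_curve(labels, ranks, positive: str, direction: str = "synergy"):
    """ROC staircase from calling the top-i ranked pairs positive.

    ``ranks``: 1 = most synergistic. For ``direction='synergy'`` the sweep
    follows increasing rank (most synergistic first); for ``'antagonism'``
    it follows decreasing rank. Returns (points DataFrame with i, fpr, tpr;
    AUC by trapezoidal integration).
    """
    labels = np.asarray(labels)
    ranks = np.asarray(ranks, dtype=float)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    order = np.argsort(ranks if direction == "synergy" else -ranks, kind="stable")
    tp = np.concatenate([[0], np.cumsum(pos[order])])
    fp = np.concatenate([[0], np.cumsum(~pos[order])])
    tpr = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"i": np.arange(len(tpr)), "fpr": fpr, "tpr": tpr})
    return points, auc


def precision_at_k(labels, ranks, k: int, positive: str, direction: str = "synergy") -> float:
    """Fraction of the top-k called pairs that carry the positive label."""
    labels = np.asarray(labels)
    ranks = np.asarray(ranks, dtype=float)
    if not 1 <= k <= labels.size:
        raise ValueError("k must be in [1, n]")
    order = np.argsort(ranks if direction == "synergy" else -ranks, kind="stable")
    top = labels[order[:k]]
    return float(np.mean(top == positive))


def evaluate_ranking(
    gold: GoldStandard,
    predicted_ranks,
    b_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Full evaluation report of one predicted ranking.

    Returns c-index, PC-index with permutation p-value, PC extremes and the
    normalized PC-index, synergy/antagonism AUCs and precisions (k = number
    of pairs in each class), and class counts.
    """
    t = gold.table
    v = np.asarray(predicted_ranks, dtype=float)
    u = t["gold_rank"].to_numpy(float)
    pc = pc_index(gold, v)
    pc_max, pc_min = pc_extremes(gold)
    labels = t["label"].to_numpy()
    counts = gold.class_counts
    report: dict = {
        "n_pairs": len(t),
        "c_index": c_index(u, v),
        "pc_index": pc,
        "pc_max": pc_max,
        "pc_min": pc_min,
        "pc_index_norm": normalize_pc(pc, pc_max, pc_min),
        "pc_permutation_p": pc_permutation_pvalue(gold, v, b_permutations, seed),
        "pc_permutations": b_permutations,
        "seed": seed,
        "n_synergistic": counts.get("synergistic", 0),
        "n_antagonistic": counts.get("antagonistic", 0),
        "n_additive": counts.get("additive", 0),
    }
    for cls, direction in (("synergistic", "synergy"), ("antagonistic", "antagonism")):
        key = "synergy" if cls == "synergistic" else "antagonism"
        k = counts.get(cls, 0)
        if k and k < len(t):
            _, auc = roc_curve(labels, v, positive=cls, direction=direction)
            report[f"auc_{key}"] = auc
            report[f"precision_{key}"] = precision_at_k(labels, v, k, cls, direction=direction)
        else:
            report[f"auc_{key}"] = float("nan")
            report[f"precision_{key}"] = float("nan")
    return report
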