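"""Pairwise synergy scores from per-drug signatures, and pair ranking.

Three similarity scores are computed for every unordered pair of drugs
(d1, d2), each in [0, 1]; higher values predict stronger synergy:

* co-gene  = g(d1,d2) / G — fraction of the G-gene universe significantly
  changed by both drugs;
* co-GS    = n(d1,d2) / L — fraction of the L representative gene sets
  enriched in both drugs;
* co-gene/GS — over the n(d1,d2) co-enriched sets l, the average fraction
  N_l(d1,d2)/N_l of a set's (bound) genes significantly changed by both
  drugs; defined as 0 when no set is co-enriched.

When a drug was profiled at several concentrations, each concentration is
scored as a separate instance and a drug pair is represented by its most
synergistic instance pair (maximum score; a mean rule is also available).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DrugSignature",
    "co_gene_score",
    "co_gs_score",
    "co_gene_gs_score",
    "collapse_concentrations",
    "build_pair_table",
    "rank_pairs",
]

SCORE_COLUMNS = ("co_gene", "co_gs", "co_gene_gs")


@dataclass(frozen=True)
class DrugSignature:
    """What one drug instance did: significant genes and enriched sets.

    ``enriched_sets`` maps each enriched representative set name to its
    members bound to the study universe (so N_l below is the bound size).
    """

    drug: str
    concentration: str
    significant_genes: frozenset[str]
    enriched_sets: dict[str, frozenset[str]]

    @property
    def instance(self) -> str:
        return f"{self.drug}@{self.concentration}"


def co_gene_score(a: DrugSignature, b: DrugSignature, n_genes: int) -> float:
    """Fraction of the gene universe significantly changed by both drugs."""
    if n_genes < 1:
        raise ValueError("gene universe size must be >= 1")
    return len(a.significant_genes & b.significant_genes) / n_genes


def co_gs_score(a: DrugSignature, b: DrugSignature, n_sets: int) -> float:
    """Fraction of the gene-set collection enriched in both drugs."""
    if n_sets < 1:
        raise ValueError("collection size must be >= 1")
    return len(a.enriched_sets.keys() & b.enriched_sets.keys()) / n_sets


def co_gene_gs_score(a: DrugSignature, b: DrugSignature) -> float:
    """Average fraction of co-enriched set members significant in both drugs.

    Returns 0 when the two drugs share no enriched gene set, ranking such
    pairs below any pair with overlap.
    """
    shared = a.enriched_sets.keys() & b.enriched_sets.keys()
    if not shared:
        return 0.0
    co_sig = a.significant_genes & b.significant_genes
    fractions = [len(a.enriched_sets[l] & co_sig) / len(a.enriched_sets[l]) for l in shared]
    return sum(fractions) / len(shared)


def co_enriched_sets(a: DrugSignature, b: DrugSignature) -> list[str]:
    return sorted(a.enriched_sets.keys() & b.enriched_sets.keys())


def collapse_concentrations(instance_scores, rule: str = "max") -> float:
    """Collapse instance-pair scores of one drug pair to a single value."""
    scores = list(instance_scores)
    if not scores:
        raise ValueError("no instance-pair scores to collapse")
    if rule == "max":
        return max(scores)
    if rule == "mean":
        return sum(scores) / len(scores)
    raise ValueError(f"unknown collapse rule {rule!r}")


def build_pair_table(
    signatures: list[DrugSignature],
    n_genes: int,
    n_sets: int,
    collapse_rule: str = "max",
) -> pd.DataFrame:
    """Score all unordered drug pairs; one row per pair, C(K,2) rows.

    Scores are computed for every (instance of a) x (instance of b)
    combination and collapsed per score column with ``collapse_rule``. The
    reported co-enriched set names come from the instance pair maximizing
    the co-gene/GS score (first in instance order on ties). Ranks per score
    column are attached by :func:`rank_pairs`.
    """
    by_drug: dict[str, list[DrugSignature]] = {}
    for sig in signatures:
        by_drug.setdefault(sig.drug, []).append(sig)
    drugs = sorted(by_drug)
    if len(drugs) < 2:
        raise ValueError("need at least two distinct drugs")

    rows = []
    for da, db in itertools.combinations(drugs, 2):
        inst_scores = {c: [] for c in SCORE_COLUMNS}
        best_sets, best_cggs = [], -1.0
        for sa in by_drug[da]:
            for sb in by_drug[db]:
                cg = co_gene_score(sa, sb, n_genes)
                cgs = co_gs_score(sa, sb, n_sets)
                cggs = co_gene_gs_score(sa, sb)
                inst_scores["co_gene"].append(cg)
                inst_scores["co_gs"].append(cgs)
                inst_scores["co_gene_gs"].append(cggs)
                if cggs > best_cggs:
                    best_cggs = cggs
                    best_sets = co_enriched_sets(sa, sb)
        rows.append({
            "drug_a": da,
            "drug_b": db,
            **{c: collapse_concentrations(inst_scores[c], collapse_rule) for c in SCORE_COLUMNS},
            "co_enriched_sets": "|".join(best_sets),
        })
    table = pd.DataFrame(rows)
    for col in SCORE_COLUMNS:
        table = rank_pairs(table, col)
    return table


def rank_pairs(table: pd.DataFrame, score_column: str) -> pd.DataFrame:
    """Attach ranks 1..n for a score column, 1 = highest (most synergistic).

    Ties are broken deterministically by (drug_a, drug_b) lexicographic
    order, so ranks are always a permutation of 1..n.
    """
    if score_column not in table.columns:
        raise ValueError(f"no score column {score_column!r}")
    order = table.sort_values(
        by=[score_column, "drug_a", "drug_b"], ascending=[False, True, True], kind="mergesort"
    ).index
    ranks = pd.Series(range(1, len(table) + 1), index=order)
    out = table.copy()
    out[f"rank_{score_column}"] = ranks
    return out
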