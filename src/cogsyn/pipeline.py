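"""End-to-end scoring pipeline: study + gene sets -> ranked pair table.

Chains delta z-scores, per-gene significance, permutation enrichment and
the three pair scores; the CLI wraps these functions, and they are equally
usable from Python.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .enrichment import permutation_pvalues
from .expression import ExpressionStudy, delta_z, gene_significance
from .genesets import GeneSetCollection
from .scores import DrugSignature, build_pair_table

logger = logging.getLogger(__name__)

__all__ = ["ScoringConfig", "score_study", "drug_signatures"]


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds and reproducibility knobs of one scoring run."""

    seed: int
    gene_alpha: float = 0.05
    set_alpha: float = 0.05
    b_permutations: int = 1000
    std_mode: str = "sample"
    null_variance: float = 1.0
    collapse_rule: str = "max"

    def __post_init__(self) -> None:
        for name in ("gene_alpha", "set_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.b_permutations < 1:
            raise ValueError("b_permutations must be >= 1")


def drug_signatures(
    study: ExpressionStudy,
    coll: GeneSetCollection,
    cfg: ScoringConfig,
) -> tuple[list[DrugSignature], pd.DataFrame, GeneSetCollection]:
    """Per-instance signatures plus the full enrichment table.

    The collection is bound to the study's gene universe first. Each treated
    sample gets its own sub-generator spawned deterministically from the
    run seed, so results do not depend on sample order.
    """
    bound = coll.bind(study.genes)
    seq = np.random.SeedSequence(cfg.seed)
    children = seq.spawn(len(study.treated))

    signatures: list[DrugSignature] = []
    tables: list[pd.DataFrame] = []
    bound_members = bound.bound_members()
    for info, child in zip(study.treated, children):
        profile = delta_z(study, info.sample_id, std_mode=cfg.std_mode)
        profile = gene_significance(profile, alpha=cfg.gene_alpha,
                                    null_variance=cfg.null_variance)
        enr = permutation_pvalues(profile, bound, cfg.b_permutations,
                                  seed=np.random.default_rng(child), alpha=cfg.set_alpha)
        tables.append(enr)
        enriched = {name: bound_members[name]
                    for name in enr.loc[enr["enriched"], "set_name"]}
        signatures.append(DrugSignature(
            drug=info.drug,
            concentration=info.concentration,
            significant_genes=profile.significant_genes,
            enriched_sets=enriched,
        ))
    enrichment_table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return signatures, enrichment_table, bound


def score_study(
    study: ExpressionStudy,
    coll: GeneSetCollection,
    cfg: ScoringConfig,
) -> dict:
    """Run the full pipeline; returns pair table, enrichment table, manifest."""
    signatures, enrichment_table, bound = drug_signatures(study, coll, cfg)
    pair_table = build_pair_table(
        signatures,
        n_genes=study.n_genes,
        n_sets=len(bound),
        collapse_rule=cfg.collapse_rule,
    )
    manifest = {
        "config": asdict(cfg),
        "n_genes": study.n_genes,
        "n_samples": len(study.samples),
        "n_sets_bound": len(bound),
        "n_drugs": len({s.drug for s in signatures}),
    }
    return {
        "pair_table": pair_table,
        "enrichment_table": enrichment_table,
        "signatures": signatures,
        "collection": bound,
        "manifest": manifest,
    }
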