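"""Synthetic expression studies with planted gene-set perturbations.

The generator encodes the working hypothesis — synergistic drug pairs
perturb overlapping biological functions — as its ground truth. Each drug
is assigned a window of gene sets from the collection; treated samples
shift the member genes of those sets by a common effect size on top of
Gaussian noise, and the gold-standard EOB of a drug pair is a scaled
Jaccard overlap of the two drugs' planted set lists plus Gaussian noise.
Recovery of the planted pair ordering by the scoring pipeline is therefore
a test of the implementation, not of the biology.

Consecutive drugs' windows overlap by ``sets_per_drug - overlap_step``
sets, producing a graded spectrum of pair overlaps (strong / weak / none),
which is what a ranking method must resolve.

Defaults follow the reference study design: 2,000 genes, 100 gene sets of
15-25 genes, 8 drugs perturbing 20 sets each (window step 8), effect size
2 delta-z units, noise sd 1, 200 permutations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionStudy, SampleInfo
from .evaluation import GoldStandard
from .genesets import GeneSet, GeneSetCollection, write_gmt

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "simulate_study",
    "planted_gold_standard",
    "write_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; the seed is mandatory.

    ``effect_size`` is in delta-z units (shift added to member genes of a
    drug's planted sets, before the per-sample Gaussian noise of sd
    ``noise_sd``); ``overlap_step`` is the offset between consecutive
    drugs' gene-set windows, so adjacent drugs share
    ``sets_per_drug - overlap_step`` planted sets.
    """

    seed: int
    n_genes: int = 2000
    n_sets: int = 100
    set_size_range: tuple[int, int] = (15, 25)
    n_drugs: int = 8
    sets_per_drug: int = 20
    overlap_step: int = 8
    effect_size: float = 2.0
    noise_sd: float = 1.0
    n_controls: int = 1
    n_concentrations: int = 1
    b_permutations: int = 200

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_sets", "n_drugs", "sets_per_drug",
                     "overlap_step", "n_controls", "n_concentrations", "b_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ValueError("set_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError("set size exceeds number of genes")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.sets_per_drug > self.n_sets:
            raise ValueError("sets_per_drug exceeds n_sets")


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: what each drug perturbs."""

    drug_sets: dict[str, list[str]]
    drug_genes: dict[str, frozenset[str]]
    set_signs: dict[str, int]

    def pair_jaccard(self, drug_a: str, drug_b: str) -> float:
        a, b = set(self.drug_sets[drug_a]), set(self.drug_sets[drug_b])
        return len(a & b) / len(a | b)

    def pair_overlaps(self) -> pd.DataFrame:
        rows = [
            {"drug_a": a, "drug_b": b, "jaccard": self.pair_jaccard(a, b)}
            for a, b in itertools.combinations(sorted(self.drug_sets), 2)
        ]
        return pd.DataFrame(rows)


def simulate_study(cfg: SimulationConfig) -> tuple[ExpressionStudy, GeneSetCollection, PlantedTruth]:
    """Generate an expression study, a gene-set collection and the truth.

    Genes carry an N(8, 2) baseline (log2-intensity-like); every sample adds
    N(0, noise_sd) noise; a treated sample additionally shifts each member
    gene of the drug's planted sets by sign(set) * effect_size * dose, where
    dose = c/n_concentrations for concentration index c (top dose = full
    effect). Shifts of a drug's overlapping sets add.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}

    lo, hi = cfg.set_size_range
    sets = []
    for s in range(cfg.n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(cfg.n_genes, size=size, replace=False)
        sets.append(GeneSet(name=f"SET{s:04d}", members=frozenset(genes[i] for i in members),
                            category="simulated"))
    coll = GeneSetCollection(sets=sets, universe=frozenset(genes))
    set_signs = {s.name: int(rng.choice([-1, 1])) for s in sets}

    drugs = [f"drug{d:02d}" for d in range(cfg.n_drugs)]
    drug_sets: dict[str, list[str]] = {}
    for d, drug in enumerate(drugs):
        start = (d * cfg.overlap_step) % cfg.n_sets
        idx = [(start + k) % cfg.n_sets for k in range(cfg.sets_per_drug)]
        drug_sets[drug] = [sets[i].name for i in sorted(set(idx))]
    drug_genes = {
        drug: frozenset().union(*(coll.get(n).members for n in names))
        for drug, names in drug_sets.items()
    }

    baseline = rng.normal(8.0, 2.0, size=cfg.n_genes)
    columns: dict[str, np.ndarray] = {}
    samples: list[SampleInfo] = []
    for c in range(cfg.n_controls):
        sid = f"DMSO_{c+1}"
        columns[sid] = baseline + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
        samples.append(SampleInfo(sid, "DMSO", "0", True))
    for drug in drugs:
        shift = np.zeros(cfg.n_genes)
        for name in drug_sets[drug]:
            for g in coll.get(name).members:
                shift[gene_pos[g]] += set_signs[name] * cfg.effect_size
        for c in range(1, cfg.n_concentrations + 1):
            dose = c / cfg.n_concentrations
            sid = f"{drug}_c{c}"
            columns[sid] = baseline + dose * shift + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
            samples.append(SampleInfo(sid, drug, str(c), False))

    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    study = ExpressionStudy(values=values, samples=samples)
    truth = PlantedTruth(drug_sets=drug_sets, drug_genes=drug_genes, set_signs=set_signs)
    return study, coll, truth


def planted_gold_standard(
    truth: PlantedTruth,
    eob_scale: float = 10.0,
    eob_noise_sd: float = 0.5,
    seed: int = 0,
) -> GoldStandard:
    """Gold standard whose EOB is scaled planted overlap plus noise.

    EOB_mean(a, b) = eob_scale * Jaccard(planted sets of a, of b) + N(0,
    eob_noise_sd); eob_sem is reported as eob_noise_sd (single-draw
    convention). Ranks and SNR class labels are derived as for real data.
    """
    rng = np.random.default_rng(seed)
    rows = truth.pair_overlaps()
    noise = rng.normal(0.0, eob_noise_sd, size=len(rows)) if eob_noise_sd > 0 else 0.0
    table = pd.DataFrame({
        "drug_a": rows["drug_a"],
        "drug_b": rows["drug_b"],
        "eob_mean": eob_scale * rows["jaccard"] + noise,
        "eob_sem": float(eob_noise_sd),
    })
    return GoldStandard(table)


def write_study(
    study: ExpressionStudy,
    coll: GeneSetCollection,
    gold: GoldStandard,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write expression TSV, metadata TSV, GMT and gold-standard TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "samples.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "gold_standard": out / "gold_standard.tsv",
    }
    study.values.to_csv(paths["expression"], sep="\t")
    pd.DataFrame(
        [(s.sample_id, s.drug, s.concentration, int(s.is_control)) for s in study.samples],
        columns=["sample_id", "drug", "concentration", "is_control"],
    ).to_csv(paths["metadata"], sep="\t", index=False)
    write_gmt(coll, paths["gene_sets"])
    gold.table[["drug_a", "drug_b", "eob_mean", "eob_sem"]].to_csv(
        paths["gold_standard"], sep="\t", index=False)
    return paths
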