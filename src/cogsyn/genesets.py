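"""Gene-set collections: GMT I/O, Cohen's kappa, redundancy clustering.

Functional gene-set collections (GO, curated perturbation signatures, ...)
are highly redundant. Before enrichment analysis the collection is reduced
by clustering sets whose membership agreement, measured by Cohen's kappa
over the study's gene universe, exceeds a threshold, and keeping one
representative per cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "kappa",
    "cluster_representatives",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers with an origin/category label."""

    name: str
    members: frozenset[str]
    category: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def bound(self, universe: Iterable[str]) -> frozenset[str]:
        """Members restricted to a gene universe (original size retained)."""
        return self.members & frozenset(universe)


@dataclass
class GeneSetCollection:
    """A list of uniquely named gene sets over a gene universe.

    ``universe`` defaults to the union of all members; binding to an
    expression study replaces it by the intersection with the study's genes.
    After clustering, ``representative_of`` maps every set name to the name
    of its cluster representative.
    """

    sets: list[GeneSet]
    universe: frozenset[str] = field(default_factory=frozenset)
    representative_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise ValueError("gene set names must be unique")
        if not self.universe:
            self.universe = frozenset().union(*(s.members for s in self.sets)) if self.sets else frozenset()

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def bind(self, genes: Iterable[str], min_size: int = 1) -> "GeneSetCollection":
        """Bind the collection to a study: the universe becomes the
        intersection of the collection's gene space (union of members) with
        the given genes; sets whose bound size falls below ``min_size`` are
        dropped (logged)."""
        gene_space = frozenset().union(*(s.members for s in self.sets)) if self.sets else frozenset()
        uni = gene_space & frozenset(genes) & self.universe
        kept, dropped = [], []
        for s in self.sets:
            if len(s.members & uni) >= min_size:
                kept.append(s)
            else:
                dropped.append(s.name)
        if dropped:
            logger.info("dropped %d gene sets with <%d genes in the study universe", len(dropped), min_size)
        return GeneSetCollection(sets=kept, universe=uni, representative_of=self.representative_of)

    def bound_members(self) -> dict[str, frozenset[str]]:
        return {s.name: s.members & self.universe for s in self.sets}


def read_gmt(path: str | Path, category: str = "") -> GeneSetCollection:
    """Parse a GMT file (name, description, tab-separated member genes)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}: expected name, "
                                 f"description and at least one member")
            name, _desc = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValueError(f"{path}: gene set {name!r} on line {lineno} has no members")
            sets.append(GeneSet(name=name, members=members, category=category))
    return GeneSetCollection(sets=sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in coll.sets:
            fh.write("\t".join([s.name, s.category or "na", *sorted(s.members)]) + "\n")


def kappa(set_a: GeneSet | frozenset[str], set_b: GeneSet | frozenset[str],
          universe: Iterable[str]) -> float:
    """Cohen's kappa between two binary membership vectors over a universe.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement
    p_o = (|A∩B| + |Aᶜ∩Bᶜ|)/U and chance agreement
    p_e = (|A||B| + (U-|A|)(U-|B|))/U². The degenerate case p_e = 1 (both
    sets empty or both equal to the universe) is defined as 1 for identical
    sets, else 0.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    a = (set_a.members if isinstance(set_a, GeneSet) else frozenset(set_a)) & uni
    b = (set_b.members if isinstance(set_b, GeneSet) else frozenset(set_b)) & uni
    u = len(uni)
    both = len(a & b)
    neither = u - len(a | b)
    p_o = (both + neither) / u
    p_e = (len(a) * len(b) + (u - len(a)) * (u - len(b))) / u**2
    if p_e == 1.0:
        logger.info("degenerate kappa (p_e = 1); returning %d", int(a == b))
        return 1.0 if a == b else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def _kappa_matrix(members: list[frozenset[str]], universe: frozenset[str]) -> np.ndarray:
    """Pairwise Cohen's kappa via binary membership linear algebra."""
    genes = sorted(universe)
    idx = {g: i for i, g in enumerate(genes)}
    u = len(genes)
    m = np.zeros((len(members), u), dtype=np.int32)
    for i, mem in enumerate(members):
        for g in mem & universe:
            m[i, idx[g]] = 1
    sizes = m.sum(axis=1)
    inter = m @ m.T
    neither = u - sizes[:, None] - sizes[None, :] + inter
    p_o = (inter + neither) / u
    p_e = (sizes[:, None] * sizes[None, :] + (u - sizes)[:, None] * (u - sizes)[None, :]) / u**2
    with np.errstate(invalid="ignore", divide="ignore"):
        k = (p_o - p_e) / (1.0 - p_e)
    # degenerate p_e = 1: identical -> 1, else 0
    deg = p_e >= 1.0
    if deg.any():
        same = (inter == sizes[:, None]) & (inter == sizes[None, :])
        k[deg] = np.where(same[deg], 1.0, 0.0)
    return k


def cluster_representatives(
    coll: GeneSetCollection,
    threshold: float = 0.5,
    selection: str = "largest",
) -> GeneSetCollection:
    """Single-linkage kappa clustering with one representative per cluster.

    Gene sets are nodes; an edge joins two sets when their kappa over the
    collection's universe is >= ``threshold``; clusters are the connected
    components. Within a cluster the representative is the set with the most
    bound members (ties broken by lexicographically smallest name), so the
    result is independent of input order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if selection != "largest":
        raise ValueError(f"unknown selection rule {selection!r}")
    if not coll.sets:
        return GeneSetCollection(sets=[], universe=coll.universe, representative_of={})

    order = sorted(range(len(coll.sets)), key=lambda i: coll.sets[i].name)
    sets = [coll.sets[i] for i in order]
    members = [s.members & coll.universe for s in sets]
    k = _kappa_matrix(members, coll.universe)
    adj = csr_matrix(k >= threshold)
    n_comp, labels = connected_components(adj, directed=False)

    reps: dict[int, GeneSet] = {}
    rep_of: dict[str, str] = {}
    for comp in range(n_comp):
        idxs = [i for i in range(len(sets)) if labels[i] == comp]
        best = min(idxs, key=lambda i: (-len(members[i]), sets[i].name))
        reps[comp] = sets[best]
        for i in idxs:
            rep_of[sets[i].name] = sets[best].name
    rep_sets = sorted(reps.values(), key=lambda s: s.name)
    logger.info("kappa clustering: %d sets -> %d representatives (threshold %.2f)",
                len(sets), len(rep_sets), threshold)
    return GeneSetCollection(sets=rep_sets, universe=coll.universe, representative_of=rep_of)
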