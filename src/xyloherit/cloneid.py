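"""Clone identification from multilocus SSR genotypes.

White spruce reproduces vegetatively by layering, so a stand contains
ramets (genetically identical stems) of the same genet.  Genets are
recovered from microsatellite fingerprints with an error-tolerant
threshold rule: two trees are considered clone-mates when their
genotypes deviate at no more than ``max_mismatch`` loci, and trees whose
genotypes carry more than ``max_null`` null-allele loci are excluded
beforehand.  Because genotyping errors are far more likely to split a
true clone than to merge two distinct genets, the mismatch threshold is
deliberately permissive and grouping is transitive (single linkage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

#: Sentinel for a null allele (locus amplified on one chromosome only,
#: or flagged as containing a non-amplifying allele).
NULL = "NULL"

# A locus call is either None (missing: no data at all) or an unordered
# pair of allele states; each state is an int fragment size or NULL.
LocusCall = "frozenset | None"


def make_locus_call(a1, a2) -> frozenset | None:
    """Build an order-independent locus call from two allele entries.

    ``None``/empty on both sides means the locus is missing.  A single
    empty entry is treated as a null allele on that chromosome.
    """
    def norm(a):
        if a is None or (isinstance(a, str) and a.strip() in ("", "NA")):
            return None
        if isinstance(a, str) and a.strip().upper() == NULL:
            return NULL
        return int(a)

    a1, a2 = norm(a1), norm(a2)
    if a1 is None and a2 is None:
        return None
    if a1 is None:
        a1 = NULL
    if a2 is None:
        a2 = NULL
    return frozenset({a1, a2}) if a1 != a2 else frozenset({a1})


@dataclass
class Genotype:
    """Multilocus SSR genotype of one tree.

    Parameters
    ----------
    tree_id : str
        Tree identifier.
    locus_calls : list
        One entry per locus; each is ``None`` (missing) or a frozenset
        of allele states (ints, or the string ``"NULL"``).
    """

    tree_id: str
    locus_calls: list = field(default_factory=list)

    @property
    def n_loci(self) -> int:
        return len(self.locus_calls)

    def n_null_loci(self) -> int:
        """Number of loci flagged as containing a null allele."""
        return sum(
            1 for c in self.locus_calls if c is not None and NULL in c
        )


@dataclass
class CloneAssignment:
    """Partition of trees into clonal groups and singletons.

    ``group_of`` maps every tree_id to a group label; ``singleton``
    flags trees that are the sole member of their group (non-clonal).
    Clone group labels are ``"C<k>"`` numbered by the smallest member
    tree_id; singletons keep their own tree_id as label.
    """

    group_of: dict
    singleton: dict

    @property
    def clone_groups(self) -> dict:
        """Mapping group label -> sorted member list, clones only."""
        out: dict = {}
        for t, g in self.group_of.items():
            if not self.singleton[t]:
                out.setdefault(g, []).append(t)
        return {g: sorted(m) for g, m in out.items()}

    @property
    def n_clonal_trees(self) -> int:
        return sum(1 for t, s in self.singleton.items() if not s)


def count_locus_mismatches(g1: Genotype, g2: Genotype) -> int:
    """Number of loci at which two genotypes deviate.

    A locus counts as a mismatch only when both genotypes have a
    non-missing call there and the unordered allele pairs differ.  Loci
    missing on either side are excluded — missing data must not split
    clones.  Null-allele states participate in the comparison like any
    other allele.
    """
    if g1.n_loci != g2.n_loci:
        raise ValueError(
            f"locus count mismatch: {g1.tree_id} has {g1.n_loci}, "
            f"{g2.tree_id} has {g2.n_loci}"
        )
    return sum(
        1
        for c1, c2 in zip(g1.locus_calls, g2.locus_calls)
        if c1 is not None and c2 is not None and c1 != c2
    )


def filter_null_alleles(
    genotypes: list[Genotype], max_null: int = 2
) -> list[Genotype]:
    """Drop trees whose genotype has more than ``max_null`` null-allele loci."""
    kept = []
    for g in genotypes:
        n = g.n_null_loci()
        if n > max_null:
            logger.warning(
                "tree %s removed: %d null-allele loci (max %d)",
                g.tree_id, n, max_null,
            )
        else:
            kept.append(g)
    return kept


def cluster_clones(
    genotypes: list[Genotype], max_mismatch: int = 2
) -> CloneAssignment:
    """Group genotypes into clones by the pairwise-mismatch threshold.

    Builds the graph with an edge between every pair deviating at no
    more than ``max_mismatch`` loci and takes connected components
    (single linkage): clone membership is transitive through chains of
    pairwise similarity.  Components of size one are singletons.
    """
    graph = nx.Graph()
    graph.add_nodes_from(g.tree_id for g in genotypes)
    for i, g1 in enumerate(genotypes):
        for g2 in genotypes[i + 1:]:
            if count_locus_mismatches(g1, g2) <= max_mismatch:
                graph.add_edge(g1.tree_id, g2.tree_id)

    group_of: dict = {}
    singleton: dict = {}
    clones = sorted(
        (c for c in nx.connected_components(graph) if len(c) > 1),
        key=lambda c: str(min(c, key=str)),
    )
    for k, comp in enumerate(clones, start=1):
        label = f"C{k}"
        for t in comp:
            group_of[t] = label
            singleton[t] = False
    for comp in nx.connected_components(graph):
        if len(comp) == 1:
            (t,) = comp
            group_of[t] = t
            singleton[t] = True
    return CloneAssignment(group_of=group_of, singleton=singleton)
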