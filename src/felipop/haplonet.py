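"""Haplotype extraction over gene regions and minimum-spanning networks.

Haplotypes are allele strings over the phased variant sites of a region.
The statistical-parsimony network of TCS is approximated by a
minimum-spanning network (MSN): a minimum-spanning-tree construction over
pairwise Hamming distances that, at each accepted edge weight, also keeps
all tied-weight edges joining components that were still separate when
that weight class was reached.  A connection limit drops edges above a
maximum mutational distance; the automatic limit is the largest number of
steps j whose no-homoplasy probability, approximated as
prod_{i=1}^{j-1} (1 - i/L) for L variable sites, stays >= 0.95.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .genomatrix import GenotypeMatrix, PopulationMap


@dataclass
class HaplotypeSet:
    region: str
    haplotypes: list[str]                     # unique, in first-seen order
    multiplicity: dict[tuple[str, str], int]  # (haplotype, group) -> count
    n_sites: int
    excluded_samples: list[str] = field(default_factory=list)

    def group_multiplicity(self, hap: str, group: str) -> int:
        return self.multiplicity.get((hap, group), 0)

    def total_multiplicity(self) -> int:
        return sum(self.multiplicity.values())

    @property
    def groups(self) -> list[str]:
        out = []
        for (_, g) in self.multiplicity:
            if g not in out:
                out.append(g)
        return out


def extract_haplotypes(
    gm: GenotypeMatrix, pm: PopulationMap, chrom: str, start: int, end: int
) -> HaplotypeSet:
    """Two allele strings per sample over the region's variants.

    Requires phased data; samples with any missing call in the region are
    excluded (and listed in the result).
    """
    if not gm.phased:
        raise ValueError(
            "haplotype extraction requires phased input; phase externally"
        )
    idx = [
        i for i, v in enumerate(gm.variants)
        if v.chrom == chrom and start <= v.pos < end
    ]
    if not idx:
        raise ValueError(f"region {chrom}:{start}-{end} contains no variants")
    sub = gm.calls[idx]
    haps: list[str] = []
    mult: dict[tuple[str, str], int] = {}
    excluded = []
    for j, sample in enumerate(gm.samples):
        group = pm.assignments.get(sample)
        if group is None:
            continue
        calls = sub[:, j, :]
        if (calls < 0).any():
            excluded.append(sample)
            continue
        for hap_alleles in (calls[:, 0], calls[:, 1]):
            h = "".join(str(int(a)) for a in hap_alleles)
            if h not in haps:
                haps.append(h)
            mult[(h, group)] = mult.get((h, group), 0) + 1
    return HaplotypeSet(
        f"{chrom}:{start}-{end}", haps, mult, len(idx), excluded
    )


def shared_counts(hs: HaplotypeSet) -> dict[tuple[str, str], int]:
    """Per group pair: number of unique haplotypes present in both."""
    groups = hs.groups
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for sharing counts")
    out = {}
    for g1, g2 in itertools.combinations(groups, 2):
        out[(g1, g2)] = sum(
            1
            for h in hs.haplotypes
            if hs.group_multiplicity(h, g1) > 0 and hs.group_multiplicity(h, g2) > 0
        )
    return out


def hamming(h1: str, h2: str) -> int:
    if len(h1) != len(h2):
        raise ValueError("haplotype length mismatch")
    return sum(a != b for a, b in zip(h1, h2))


def parsimony_limit(n_sites: int, confidence: float = 0.95) -> int:
    """Largest step count whose approximate no-homoplasy probability
    (each new mutation hits a previously unhit site:
    prod_{i=1}^{j-1}(1 - i/L)) is >= ``confidence``."""
    if n_sites < 1:
        return 0
    j = 1
    prob = 1.0
    while j < n_sites:
        nxt = prob * (1 - j / n_sites)
        if nxt < confidence:
            break
        prob = nxt
        j += 1
    return j


def build_network(hs: HaplotypeSet, limit=None) -> nx.Graph:
    """Minimum-spanning network over pairwise Hamming distances.

    Kruskal by increasing weight; within each weight class, every edge
    joining components that were distinct at the start of the class is
    kept (ties are not broken).  Edges with weight above ``limit`` are
    dropped afterwards; ``limit=None`` means the automatic parsimony
    limit, ``limit=np.inf`` keeps the full (connected) network.
    """
    if limit is None:
        limit = parsimony_limit(hs.n_sites)
    g = nx.Graph(approximation="minimum-spanning-network (TCS approximated)")
    for h in hs.haplotypes:
        g.add_node(
            h,
            multiplicity={grp: hs.group_multiplicity(h, grp) for grp in hs.groups},
        )
    if len(hs.haplotypes) < 2:
        return g
    dist: dict[int, list[tuple[str, str]]] = {}
    for h1, h2 in itertools.combinations(hs.haplotypes, 2):
        dist.setdefault(hamming(h1, h2), []).append((h1, h2))
    uf = nx.utils.UnionFind(hs.haplotypes)
    for w in sorted(dist):
        klass = [
            (h1, h2) for h1, h2 in dist[w] if uf[h1] != uf[h2]
        ]
        for h1, h2 in klass:
            if w <= limit:
                g.add_edge(h1, h2, weight=w)
        for h1, h2 in klass:
            uf.union(h1, h2)
    return g


def write_network_tsv(g: nx.Graph, nodes_path, edges_path) -> None:
    with open(nodes_path, "w") as fh:
        groups = sorted(
            {grp for _, d in g.nodes(data=True) for grp in d.get("multiplicity", {})}
        )
        fh.write("haplotype\t" + "\t".join(groups) + "\n")
        for h, d in g.nodes(data=True):
            m = d.get("multiplicity", {})
            fh.write(h + "\t" + "\t".join(str(m.get(grp, 0)) for grp in groups) + "\n")
    with open(edges_path, "w") as fh:
        fh.write("hap1\thap2\tdistance\n")
        for h1, h2, d in g.edges(data=True):
            fh.write(f"{h1}\t{h2}\t{d['weight']}\n")


def write_network_nexus(g: nx.Graph, path) -> None:
    """Minimal nexus-style network block for external drawing tools."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n[minimum-spanning network; TCS approximated]\n")
        fh.write("BEGIN NETWORK;\n")
        ids = {h: i + 1 for i, h in enumerate(g.nodes)}
        fh.write("  VERTICES\n")
        for h, i in ids.items():
            fh.write(f"    {i} {h}\n")
        fh.write("  ;\n  EDGES\n")
        for h1, h2, d in g.edges(data=True):
            fh.write(f"    {ids[h1]} {ids[h2]} {d['weight']}\n")
        fh.write("  ;\nEND;\n")
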