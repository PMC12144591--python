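"""Differentiation statistics and mtDNA haplotype analysis.

Covers: collapsing aligned control-region sequences into haplotypes,
nearest-reference haplogroup assignment, median-joining network
construction, and distance-based AMOVA Phi-ST for sequence and SNP
partitions.

Phi-ST here is the two-level AMOVA ratio sigma2_among / sigma2_total
computed from pairwise-distance sums of squares. For aligned sequences the
squared inter-individual distance is the number of differing sites
(pairwise deletion of N/gap positions). For SNP partitions the AMOVA is
taken over alleles rather than diploid genotype vectors: each individual
contributes two alleles per locus, and the sums of squares have a closed
form in the per-group allele counts, so no phase assignment is needed.
This keeps the multi-locus estimate consistent with the classical
fixation-index scale (a two-pool drift model with differentiation F yields
Phi-ST ~ F in expectation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from duckmix.genofilter import MISSING, GenotypeMatrix

VALID_BASES = set("ACGT")
ALPHABET = set("ACGTN-")


@dataclass
class SequenceSet:
    """Aligned nucleotide sequences with optional per-sequence group labels."""

    ids: list[str]
    sequences: list[str]
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if self.groups is not None and len(self.groups) != len(self.ids):
            raise ValueError("groups length mismatch")
        self.sequences = [s.upper() for s in self.sequences]
        lens = {len(s) for s in self.sequences}
        if len(lens) > 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        for s in self.sequences:
            bad = set(s) - ALPHABET
            if bad:
                raise ValueError(f"invalid characters in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


def read_fasta(path: str | Path, groups: dict[str, str] | None = None) -> SequenceSet:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    grp = [groups.get(i, "unknown") for i in ids] if groups else None
    return SequenceSet(ids, seqs, grp)


def write_fasta(seqset: SequenceSet, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="")
               for i, s in zip(seqset.ids, seqset.sequences)]
    SeqIO.write(records, str(path), "fasta")


def hamming(a: str, b: str, pairwise_exclude: bool = True) -> int:
    """Number of differing sites; N/gap sites excluded pairwise by default."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    d = 0
    for x, y in zip(a, b):
        if pairwise_exclude and (x not in VALID_BASES or y not in VALID_BASES):
            continue
        if x != y:
            d += 1
    return d


# ---------------------------------------------------------------------------
# Haplotypes
# ---------------------------------------------------------------------------

def collapse_haplotypes(seqs: SequenceSet, ignore_ambiguous: bool = True
                        ) -> pd.DataFrame:
    """Collapse identical sequences into haplotypes with per-group counts.

    Two sequences match when they have zero mismatches; with
    ``ignore_ambiguous`` (default) sites where either carries N or a gap
    are excluded from the comparison, and each sequence joins the first
    matching haplotype in input order (comparison with ambiguity is not
    transitive, so the greedy order matters and is documented behaviour).
    """
    reps: list[str] = []
    members: list[list[int]] = []
    for i, s in enumerate(seqs.sequences):
        placed = False
        for h, rep in enumerate(reps):
            same = (hamming(s, rep) == 0) if ignore_ambiguous else (s == rep)
            if same:
                members[h].append(i)
                placed = True
                break
        if not placed:
            reps.append(s)
            members.append([i])

    groups = seqs.groups or ["all"] * len(seqs)
    group_names = sorted(set(groups))
    rows = []
    for h, (rep, idx) in enumerate(zip(reps, members)):
        row = {"haplotype_id": f"H{h + 1}", "sequence": rep, "count": len(idx)}
        for g in group_names:
            row[f"n_{g}"] = sum(1 for i in idx if groups[i] == g)
        rows.append(row)
    return pd.DataFrame(rows)


def assign_haplogroup(seq: str, references: SequenceSet) -> str:
    """Label of the minimum-Hamming-distance reference; ties -> 'ambiguous'."""
    if len(references) == 0:
        raise ValueError("no reference sequences supplied")
    labels = references.groups or references.ids
    dists = np.array([hamming(seq, r) for r in references.sequences])
    best = dists.min()
    winners = {labels[i] for i in np.flatnonzero(dists == best)}
    return winners.pop() if len(winners) == 1 else "ambiguous"


def assign_haplogroups(seqs: SequenceSet, references: SequenceSet) -> pd.Series:
    return pd.Series([assign_haplogroup(s, references) for s in seqs.sequences],
                     index=seqs.ids, name="haplogroup")


# ---------------------------------------------------------------------------
# Median-joining network
# ---------------------------------------------------------------------------

def _distance_matrix(seqs: list[str]) -> np.ndarray:
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = hamming(seqs[i], seqs[j])
    return d


def _mst_weight(d: np.ndarray) -> float:
    from scipy.sparse.csgraph import minimum_spanning_tree

    return float(minimum_spanning_tree(d).sum())


def _msn_edges(d: np.ndarray, epsilon: int = 0) -> list[tuple[int, int, float]]:
    """Minimum-spanning network: union of all MSTs plus ties within epsilon.

    Kruskal by distance class; within a class, every pair joining two
    components (as they stood before the class) is kept, so equally short
    alternative connections survive. Classes continue until the graph is
    connected, then for ``epsilon`` > 0 additional classes within epsilon
    of the connecting distance are admitted between pre-class components.
    """
    n = d.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int, float]] = []
    weights = sorted({d[i, j] for i in range(n) for j in range(i + 1, n) if d[i, j] > 0})
    connected_at: float | None = None
    for w in weights:
        if connected_at is not None and w > connected_at + epsilon:
            break
        comp_before = [find(i) for i in range(n)]
        batch = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if d[i, j] == w and comp_before[i] != comp_before[j]]
        for i, j in batch:
            edges.append((i, j, w))
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        if connected_at is None and len({find(i) for i in range(n)}) == 1:
            connected_at = w
    return edges


def _consensus(a: str, b: str, c: str) -> str:
    """Site-wise majority consensus of three aligned sequences."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(x)  # three-way tie: keep first (epsilon-0 convention)
    return "".join(out)


def median_joining_network(haplotypes: pd.DataFrame | SequenceSet,
                           epsilon: int = 0) -> nx.Graph:
    """Build a median-joining haplotype network.

    Observed haplotypes are the initial nodes. The algorithm alternates
    between (a) building the minimum-spanning network under Hamming
    distance, keeping equally short alternative connections within
    ``epsilon``, and (b) proposing median (majority-consensus) vectors of
    node triplets; a median is added when it strictly reduces the weight of
    the minimum spanning tree over the node set, and the best such median
    is added per round. Obsolete medians whose removal leaves the spanning
    weight unchanged are pruned. Terminates because the spanning weight is
    a strictly decreasing nonnegative integer sequence.

    Returns a networkx graph whose nodes carry ``sequence``, ``count``,
    ``median`` (bool) and any per-group count attributes; edge weights are
    the Hamming distances between endpoint haplotypes.
    """
    if isinstance(haplotypes, SequenceSet):
        haplotypes = collapse_haplotypes(haplotypes)
    if len(haplotypes) == 0:
        raise ValueError("no haplotypes supplied")

    seqs = list(haplotypes["sequence"])
    attrs = haplotypes.set_index("sequence").to_dict("index")
    is_median = [False] * len(seqs)

    # -- median addition ----------------------------------------------------
    while True:
        d = _distance_matrix(seqs)
        base = _mst_weight(d)
        best_gain, best_seq = 0.0, None
        # Candidate triplets: nodes adjacent in the current MSN keep the
        # search local; fall back to all triples for very small networks.
        edges = _msn_edges(d, epsilon)
        adj: dict[int, set[int]] = {}
        for i, j, _ in edges:
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
        if len(seqs) <= 12:
            triples = itertools.combinations(range(len(seqs)), 3)
        else:
            triples = {tuple(sorted((i, j, k)))
                       for i in adj for j in adj[i] for k in adj[j] if k != i}
        for i, j, k in triples:
            med = _consensus(seqs[i], seqs[j], seqs[k])
            if med in seqs:
                continue
            d2 = _distance_matrix(seqs + [med])
            gain = base - _mst_weight(d2)
            if gain > best_gain:
                best_gain, best_seq = gain, med
        if best_seq is None:
            break
        seqs.append(best_seq)
        is_median.append(True)

    # -- prune obsolete medians --------------------------------------------
    changed = True
    while changed:
        changed = False
        d = _distance_matrix(seqs)
        base = _mst_weight(d)
        for idx in range(len(seqs) - 1, -1, -1):
            if not is_median[idx]:
                continue
            rest = [s for t, s in enumerate(seqs) if t != idx]
            if _mst_weight(_distance_matrix(rest)) <= base:
                del seqs[idx]
                del is_median[idx]
                changed = True
                break

    # -- final network ------------------------------------------------------
    d = _distance_matrix(seqs)
    g = nx.Graph()
    for idx, s in enumerate(seqs):
        if is_median[idx]:
            g.add_node(f"median_{idx}", sequence=s, count=0, median=True)
        else:
            info = attrs[s]
            g.add_node(info["haplotype_id"], sequence=s, median=False,
                       **{k: v for k, v in info.items() if k != "haplotype_id"})
    names = list(g.nodes)
    for i, j, w in _msn_edges(d, epsilon):
        g.add_edge(names[i], names[j], weight=float(w))
    return g


def export_network(g: nx.Graph, nodes_path: str | Path, edges_path: str | Path,
                   graphml_path: str | Path | None = None) -> None:
    """Write node/edge lists as delimited text (and optionally GraphML)."""
    nodes = pd.DataFrame(
        [{"node": n, **{k: v for k, v in a.items()}} for n, a in g.nodes(data=True)]
    )
    edges = pd.DataFrame(
        [{"source": u, "target": v, "weight": w.get("weight", 1.0)}
         for u, v, w in g.edges(data=True)]
    )
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edges.to_csv(edges_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(g, str(graphml_path))


# ---------------------------------------------------------------------------
# Phi-ST (distance-based AMOVA)
# ---------------------------------------------------------------------------

@dataclass
class PhiStResult:
    partition: str
    groups: tuple[str, ...]
    phi_st: float
    sigma2_among: float
    sigma2_within: float


def _amova_from_ss(ss_within: float, ss_total: float, sizes: np.ndarray
                   ) -> tuple[float, float]:
    """Variance components from within/total sums of squares.

    ``sizes`` are per-group sample counts (alleles or sequences). Returns
    (sigma2_among, sigma2_within) using the standard two-level AMOVA
    expectations with unequal group sizes.
    """
    n_tot = sizes.sum()
    g = len(sizes)
    ss_among = ss_total - ss_within
    df_among = g - 1
    df_within = n_tot - g
    if df_within <= 0:
        raise ValueError("every group needs at least 2 members")
    ms_within = ss_within / df_within
    ms_among = ss_among / df_among
    n_prime = (n_tot - (sizes ** 2).sum() / n_tot) / df_among
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / n_prime
    return sigma2_among, sigma2_within


def phi_st_sequences(seqs: SequenceSet, groups: list[str] | None = None,
                     partition: str = "mtDNA") -> PhiStResult:
    """Phi-ST for aligned sequences via pairwise-difference AMOVA.

    The squared distance between two sequences is their number of
    nucleotide differences (N/gap sites excluded pairwise). Negative
    estimates are reported as computed.
    """
    groups = list(groups if groups is not None else (seqs.groups or []))
    if not groups:
        raise ValueError("group labels required")
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    sizes = np.array([groups.count(g) for g in labels], dtype=float)
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 members")

    n = len(seqs)
    d2 = _distance_matrix(seqs.sequences)
    idx = {g: [i for i in range(n) if groups[i] == g] for g in labels}
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in labels:
        ii = np.ix_(idx[g], idx[g])
        ss_within += d2[ii][np.triu_indices(len(idx[g]), 1)].sum() / len(idx[g])
    s2a, s2w = _amova_from_ss(ss_within, ss_total, sizes)
    total = s2a + s2w
    phi = s2a / total if total > 0 else 0.0
    return PhiStResult(partition, tuple(labels), float(phi), s2a, s2w)


def phi_st_snps(matrix: GenotypeMatrix, groups: list[str] | pd.Series,
                partition: str = "autosomal") -> PhiStResult:
    """Multi-locus Phi-ST for diploid SNP genotypes via allele-level AMOVA.

    Each individual contributes its two alleles per locus; the per-locus
    sums of squares have closed forms in the per-group alternate-allele
    counts (the squared distance between two alleles is 0/1). Variance
    components are summed over loci (ratio-of-sums), which weights loci by
    information and matches the classical multi-locus estimator.
    """
    groups = list(groups)
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    grp_idx = {g: np.array([i for i, x in enumerate(groups) if x == g])
               for g in labels}
    for g in labels:
        if len(grp_idx[g]) < 2:
            raise ValueError("every group needs at least 2 members")

    sum_s2a = 0.0
    sum_s2w = 0.0
    geno = matrix.genotypes
    obs = geno != MISSING
    for l in range(matrix.n_loci):
        sizes, alts = [], []
        for g in labels:
            rows = grp_idx[g]
            ok = obs[rows, l]
            m = 2 * ok.sum()
            if m < 2:
                sizes = []
                break
            sizes.append(m)
            alts.append(geno[rows, l][ok].sum())
        if not sizes:
            continue
        sizes = np.array(sizes, dtype=float)
        alts = np.array(alts, dtype=float)
        n_tot = sizes.sum()
        c_tot = alts.sum()
        ss_total = c_tot * (n_tot - c_tot) / n_tot
        ss_within = (alts * (sizes - alts) / sizes).sum()
        try:
            s2a, s2w = _amova_from_ss(ss_within, ss_total, sizes)
        except ValueError:
            continue
        sum_s2a += s2a
        sum_s2w += s2w
    total = sum_s2a + sum_s2w
    phi = sum_s2a / total if total > 0 else 0.0
    return PhiStResult(partition, tuple(labels), float(phi), sum_s2a, sum_s2w)


def phi_st(data, groups, partition: str = "autosomal") -> PhiStResult:
    """Dispatch Phi-ST by data kind (SequenceSet vs GenotypeMatrix)."""
    if isinstance(data, SequenceSet):
        return phi_st_sequences(data, groups, partition)
    if isinstance(data, GenotypeMatrix):
        return phi_st_snps(data, groups, partition)
    raise TypeError("data must be a SequenceSet or GenotypeMatrix")
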