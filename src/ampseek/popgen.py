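"""Consensus haplotypes, diversity statistics, haplotype networks, NJ trees.

Per-sample consensus sequences are built from pileups of the phylogenetic
amplicons (*its2*, *cox1*), keeping only samples above a mean-coverage
threshold (default > 50-fold).  Same-amplicon consensus sequences are equal
length by construction, so alignment is positional; sites containing N or a
gap in any retained sequence are masked set-wide (complete deletion) before
all statistics.

Implemented statistics: nucleotide diversity π (mean pairwise differences per
site), haplotype diversity Hd with the n/(n−1) small-sample correction,
Watterson's θ_W, and Tajima's D with the standard variance coefficients.
Haplotype networks are minimum spanning trees over pairwise nucleotide
differences (deterministic lexicographic tie-break); trees are classical
neighbour-joining with negative branch lengths clamped to zero and the
deficit moved to the sister branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .pileup_caller import FilterConfig, PileupMatrix, _BASE_IDX

_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    sample_id: str
    amplicon: str
    sequence: str | None
    mean_depth: float
    rejected_reason: str = ""


def consensus_from_pileup(
    p: PileupMatrix,
    min_fold: int = 50,
    min_site_depth: int = 5,
    iupac_het: bool = False,
    cfg: FilterConfig | None = None,
) -> ConsensusResult:
    """Majority-base consensus for one sample's amplicon pileup.

    Samples whose mean depth across the amplicon is ≤ ``min_fold`` are
    rejected (the assay keeps samples with > 50-fold coverage).  Positions
    with depth < ``min_site_depth`` become N.  Heterozygous positions
    (alternate fraction within the het band) emit the major allele by
    default, or the two-allele IUPAC ambiguity code with ``iupac_het``.
    """
    cfg = cfg or FilterConfig()
    md = p.mean_depth()
    if p.counts.sum() == 0:
        return ConsensusResult(p.sample_id, p.amplicon, None, 0.0, "empty_pileup")
    if md <= min_fold:
        return ConsensusResult(p.sample_id, p.amplicon, None, md,
                               f"mean_depth {md:.1f} <= {min_fold}")
    bases = "ACGT"
    out = []
    for pos in range(len(p.ref)):
        row = p.counts[pos, :4]
        depth = int(row.sum())
        if depth < min_site_depth:
            out.append("N")
            continue
        order = sorted(range(4), key=lambda i: (-row[i], bases[i]))
        major, second = order[0], order[1]
        if iupac_het and row[second] > 0:
            f2 = row[second] / (row[major] + row[second])
            if cfg.het_low <= f2 <= cfg.het_high:
                out.append(_IUPAC.get(frozenset({bases[major], bases[second]}),
                                      bases[major]))
                continue
        out.append(bases[major])
    return ConsensusResult(p.sample_id, p.amplicon, "".join(out), md)


# ---------------------------------------------------------------------------
# Haplotype sets
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSet:
    """Aligned equal-length sequences with sample and population labels."""

    sequences: list[str]
    sample_ids: list[str]
    populations: list[str]

    def __post_init__(self) -> None:
        if not (len(self.sequences) == len(self.sample_ids) == len(self.populations)):
            raise ValueError("parallel lists must have equal length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences must be aligned to equal length")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of complete sites (no N or gap in any sequence)."""
        if not self.sequences:
            return np.zeros(0, dtype=bool)
        arr = np.array([list(s.upper()) for s in self.sequences])
        return ~np.any((arr == "N") | (arr == "-"), axis=0)

    def masked_sequences(self) -> list[str]:
        m = self.mask
        return ["".join(c for c, keep in zip(s, m) if keep) for s in self.sequences]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "HaplotypeSet":
        """Read an aligned FASTA with ``sample|population`` headers."""
        seqs, samples, pops = [], [], []
        name, chunks = None, []
        def flush():
            if name is None:
                return
            parts = name.split("|")
            samples.append(parts[0])
            pops.append(parts[1] if len(parts) > 1 else "NA")
            seqs.append("".join(chunks).upper())
        for line in Path(path).read_text().splitlines():
            if line.startswith(">"):
                flush()
                name, chunks = line[1:].strip(), []
            elif line.strip():
                chunks.append(line.strip())
        flush()
        return cls(seqs, samples, pops)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, sid, pop in zip(self.sequences, self.sample_ids, self.populations):
                fh.write(f">{sid}|{pop}\n{s}\n")


def pairwise_differences(h: HaplotypeSet) -> np.ndarray:
    """Pairwise Hamming distances on masked (complete) sites."""
    seqs = h.masked_sequences()
    n = len(seqs)
    d = np.zeros((n, n), dtype=float)
    arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = int((arrs[i] != arrs[j]).sum())
    return d


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------

@dataclass
class PopGenStats:
    n: int
    L: int              # analysed (masked) sites
    S: int              # segregating sites
    pi: float           # nucleotide diversity per site
    Hd: float           # haplotype diversity
    theta_w: float      # Watterson estimator per locus
    D: float            # Tajima's D (nan when undefined)
    k: int              # distinct haplotypes
    D_undefined: bool = False


def tajimas_d(n: int, S: int, mean_pairwise: float) -> float:
    """Tajima's D from n sequences, S segregating sites and mean pairwise
    differences per locus, with the standard variance coefficients."""
    if S == 0 or n < 2:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (mean_pairwise - S / a1) / math.sqrt(var)


def diversity_stats(h: HaplotypeSet) -> PopGenStats:
    """π, Hd, θ_W, Tajima's D and haplotype count on masked sites."""
    if h.n < 2:
        raise ValueError("diversity statistics require at least 2 sequences")
    seqs = h.masked_sequences()
    n = len(seqs)
    L = len(seqs[0])
    d = pairwise_differences(h)
    iu = np.triu_indices(n, 1)
    total_diffs = float(d[iu].sum())
    n_pairs = n * (n - 1) / 2
    mean_pairwise = total_diffs / n_pairs
    pi = mean_pairwise / L if L > 0 else 0.0

    arr = np.array([list(s) for s in seqs]) if L > 0 else np.zeros((n, 0), dtype="<U1")
    S = int(sum(len(set(arr[:, j])) > 1 for j in range(L)))

    hap_counts: dict[str, int] = {}
    for s in seqs:
        hap_counts[s] = hap_counts.get(s, 0) + 1
    freqs = np.array(list(hap_counts.values())) / n
    Hd = (n / (n - 1)) * (1.0 - float((freqs ** 2).sum()))

    a1 = sum(1.0 / i for i in range(1, n))
    theta_w = S / a1
    D = tajimas_d(n, S, mean_pairwise)
    # undefined when S = 0, and also at n = 2 where the variance degenerates
    return PopGenStats(n, L, S, pi, Hd, theta_w, D, len(hap_counts),
                       D_undefined=math.isnan(D))


# ---------------------------------------------------------------------------
# Haplotype network (minimum spanning tree)
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNetwork:
    graph: nx.Graph                           # nodes H1.. with 'count', 'populations'
    haplotypes: dict[str, str]                # node label → masked sequence

    @property
    def total_samples(self) -> int:
        return sum(d["count"] for _, d in self.graph.nodes(data=True))

    def write_gml(self, path: str | Path) -> None:
        g = nx.Graph()
        for node, d in self.graph.nodes(data=True):
            g.add_node(node, count=d["count"],
                       populations=";".join(f"{p}:{c}" for p, c in sorted(d["populations"].items())))
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, weight=int(d["weight"]))
        nx.write_gml(g, str(path))

    def write_dot(self, path: str | Path) -> None:
        lines = ["graph haplotype_network {"]
        for node, d in self.graph.nodes(data=True):
            lines.append(f'  {node} [label="{node} (n={d["count"]})"];')
        for u, v, d in sorted(self.graph.edges(data=True)):
            lines.append(f'  {u} -- {v} [label="{int(d["weight"])}"];')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")


def build_network(h: HaplotypeSet) -> HaplotypeNetwork:
    """Minimum spanning tree over distinct haplotypes.

    Identical (masked) sequences collapse into one node carrying
    population-stratified sample counts; edge weights are nucleotide
    differences; ties between equal-weight edges break lexicographically by
    node labels (Kruskal with sorted edge insertion).
    """
    seqs = h.masked_sequences()
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for i, s in enumerate(seqs):
        if s not in members:
            members[s] = []
            order.append(s)
        members[s].append(i)
    labels = {s: f"H{k + 1}" for k, s in enumerate(order)}

    g = nx.Graph()
    for s in order:
        pops: dict[str, int] = {}
        for i in members[s]:
            pops[h.populations[i]] = pops.get(h.populations[i], 0) + 1
        g.add_node(labels[s], count=len(members[s]), populations=pops)
    arrs = {s: np.frombuffer(s.encode(), dtype=np.uint8) for s in order}
    edges = []
    for i, si in enumerate(order):
        for sj in order[i + 1:]:
            w = int((arrs[si] != arrs[sj]).sum())
            edges.append((w, labels[si], labels[sj]))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    for w, u, v in edges:
        g.add_edge(u, v, weight=w)
    if g.number_of_nodes() > 1:
        mst = nx.minimum_spanning_tree(g, weight="weight", algorithm="kruskal")
    else:
        mst = g.copy()
    for node in g.nodes:
        mst.nodes[node].update(g.nodes[node])
    return HaplotypeNetwork(mst, {labels[s]: s for s in order})


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

@dataclass
class NJTree:
    newick: str
    leaves: list[str]


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None, children=None):
        self.label = label
        self.children = children or []   # (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.6g}" for c, bl in self.children)
        return f"({inner})"

    def min_leaf(self) -> str:
        if not self.children:
            return self.label
        return min(c.min_leaf() for c, _ in self.children)


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor distance from a per-site difference proportion."""
    if p >= 0.75:
        raise ValueError("JC correction undefined for p >= 0.75")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nj_tree(
    dist: np.ndarray | HaplotypeSet,
    labels: list[str] | None = None,
    jc_correction: bool = False,
) -> NJTree:
    """Classical neighbour joining on a pairwise-difference matrix.

    Accepts a HaplotypeSet (distances = pairwise differences on masked
    sites, optionally Jukes–Cantor corrected per site) or a symmetric
    distance matrix with labels.  Joins minimise the Q criterion, ties break
    by the lexicographically smallest leaf under each candidate pair, and
    negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.
    """
    if isinstance(dist, HaplotypeSet):
        h = dist
        labels = [f"{s}|{p}" for s, p in zip(h.sample_ids, h.populations)]
        d = pairwise_differences(h)
        if jc_correction:
            L = len(h.masked_sequences()[0])
            d = np.vectorize(lambda x: jukes_cantor(x / L) * L if L else 0.0)(d)
    else:
        d = np.asarray(dist, dtype=float)
        if labels is None:
            raise ValueError("labels required with a distance matrix")
        if d.shape[0] != d.shape[1] or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")

    nodes: list[_Node] = [_Node(l) for l in labels]
    D = d.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                q = (r - 2) * D[i, j] - R[i] - R[j]
                tie_key = tuple(sorted((nodes[i].min_leaf(), nodes[j].min_leaf())))
                cand = (q, tie_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = D[i, j] / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(None, [(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        k = len(nodes) - 1
        D = np.pad(D, ((0, 1), (0, 1)))
        for m in active:
            if m in (i, j):
                continue
            D[k, m] = D[m, k] = (D[i, m] + D[j, m] - D[i, j]) / 2.0
        active = [m for m in active if m not in (i, j)] + [k]

    # final unrooted star over the last three lineages (closed form)
    a, b, c = active
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2.0
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    root = _Node(None, [(nodes[a], max(la, 0.0)), (nodes[b], max(lb, 0.0)),
                        (nodes[c], max(lc, 0.0))])
    newick = root.newick() + ";"
    return NJTree(newick, list(labels))
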