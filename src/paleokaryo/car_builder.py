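"""Reconstruction of pre-speciation ancestors as ordered CARs.

The reconstruction follows the strict-adjacency paradigm: ancestral markers
are informative gene families orthologous across genome pairs that straddle
the target ancestor; adjacencies (pairs contiguous in >= 2 informative
genomes) and maximal common intervals (sets contiguous, in any order, in a
genome pair) become rows of a 1/0/X sandwich matrix whose columns are ordered
so that no 0 falls between two 1s in any satisfied row. Connected components
of the satisfied rows become contiguous ancestral regions (CARs).

The sandwich problem is NP-hard in general; rows without X are handled
exactly by PQ-tree reduction, X-bearing rows are inserted greedily in
decreasing support order and discarded (logged) when they break
consecutiveness. Small components that still carry unsatisfied rows are
re-solved by an exact depth-first search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pqtree import PQTree, exact_c1p_order, sandwich_satisfied

logger = logging.getLogger("paleokaryo")


@dataclass
class AncestralMarker:
    """An informative gene family with its member genes per genome."""

    id: str
    family: str
    members: dict[str, list[str]] = field(default_factory=dict)  # genome -> gene ids

    def genomes(self) -> set[str]:
        return set(self.members)


@dataclass(frozen=True)
class Adjacency:
    """Unordered pair of markers contiguous in ``support`` informative genomes."""

    markers: frozenset
    support: int
    extremities: tuple = ()  # ((marker, end), (marker, end)) of the majority joint


@dataclass
class CommonInterval:
    """Set of markers contiguous (any internal order) in >= 2 genomes."""

    markers: frozenset
    pairs: list[tuple[str, str]] = field(default_factory=list)
    maximal: bool = True


@dataclass(frozen=True)
class MatrixRow:
    ones: frozenset
    zeros: frozenset
    support: int


@dataclass
class SandwichMatrix:
    """Rows = interval constraints, columns = markers, entries 1/0/X.

    A row stores its 1-set and 0-set explicitly; every other column is X.
    """

    columns: list[str]
    rows: list[MatrixRow] = field(default_factory=list)

    @property
    def shape(self):
        return (len(self.rows), len(self.columns))


@dataclass
class CAR:
    """A contiguous ancestral region: ordered, oriented markers."""

    id: str
    markers: list[str]
    orientations: list[str]
    linked: bool = False
    protochromosome: str | None = None
    order_ambiguous: bool = False

    def __len__(self):
        return len(self.markers)


@dataclass
class C1POrdering:
    """Result of :func:`order_c1p`: CARs plus bookkeeping of discards."""

    cars: list[CAR]
    discarded_rows: list[MatrixRow]
    unplaced_markers: list[str]

    def __iter__(self):
        return iter(self.cars)

    def __len__(self):
        return len(self.cars)


# ---------------------------------------------------------------------------


def build_markers(pairs, genomes, informative_pairs, expected_copies: int = 1,
                  marker_prefix: str = "m") -> list[AncestralMarker]:
    """Define ancestral markers from filtered ortholog pairs.

    A gene family becomes a marker when it is present with exactly
    ``expected_copies`` members in each genome where it occurs, occurs in both
    genomes of at least one informative pair, and at least one retained
    ortholog pair connects its members across an informative pair. Families
    violating the copy-number expectation are excluded and counted.
    """
    if not informative_pairs:
        raise ValueError("no informative genome pair for the target ancestor")
    gmap = {gm.name: gm for gm in genomes}
    for a, b in informative_pairs:
        if a not in gmap or b not in gmap:
            raise ValueError(f"informative pair ({a}, {b}) references unknown genome")
    pairset = {frozenset(p) for p in informative_pairs}
    gene_info = {}
    for gm in genomes:
        for g in gm.genes():
            gene_info[g.id] = g

    fam_members: dict[str, dict[str, list[str]]] = {}
    for gm in genomes:
        for fam, members in gm.families().items():
            fam_members.setdefault(fam, {})[gm.name] = sorted(m.id for m in members)

    # families linked by at least one ortholog pair across an informative pair
    linked_fams: set[str] = set()
    for g1, g2 in zip(pairs["gene1"], pairs["gene2"]):
        a, b = gene_info.get(g1), gene_info.get(g2)
        if a is None or b is None or a.family != b.family:
            continue
        if frozenset((a.genome, b.genome)) in pairset:
            linked_fams.add(a.family)

    markers, n_excluded = [], 0
    for fam in sorted(linked_fams):
        members = fam_members[fam]
        if any(len(v) != expected_copies for v in members.values()):
            n_excluded += 1
            continue
        if not any(frozenset((a, b)) <= set(members) for a, b in pairset):
            continue
        markers.append(AncestralMarker(
            id=f"{marker_prefix}:{fam}", family=fam, members=members,
        ))
    if n_excluded:
        logger.info("build_markers: excluded %d families violating the "
                    "%d-copy expectation", n_excluded, expected_copies)
    return markers


def project_markers(genome, markers) -> dict[str, list[str]]:
    """Per chromosome, the ordered marker-id list (non-marker genes ignored)."""
    by_gene = {}
    for m in markers:
        for gid in m.members.get(genome.name, ()):
            by_gene[gid] = m.id
    out: dict[str, list[str]] = {}
    for chrom, genes in genome.chromosomes.items():
        seq = [by_gene[g.id] for g in genes if g.id in by_gene]
        if seq:
            out[chrom] = seq
    return out


def _marker_strands(genome, markers) -> dict[str, str]:
    out = {}
    for m in markers:
        mem = m.members.get(genome.name)
        if mem:
            out[m.id] = genome[mem[0]].strand
    return out


def compute_adjacencies_and_intervals(genomes, markers, min_support: int = 2,
                                      genome_pairs=None):
    """All supported adjacencies and maximal common intervals of the markers.

    Contiguity is evaluated in marker rank space (intervening non-marker
    genes are ignored). Adjacencies need support from >= ``min_support``
    genomes; common intervals are computed per genome pair and only maximal
    ones are retained (deduplicated across pairs).
    """
    projections = {gm.name: project_markers(gm, markers) for gm in genomes}
    strands = {gm.name: _marker_strands(gm, markers) for gm in genomes}

    # adjacencies -----------------------------------------------------------
    adj_support: dict[frozenset, int] = {}
    adj_ext: dict[frozenset, dict] = {}
    for gname, proj in projections.items():
        seen_here = set()
        for chrom, seq in proj.items():
            for m1, m2 in zip(seq, seq[1:]):
                key = frozenset((m1, m2))
                if key in seen_here or len(key) == 1:
                    continue
                seen_here.add(key)
                adj_support[key] = adj_support.get(key, 0) + 1
                s1 = strands[gname].get(m1, "+")
                s2 = strands[gname].get(m2, "+")
                ext = ((m1, "tail" if s1 == "+" else "head"),
                       (m2, "head" if s2 == "+" else "tail"))
                d = adj_ext.setdefault(key, {})
                d[ext] = d.get(ext, 0) + 1
    adjacencies = [
        Adjacency(markers=k, support=v,
                  extremities=max(adj_ext[k].items(), key=lambda kv: kv[1])[0])
        for k, v in sorted(adj_support.items(), key=lambda kv: sorted(kv[0]))
        if v >= min_support
    ]

    # maximal common intervals ---------------------------------------------
    names = sorted(projections)
    if genome_pairs is None:
        genome_pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    interval_map: dict[frozenset, CommonInterval] = {}
    for ga, gb in genome_pairs:
        shared = ({m for seq in projections[ga].values() for m in seq}
                  & {m for seq in projections[gb].values() for m in seq})
        if len(shared) < 2:
            continue
        proj_a = {c: [m for m in seq if m in shared]
                  for c, seq in projections[ga].items()}
        posb: dict[str, tuple[str, int]] = {}
        for c, seq in projections[gb].items():
            k = 0
            for m in seq:
                if m in shared:
                    posb[m] = (c, k)
                    k += 1
        for chrom, seq in proj_a.items():
            n = len(seq)
            if n < 2:
                continue
            best_end = np.full(n, -1)
            for i in range(n):
                cb, lo = posb[seq[i]]
                hi = lo
                for j in range(i + 1, n):
                    cbj, pj = posb[seq[j]]
                    if cbj != cb:
                        break
                    lo, hi = min(lo, pj), max(hi, pj)
                    if hi - lo == j - i:
                        best_end[i] = j
            pm = -1
            for i in range(n):
                j = best_end[i]
                if j < 0:
                    continue
                if j > pm:  # not contained in an earlier window
                    mset = frozenset(seq[i:j + 1])
                    ci = interval_map.get(mset)
                    if ci is None:
                        interval_map[mset] = CommonInterval(mset, [(ga, gb)])
                    elif (ga, gb) not in ci.pairs:
                        ci.pairs.append((ga, gb))
                pm = max(pm, j)
    intervals = sorted(interval_map.values(), key=lambda ci: sorted(ci.markers))
    return adjacencies, intervals


def build_sandwich_matrix(markers, intervals, adjacencies=(), genomes=None,
                          projections=None) -> SandwichMatrix:
    """Assemble the 1/0/X matrix from intervals (and adjacency constraints).

    For each interval row, a marker is 1 if inside the interval, 0 if present
    in both genomes of the row's supporting pair but outside the interval,
    and X otherwise. Adjacency rows (size-2 intervals) are added with zeros
    over markers shared by any pair of genomes supporting the adjacency; when
    genome content is not supplied their zero-set is every other marker.
    """
    columns = sorted(m.id for m in markers)
    colset = set(columns)
    present: dict[str, set] = {}
    if genomes is not None:
        for gm in genomes:
            present[gm.name] = {m.id for m in markers if gm.name in m.members}
    rows: dict[tuple, int] = {}

    def add(ones, zeros, support=1):
        key = (frozenset(ones), frozenset(zeros) - frozenset(ones))
        rows[key] = rows.get(key, 0) + support

    for ci in intervals:
        for (ga, gb) in (ci.pairs or [(None, None)]):
            if ga in present and gb in present:
                both = present[ga] & present[gb]
            else:
                both = colset
            add(ci.markers, both - ci.markers)
    for adj in adjacencies:
        add(adj.markers, colset - adj.markers, support=adj.support)
    mrows = [MatrixRow(ones=o, zeros=z, support=s)
             for (o, z), s in rows.items() if len(o) >= 2]
    mrows.sort(key=lambda r: (-r.support, len(r.ones), sorted(r.ones), sorted(r.zeros)))
    return SandwichMatrix(columns=columns, rows=mrows)


def _components(columns, rows):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(columns)
    for r in rows:
        ones = sorted(r.ones)
        for a, b in zip(ones, ones[1:]):
            g.add_edge(a, b)
    placed = []
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            placed.append(sorted(comp))
    singletons = sorted(c for c in columns
                        if not any(c in comp for comp in placed))
    placed.sort(key=lambda c: c[0])
    return placed, singletons


def order_c1p(matrix: SandwichMatrix, reference_order=None,
              exact_max: int = 9) -> C1POrdering:
    """Order the matrix columns into CARs (no 0 between two 1s in any row).

    Rows without X are reduced first on a PQ-tree; X-bearing rows follow
    greedily in decreasing support order, discarded if they break
    consecutiveness. A small component left with unsatisfied rows is
    re-solved exactly. ``reference_order`` (marker -> (chromosome, rank))
    orients each CAR to maximise rank correlation with a reference genome.
    """
    if not matrix.rows:
        return C1POrdering([], [], list(matrix.columns))
    comps, singles = _components(matrix.columns, matrix.rows)
    cars, discards = [], []
    for ci, comp in enumerate(comps):
        compset = set(comp)
        crows = [r for r in matrix.rows if r.ones & compset]
        no_x = [r for r in crows if not (compset - r.ones - r.zeros)]
        with_x = [r for r in crows if compset - r.ones - r.zeros]
        tree = PQTree(comp)
        local_discards = []
        for r in no_x + with_x:
            if not tree.reduce(r.ones):
                local_discards.append(r)
        order = tree.frontier()
        unsatisfied = [r for r in crows
                       if not sandwich_satisfied(order, r.ones, r.zeros)]
        ambiguous = tree.n_arrangements() > 2
        if unsatisfied and len(comp) <= exact_max:
            exact = exact_c1p_order(comp, [(r.ones, r.zeros) for r in crows])
            if exact is not None:
                order, local_discards, unsatisfied = exact, [], []
        for r in local_discards:
            if sandwich_satisfied(order, r.ones, r.zeros):
                continue
            logger.info("order_c1p: discarded row ones=%s (support %d)",
                        sorted(r.ones), r.support)
            discards.append(r)
        if reference_order is not None:
            order = _orient(order, reference_order)
        cars.append(CAR(
            id=f"CAR{ci + 1:03d}",
            markers=list(order),
            orientations=["+"] * len(order),
            order_ambiguous=ambiguous or len(order) == 2,
        ))
    return C1POrdering(cars=cars, discarded_rows=discards, unplaced_markers=singles)


def _orient(order, reference_order):
    ranks = [reference_order[m][1] for m in order if m in reference_order]
    if len(ranks) >= 2 and len(set(ranks)) >= 2:
        rho = stats.spearmanr(range(len(ranks)), ranks).statistic
        if rho < 0:
            return list(reversed(order))
    return list(order)


def anchor_cars(cars, painting: dict) -> list[CAR]:
    """Link each CAR to the protochromosome carrying the majority of its markers.

    ``painting`` maps marker id -> protochromosome/block id. CARs with a tied
    or empty majority stay unlinked (ties logged).
    """
    out = []
    for car in cars:
        votes: dict[str, int] = {}
        for m in car.markers:
            p = painting.get(m)
            if p is not None:
                votes[p] = votes.get(p, 0) + 1
        linked, proto = False, None
        if votes:
            ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
            if len(ranked) == 1 or ranked[0][1] > ranked[1][1]:
                linked, proto = True, ranked[0][0]
            else:
                logger.info("anchor_cars: %s tie between %s and %s -> unlinked",
                            car.id, ranked[0][0], ranked[1][0])
        out.append(CAR(id=car.id, markers=car.markers,
                       orientations=car.orientations, linked=linked,
                       protochromosome=proto,
                       order_ambiguous=car.order_ambiguous))
    return out
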