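"""Density-based chaining of homologous anchors into synteny/duplication blocks.

The detector is a transparent surrogate for the classic Closeup criterion and
honours its three parameters: chains of anchors with gaps of at most CL gene
ranks on both sides, at least MN anchors per block, and a within-block anchor
density at least DR times the background anchor density of the chromosome
pair. Overlapping candidate blocks are resolved greedily by descending anchor
count, then density, then chromosome ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger("paleokaryo")


@dataclass
class AnchorMap:
    """Retained homologous anchors between two genomes (or one genome twice)."""

    genome_a: str
    genome_b: str
    anchors: list[tuple] = field(default_factory=list)
    # each anchor: (chrA, rankA, chrB, rankB, pair_id)
    chrom_sizes_a: dict[str, int] = field(default_factory=dict)
    chrom_sizes_b: dict[str, int] = field(default_factory=dict)

    @property
    def kind(self) -> str:
        return "paralogous" if self.genome_a == self.genome_b else "orthologous"

    @classmethod
    def from_pairs(cls, pairs, genome_a, genome_b, collapse_tandem: bool = True):
        """Build an anchor map from a filtered pair table and two Genomes.

        Consecutive same-family genes (tandem arrays) are collapsed to their
        first copy so that an array counts once as an anchor endpoint.
        """
        def tandem_rep(genome):
            rep = {}
            for chrom, genes in genome.chromosomes.items():
                prev = None
                for g in genes:
                    if collapse_tandem and prev is not None and prev.family == g.family:
                        rep[g.id] = rep[prev.id]
                    else:
                        rep[g.id] = g
                    prev = g
            return rep

        rep_a, rep_b = tandem_rep(genome_a), tandem_rep(genome_b)
        anchors = set()
        for pid, (g1, g2) in enumerate(zip(pairs["gene1"], pairs["gene2"])):
            if g1 in rep_a and g2 in rep_b:
                a, b = rep_a[g1], rep_b[g2]
            elif g2 in rep_a and g1 in rep_b:
                a, b = rep_a[g2], rep_b[g1]
            else:
                continue
            anchors.add((a.chromosome, a.rank, b.chromosome, b.rank, f"p{pid}"))
        return cls(
            genome_a=genome_a.name, genome_b=genome_b.name,
            anchors=sorted(anchors),
            chrom_sizes_a={c: len(v) for c, v in genome_a.chromosomes.items()},
            chrom_sizes_b={c: len(v) for c, v in genome_b.chromosomes.items()},
        )


@dataclass
class SyntenyBlock:
    id: str
    genome_a: str
    genome_b: str
    chr_a: str
    span_a: tuple[int, int]
    chr_b: str
    span_b: tuple[int, int]
    anchors: list[tuple] = field(default_factory=list)
    orientation: str = "same"  # or "inverted"
    kind: str = "orthologous"
    origin: str = "unclassified"

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def density(self) -> float:
        la = self.span_a[1] - self.span_a[0] + 1
        lb = self.span_b[1] - self.span_b[0] + 1
        return self.n_anchors / max(la, lb)


def detect_blocks(anchor_map: AnchorMap, dr: float = 2.0, cl: int = 20,
                  mn: int = 5) -> list[SyntenyBlock]:
    """Chain anchors into blocks under the DR/CL/MN criteria.

    A candidate chain extends while both rank gaps are <= CL and the B-side
    direction stays monotone; it is kept if it has >= MN anchors and its
    anchor density is >= DR times the chromosome-pair background density.
    Retained blocks are non-overlapping on both sides.
    """
    if dr <= 0:
        raise ValueError("DR must be positive")
    if cl < 1 or mn < 1:
        raise ValueError("CL and MN must be >= 1")

    by_pair: dict[tuple, list] = {}
    for a in anchor_map.anchors:
        by_pair.setdefault((a[0], a[2]), []).append(a)

    candidates = []
    for (ca, cb), anchors in sorted(by_pair.items()):
        size_a = anchor_map.chrom_sizes_a.get(ca, max(x[1] for x in anchors) + 1)
        size_b = anchor_map.chrom_sizes_b.get(cb, max(x[3] for x in anchors) + 1)
        for direction in (+1, -1):
            chains = _chain(sorted(anchors, key=lambda x: (x[1], direction * x[3])),
                            cl, direction)
            for chain in chains:
                if len(chain) < mn:
                    continue
                blk = _to_block(anchor_map, ca, cb, chain, direction)
                # background: anchor density of the chromosome pair OUTSIDE
                # the candidate (local enrichment, Closeup-style)
                bg_anchors = len(anchors) - len(chain)
                span_len = max(blk.span_a[1] - blk.span_a[0],
                               blk.span_b[1] - blk.span_b[0]) + 1
                bg_len = max(size_a, size_b) - span_len
                if bg_anchors <= 0 or bg_len <= 0:
                    candidates.append(blk)
                elif blk.density() >= dr * (bg_anchors / bg_len):
                    candidates.append(blk)

    # greedy overlap resolution: big, dense, lexicographically early first
    candidates.sort(key=lambda b: (-b.n_anchors, -b.density(), b.chr_a, b.chr_b,
                                   b.span_a))
    used: set = set()
    blocks = []
    for blk in candidates:
        keyset = {(a[0], a[1]) for a in blk.anchors} | \
                 {("B", a[2], a[3]) for a in blk.anchors}
        if keyset & used:
            continue
        used |= keyset
        blk.id = f"blk{len(blocks) + 1:04d}"
        blk.kind = anchor_map.kind
        blocks.append(blk)
    return blocks


def _chain(anchors, cl, direction):
    chains, current = [], []
    for a in anchors:
        if not current:
            current = [a]
            continue
        prev = current[-1]
        gap_a = a[1] - prev[1]
        gap_b = direction * (a[3] - prev[3])
        if 0 <= gap_a <= cl and 0 < gap_b <= cl:
            current.append(a)
        elif gap_a == 0:
            # same A rank (tandem remnant): skip rather than break the chain
            continue
        else:
            chains.append(current)
            current = [a]
    if current:
        chains.append(current)
    return chains


def _to_block(amap, ca, cb, chain, direction):
    ra = [a[1] for a in chain]
    rb = [a[3] for a in chain]
    return SyntenyBlock(
        id="", genome_a=amap.genome_a, genome_b=amap.genome_b,
        chr_a=ca, span_a=(min(ra), max(ra)),
        chr_b=cb, span_b=(min(rb), max(rb)),
        anchors=list(chain),
        orientation="same" if direction > 0 else "inverted",
    )


# ---------------------------------------------------------------------------


def _overlap(span1, span2) -> bool:
    return span1[0] <= span2[1] and span2[0] <= span1[1]


def classify_block_origin(paralog_blocks, ortholog_blocks,
                          other_paralog_blocks) -> list[SyntenyBlock]:
    """Classify duplicated blocks of genome X as ancestral or lineage-specific.

    A paralogous block of X is *ancestral* when both of its copies map,
    through orthologous blocks X<->Y, to regions of Y that themselves form a
    duplicated pair in Y (shared, pre-speciation duplication). It is
    *lineage-specific* when orthology covers its copies but no duplicated
    counterpart exists at the orthologous positions, and *unclassified* when
    no orthologous block covers it at all.
    """
    def y_regions(chrom, span):
        regions = []
        for ob in ortholog_blocks:
            if ob.chr_a == chrom and _overlap(ob.span_a, span):
                regions.append((ob.chr_b, ob.span_b))
            if ob.chr_b == chrom and _overlap(ob.span_b, span):
                regions.append((ob.chr_a, ob.span_a))
        return regions

    out = []
    for pb in paralog_blocks:
        ya = y_regions(pb.chr_a, pb.span_a)
        yb = y_regions(pb.chr_b, pb.span_b)
        if not ya or not yb:
            origin = "unclassified"
        else:
            origin = "lineage_specific"
            for qb in other_paralog_blocks:
                sides = ((qb.chr_a, qb.span_a), (qb.chr_b, qb.span_b))
                for s1, s2 in (sides, sides[::-1]):
                    hit_a = any(s1[0] == c and _overlap(s1[1], s) for c, s in ya)
                    hit_b = any(s2[0] == c and _overlap(s2[1], s) for c, s in yb)
                    if hit_a and hit_b:
                        origin = "ancestral"
                        break
                if origin == "ancestral":
                    break
        out.append(SyntenyBlock(
            id=pb.id, genome_a=pb.genome_a, genome_b=pb.genome_b,
            chr_a=pb.chr_a, span_a=pb.span_a, chr_b=pb.chr_b, span_b=pb.span_b,
            anchors=pb.anchors, orientation=pb.orientation, kind=pb.kind,
            origin=origin,
        ))
    return out
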