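"""Genome painting with ancestral blocks and fusion/fission bookkeeping.

Every modern karyotype descends from the reconstructed ancestor through
whole-genome duplications, chromosome fissions (Cfis) and fusions (Cfus),
which are tied together by the conservation identity

    n_modern = n_anc * wgd_factor + Cfis - Cfus

where wgd_factor is the product of WGD multipliers on the lineage (1 for
none, 2 per tetraploidy, and so on). ``paint_genome`` projects ancestral
protochromosome labels onto a modern genome, ``count_events`` reads Cfis and
Cfus off the painting, and ``chromosome_equation`` evaluates the identity.
Inversions do not change segment counts and are deliberately invisible here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger("paleokaryo")


@dataclass
class PaintSegment:
    protochromosome: str
    start_rank: int
    end_rank: int
    orientation: str = "+"
    n_genes: int = 0


@dataclass
class GenomePainting:
    genome: str
    segments: dict[str, list[PaintSegment]] = field(default_factory=dict)

    @property
    def n_chromosomes(self) -> int:
        return len(self.segments)

    def n_segments(self) -> int:
        return sum(len(v) for v in self.segments.values())


@dataclass
class EventScenario:
    n_anc: int
    wgd_factor: int
    cfis: int
    cfus: int
    n_modern: int

    def equation(self) -> str:
        wgd = f"{self.n_anc} x {self.wgd_factor}" if self.wgd_factor > 1 else str(self.n_anc)
        return f"{self.n_modern} = ({wgd}) + {self.cfis}Cfis - {self.cfus}Cfus"

    def check(self) -> bool:
        return self.n_modern == self.n_anc * self.wgd_factor + self.cfis - self.cfus


def chromosome_equation(n_anc: int, wgd_factor: int, cfis: int, cfus: int) -> int:
    """Modern chromosome number implied by the conservation identity.

    Raises when the implied karyotype would have fewer than one chromosome.
    """
    for name, v in (("n_anc", n_anc), ("cfis", cfis), ("cfus", cfus)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    if wgd_factor < 1:
        raise ValueError("wgd_factor must be >= 1")
    n_modern = n_anc * wgd_factor + cfis - cfus
    if n_modern < 1:
        raise ValueError(
            f"impossible karyotype: {n_anc} x {wgd_factor} + {cfis} - {cfus} = {n_modern}"
        )
    return n_modern


def paint_genome(genome, marker_to_proto: dict, marker_rank: dict | None = None,
                 min_run: int = 5) -> GenomePainting:
    """Label each modern chromosome with runs of ancestral protochromosomes.

    ``marker_to_proto`` maps a gene's family (or marker id) to its
    protochromosome; ``marker_rank`` optionally gives the ancestral position
    of each family, used to split runs where a protochromosome's gene order
    restarts (two fused post-WGD copies of the same protochromosome).
    Runs shorter than ``min_run`` genes are absorbed into flanking segments
    (single-gene transposition noise).
    """
    painting = GenomePainting(genome=genome.name)
    any_mapped = False
    for chrom, genes in genome.chromosomes.items():
        labeled = [
            (g.rank, marker_to_proto.get(g.family),
             marker_rank.get(g.family) if marker_rank else None)
            for g in genes
        ]
        labeled = [t for t in labeled if t[1] is not None]
        if not labeled:
            continue
        any_mapped = True
        runs = _runs(labeled)
        runs = _absorb_short(runs, min_run)
        painting.segments[chrom] = [
            PaintSegment(
                protochromosome=proto,
                start_rank=items[0][0], end_rank=items[-1][0],
                orientation=_orientation(items),
                n_genes=len(items),
            )
            for proto, items in runs
        ]
    if not any_mapped:
        logger.warning("paint_genome: %s has no mapped markers", genome.name)
    return painting


def _runs(labeled):
    """Maximal same-protochromosome runs, split where ancestral rank revisits
    the span already covered (a second post-WGD copy)."""
    runs = []
    cur_proto, items, lo, hi = None, [], None, None
    for rank, proto, arank in labeled:
        # within one copy (no inversions) ancestral ranks run strictly
        # monotone, so a rank inside the covered span signals a second copy
        revisit = (
            proto == cur_proto and arank is not None
            and lo is not None and lo <= arank <= hi
        )
        if proto != cur_proto or revisit:
            if items:
                runs.append((cur_proto, items))
            cur_proto, items = proto, []
            lo = hi = arank
        items.append((rank, proto, arank))
        if arank is not None and lo is not None:
            lo, hi = min(lo, arank), max(hi, arank)
        elif arank is not None:
            lo = hi = arank
    if items:
        runs.append((cur_proto, items))
    return runs


def _absorb_short(runs, min_run):
    # iteratively merge sub-minimum runs into their larger neighbours
    runs = [list(r) for r in runs]
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, (proto, items) in enumerate(runs):
            if len(items) >= min_run:
                continue
            neighbors = []
            if i > 0:
                neighbors.append(i - 1)
            if i < len(runs) - 1:
                neighbors.append(i + 1)
            j = max(neighbors, key=lambda k: len(runs[k][1]))
            if len(runs[j][1]) <= len(items):
                continue
            if j < i:
                runs[j][1].extend(items)
            else:
                runs[j][1][:0] = items
            del runs[i]
            changed = True
            break
    # merge now-adjacent same-protochromosome runs, but only when their
    # ancestral spans are disjoint (overlapping spans are two post-WGD copies)
    def span(items):
        aranks = [a for _, _, a in items if a is not None]
        return (min(aranks), max(aranks)) if aranks else None

    merged = []
    for proto, items in runs:
        if merged and merged[-1][0] == proto:
            s1, s2 = span(merged[-1][1]), span(items)
            if s1 is None or s2 is None or s1[1] < s2[0] or s2[1] < s1[0]:
                merged[-1][1].extend(items)
                continue
        merged.append([proto, list(items)])
    return [(p, sorted(it)) for p, it in merged]


def _orientation(items):
    aranks = [a for _, _, a in items if a is not None]
    if len(aranks) >= 2 and aranks[-1] < aranks[0]:
        return "-"
    return "+"


def count_events(painting: GenomePainting, n_anc: int,
                 wgd_factor: int = 1) -> EventScenario:
    """Read Cfis and Cfus off a painting, treating post-WGD copies separately.

    cfus = sum over modern chromosomes of (segments - 1);
    cfis = sum over ancestral chromosomes of (segments of it - wgd_factor).
    The conservation identity then holds whenever the painting is complete.
    """
    n_modern = painting.n_chromosomes
    cfus = sum(len(v) - 1 for v in painting.segments.values())
    per_anc: dict[str, int] = {}
    for segs in painting.segments.values():
        for s in segs:
            per_anc[s.protochromosome] = per_anc.get(s.protochromosome, 0) + 1
    cfis = 0
    for proto in sorted(per_anc):
        pieces = per_anc[proto]
        cfis += pieces - wgd_factor
    missing = n_anc - len(per_anc)
    if missing > 0:
        logger.warning("count_events: %d ancestral chromosomes unrepresented "
                       "in the painting of %s", missing, painting.genome)
        cfis -= missing * wgd_factor  # they contribute no pieces at all
    if cfis < 0:
        raise ValueError(
            "painting inconsistent with wgd_factor: fewer pieces than copies"
        )
    scenario = EventScenario(n_anc=n_anc, wgd_factor=wgd_factor,
                             cfis=cfis, cfus=cfus, n_modern=n_modern)
    if not scenario.check():
        logger.warning("count_events: conservation identity violated for %s "
                       "(incomplete painting?)", painting.genome)
    return scenario
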