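"""Double-conserved-synteny detection and pre-WGD ancestor ordering.

A DCS segment is a run of contiguous ancestral genes seen once in a
lower-ploidy genome and twice, on two distinct chromosomes, in a duplicated
genome (duplication mode) — or, in triplication mode for a paleohexaploidy,
once on a base chromosome with paralogous copies on up to two companion
chromosomes of the same genome. All runs are strictly contiguous in
*ancestral-gene space* (the gene order projected to genes that participate in
the ortholog/paralog pattern): zero flexibility, so an unpaired ancestral
gene breaks a segment.

Segment significance comes from a permutation null: gene positions are
shuffled within chromosomes and the null distribution of the maximal segment
size is recorded; Benjamini-Hochberg correction is applied at the requested
FDR. Significant segments become ancestral markers and are ordered into
pre-WGD CARs with the same consecutive-ones machinery as the
post-speciation reconstruction (0/1 matrix, no X entries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .car_builder import MatrixRow, SandwichMatrix, order_c1p

logger = logging.getLogger("paleokaryo")

UNPAIRED = object()  # sentinel: ancestral gene without the clean copy pattern


@dataclass
class DCSSegment:
    """One DCS segment: a base run plus its duplicated companion runs."""

    id: str
    base_chrom: str
    base_span: tuple[int, int]          # gene ranks on the base chromosome
    copy_runs: dict[str, tuple[int, int]]  # chrom -> span in ancestral space
    genes: list = field(default_factory=list)  # ancestral gene ids, base order
    p_value: float = 1.0
    q_value: float = 1.0
    significant: bool = False

    @property
    def n_ancestral_genes(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# duplication mode


def _dup_spaces(low_genome, high_genome, pairs):
    """Ancestral-gene spaces for duplication mode.

    Returns (base_lists, high_lists): base_lists[chrom] is the ordered list of
    (base_gene_id, rank); high_lists[chrom] the ordered list of base_gene_id
    labels carried by the duplicated genome's ortholog-bearing genes.
    """
    omap: dict[str, list[str]] = {}
    for g1, g2 in zip(pairs["gene1"], pairs["gene2"]):
        if g1 in low_genome and g2 in high_genome:
            omap.setdefault(g1, []).append(g2)
        elif g2 in low_genome and g1 in high_genome:
            omap.setdefault(g2, []).append(g1)
    base_lists = {
        chrom: [(g.id, g.rank) for g in genes if g.id in omap]
        for chrom, genes in low_genome.chromosomes.items()
    }
    rev: dict[str, str] = {}
    for b, hs in omap.items():
        for h in hs:
            rev[h] = b
    high_lists = {
        chrom: [rev[g.id] for g in genes if g.id in rev]
        for chrom, genes in high_genome.chromosomes.items()
    }
    return base_lists, high_lists


def _scan_dup(base_lists, high_lists, rank_of=None):
    """Partition each base chromosome into maximal 1:2 runs (flexibility 0)."""
    pos: dict[str, list[tuple[str, int]]] = {}
    for chrom, labels in high_lists.items():
        for idx, b in enumerate(labels):
            pos.setdefault(b, []).append((chrom, idx))
    segments = []
    for chrom in sorted(base_lists):
        cur = None

        def close():
            nonlocal cur
            if cur is not None and cur["genes"]:
                segments.append(cur)
            cur = None

        for gid, rank in base_lists[chrom]:
            copies = pos.get(gid, [])
            chroms = {c for c, _ in copies}
            clean = len(copies) == 2 and len(chroms) == 2
            if not clean:
                close()  # unpaired ancestral gene: zero flexibility
                continue
            if cur is not None and _extends(cur["intervals"], copies, set(cur["intervals"])):
                cur["genes"].append(gid)
                cur["span"] = (cur["span"][0], rank)
            else:
                close()
                cur = {"chrom": chrom, "genes": [gid], "span": (rank, rank),
                       "intervals": {c: [i, i] for c, i in copies}}
        close()
    return segments


def _extends(intervals, copies, required_chroms):
    chroms = {c for c, _ in copies}
    if not chroms <= required_chroms:
        return False
    for c, i in copies:
        if c in intervals:
            lo, hi = intervals[c]
            if i != hi + 1 and i != lo - 1:
                return False
    for c, i in copies:
        lo, hi = intervals.get(c, (i, i))
        intervals[c] = [min(lo, i), max(hi, i)]
    return True


def find_dcs_segments(low_genome, high_genome, pairs, flexibility: int = 0,
                      fdr: float = 0.05, min_genes: int = 2,
                      n_permutations: int = 200, seed: int = 0) -> list[DCSSegment]:
    """Detect DCS segments between a lower- and a higher-ploidy genome.

    ``pairs`` is a filtered (and Ks-classed, if desired) ortholog table with
    gene1/gene2 columns. Only ``flexibility=0`` is implemented: runs must be
    strictly contiguous in ancestral-gene space on the base and on both copy
    chromosomes.
    """
    if flexibility != 0:
        raise NotImplementedError("only flexibility=0 is supported")
    if low_genome.ploidy_tag is None or high_genome.ploidy_tag is None:
        raise ValueError("genomes must carry a ploidy_tag")
    base_lists, high_lists = _dup_spaces(low_genome, high_genome, pairs)
    raw = _scan_dup(base_lists, high_lists)
    for seg in raw:  # report ancestral genes by family, keep base gene ids
        seg["base_genes"] = list(seg["genes"])
        seg["genes"] = [low_genome[g].family for g in seg["genes"]]
    null_max = _null_max(
        lambda lists: _scan_dup(base_lists, lists),
        high_lists, n_permutations, seed,
    )
    return _finalize(raw, null_max, n_permutations, fdr, min_genes)


# ---------------------------------------------------------------------------
# triplication mode


def _tri_space(genome, pairs):
    """Per-chromosome ordered family lists for triplication mode.

    An ancestral gene is a family whose surviving paralogous copies (linked by
    the supplied gamma-class pairs) sit on >= 2 distinct chromosomes, one copy
    per chromosome; families breaking that pattern are kept in the space as
    run-breakers.
    """
    in_pairs = set(pairs["gene1"]) | set(pairs["gene2"])
    fam_copies: dict[str, list] = {}
    for chrom, genes in genome.chromosomes.items():
        for g in genes:
            if g.id in in_pairs:
                fam_copies.setdefault(g.family, []).append(g)
    lists = {}
    ranks = {}
    for chrom, genes in genome.chromosomes.items():
        seq = [g for g in genes if g.id in in_pairs]
        if seq:
            lists[chrom] = [g.family for g in seq]
            ranks[chrom] = [g.rank for g in seq]
    return lists, ranks


def _scan_tri(lists, strict_triples=False):
    pos: dict[str, list[tuple[str, int]]] = {}
    for chrom, fams in lists.items():
        for idx, f in enumerate(fams):
            pos.setdefault(f, []).append((chrom, idx))
    candidates = []
    for base in sorted(lists):
        cur = None

        def close():
            nonlocal cur
            if cur is not None and cur["genes"]:
                candidates.append(cur)
            cur = None

        for idx, fam in enumerate(lists[base]):
            copies = pos.get(fam, [])
            chroms = [c for c, _ in copies]
            companions = {c for c in chroms if c != base}
            clean = (
                len(chroms) == len(set(chroms))        # one copy per chromosome
                and 2 <= len(copies) <= 3
                and base in set(chroms)
                and (not strict_triples or len(companions) == 2)
                and len(companions) >= 1
            )
            if not clean:
                close()
                continue
            if cur is not None and len(cur["companions"] | companions) <= 2 \
                    and _extends(cur["intervals"], copies,
                                 set(cur["intervals"]) | companions | {base}):
                cur["genes"].append(fam)
                cur["companions"] |= companions
            else:
                close()
                cur = {"chrom": base, "genes": [fam],
                       "companions": set(companions),
                       "intervals": {c: [i, i] for c, i in copies}}
        close()
    # the same triplet is discovered from each base chromosome: deduplicate
    candidates.sort(key=lambda s: (-len(s["genes"]), s["chrom"]))
    kept, used = [], set()
    for cand in candidates:
        if used & set(cand["genes"]):
            continue
        used |= set(cand["genes"])
        kept.append(cand)
    return kept


def find_triplication_segments(genome, paralog_pairs, fdr: float = 0.05,
                               min_genes: int = 2, n_permutations: int = 200,
                               seed: int = 0,
                               strict_triples: bool = False) -> list[DCSSegment]:
    """Detect triplets of mutually paralogous runs on three chromosomes.

    ``paralog_pairs`` should be filtered to the targeted WGD's Ks class
    (gamma for the paleohexaploidy). By default an ancestral gene may be
    witnessed by a single surviving paralog pair (fractionation destroys
    third copies); ``strict_triples`` demands all three copies.
    """
    if genome.n_chromosomes < 3:
        logger.warning("find_triplication_segments: %s has < 3 chromosomes",
                       genome.name)
        return []
    if len(paralog_pairs) == 0:
        return []
    lists, ranks = _tri_space(genome, paralog_pairs)
    raw = _scan_tri(lists, strict_triples)
    for seg in raw:
        lo, hi = seg["intervals"][seg["chrom"]]
        seg["span"] = (ranks[seg["chrom"]][lo], ranks[seg["chrom"]][hi])
    null_max = _null_max(
        lambda ls: _scan_tri(ls, strict_triples), lists, n_permutations, seed,
    )
    return _finalize(raw, null_max, n_permutations, fdr, min_genes)


# ---------------------------------------------------------------------------
# significance + packaging


def _null_max(scan, lists, n_permutations, seed):
    rng = np.random.default_rng(seed)
    null = np.zeros(n_permutations, dtype=int)
    for b in range(n_permutations):
        shuffled = {}
        for chrom, labels in lists.items():
            labels = list(labels)
            perm = rng.permutation(len(labels))
            shuffled[chrom] = [labels[i] for i in perm]
        segs = scan(shuffled)
        null[b] = max((len(s["genes"]) for s in segs), default=0)
    return null


def _finalize(raw, null_max, n_permutations, fdr, min_genes):
    segments = []
    for i, seg in enumerate(sorted(raw, key=lambda s: (s["chrom"], s["span"]))):
        n = len(seg["genes"])
        p = (1.0 + int((null_max >= n).sum())) / (n_permutations + 1.0)
        segments.append(DCSSegment(
            id=f"dcs{i + 1:04d}",
            base_chrom=seg["chrom"],
            base_span=tuple(seg["span"]),
            copy_runs={c: tuple(v) for c, v in seg["intervals"].items()
                       if c != seg["chrom"]},
            genes=list(seg["genes"]),
            p_value=p,
        ))
    if segments:
        reject, q, _, _ = multipletests([s.p_value for s in segments],
                                        alpha=fdr, method="fdr_bh")[:4]
        for s, r, qv in zip(segments, reject, q):
            s.q_value = float(qv)
            s.significant = bool(r) and s.n_ancestral_genes >= min_genes
    return segments


# ---------------------------------------------------------------------------
# ordering the pre-WGD ancestor


def _segment_sequences(segments):
    """Per chromosome, segment ids ordered by their run position."""
    seqs: dict[str, list[tuple[int, str]]] = {}
    for s in segments:
        seqs.setdefault(s.base_chrom, []).append((s.base_span[0], s.id))
        for chrom, (lo, _hi) in s.copy_runs.items():
            seqs.setdefault(chrom, []).append((lo, s.id))
    return {c: [sid for _, sid in sorted(v)] for c, v in seqs.items()}


def _seq_common_intervals(seqs):
    """Maximal sets of segment ids contiguous (any order) in >= 2 sequences."""
    out = {}
    names = sorted(seqs)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = seqs[a], seqs[b]
            shared = set(sa) & set(sb)
            if len(shared) < 2:
                continue
            pa = [x for x in sa if x in shared]
            posb = {x: k for k, x in enumerate(y for y in sb if y in shared)}
            n = len(pa)
            best = [-1] * n
            for s0 in range(n):
                lo = hi = posb[pa[s0]]
                for j in range(s0 + 1, n):
                    p = posb[pa[j]]
                    lo, hi = min(lo, p), max(hi, p)
                    if hi - lo == j - s0:
                        best[s0] = j
            pm = -1
            for s0 in range(n):
                j = best[s0]
                if j >= 0 and j > pm:
                    out.setdefault(frozenset(pa[s0:j + 1]), 0)
                    out[frozenset(pa[s0:j + 1])] += 1
                pm = max(pm, j)
    return out


def order_pre_wgd(segments, min_support: int = 2, reference_order=None):
    """Order significant DCS segments into CARs for the pre-WGD ancestor.

    Segments act as ancestral markers; adjacencies and common intervals are
    computed over their projections onto every chromosome (base and copies),
    then ordered with the consecutive-ones machinery on a 0/1 matrix (every
    marker is present in the genomes considered, so there are no X entries).
    """
    segments = [s for s in segments if s.significant]
    if not segments:
        return order_c1p(SandwichMatrix(columns=[], rows=[]))
    seqs = _segment_sequences(segments)
    columns = sorted(s.id for s in segments)
    colset = frozenset(columns)
    adj: dict[frozenset, int] = {}
    for seq in seqs.values():
        for a, b in zip(seq, seq[1:]):
            if a != b:
                key = frozenset((a, b))
                adj[key] = adj.get(key, 0) + 1
    rows = [MatrixRow(ones=k, zeros=colset - k, support=v)
            for k, v in adj.items() if v >= min_support]
    for mset, support in _seq_common_intervals(seqs).items():
        if support >= 1 and len(mset) < len(columns):
            rows.append(MatrixRow(ones=mset, zeros=colset - mset, support=support))
    rows.sort(key=lambda r: (-r.support, len(r.ones), sorted(r.ones)))
    matrix = SandwichMatrix(columns=columns, rows=rows)
    return order_c1p(matrix, reference_order=reference_order)


def pre_wgd_gene_order(ordering, segments) -> list[list]:
    """Expand segment-level CARs into ancestral gene (family) order lists.

    Each CAR yields one list: segments in CAR order, genes within a segment
    in base-run order, a segment reversed when that chains better with its
    predecessor's base span.
    """
    seg_by_id = {s.id: s for s in segments}
    out = []
    for car in ordering.cars:
        genes: list = []
        prev = None
        for sid in car.markers:
            seg = seg_by_id[sid]
            block = list(seg.genes)
            if prev is not None and seg.base_chrom == prev.base_chrom:
                if seg.base_span[0] < prev.base_span[0]:
                    block = block[::-1]
            genes.extend(block)
            prev = seg
        out.append(genes)
    for sid in ordering.unplaced_markers:
        out.append(list(seg_by_id[sid].genes))
    return out
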