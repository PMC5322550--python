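"""Subgenome dominance statistics and the two-step allohexaploidy partition.

After a paleohexaploidy the ancestor's chromosomes exist as triplets of
homoeologous blocks. Biased fractionation leaves some blocks gene-rich
(dominant, D) and some gene-poor (sensitive, S). Within each triplet the
three pairwise retention counts are compared by an exact binomial test
B(n1+n2, 1/2); a block is S when it retains significantly fewer ancestral
genes than another member of its triplet (p < alpha, strict, default 0.005).

The two-step model explains the 21 post-hexaploidy blocks as three ancestral
subgenomes: a first tetraploidization A (dominant) + B (sensitive) followed
by hybridization with C (dominant, hence expected D). ``fit_two_step_partition``
searches all per-triplet assignments of blocks to A/B/C for the one most
consistent with the observed D/S labels.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("paleokaryo")

EXPECTED_LABEL = {"A": "D", "B": "S", "C": "D"}


@dataclass
class RetentionTable:
    """Retained ancestral-gene counts: rows = ancestral blocks, cols = genomes."""

    counts: pd.DataFrame               # index = block ids, columns = genome names
    triplets: list[tuple[str, str, str]]

    def pooled(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def blocks(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class DominanceCall:
    block: str
    label: str                          # "D", "S" or "NA"
    no_bias: bool = False
    pairwise_p: dict = field(default_factory=dict)


@dataclass
class TwoStepPartition:
    assignment: dict[str, str]          # block -> "A" | "B" | "C"
    consistency: int
    exceptions: list[str]
    n_ties: int = 1

    def subgenome(self, name: str) -> list[str]:
        return sorted(b for b, s in self.assignment.items() if s == name)


# ---------------------------------------------------------------------------


def retention_counts(ancestor_genes: dict[str, list], genomes,
                     painting: dict[str, dict[str, str]],
                     triplets=None) -> RetentionTable:
    """Count surviving ancestral genes per triplicated block per modern genome.

    ``ancestor_genes`` maps block id -> list of ancestral gene (family) ids;
    ``painting`` maps genome name -> {modern chromosome -> block id}, i.e.
    which homoeologous block each modern chromosome (or chromosome segment
    set) descends from. A block's entry for a genome is the number of its
    ancestral genes with a surviving family member on a chromosome painted to
    that block. Genes on unpainted chromosomes are tallied under
    "unassigned" with a warning.
    """
    gnames = [gm.name for gm in genomes]
    data = {}
    unassigned = 0
    for gm in genomes:
        pmap = painting.get(gm.name, {})
        fams_by_block: dict[str, set] = {}
        for g in gm.genes():
            block = pmap.get(g.chromosome)
            if block is None:
                unassigned += 1
                continue
            fams_by_block.setdefault(block, set()).add(g.family)
        data[gm.name] = {
            block: sum(1 for f in genes if f in fams_by_block.get(block, ()))
            for block, genes in ancestor_genes.items()
        }
    if unassigned:
        logger.warning("retention_counts: %d genes on unpainted chromosomes "
                       "tallied as unassigned", unassigned)
    counts = pd.DataFrame(data, columns=gnames).loc[sorted(ancestor_genes)]
    if triplets is None:
        blocks = list(counts.index)
        if len(blocks) % 3:
            raise ValueError("cannot infer triplets: block count not divisible by 3")
        triplets = [tuple(blocks[i:i + 3]) for i in range(0, len(blocks), 3)]
    return RetentionTable(counts=counts, triplets=list(triplets))


def binomial_dominance_test(n1: int, n2: int, alpha: float = 0.005):
    """Exact two-sided binomial test of n1 vs n2 at p = 1/2.

    Two-sided by the minimum-likelihood convention (outcomes with pmf <= the
    observed pmf are summed). Returns (p_value, significant); significance is
    strict (p < alpha). (0, 0) is undefined and returns (nan, False) with a
    warning.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be nonnegative")
    if n1 + n2 == 0:
        logger.warning("binomial_dominance_test: n1 + n2 = 0, returning NA")
        return (float("nan"), False)
    p = stats.binomtest(n1, n1 + n2, 0.5, alternative="two-sided").pvalue
    return (float(p), bool(p < alpha))


def classify_blocks(table: RetentionTable, alpha: float = 0.005,
                    pooled: bool = True) -> list[DominanceCall]:
    """Label each block D or S from within-triplet pairwise binomial tests.

    Counts are summed across genomes by default (``pooled``); a block is S
    when significantly lower than any other member of its triplet, D
    otherwise. Triplets with no significant pair are all-D with a no-bias
    flag; all-zero triplets get NA labels. With ``pooled=False`` the tests
    run per genome and a pair is called significant when it is significant
    in a majority of genomes (per-genome p-values are Fisher-combined for
    reporting).
    """
    if not pooled:
        return _classify_per_genome(table, alpha)
    counts = table.pooled()
    calls: dict[str, DominanceCall] = {}
    for triplet in table.triplets:
        c = {b: int(counts[b]) for b in triplet}
        if sum(c.values()) == 0:
            for b in triplet:
                calls[b] = DominanceCall(block=b, label="NA")
            continue
        pvals = {}
        lower: set = set()
        any_sig = False
        for b1, b2 in itertools.combinations(triplet, 2):
            p, sig = binomial_dominance_test(c[b1], c[b2], alpha)
            pvals[(b1, b2)] = p
            if sig:
                any_sig = True
                lower.add(b1 if c[b1] < c[b2] else b2)
        for b in triplet:
            pp = {k: v for k, v in pvals.items() if b in k}
            if b in lower:
                calls[b] = DominanceCall(block=b, label="S", pairwise_p=pp)
            else:
                calls[b] = DominanceCall(block=b, label="D",
                                         no_bias=not any_sig, pairwise_p=pp)
    return [calls[b] for b in table.blocks]


def _classify_per_genome(table: RetentionTable, alpha: float) -> list[DominanceCall]:
    calls: dict[str, DominanceCall] = {}
    for triplet in table.triplets:
        pvals: dict = {}
        lower: set = set()
        any_sig = False
        all_zero = bool((table.counts.loc[list(triplet)].sum(axis=1) == 0).all())
        for b1, b2 in itertools.combinations(triplet, 2):
            per_p, sig_votes, low_votes = [], 0, {b1: 0, b2: 0}
            for g in table.counts.columns:
                c1, c2 = int(table.counts.at[b1, g]), int(table.counts.at[b2, g])
                if c1 + c2 == 0:
                    continue
                p, sig = binomial_dominance_test(c1, c2, alpha)
                per_p.append(p)
                if sig:
                    sig_votes += 1
                    low_votes[b1 if c1 < c2 else b2] += 1
            if per_p:
                pvals[(b1, b2)] = float(stats.combine_pvalues(
                    np.clip(per_p, 1e-300, 1.0)).pvalue)
            if sig_votes > len(table.counts.columns) / 2:
                any_sig = True
                lower.add(max(low_votes, key=low_votes.get))
        for b in triplet:
            pp = {k: v for k, v in pvals.items() if b in k}
            if all_zero:
                calls[b] = DominanceCall(block=b, label="NA")
            elif b in lower:
                calls[b] = DominanceCall(block=b, label="S", pairwise_p=pp)
            else:
                calls[b] = DominanceCall(block=b, label="D",
                                         no_bias=not any_sig, pairwise_p=pp)
    return [calls[b] for b in table.blocks]


def chi_square_cross_check(n1: int, n2: int) -> float:
    """Chi-square goodness-of-fit p-value against an equal 50/50 split."""
    if n1 + n2 == 0:
        return float("nan")
    return float(stats.chisquare([n1, n2]).pvalue)


def fit_two_step_partition(labels: dict[str, str], triplets,
                           reference: dict[str, str] | None = None) -> TwoStepPartition:
    """Exhaustive search for the A/B/C assignment most consistent with D/S labels.

    Each triplet contributes one block to each subgenome; expectation is
    A, C -> D and B -> S. All 6 assignments per triplet are scored (the
    search is separable across triplets, equivalent to scanning all 6^7
    global assignments). Ties are broken toward ``reference`` when supplied;
    otherwise the count of optimal assignments is reported in ``n_ties``.
    """
    triplets = [tuple(t) for t in triplets]
    for t in triplets:
        for b in t:
            if b not in labels:
                raise ValueError(f"no D/S label for block {b}")
    assignment: dict[str, str] = {}
    total, n_ties = 0, 1
    for t in triplets:
        best_score, best_assigns = -1, []
        for perm in itertools.permutations("ABC"):
            score = sum(
                1 for b, s in zip(t, perm) if labels[b] == EXPECTED_LABEL[s]
            )
            if score > best_score:
                best_score, best_assigns = score, [perm]
            elif score == best_score:
                best_assigns.append(perm)
        chosen = best_assigns[0]
        if reference is not None and len(best_assigns) > 1:
            def agreement(perm):
                return sum(1 for b, s in zip(t, perm) if reference.get(b) == s)
            chosen = max(best_assigns, key=agreement)
        for b, s in zip(t, chosen):
            assignment[b] = s
        total += best_score
        n_ties *= len(best_assigns)
    exceptions = sorted(
        b for b, s in assignment.items() if labels[b] != EXPECTED_LABEL[s]
    )
    return TwoStepPartition(assignment=assignment, consistency=total,
                            exceptions=exceptions, n_ties=n_ties)


# ---------------------------------------------------------------------------
# the published rosid configuration, for convenience and cross-checks

ROSID_D_BLOCKS = ["A1", "A3", "A4", "A6", "A7", "A8", "A10", "A11", "A15",
                  "A16", "A18", "A20", "A21"]
ROSID_S_BLOCKS = ["A2", "A5", "A9", "A12", "A13", "A14", "A17", "A19"]
# Subgenome lists as established for the rosid hexaploidy; the C list is the
# 21-block completion in which A18 joins C (A16 belongs to A).
ROSID_SUBGENOME_A = ["A3", "A4", "A8", "A10", "A14", "A16", "A20"]
ROSID_SUBGENOME_B = ["A2", "A5", "A9", "A12", "A13", "A17", "A19"]
ROSID_SUBGENOME_C = ["A1", "A6", "A7", "A11", "A15", "A18", "A21"]


def rosid_reference_assignment() -> dict[str, str]:
    ref = {}
    for name, blocks in (("A", ROSID_SUBGENOME_A), ("B", ROSID_SUBGENOME_B),
                         ("C", ROSID_SUBGENOME_C)):
        for b in blocks:
            ref[b] = name
    return ref


def rosid_triplets() -> list[tuple[str, str, str]]:
    """The 7 homoeologous triplets implied by the subgenome lists."""
    return [
        (a, b, c) for a, b, c in
        zip(ROSID_SUBGENOME_A, ROSID_SUBGENOME_B, ROSID_SUBGENOME_C)
    ]


def rosid_labels() -> dict[str, str]:
    labels = {b: "D" for b in ROSID_D_BLOCKS}
    labels.update({b: "S" for b in ROSID_S_BLOCKS})
    return labels
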