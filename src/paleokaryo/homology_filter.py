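"""Cumulative alignment statistics (CIP/CALP), homology filtering and Ks-class labels.

A gene pair is summarized over all of its HSPs (high-scoring segment pairs)
after overlap-trimming on the query axis:

    CIP  = 100 * sum(identities) / sum(aligned_length)   (cumulative identity %)
    CALP = 100 * sum(aligned_length) / query_length      (cumulative aligned-length %)

Pairs are retained when CIP >= 60 and CALP >= 70 (inclusive, both thresholds
configurable), and can be labeled with the polyploidy/speciation event
(rho, alpha, beta, gamma, or a speciation node) whose fitted Ks-mixture
component has the highest posterior probability at the pair's Ks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("paleokaryo")


@dataclass
class HSPSet:
    """All HSPs of one query/subject gene pair.

    Each HSP is a tuple ``(aligned_length, identities, query_start, query_end)``
    with 0-based half-open query coordinates.
    """

    query: str
    subject: str
    query_length: int
    hsps: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.query_length <= 0:
            raise ValueError("query_length must be positive")
        for (alen, ident, qs, qe) in self.hsps:
            if ident > alen:
                raise ValueError(f"identities {ident} exceed aligned length {alen}")


@dataclass
class HomologyPair:
    """A filtered homologous gene pair with its alignment summary and Ks."""

    gene1: str
    gene2: str
    cip: float
    calp: float
    ks: float | None = None
    relation: str = "ortholog"  # "paralog" iff both genes share a genome
    ks_class: str | None = None


def cumulative_alignment_stats(hspset: HSPSet) -> tuple[float, float]:
    """Return (CIP, CALP) percentages for one HSP set.

    Overlapping HSPs on the query axis are trimmed before summation — within
    an overlap the HSP with higher identity fraction wins — so CALP cannot
    exceed 100 and duplicated HSPs are idempotent.
    """
    if not hspset.hsps:
        raise ValueError("empty HSP set")
    L = hspset.query_length
    # per-position attribution: identity fraction of the owning HSP
    frac = np.zeros(L)
    covered = np.zeros(L, dtype=bool)
    order = sorted(hspset.hsps, key=lambda h: (-(h[1] / h[0] if h[0] else 0.0), h[2]))
    for (alen, ident, qs, qe) in order:
        if alen <= 0:
            continue
        qs, qe = max(0, qs), min(L, qe)
        f = ident / alen
        sl = slice(qs, qe)
        # higher-identity HSPs were placed first; only fill uncovered positions
        take = ~covered[sl]
        frac[sl] = np.where(take, f, frac[sl])
        covered[sl] = True
    cum_len = int(covered.sum())
    cum_ident = float(frac[covered].sum())
    cip = 100.0 * cum_ident / cum_len if cum_len else 0.0
    calp = 100.0 * cum_len / L
    return (cip, calp)


def filter_pairs(pairs: pd.DataFrame, cip_min: float = 60.0,
                 calp_min: float = 70.0) -> pd.DataFrame:
    """Keep pairs with cip >= cip_min and calp >= calp_min (inclusive)."""
    if pairs.empty:
        return pairs.copy()
    if not {"cip", "calp"} <= set(pairs.columns):
        raise ValueError("pairs must carry cip and calp columns")
    keep = (pairs["cip"] >= cip_min) & (pairs["calp"] >= calp_min)
    return pairs[keep].reset_index(drop=True)


def assign_ks_class(pairs: pd.DataFrame, mixture, labels=None) -> pd.DataFrame:
    """Label each pair with the Ks-mixture component of maximal posterior.

    ``mixture`` is a fitted :class:`~paleokaryo.ks_dating.KsMixture`.
    ``labels`` optionally names the components in increasing order of their
    log-Ks means (e.g. ``["rho", "alpha", "gamma"]``); defaults to
    ``"k0", "k1", ...``. Pairs without Ks are left unlabeled. Equal-posterior
    ties go to the lower-Ks-mean component (logged).
    """
    if mixture.k == 0:
        raise ValueError("mixture has zero components")
    order = np.argsort(mixture.means)
    if labels is None:
        labels = [f"k{i}" for i in range(mixture.k)]
    if len(labels) != mixture.k:
        raise ValueError("need one label per mixture component")
    out = pairs.copy()
    out["ks_class"] = pd.array([None] * len(out), dtype=object)
    has_ks = out["ks"].notna() & (out["ks"] > 0) if "ks" in out else pd.Series(False, index=out.index)
    if not has_ks.any():
        return out
    ks = out.loc[has_ks, "ks"].to_numpy(dtype=float)
    post = mixture.posterior(ks)  # (n, k)
    # resolve exact ties toward the lower-mean component
    post_sorted = post[:, order]
    best_sorted = np.argmax(post_sorted, axis=1)  # argmax takes first == lowest mean
    ties = (post_sorted == post_sorted[np.arange(len(ks)), best_sorted][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("assign_ks_class: %d posterior ties resolved to lower-Ks component",
                    int(ties.sum()))
    out.loc[has_ks, "ks_class"] = [labels[i] for i in best_sorted]
    return out


def annotate_relation(pairs: pd.DataFrame, genomes) -> pd.DataFrame:
    """Add a relation column: paralog iff both genes lie in the same genome."""
    gmap = {}
    for gm in genomes:
        for g in gm.genes():
            gmap[g.id] = gm.name
    out = pairs.copy()
    out["relation"] = [
        "paralog" if gmap.get(a) == gmap.get(b) else "ortholog"
        for a, b in zip(out["gene1"], out["gene2"])
    ]
    return out
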