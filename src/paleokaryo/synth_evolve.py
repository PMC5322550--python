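"""Forward simulator of paleopolyploid genome evolution with full ground truth.

The simulator emulates the evolutionary history inferred for rosid genomes:
a diploid ancestor with 7 protochromosomes undergoes a two-step
allohexaploidy — a tetraploidization joining subgenomes A (dominant) and B
(sensitive), followed by hybridization with subgenome C — with
subgenome-specific gene-retention probabilities; descendant lineages then
accumulate lineage-specific WGDs, telomeric chromosome fusions, fissions,
inversions and gene loss. Synonymous distances follow the molecular clock
Ks = 2 r T with multiplicative log-normal noise, so the Ks of a pair is set
by the event (polyploidy or speciation) at which its two genes diverged.

Every stochastic choice flows through one seeded generator, every event is
logged with enough detail to replay it exactly, and the emitted gene tables,
homology tables and species tree use the package's own input formats, making
the simulator both a test fixture factory and a ground-truth oracle for
recovery scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dominance import (
    ROSID_SUBGENOME_A,
    ROSID_SUBGENOME_B,
    ROSID_SUBGENOME_C,
)
from .genome_io import Gene, Genome
from .ks_dating import DEFAULT_RATE

logger = logging.getLogger("paleokaryo")

# default event ages (years); the hexaploidy is the oldest, shared event
AGE_GAMMA = 1.25e8
AGE_ALPHA_BETA = 6.0e7
AGE_RHO = 1.1e7


@dataclass
class BranchEvents:
    """Events on one lineage, applied in the order:
    WGD -> fissions -> fusions -> inversions -> gene loss."""

    age: float = 5.0e7                 # speciation age of this lineage, years
    wgd_age: float | None = None       # None: no lineage-specific WGD
    wgd_retention: float = 1.0
    n_fissions: int = 0
    n_fusions: int = 0
    n_inversions: int = 0
    loss_rate: float = 0.0


@dataclass
class SimParams:
    n_anc: int = 7
    genes_per_chromosome: int = 200
    retention_a: float = 0.9
    retention_b: float = 0.4
    retention_c: float = 0.95
    rate: float = DEFAULT_RATE
    ks_noise_sd: float = 0.1
    age_gamma: float = AGE_GAMMA
    corruption_rate: float = 0.0       # fraction of pairs given sub-threshold scores
    seed: int = 42

    def __post_init__(self):
        for name in ("retention_a", "retention_b", "retention_c"):
            p = getattr(self, name)
            if not (0.0 < p <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.age_gamma <= 0 or self.rate <= 0:
            raise ValueError("ages and rate must be positive")


@dataclass
class SimGene:
    """Internal simulator gene: a family plus its copy-lineage tag."""

    family: str
    tag: tuple            # (subgenome, wgd copy, wgd copy, ...)
    strand: str = "+"


@dataclass
class TruthBundle:
    params: SimParams
    ancestor_order: dict[str, list]            # pre-WGD chrom -> family ids
    post_wgd_order: dict[str, list]            # post-hexaploidy block -> family ids
    block_subgenome: dict[str, str]            # block -> A/B/C
    block_of_chrom: dict[str, str]             # ancestor chrom of each block
    genomes: dict[str, Genome] = field(default_factory=dict)
    sim_chromosomes: dict = field(default_factory=dict)  # genome -> chrom -> [SimGene]
    event_logs: dict[str, list] = field(default_factory=dict)
    branch_events: dict[str, BranchEvents] = field(default_factory=dict)
    wgd_ages: dict[str, list] = field(default_factory=dict)

    def hexaploid(self) -> Genome:
        return self.genomes["hexaploid"]


# ---------------------------------------------------------------------------
# construction


def _family_id(chrom_index: int, gene_index: int) -> str:
    return f"F{chrom_index + 1:02d}{gene_index:04d}"


def simulate_two_step_hexaploidy(params: SimParams) -> TruthBundle:
    """Build the diploid ancestor and its two-step allohexaploid descendant.

    Step 1 joins subgenomes A and B (B fractionated at ``retention_b``, A at
    ``retention_a``); step 2 adds subgenome C (fractionated at
    ``retention_c``). Families losing all three copies keep one copy on the
    most retentive subgenome, so the ancestral gene repertoire survives.
    With all retentions at 1 the hexaploid has exactly 3x the ancestor's
    genes on 3 x n_anc chromosomes.
    """
    rng = np.random.default_rng(params.seed)
    n, g = params.n_anc, params.genes_per_chromosome
    ancestor_order = {
        f"P{i + 1}": [_family_id(i, j) for j in range(g)] for i in range(n)
    }
    # block naming follows the rosid convention when n_anc == 7
    if n == 7:
        names = {"A": ROSID_SUBGENOME_A, "B": ROSID_SUBGENOME_B,
                 "C": ROSID_SUBGENOME_C}
    else:
        names = {s: [f"{s}{i + 1}" for i in range(n)] for s in "ABC"}
    retention = {"A": params.retention_a, "B": params.retention_b,
                 "C": params.retention_c}
    keep: dict[tuple, np.ndarray] = {
        s: rng.random((n, g)) < retention[s] for s in "ABC"
    }
    # protection: a family losing all three copies keeps its best-subgenome copy
    order_pref = sorted("ABC", key=lambda s: -retention[s])
    for i in range(n):
        for j in range(g):
            if not any(keep[s][i, j] for s in "ABC"):
                keep[order_pref[0]][i, j] = True

    sim_chroms: dict[str, list[SimGene]] = {}
    post_order: dict[str, list] = {}
    block_sub: dict[str, str] = {}
    block_of: dict[str, str] = {}
    for i in range(n):
        for s in "ABC":
            block = names[s][i]
            genes = [
                SimGene(family=_family_id(i, j), tag=(s,))
                for j in range(g) if keep[s][i, j]
            ]
            sim_chroms[block] = genes
            post_order[block] = [sg.family for sg in genes]
            block_sub[block] = s
            block_of[block] = f"P{i + 1}"

    bundle = TruthBundle(
        params=params,
        ancestor_order=ancestor_order,
        post_wgd_order=post_order,
        block_subgenome=block_sub,
        block_of_chrom=block_of,
    )
    bundle.sim_chromosomes["hexaploid"] = sim_chroms
    bundle.event_logs["hexaploid"] = [
        {"event": "hexaploidy", "age": params.age_gamma,
         "retention": retention, "n_chromosomes": 3 * n},
    ]
    bundle.wgd_ages["hexaploid"] = []
    bundle.branch_events["hexaploid"] = BranchEvents(age=params.age_gamma)
    bundle.genomes["hexaploid"] = _materialize("hexaploid", sim_chroms)
    return bundle


def _materialize(name: str, sim_chroms: dict[str, list[SimGene]]) -> Genome:
    genes = []
    for chrom in sim_chroms:
        for rank, sg in enumerate(sim_chroms[chrom]):
            tag = ".".join(str(t) for t in sg.tag)
            genes.append(Gene(
                id=f"{name}|{chrom}|{rank:04d}|{sg.family}|{tag}",
                family=sg.family, genome=name, chromosome=chrom,
                rank=rank, strand=sg.strand,
            ))
    return Genome(name, genes)


# ---------------------------------------------------------------------------
# lineage evolution


def evolve_lineage(bundle: TruthBundle, name: str, events: BranchEvents,
                   seed: int, source: str = "hexaploid") -> Genome:
    """Evolve one modern genome from the hexaploid and log every event.

    Events apply in the order WGD -> fissions -> fusions -> inversions ->
    gene loss. Fusions are telomeric (end-to-end joins of two uniformly
    chosen chromosomes, the second possibly reversed); fissions split at a
    uniform internal gene boundary. The event log allows exact replay.
    """
    rng = np.random.default_rng(seed)
    chroms = {c: list(genes) for c, genes in bundle.sim_chromosomes[source].items()}
    log: list[dict] = []
    wgd_ages = list(bundle.wgd_ages[source])

    if events.wgd_age is not None:
        depth = len(wgd_ages)
        new = {}
        loss_record = {}
        for c in sorted(chroms):
            for copy in ("a", "b"):
                new[f"{c}.{copy}"] = [
                    SimGene(sg.family, sg.tag + (copy,), sg.strand)
                    for sg in chroms[c]
                ]
            # fractionation: drop one copy of a pair with prob 1 - retention
            lost = rng.random(len(chroms[c])) >= events.wgd_retention
            which = rng.integers(0, 2, size=len(chroms[c]))
            idx_by_copy = {"a": [], "b": []}
            for j, (is_lost, w) in enumerate(zip(lost, which)):
                if is_lost:
                    idx_by_copy["a" if w == 0 else "b"].append(j)
            for copy in ("a", "b"):
                drop = set(idx_by_copy[copy])
                new[f"{c}.{copy}"] = [
                    sg for j, sg in enumerate(new[f"{c}.{copy}"]) if j not in drop
                ]
            loss_record[c] = {k: list(v) for k, v in idx_by_copy.items()}
        chroms = new
        wgd_ages.append(events.wgd_age)
        log.append({"event": "wgd", "age": events.wgd_age, "depth": depth,
                    "retention": events.wgd_retention, "losses": loss_record})

    for _ in range(events.n_fissions):
        eligible = sorted(c for c in chroms if len(chroms[c]) >= 2)
        if not eligible:
            raise ValueError("no chromosome long enough to split")
        c = eligible[rng.integers(len(eligible))]
        cut = int(rng.integers(1, len(chroms[c])))
        left, right = chroms[c][:cut], chroms[c][cut:]
        del chroms[c]
        chroms[f"{c}:1"], chroms[f"{c}:2"] = left, right
        log.append({"event": "fission", "chromosome": c, "cut": cut})

    for _ in range(events.n_fusions):
        if len(chroms) < 2:
            raise ValueError("cannot fuse: fewer than two chromosomes")
        cs = sorted(chroms)
        i, j = rng.choice(len(cs), size=2, replace=False)
        c1, c2 = cs[i], cs[j]
        flip = bool(rng.random() < 0.5)
        tail = _reversed_genes(chroms[c2]) if flip else chroms[c2]
        chroms[f"{c1}+{c2}"] = chroms[c1] + tail
        del chroms[c1], chroms[c2]
        log.append({"event": "fusion", "chromosomes": [c1, c2], "flip": flip})

    for _ in range(events.n_inversions):
        eligible = sorted(c for c in chroms if len(chroms[c]) >= 2)
        if not eligible:
            break
        c = eligible[rng.integers(len(eligible))]
        m = len(chroms[c])
        a, b = sorted(rng.choice(m + 1, size=2, replace=False))
        if b - a < 2:
            b = min(m, a + 2)
        chroms[c] = chroms[c][:a] + _reversed_genes(chroms[c][a:b]) + chroms[c][b:]
        log.append({"event": "inversion", "chromosome": c, "span": [int(a), int(b)]})

    if events.loss_rate > 0:
        loss_log = {}
        for c in sorted(chroms):
            lost = rng.random(len(chroms[c])) < events.loss_rate
            loss_log[c] = [int(i) for i in np.flatnonzero(lost)]
            chroms[c] = [sg for i, sg in enumerate(chroms[c]) if not lost[i]]
        log.append({"event": "loss", "rate": events.loss_rate, "lost": loss_log})

    bundle.sim_chromosomes[name] = chroms
    bundle.event_logs[name] = log
    bundle.branch_events[name] = events
    bundle.wgd_ages[name] = wgd_ages
    genome = _materialize(name, chroms)
    bundle.genomes[name] = genome
    return genome


def _reversed_genes(genes):
    return [SimGene(sg.family, sg.tag, "-" if sg.strand == "+" else "+")
            for sg in reversed(genes)]


def replay_log(bundle: TruthBundle, name: str, source: str = "hexaploid") -> Genome:
    """Re-apply a logged event list deterministically; must equal the emitted genome."""
    chroms = {c: list(g) for c, g in bundle.sim_chromosomes[source].items()}
    for entry in bundle.event_logs[name]:
        ev = entry["event"]
        if ev == "wgd":
            new = {}
            for c in sorted(chroms):
                for copy in ("a", "b"):
                    drop = set(entry["losses"][c][copy])
                    new[f"{c}.{copy}"] = [
                        SimGene(sg.family, sg.tag + (copy,), sg.strand)
                        for j, sg in enumerate(chroms[c]) if j not in drop
                    ]
            chroms = new
        elif ev == "fission":
            c, cut = entry["chromosome"], entry["cut"]
            left, right = chroms[c][:cut], chroms[c][cut:]
            del chroms[c]
            chroms[f"{c}:1"], chroms[f"{c}:2"] = left, right
        elif ev == "fusion":
            c1, c2 = entry["chromosomes"]
            tail = _reversed_genes(chroms[c2]) if entry["flip"] else chroms[c2]
            chroms[f"{c1}+{c2}"] = chroms[c1] + tail
            del chroms[c1], chroms[c2]
        elif ev == "inversion":
            c, (a, b) = entry["chromosome"], entry["span"]
            chroms[c] = chroms[c][:a] + _reversed_genes(chroms[c][a:b]) + chroms[c][b:]
        elif ev == "loss":
            for c, lost in entry["lost"].items():
                drop = set(lost)
                chroms[c] = [sg for i, sg in enumerate(chroms[c]) if i not in drop]
    return _materialize(name, chroms)


def logged_event_counts(bundle: TruthBundle, name: str) -> dict:
    """(wgd_factor, cfis, cfus) implied by a lineage's event log."""
    wgd_factor, cfis, cfus = 1, 0, 0
    for entry in bundle.event_logs[name]:
        if entry["event"] == "wgd":
            wgd_factor *= 2
        elif entry["event"] == "fission":
            cfis += 1
        elif entry["event"] == "fusion":
            cfus += 1
    return {"wgd_factor": wgd_factor, "cfis": cfis, "cfus": cfus}


# ---------------------------------------------------------------------------
# homology emission


def _divergence_age(bundle, g1, g2, tag1, tag2):
    """Age of the event at which two gene copies diverged."""
    if tag1[0] != tag2[0]:
        return bundle.params.age_gamma
    if g1 == g2:
        ages = bundle.wgd_ages[g1]
        for d in range(1, min(len(tag1), len(tag2))):
            if tag1[d] != tag2[d]:
                return ages[d - 1]
        return ages[min(len(tag1), len(tag2)) - 1] if len(tag1) != len(tag2) else 0.0
    return min(bundle.branch_events[g1].age, bundle.branch_events[g2].age)


def emit_homology(bundle: TruthBundle, genome_names=None,
                  seed: int | None = None) -> pd.DataFrame:
    """All same-family gene pairs across/within the requested genomes.

    Columns: gene1, gene2, cip, calp, ks, relation, true_event_age.
    Ks = 2 r T * exp(noise); cip/calp decay mildly with Ks and pass the
    60/70 thresholds except for an optional corrupted fraction.
    """
    params = bundle.params
    if genome_names is None:
        genome_names = sorted(bundle.genomes)
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    by_family: dict[str, list] = {}
    for gname in genome_names:
        for gene in bundle.genomes[gname].genes():
            tag = tuple(gene.id.split("|")[-1].split("."))
            by_family.setdefault(gene.family, []).append((gname, gene.id, tag))
    rows = []
    for fam in sorted(by_family):
        members = by_family[fam]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                (ga, ida, taga), (gb, idb, tagb) = members[i], members[j]
                age = _divergence_age(bundle, ga, gb, taga, tagb)
                noise = float(rng.normal(0.0, params.ks_noise_sd))
                ks = 2.0 * params.rate * age * np.exp(noise)
                cip = float(np.clip(95.0 - 8.0 * ks + rng.normal(0, 2), 0, 100))
                calp = float(np.clip(97.0 - 5.0 * ks + rng.normal(0, 2), 0, 100))
                if params.corruption_rate > 0 and rng.random() < params.corruption_rate:
                    cip = float(rng.uniform(20, 55))
                g1, g2 = sorted((ida, idb))
                rows.append((g1, g2, cip, calp, ks,
                             "paralog" if ga == gb else "ortholog", age))
    return pd.DataFrame(rows, columns=[
        "gene1", "gene2", "cip", "calp", "ks", "relation", "true_event_age",
    ])


def species_tree_newick(bundle: TruthBundle, names=None) -> str:
    """A caterpillar newick over the evolved lineages, oldest split first."""
    names = [n for n in (names or bundle.genomes) if n != "hexaploid"]
    if not names:
        return "(hexaploid);"
    names = sorted(names, key=lambda n: -bundle.branch_events[n].age)
    tree = names[-1]
    for n in reversed(names[:-1]):
        tree = f"({n},{tree})"
    return tree + ";"


# ---------------------------------------------------------------------------
# recovery scoring


def _adjacencies(order_lists) -> set:
    out = set()
    for seq in order_lists:
        for a, b in zip(seq, seq[1:]):
            out.add(frozenset((a, b)))
    return out


def score_recovery(true_order: dict[str, list], cars: list[list],
                   car_assignment: dict | None = None,
                   true_chrom_of: dict | None = None,
                   subgenome_assignment: dict | None = None,
                   true_subgenome: dict | None = None) -> dict:
    """Score a reconstruction against the simulator's ground truth.

    ``true_order``: chromosome -> ordered family ids; ``cars``: reconstructed
    ordered family lists. Truth is projected onto the reconstructed families,
    so the metrics measure ordering quality of what was reconstructed.
    Returns adjacency recall/precision, mean per-CAR |rank correlation|, and
    (when assignments are provided) protochromosome and subgenome accuracy.
    """
    recon_fams = {f for car in cars for f in car}
    true_fams = {f for seq in true_order.values() for f in seq}
    if recon_fams and not (recon_fams & true_fams):
        raise ValueError("reconstruction and truth share no identifiers")
    projected = [
        [f for f in seq if f in recon_fams] for seq in true_order.values()
    ]
    true_adj = _adjacencies(projected)
    recon_adj = _adjacencies(cars)
    recall = len(true_adj & recon_adj) / len(true_adj) if true_adj else float("nan")
    precision = (len(true_adj & recon_adj) / len(recon_adj)
                 if recon_adj else float("nan"))

    true_pos: dict[str, tuple[str, int]] = {}
    for chrom, seq in true_order.items():
        for k, f in enumerate(seq):
            true_pos[f] = (chrom, k)
    rhos, weights = [], []
    for car in cars:
        placed = [f for f in car if f in true_pos]
        if len(placed) < 2:
            continue
        chroms = [true_pos[f][0] for f in placed]
        major = max(set(chroms), key=chroms.count)
        pos = [true_pos[f][1] for f in placed if true_pos[f][0] == major]
        if len(pos) >= 2 and len(set(pos)) >= 2:
            rho = stats.spearmanr(range(len(pos)), pos).statistic
            rhos.append(abs(rho))
            weights.append(len(pos))
    out = {
        "adjacency_recall": recall,
        "adjacency_precision": precision,
        "mean_car_rank_correlation": (
            float(np.average(rhos, weights=weights)) if rhos else float("nan")
        ),
        "n_cars": len(cars),
        "n_markers": len(recon_fams),
    }
    if car_assignment is not None and true_chrom_of is not None:
        hits = total = 0
        for ci, car in enumerate(cars):
            proto = car_assignment.get(ci)
            for f in car:
                if f in true_chrom_of:
                    total += 1
                    hits += int(proto == true_chrom_of[f])
        out["protochromosome_accuracy"] = hits / total if total else float("nan")
    if subgenome_assignment is not None and true_subgenome is not None:
        shared = set(subgenome_assignment) & set(true_subgenome)
        out["subgenome_accuracy"] = (
            sum(subgenome_assignment[b] == true_subgenome[b] for b in shared)
            / len(shared) if shared else float("nan")
        )
    return out
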