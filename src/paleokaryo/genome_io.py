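"""Data model and readers/writers for gene tables, homology tables, trees and ancestors.

Gene order is represented throughout in *rank space*: each gene carries a
0-based integer rank along its chromosome. Physical coordinates, when present
in a GFF3 input, are used only to derive ranks; all downstream reasoning is in
gene-order space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import Phylo

logger = logging.getLogger("paleokaryo")

GENE_TABLE_COLUMNS = ["genome", "chromosome", "rank", "strand", "gene", "family"]
ANCESTOR_COLUMNS = ["car_id", "position", "marker_id", "orientation", "linked_flag"]


@dataclass(frozen=True)
class Gene:
    """A gene placed on a chromosome, identified by id and gene family."""

    id: str
    family: str
    genome: str
    chromosome: str
    rank: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


class Genome:
    """A named set of chromosomes, each an ordered, stranded list of genes.

    ``ploidy_tag`` records ploidy relative to the shared paleohexaploidy
    (gamma): "1R" for genomes with no later WGD, "2R"/"3R" for genomes with
    one/two lineage-specific WGDs on top.
    """

    def __init__(self, name: str, genes: Iterable[Gene], ploidy_tag: str | None = None):
        self.name = name
        self.ploidy_tag = ploidy_tag
        self.chromosomes: dict[str, list[Gene]] = {}
        seen: set[str] = set()
        for g in genes:
            if g.genome != name:
                raise ValueError(f"gene {g.id} belongs to genome {g.genome!r}, not {name!r}")
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id!r} in genome {name!r}")
            seen.add(g.id)
            self.chromosomes.setdefault(g.chromosome, []).append(g)
        for chrom, genes_ in self.chromosomes.items():
            genes_.sort(key=lambda g: g.rank)
            ranks = [g.rank for g in genes_]
            if ranks != list(range(len(genes_))):
                raise ValueError(
                    f"ranks on {name}:{chrom} are not 0-based consecutive: {ranks[:5]}..."
                )
        self._index = {g.id: g for g in self.genes()}

    def genes(self) -> Iterable[Gene]:
        for chrom in self.chromosomes:
            yield from self.chromosomes[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __getitem__(self, gene_id: str) -> Gene:
        return self._index[gene_id]

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def families(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes():
            out.setdefault(g.family, []).append(g)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return (
            self.name == other.name
            and list(self.chromosomes) == list(other.chromosomes)
            and all(
                self.chromosomes[c] == other.chromosomes[c] for c in self.chromosomes
            )
        )

    def __repr__(self) -> str:
        return f"Genome({self.name!r}, {self.n_chromosomes} chromosomes, {len(self)} genes)"


class SpeciesTree:
    """Rooted species tree with genome names as leaves and optional WGD branch tags.

    Thin wrapper over ``Bio.Phylo``; WGD events (e.g. rho, alpha, beta, gamma)
    are attached to named clades via ``wgd_events``.
    """

    def __init__(self, tree, wgd_events: Mapping[str, str] | None = None):
        self.tree = tree
        self.wgd_events = dict(wgd_events or {})
        names = [t.name for t in tree.get_terminals()]
        if len(names) != len(set(names)):
            raise ValueError("genome names must be unique tree leaves")
        self.leaves = names

    @classmethod
    def from_newick(cls, source: str | Path, wgd_events=None) -> "SpeciesTree":
        p = Path(source)
        if p.exists():
            tree = Phylo.read(str(p), "newick")
        else:
            tree = Phylo.read(StringIO(str(source)), "newick")
        return cls(tree, wgd_events)

    def mrca(self, a: str, b: str):
        return self.tree.common_ancestor({"name": a}, {"name": b})

    def informative_pairs(self, ancestor_name: str) -> list[tuple[str, str]]:
        """Genome pairs whose most recent common ancestor is the named node."""
        node = next(
            (c for c in self.tree.find_clades() if c.name == ancestor_name), None
        )
        if node is None:
            raise KeyError(f"no node named {ancestor_name!r} in tree")
        kids = node.clades
        pairs = []
        leaves = sorted(self.leaves)
        for i, a in enumerate(leaves):
            for b in leaves[i + 1:]:
                if self.mrca(a, b) is node:
                    pairs.append((a, b))
        return pairs


@dataclass
class RunConfig:
    """Thresholds and paths for one reconstruction run."""

    cip_min: float = 60.0
    calp_min: float = 70.0
    dr: float = 2.0
    cl: int = 20
    mn: int = 5
    alpha: float = 0.005
    fdr: float = 0.05
    rate: float = 6.5e-9
    seed: int = 42
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("cip_min", "calp_min", "dr", "cl", "mn", "fdr", "rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in (
            "cip_min", "calp_min", "dr", "cl", "mn", "alpha", "fdr", "rate", "seed",
        )}
        data["paths"] = self.paths
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# gene tables


def _genes_from_records(records: pd.DataFrame) -> list[Genome]:
    genomes = []
    for gname, sub in records.groupby("genome", sort=True):
        genes = []
        for chrom, csub in sub.groupby("chromosome", sort=True):
            # recompute ranks from stated order; ties broken lexicographically
            csub = csub.sort_values(["rank", "gene"], kind="mergesort")
            dup = csub["rank"].duplicated()
            if dup.any():
                logger.warning(
                    "%s:%s: %d rank ties broken by lexicographic gene id",
                    gname, chrom, int(dup.sum()),
                )
            for new_rank, row in enumerate(csub.itertuples(index=False)):
                genes.append(Gene(
                    id=row.gene, family=row.family, genome=gname,
                    chromosome=chrom, rank=new_rank, strand=row.strand,
                ))
        genomes.append(Genome(gname, genes))
    return genomes


def read_gene_table(path: str | Path, format: str = "tsv",
                    family_attribute: str = "family",
                    genome_name: str | None = None) -> list[Genome]:
    """Read gene positions from a TSV gene table or a GFF3 of gene features.

    Ranks are recomputed from coordinate order (GFF3) or from the stated rank
    column (TSV); coordinate/rank ties are broken by lexicographic gene id
    with a logged warning. Returns one :class:`Genome` per distinct genome.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        df["rank"] = df["rank"].astype(int)
        df["strand"] = df["strand"].replace({".": "+", "?": "+"})
        return _genes_from_records(df)
    if format == "gff3":
        rows = _parse_gff3_genes(path, family_attribute, genome_name or path.stem)
        df = pd.DataFrame(rows, columns=["genome", "chromosome", "start", "strand",
                                         "gene", "family"])
        if df["gene"].duplicated().any():
            dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate gene ids in GFF3: {dups[:5]}")
        out = []
        for (gname, chrom), sub in df.groupby(["genome", "chromosome"], sort=True):
            sub = sub.sort_values(["start", "gene"], kind="mergesort")
            if sub["start"].duplicated().any():
                logger.warning("%s:%s: coordinate ties broken by gene id", gname, chrom)
            sub = sub.assign(rank=range(len(sub)))
            out.append(sub[GENE_TABLE_COLUMNS])
        return _genes_from_records(pd.concat(out, ignore_index=True))
    raise ValueError(f"unknown gene-table format {format!r}")


def _parse_gff3_genes(path: Path, family_attribute: str, genome_name: str):
    from gffutils.iterators import DataIterator

    rows = []
    for feat in DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        gid = feat.attributes.get("ID", [None])[0]
        if gid is None:
            raise ValueError(f"{path}: gene feature at {feat.seqid}:{feat.start} "
                             "without ID attribute")
        fam = feat.attributes.get(family_attribute, [None])[0]
        if fam is None:
            raise ValueError(
                f"{path}: gene {gid!r} missing {family_attribute!r} attribute"
            )
        strand = feat.strand
        if strand not in ("+", "-"):
            warnings.warn(f"gene {gid}: unknown strand {strand!r}, defaulting to '+'")
            strand = "+"
        rows.append((genome_name, feat.seqid, int(feat.start), strand, gid, fam))
    return rows


def write_gene_table(genomes: Sequence[Genome], path: str | Path) -> None:
    rows = [
        (g.genome, g.chromosome, g.rank, g.strand, g.id, g.family)
        for genome in genomes for g in genome.genes()
    ]
    df = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# homology pair tables


def read_pair_table(path: str | Path, genomes: Sequence[Genome] | None = None) -> pd.DataFrame:
    """Read a homology TSV with columns gene1, gene2 and optional cip/calp/ks.

    Pairs are canonicalized (gene1 < gene2 lexicographically), self-pairs are
    dropped with a logged count, duplicates are removed. If ``genomes`` is
    given, every gene id must resolve; unknown ids raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene1": str, "gene2": str})
    if not {"gene1", "gene2"} <= set(df.columns):
        raise ValueError("pair table needs gene1 and gene2 columns")
    n_self = int((df["gene1"] == df["gene2"]).sum())
    if n_self:
        logger.warning("dropped %d self-pairs", n_self)
        df = df[df["gene1"] != df["gene2"]]
    swap = df["gene1"] > df["gene2"]
    df.loc[swap, ["gene1", "gene2"]] = df.loc[swap, ["gene2", "gene1"]].values
    df = df.drop_duplicates(subset=["gene1", "gene2"]).reset_index(drop=True)
    if genomes is not None:
        known = set()
        for gm in genomes:
            known.update(g.id for g in gm.genes())
        unknown = sorted((set(df["gene1"]) | set(df["gene2"])) - known)
        if unknown:
            raise ValueError(f"pair table references unknown gene ids: {unknown[:10]}")
    return df


def write_pair_table(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ancestor (CAR) tables


def write_ancestor(cars: Sequence, path: str | Path) -> None:
    """Write ordered CARs as a TSV (car_id, position, marker_id, orientation, linked_flag)."""
    rows = []
    for car in cars:
        for pos, (marker, orient) in enumerate(zip(car.markers, car.orientations)):
            rows.append((car.id, pos, marker, orient, int(bool(car.linked))))
    pd.DataFrame(rows, columns=ANCESTOR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ancestor(path: str | Path):
    """Read back CARs written by :func:`write_ancestor` (order preserved)."""
    from .car_builder import CAR

    df = pd.read_csv(path, sep="\t", dtype={"car_id": str, "marker_id": str,
                                            "orientation": str})
    if df.empty:
        return []
    cars = []
    for car_id, sub in df.groupby("car_id", sort=False):
        sub = sub.sort_values("position")
        cars.append(CAR(
            id=str(car_id),
            markers=list(sub["marker_id"]),
            orientations=list(sub["orientation"]),
            linked=bool(sub["linked_flag"].iloc[0]),
        ))
    return cars
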