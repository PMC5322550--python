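import random

import pytest

from paleokaryo.car_builder import (
    CAR,
    MatrixRow,
    SandwichMatrix,
    anchor_cars,
    build_markers,
    build_sandwich_matrix,
    compute_adjacencies_and_intervals,
    order_c1p,
)
from paleokaryo.genome_io import Gene, Genome
from paleokaryo.pqtree import sandwich_satisfied
from paleokaryo.synth_evolve import score_recovery


def make_genome(name, chrom_orders, family_of=None):
    """chrom_orders: {chrom: [family ids]}; gene ids unique per genome."""
    genes = []
    for chrom, fams in chrom_orders.items():
        for rank, fam in enumerate(fams):
            genes.append(Gene(f"{name}.{chrom}.{rank}", fam, name, chrom, rank))
    return Genome(name, genes)


def pairs_from_families(genomes):
    import pandas as pd

    by_fam = {}
    for gm in genomes:
        for g in gm.genes():
            by_fam.setdefault(g.family, []).append(g.id)
    rows = []
    for fam, members in by_fam.items():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = sorted((members[i], members[j]))
                rows.append((a, b, 90.0, 90.0))
    return pd.DataFrame(rows, columns=["gene1", "gene2", "cip", "calp"])


class TestBuildMarkers:
    def test_one_to_one_family_becomes_marker(self):
        g1 = make_genome("Y", {"c1": ["f1", "f2"]})
        g2 = make_genome("Z", {"c1": ["f1", "f3"]})
        markers = build_markers(pairs_from_families([g1, g2]), [g1, g2],
                                [("Y", "Z")])
        assert [m.family for m in markers] == ["f1"]

    def test_single_genome_family_excluded(self):
        g1 = make_genome("Y", {"c1": ["f1", "f2"]})
        g2 = make_genome("Z", {"c1": ["f1", "f1x"]})
        markers = build_markers(pairs_from_families([g1, g2]), [g1, g2],
                                [("Y", "Z")])
        assert all(m.family != "f2" for m in markers)

    def test_copy_number_violation_excluded(self):
        g1 = make_genome("Y", {"c1": ["f1", "f1", "f2"], "c2": ["f2"]})
        g2 = make_genome("Z", {"c1": ["f1", "f1", "f2"]})
        markers = build_markers(pairs_from_families([g1, g2]), [g1, g2],
                                [("Y", "Z")], expected_copies=1)
        assert [m.family for m in markers] == []

    def test_no_informative_pair_is_an_error(self):
        g1 = make_genome("Y", {"c1": ["f1"]})
        with pytest.raises(ValueError):
            build_markers(pairs_from_families([g1]), [g1], [])


class TestAdjacenciesAndIntervals:
    def test_adjacency_requires_two_genomes(self):
        g1 = make_genome("Y", {"c1": ["f1", "f2", "f3"]})
        g2 = make_genome("Z", {"c1": ["f1", "f2", "f4"]})
        markers = build_markers(pairs_from_families([g1, g2]), [g1, g2],
                                [("Y", "Z")])
        adj, _ = compute_adjacencies_and_intervals([g1, g2], markers)
        assert [sorted(a.markers) for a in adj] == [["m:f1", "m:f2"]]
        assert adj[0].support == 2

    def test_interval_any_internal_order(self):
        # a-b-c in Y and c-a-b in Z: {a,b,c} contiguous in both (d elsewhere
        # in Z, so the whole-chromosome set is not common and {a,b,c} is
        # maximal)
        g1 = make_genome("Y", {"c1": ["a", "b", "c", "d"]})
        g2 = make_genome("Z", {"c1": ["c", "a", "b"], "c2": ["d"]})
        markers = build_markers(pairs_from_families([g1, g2]), [g1, g2],
                                [("Y", "Z")])
        _, intervals = compute_adjacencies_and_intervals([g1, g2], markers)
        sets = {tuple(sorted(ci.markers)) for ci in intervals}
        assert ("m:a", "m:b", "m:c") in sets

    def test_contiguity_ignores_non_marker_genes(self):
        # fx is private to Y and must not break the a-b adjacency
        g1 = make_genome("Y", {"c1": ["a", "fx", "b"]})
        g2 = make_genome("Z", {"c1": ["a", "b"]})
        markers = build_markers(pairs_from_families([g1, g2]), [g1, g2],
                                [("Y", "Z")])
        adj, _ = compute_adjacencies_and_intervals([g1, g2], markers)
        assert [sorted(a.markers) for a in adj] == [["m:a", "m:b"]]


class TestSandwichMatrix:
    def test_entry_rule(self):
        g1 = make_genome("Y", {"c1": ["a", "b"], "c2": ["c"]})
        g2 = make_genome("Z", {"c1": ["a", "b"], "c2": ["c"]})
        markers = build_markers(pairs_from_families([g1, g2]), [g1, g2],
                                [("Y", "Z")])
        adj, intervals = compute_adjacencies_and_intervals([g1, g2], markers)
        mat = build_sandwich_matrix(markers, intervals, adj, genomes=[g1, g2])
        row = next(r for r in mat.rows if r.ones == frozenset({"m:a", "m:b"}))
        # c is present in both genomes but outside the interval -> 0
        assert "m:c" in row.zeros

    def test_absent_marker_is_x(self):
        g1 = make_genome("Y", {"c1": ["a", "b"]})
        g2 = make_genome("Z", {"c1": ["a", "b"]})
        g3 = make_genome("W", {"c1": ["d", "a"]})
        markers = build_markers(
            pairs_from_families([g1, g2, g3]), [g1, g2, g3],
            [("Y", "Z"), ("Y", "W"), ("Z", "W")])
        adj, intervals = compute_adjacencies_and_intervals([g1, g2, g3], markers)
        mat = build_sandwich_matrix(markers, intervals, adj, genomes=[g1, g2, g3])
        # markers d exists only in W; rows supported by (Y, Z) must not zero it
        assert len(mat.columns) >= 2

    def test_no_intervals_empty_matrix(self):
        mat = build_sandwich_matrix([], [], [])
        assert mat.shape == (0, 0)


class TestOrderC1P:
    def row(self, ones, universe):
        ones = frozenset(ones)
        return MatrixRow(ones=ones, zeros=frozenset(universe) - ones, support=2)

    def test_chain_recovers_path_order(self):
        universe = list("abcd")
        rows = [self.row(p, universe) for p in ("ab", "bc", "cd")]
        res = order_c1p(SandwichMatrix(columns=universe, rows=rows))
        (car,) = res.cars
        assert car.markers in (list("abcd"), list("dcba"))
        assert not res.discarded_rows

    def test_single_pair_row_is_flagged_ambiguous(self):
        universe = ["a", "b"]
        res = order_c1p(SandwichMatrix(columns=universe,
                                       rows=[self.row("ab", universe)]))
        (car,) = res.cars
        assert sorted(car.markers) == ["a", "b"]
        assert car.order_ambiguous

    def test_empty_matrix_gives_no_cars(self):
        res = order_c1p(SandwichMatrix(columns=[], rows=[]))
        assert res.cars == []

    def test_markers_partition_into_cars_and_unplaced(self):
        universe = list("abcde")
        rows = [self.row("ab", universe), self.row("cd", universe)]
        res = order_c1p(SandwichMatrix(columns=universe, rows=rows))
        placed = [m for car in res.cars for m in car.markers]
        assert sorted(placed + res.unplaced_markers) == universe
        assert res.unplaced_markers == ["e"]

    @pytest.mark.parametrize("seed", range(10))
    def test_satisfied_rows_verified_by_direct_scan(self, seed):
        rng = random.Random(seed)
        universe = [f"m{i}" for i in range(rng.randint(4, 10))]
        rows = []
        for _ in range(rng.randint(2, 8)):
            k = rng.randint(2, len(universe))
            ones = frozenset(rng.sample(universe, k))
            zmax = len(universe) - k
            zeros = frozenset(rng.sample(sorted(set(universe) - ones),
                                         rng.randint(0, zmax)))
            rows.append(MatrixRow(ones=ones, zeros=zeros, support=1))
        res = order_c1p(SandwichMatrix(columns=universe, rows=rows))
        # ones of any row live inside one CAR, so the concatenated order is a
        # faithful check of the no-0-between-1s rule for every kept row
        order = [m for car in res.cars for m in car.markers] + res.unplaced_markers
        discarded = set(map(id, res.discarded_rows))
        for r in rows:
            if id(r) not in discarded:
                assert sandwich_satisfied(order, r.ones, r.zeros)


class TestAnchorCars:
    def test_majority_links(self):
        cars = [CAR("CAR1", list("abc"), ["+"] * 3)]
        out = anchor_cars(cars, {"a": "P1", "b": "P1", "c": "P2"})
        assert out[0].linked and out[0].protochromosome == "P1"

    def test_tie_unlinked(self):
        cars = [CAR("CAR1", list("ab"), ["+"] * 2)]
        out = anchor_cars(cars, {"a": "P1", "b": "P2"})
        assert not out[0].linked

    def test_empty_painting_all_unlinked(self):
        cars = [CAR("CAR1", list("ab"), ["+"] * 2)]
        out = anchor_cars(cars, {})
        assert not out[0].linked and out[0].protochromosome is None


def test_simulation_recovery_without_rearrangement(diploidized_bundle,
                                                   diploidized_orthologs):
    """Markers from two modern lineages reconstruct the ancestral order
    almost perfectly (small losses only shrink the marker set)."""
    bundle = diploidized_bundle
    gY, gZ = bundle.genomes["Y"], bundle.genomes["Z"]
    markers = build_markers(diploidized_orthologs, [gY, gZ], [("Y", "Z")])
    assert len(markers) > 400
    adj, intervals = compute_adjacencies_and_intervals([gY, gZ], markers)
    mat = build_sandwich_matrix(markers, intervals, adj, genomes=[gY, gZ])
    res = order_c1p(mat)
    orders = [[m.split(":")[1] for m in car.markers] for car in res.cars]
    metrics = score_recovery(bundle.post_wgd_order, orders)
    assert metrics["adjacency_precision"] == pytest.approx(1.0)
    assert metrics["adjacency_recall"] > 0.99
    assert metrics["mean_car_rank_correlation"] == pytest.approx(1.0)
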