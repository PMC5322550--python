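import pytest

from paleokaryo.synth_evolve import (
    BranchEvents,
    SimParams,
    emit_homology,
    evolve_lineage,
    simulate_two_step_hexaploidy,
)


@pytest.fixture(scope="session")
def noloss_bundle():
    """Hexaploid with no gene loss: every family keeps all three copies."""
    params = SimParams(n_anc=7, genes_per_chromosome=50, retention_a=1.0,
                       retention_b=1.0, retention_c=1.0, seed=42)
    return simulate_two_step_hexaploidy(params)


@pytest.fixture(scope="session")
def fractionated_bundle():
    """The two-step fractionation study scenario: pA=0.9, pB=0.4, pC=0.95."""
    params = SimParams(n_anc=7, genes_per_chromosome=200, seed=42)
    return simulate_two_step_hexaploidy(params)


@pytest.fixture(scope="session")
def lineage_bundle():
    """No-loss hexaploid plus one rearranged descendant with a lineage WGD."""
    params = SimParams(n_anc=7, genes_per_chromosome=60, retention_a=1.0,
                       retention_b=1.0, retention_c=1.0, seed=5)
    bundle = simulate_two_step_hexaploidy(params)
    evolve_lineage(bundle, "X", BranchEvents(
        age=5e7, wgd_age=1.1e7, wgd_retention=0.8,
        n_fissions=3, n_fusions=5, loss_rate=0.05), seed=9)
    evolve_lineage(bundle, "Y", BranchEvents(age=5e7), seed=7)
    return bundle


@pytest.fixture(scope="session")
def diploidized_bundle():
    """Largely rediploidized hexaploid with two modern lineages + orthologs.

    Subgenome A dominates so most families are single copy, giving 1:1
    markers for the speciation-ancestor reconstruction path.
    """
    params = SimParams(n_anc=7, genes_per_chromosome=100, retention_a=0.98,
                       retention_b=0.05, retention_c=0.05, seed=10)
    bundle = simulate_two_step_hexaploidy(params)
    evolve_lineage(bundle, "Y", BranchEvents(
        age=5e7, n_fusions=2, n_inversions=2, loss_rate=0.02), seed=11)
    evolve_lineage(bundle, "Z", BranchEvents(
        age=5e7, n_fissions=1, n_inversions=1, loss_rate=0.02), seed=12)
    return bundle


@pytest.fixture(scope="session")
def diploidized_orthologs(diploidized_bundle):
    pairs = emit_homology(diploidized_bundle, ["Y", "Z"], seed=13)
    return pairs[pairs.relation == "ortholog"]
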