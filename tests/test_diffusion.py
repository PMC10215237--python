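"""Random walk with restart: loading, transitions, profiles, ranking."""

import numpy as np
import pytest

from msnetpharm import (
    DiffusionConfig,
    MultiscaleNetwork,
    ParameterError,
    SchemaError,
    ValidationError,
    build_restart_vector,
    build_transition_matrix,
    compute_diffusion_profile,
    correlate_profiles,
    load_multiscale_network,
    rank_compounds,
    simulate_restarting_walk,
    solve_stationary_exact,
)
from msnetpharm.diffusion import DiffusionProfile, write_network_tsv
from msnetpharm.synthetic import write_fixture

from conftest import make_random_network


def _write_network(tmp_path, rows):
    path = tmp_path / "net.tsv"
    path.write_text("source\ttarget\tedge_class\n" + "".join(f"{s}\t{t}\t{c}\n" for s, t, c in rows))
    return path


# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------


def test_single_pp_row_expands_to_reciprocal_pair(tmp_path):
    net = load_multiscale_network(_write_network(tmp_path, [("A", "B", "pp")]))
    assert sorted(net.edges) == [("A", "B", "pp"), ("B", "A", "pp")]
    assert net.node_class == {"A": "protein", "B": "protein"}


def test_pf_and_ff_rows_expand_with_distinct_reverse_classes(tmp_path):
    net = load_multiscale_network(
        _write_network(tmp_path, [("A", "F1", "pf"), ("F1", "F2", "ff")])
    )
    assert ("A", "F1", "pf") in net.edges
    assert ("F1", "A", "fp") in net.edges
    assert ("F1", "F2", "ff_up") in net.edges
    assert ("F2", "F1", "ff_down") in net.edges


def test_conflicting_node_classes_raise_validation_error(tmp_path):
    # X is a protein by the pp row but a function by the pf row
    path = _write_network(tmp_path, [("A", "X", "pp"), ("B", "X", "pf")])
    with pytest.raises(ValidationError, match="X"):
        load_multiscale_network(path)


def test_unknown_edge_class_is_schema_error(tmp_path):
    with pytest.raises(SchemaError, match="xx"):
        load_multiscale_network(_write_network(tmp_path, [("A", "B", "xx")]))


def test_loaded_class_counts_match_generator_manifest(tmp_path, small_bundle):
    manifest = write_fixture(small_bundle, tmp_path / "fx")
    net = load_multiscale_network(tmp_path / "fx" / "network.tsv")
    assert net.edge_class_counts() == manifest["edge_class_counts"]


def test_network_tsv_round_trip_is_byte_identical(tmp_path, small_bundle):
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_network_tsv(small_bundle.network, p1)
    write_network_tsv(load_multiscale_network(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# restart vectors and transition matrices
# ---------------------------------------------------------------------------


def test_restart_vector_uniform_over_mapped_ids(two_node_network):
    rv = build_restart_vector(two_node_network, {"A", "B"})
    assert rv.entries == {"A": 0.5, "B": 0.5}
    rv = build_restart_vector(two_node_network, {"A", "X"})
    assert rv.entries == {"A": 1.0}
    with pytest.raises(ValidationError, match="anchor"):
        build_restart_vector(two_node_network, {"X", "Y"})


def test_transition_probabilities_follow_edge_class_weights():
    # node A has out-edges: two pp and one pf; weights pp=1, pf=2
    net = MultiscaleNetwork.from_raw(
        [("A", "B", "pp"), ("A", "C", "pp"), ("A", "F1", "pf")]
    )
    weights = {"pp": 1.0, "pf": 2.0, "fp": 1.0, "ff_up": 1.0, "ff_down": 1.0}
    tm = build_transition_matrix(net, weights)
    i = net.index["A"]
    row = tm.matrix[i].toarray().ravel()
    assert row[net.index["B"]] == pytest.approx(0.25)
    assert row[net.index["C"]] == pytest.approx(0.25)
    assert row[net.index["F1"]] == pytest.approx(0.5)


def test_equal_weights_give_uniform_out_neighbor_steps(small_bundle):
    tm = build_transition_matrix(small_bundle.network)
    w = tm.matrix
    rowsums = np.asarray(w.sum(axis=1)).ravel()
    assert np.allclose(rowsums[~tm.dangling], 1.0)
    for i in range(min(10, len(rowsums))):
        row = w[i].toarray().ravel()
        nz = row[row > 0]
        assert np.allclose(nz, nz[0])


def test_nonpositive_weight_is_config_error(two_node_network):
    with pytest.raises(ParameterError):
        build_transition_matrix(two_node_network, {"pp": 0.0})
    with pytest.raises(ParameterError):
        DiffusionConfig(edge_class_weights={"pp": -1.0})


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def test_c_zero_profile_equals_restart_vector(two_node_network):
    rv = build_restart_vector(two_node_network, {"A"})
    config = DiffusionConfig(continue_prob=0.0)
    prof = compute_diffusion_profile(two_node_network, rv, config)
    assert prof.visit_frequency == {"A": 1.0, "B": 0.0}
    exact = solve_stationary_exact(two_node_network, rv, config)
    assert exact.visit_frequency["A"] == pytest.approx(1.0)


def test_two_node_closed_form(two_node_network):
    rv = build_restart_vector(two_node_network, {"A"})
    config = DiffusionConfig(continue_prob=0.5, tolerance=1e-14)
    prof = compute_diffusion_profile(two_node_network, rv, config)
    assert prof.visit_frequency["A"] == pytest.approx(2 / 3, abs=1e-12)
    assert prof.visit_frequency["B"] == pytest.approx(1 / 3, abs=1e-12)


def test_uniform_restart_on_regular_graph_stays_uniform():
    # 4-cycle of proteins: degree-regular, single edge class
    net = MultiscaleNetwork.from_raw(
        [("A", "B", "pp"), ("B", "C", "pp"), ("C", "D", "pp"), ("D", "A", "pp")]
    )
    rv = build_restart_vector(net, {"A", "B", "C", "D"})
    prof = compute_diffusion_profile(net, rv, DiffusionConfig(tolerance=1e-12))
    assert np.allclose(prof.frequencies, 0.25, atol=1e-9)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_profiles_are_normalized_and_nonnegative(seed):
    net = make_random_network(seed)
    rv = build_restart_vector(net, set(net.proteins[:5]))
    prof = compute_diffusion_profile(net, rv)
    assert prof.converged
    assert prof.frequencies.min() >= 0
    assert prof.frequencies.sum() == pytest.approx(1.0, abs=1e-9)


def test_power_iteration_matches_direct_solve_on_random_fixtures():
    config = DiffusionConfig(tolerance=1e-13)
    for seed in range(3):
        net = make_random_network(seed)
        rv = build_restart_vector(net, set(net.proteins[:4]))
        power = compute_diffusion_profile(net, rv, config)
        exact = solve_stationary_exact(net, rv, config)
        assert np.abs(power.frequencies - exact.frequencies).max() < 1e-8


def test_delta_trace_contracts_geometrically():
    net = make_random_network(4)
    rv = build_restart_vector(net, set(net.proteins[:4]))
    config = DiffusionConfig(continue_prob=0.85, tolerance=1e-10)
    prof = compute_diffusion_profile(net, rv, config)
    ratios = [b / a for a, b in zip(prof.delta_trace, prof.delta_trace[1:]) if a > 1e-14]
    assert max(ratios) <= config.continue_prob + 1e-9


def test_small_c_profile_stays_near_restart_vector():
    net = make_random_network(5)
    rv = build_restart_vector(net, set(net.proteins[:4]))
    c = 0.01
    prof = compute_diffusion_profile(net, rv, DiffusionConfig(continue_prob=c, tolerance=1e-12))
    s = np.zeros(net.n_nodes)
    for node, p in rv.entries.items():
        s[net.index[node]] = p
    assert np.abs(prof.frequencies - s).sum() <= 2 * c / (1 - c) + 1e-9


def test_walker_simulation_agrees_with_exact_solution():
    net = make_random_network(11, n_proteins=40, n_functions=8)
    rv = build_restart_vector(net, set(net.proteins[:3]))
    config = DiffusionConfig(tolerance=1e-12)
    exact = solve_stationary_exact(net, rv, config)
    rng = np.random.default_rng(5)
    blocks = np.array([
        simulate_restarting_walk(net, rv, config, n_steps=10_000, rng=rng)
        for _ in range(30)
    ])
    mean = blocks.mean(axis=0)
    se = blocks.std(axis=0, ddof=1) / np.sqrt(len(blocks))
    z = np.abs(mean - exact.frequencies) / np.maximum(se, 1e-9)
    assert z.max() < 4.0  # seeded; 3 SE nominal with finite-block slack


def test_non_convergence_sets_flag():
    net = make_random_network(6)
    rv = build_restart_vector(net, set(net.proteins[:4]))
    prof = compute_diffusion_profile(
        net, rv, DiffusionConfig(tolerance=1e-15, max_iterations=3)
    )
    assert not prof.converged
    assert prof.iterations_used == 3


def test_dangling_mass_teleports_to_restart(tmp_path):
    # isolated-output node: make a function with only incoming edges by
    # giving class weights that exist; simplest dangling case is a network
    # whose node has out-edges removed -- construct directly.
    net = MultiscaleNetwork(
        node_class={"A": "protein", "B": "protein"},
        edges=[("A", "B", "pp")],  # B has no out-edge: dangling
    )
    tm = build_transition_matrix(net)
    assert tm.dangling[net.index["B"]]
    rv = build_restart_vector(net, {"A"})
    prof = compute_diffusion_profile(net, rv, DiffusionConfig(tolerance=1e-12))
    assert prof.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
    exact = solve_stationary_exact(net, rv, DiffusionConfig())
    assert np.abs(prof.frequencies - exact.frequencies).max() < 1e-8


# ---------------------------------------------------------------------------
# correlation and ranking
# ---------------------------------------------------------------------------


def _profile(values, entity="x"):
    nodes = tuple(f"n{i}" for i in range(len(values)))
    return DiffusionProfile(nodes=nodes, frequencies=np.array(values), entity=entity)


def test_self_correlation_is_one():
    p = _profile([0.5, 0.3, 0.2])
    assert correlate_profiles(p, p) == pytest.approx(1.0)


def test_correlation_matches_direct_pearson():
    a = _profile([0.5, 0.3, 0.2], "a")
    b = _profile([0.2, 0.3, 0.5], "b")
    assert correlate_profiles(a, b) == pytest.approx(-0.928571, abs=1e-4)


def test_zero_variance_profile_is_an_error():
    a = _profile([0.5, 0.3, 0.2], "a")
    flat = _profile([1 / 3] * 3, "uniform")
    with pytest.raises(ValidationError, match="uniform"):
        correlate_profiles(a, flat)


def test_rank_compounds_orders_by_correlation_then_id():
    disease = _profile([0.6, 0.3, 0.1], "disease")
    profiles = {
        "cB": _profile([0.6, 0.3, 0.1], "cB"),
        "cA": _profile([0.59, 0.31, 0.1], "cA"),
        "cC": _profile([0.1, 0.3, 0.6], "cC"),
    }
    ranked = rank_compounds(profiles, disease)
    assert list(ranked["compound"]) == ["cB", "cA", "cC"]
    assert list(ranked["rank"]) == [1, 2, 3]


def test_rank_single_compound_is_rank_one():
    disease = _profile([0.6, 0.3, 0.1], "disease")
    ranked = rank_compounds({"only": _profile([0.5, 0.4, 0.1], "only")}, disease)
    assert len(ranked) == 1 and ranked["rank"].iloc[0] == 1
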