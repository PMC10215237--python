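"""Generator properties: determinism, composition, planted signal, round-trips."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from msnetpharm import (
    ParameterError,
    SyntheticScenario,
    generate_bundle,
    generate_disease,
    generate_multiscale_network,
    generate_pathway_library,
    load_fixture,
    write_fixture,
)
from msnetpharm.diffusion import PROTEIN


def _edge_hash(network):
    payload = "\n".join("\t".join(e) for e in sorted(network.raw_edges))
    return hashlib.sha256(payload.encode()).hexdigest()


def test_network_generation_is_seed_deterministic():
    sc = SyntheticScenario(seed=7)
    a = generate_multiscale_network(sc)
    b = generate_multiscale_network(sc)
    assert _edge_hash(a) == _edge_hash(b)
    assert a.node_class == b.node_class


def test_network_node_class_counts_are_exact():
    net = generate_multiscale_network(SyntheticScenario(seed=7))
    assert len(net.proteins) == 200
    assert len(net.functions) == 50


def test_scaled_composition_hits_requested_class_ratios():
    # protein:function and pp:pf:ff edge counts mimicking a large multiscale
    # interactome scaled down by ~1/100
    sc = SyntheticScenario(
        n_proteins=177,
        n_functions=98,
        ppi_edges=3876,
        annotation_rate=347.77 / 177,
        ff_edges=225,
        n_disease_proteins=20,
        seed=3,
    )
    net = generate_multiscale_network(sc)
    counts = net.edge_class_counts()
    realized = {
        "pp": counts["pp"] // 2,
        "pf": counts["pf"],
        "ff": counts["ff_up"],
    }
    requested = {"pp": 3876, "pf": 348, "ff": 225}
    for ec, want in requested.items():
        assert abs(realized[ec] - want) / want <= 0.10, (ec, realized[ec], want)


def test_ppi_edge_count_beyond_capacity_rejected():
    with pytest.raises(ParameterError):
        SyntheticScenario(n_proteins=10, ppi_edges=100, n_functions=5,
                          targets_per_compound=(1, 5), n_disease_proteins=3,
                          pathway_size_range=(2, 5))


def test_every_node_has_an_incident_edge(default_bundle):
    net = default_bundle.network
    touched = set()
    for s, t, _ in net.edges:
        touched.add(s)
        touched.add(t)
    assert touched == set(net.node_class)


def test_compound_sizes_stay_in_requested_range(default_bundle):
    table = default_bundle.compounds
    lo, hi = default_bundle.scenario.targets_per_compound
    for cid in table.compounds:
        assert lo <= len(table.targets_of(cid)) <= hi


def test_planted_targets_fall_in_disease_neighborhood(default_bundle):
    net = default_bundle.network
    disease = default_bundle.disease.ids
    neighbors = {
        t for s, t, ec in net.edges if ec == "pp" and s in disease
    }
    pool = disease | neighbors
    for cid in default_bundle.truth["planted"]:
        assert default_bundle.compounds.targets_of(cid) <= pool


def test_decoy_targets_avoid_disease_when_possible(default_bundle):
    for cid in default_bundle.truth["decoys"]:
        assert not (default_bundle.compounds.targets_of(cid) & default_bundle.disease.ids)


def test_disease_size_91_on_200_protein_network():
    sc = SyntheticScenario(n_disease_proteins=91, seed=5)
    net = generate_multiscale_network(sc)
    disease = generate_disease(net, sc)
    assert len(disease.ids) == 91
    assert all(net.node_class[p] == PROTEIN for p in disease.ids)


def test_disease_of_size_one_is_the_seed_node():
    sc = SyntheticScenario(n_disease_proteins=1, seed=5)
    net = generate_multiscale_network(sc)
    disease = generate_disease(net, sc)
    assert len(disease.ids) == 1


def test_disease_draws_differ_across_seeds():
    sets = set()
    for seed in range(20):
        sc = SyntheticScenario(n_disease_proteins=20, seed=seed)
        net = generate_multiscale_network(sc)
        sets.add(frozenset(generate_disease(net, sc).ids))
    assert len(sets) >= 18


def test_pathway_library_shape(default_bundle):
    sets = default_bundle.pathways.sets
    assert len(sets) == 9
    lo, hi = default_bundle.scenario.pathway_size_range
    for members in sets.values():
        assert lo <= len(members) <= hi


def test_pathway_library_deterministic_under_seed():
    sc = SyntheticScenario(seed=13)
    net = generate_multiscale_network(sc)
    a = generate_pathway_library(net, sc)
    b = generate_pathway_library(net, sc)
    assert a.sets == b.sets


def test_referential_closure(default_bundle):
    proteins = set(default_bundle.network.proteins)
    assert set(default_bundle.compounds.targets) <= proteins
    assert default_bundle.disease.ids <= proteins
    for members in default_bundle.pathways.sets.values():
        assert members <= proteins
    assert set(default_bundle.truth["planted"]) <= set(default_bundle.compounds.compounds)


def test_fixture_round_trip(tmp_path, small_bundle):
    manifest = write_fixture(small_bundle, tmp_path / "fx")
    reloaded = load_fixture(tmp_path / "fx")
    assert reloaded.network.node_class == small_bundle.network.node_class
    assert sorted(reloaded.network.edges) == sorted(small_bundle.network.edges)
    assert reloaded.compounds.records == sorted(small_bundle.compounds.records)
    assert reloaded.disease.ids == small_bundle.disease.ids
    assert reloaded.pathways.sets == small_bundle.pathways.sets
    assert reloaded.truth == small_bundle.truth
    # rewriting the reloaded bundle is byte-identical
    write_fixture(reloaded, tmp_path / "fx2")
    for name in ("network.tsv", "compounds.tsv", "disease.txt", "pathways.gmt", "truth.json"):
        assert (tmp_path / "fx" / name).read_bytes() == (tmp_path / "fx2" / name).read_bytes()
    assert manifest["n_cpis"] == len(small_bundle.compounds.records)


def test_fixture_creates_directory_on_demand(tmp_path, small_bundle):
    target = tmp_path / "deep" / "nested" / "dir"
    write_fixture(small_bundle, target)
    assert (target / "manifest.json").exists()


def test_fixture_unwritable_path_reports_path(small_bundle):
    bad = Path("/proc/definitely-unwritable/fixture")
    with pytest.raises(OSError, match="definitely-unwritable"):
        write_fixture(small_bundle, bad)


def test_identical_scenarios_produce_identical_bundles(tmp_path):
    sc = SyntheticScenario(seed=21)
    for sub in ("a", "b"):
        write_fixture(generate_bundle(sc), tmp_path / sub)
    digests = []
    for sub in ("a", "b"):
        h = hashlib.sha256()
        for name in ("network.tsv", "compounds.tsv", "disease.txt", "pathways.gmt", "truth.json"):
            h.update((tmp_path / sub / name).read_bytes())
        digests.append(h.hexdigest())
    assert digests[0] == digests[1]


def test_planted_signal_exceeds_decoys_across_seeds():
    """With planted_overlap_fraction >= 0.5 the planted compound overlaps the
    disease neighborhood more than decoys do, on average over 20 seeds."""
    planted_avgs, decoy_avgs = [], []
    for seed in range(20):
        sc = SyntheticScenario(planted_overlap_fraction=0.5, seed=seed)
        bundle = generate_bundle(sc)
        net, disease = bundle.network, bundle.disease.ids
        pool = disease | {t for s, t, ec in net.edges if ec == "pp" and s in disease}

        def frac(cid):
            targets = bundle.compounds.targets_of(cid)
            return len(targets & pool) / len(targets)

        planted_avgs.append(np.mean([frac(c) for c in bundle.truth["planted"]]))
        decoy_avgs.append(np.mean([frac(c) for c in bundle.truth["decoys"]]))
    assert np.mean(planted_avgs) > np.mean(decoy_avgs)
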