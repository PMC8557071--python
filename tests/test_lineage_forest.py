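import networkx as nx
import numpy as np
import pytest

from scmovie import (
    CellList,
    SimulationConfig,
    add_branch,
    build_fdt,
    build_flt,
    cell_life_table,
    corrupt_tracking,
    extract_branch,
    simulate_movie,
)
from scmovie.lineage_forest import MASTER, instance_key, is_synthetic

from conftest import binary_movie, make_cell


def forests_equal(a, b):
    """Node-set, edge-set, and attribute equality of two forests."""
    if set(a.graph.nodes) != set(b.graph.nodes):
        return False
    if set(a.graph.edges) != set(b.graph.edges):
        return False
    return all(a.graph.nodes[n] == b.graph.nodes[n] for n in a.graph.nodes)


def test_single_cell_chain():
    cells = CellList(frame_period=5.0, n_frames=5, cells=[make_cell("a", range(1, 6))])
    flt = build_flt(cells)
    # 5 instances + master + 1 colony root
    assert flt.graph.number_of_nodes() == 7
    assert flt.colony_ids == ["colony_1"]
    for f in range(1, 6):
        assert flt.level(instance_key("a", f)) == f + 2
    assert nx.is_arborescence(flt.graph)


def test_division_edges_and_generations():
    cells = CellList(
        frame_period=5.0,
        n_frames=7,
        cells=[
            make_cell("m", [1, 2, 3]),
            make_cell("d1", [4, 5, 6, 7], mother="m"),
            make_cell("d2", [4, 5, 6, 7], mother="m"),
        ],
    )
    flt = build_flt(cells)
    last = instance_key("m", 3)
    assert set(flt.graph.successors(last)) == {instance_key("d1", 4), instance_key("d2", 4)}
    assert flt.graph.nodes[instance_key("d1", 5)]["generation"] == 1
    assert flt.graph.nodes[instance_key("m", 2)]["generation"] == 0
    assert flt.daughters("m") == ["d1", "d2"]
    assert flt.mother("d2") == "m"


def test_node_count_invariant(sim_movie, sim_forest):
    cells, _ = sim_movie
    flt, _ = sim_forest
    expected = sum(r.lifespan for r in cells.cells) + 1 + len(flt.colony_ids)
    assert flt.graph.number_of_nodes() == expected
    assert len(flt.motherless_store) == 0


def test_level_frame_convention(sim_forest):
    flt, fdt = sim_forest
    for n in flt.graph.nodes:
        if not is_synthetic(n):
            assert flt.level(n) - 2 == flt.graph.nodes[n]["frame"]
    for n in fdt.graph.nodes:
        if not is_synthetic(n):
            assert fdt.level(n) - 3 == fdt.graph.nodes[n]["generation"]


def test_colony_label_inherited_from_progenitor():
    # daughter tagged with a different colony id by the tracker still
    # inherits the progenitor's colony
    cells = CellList(
        frame_period=1.0,
        n_frames=4,
        cells=[
            make_cell("m", [1, 2], colony="colony_A"),
            make_cell("d", [3, 4], mother="m", colony="colony_B"),
        ],
    )
    flt = build_flt(cells)
    assert flt.graph.nodes[instance_key("d", 4)]["colony"] == "colony_A"


def test_fdt_binary_enumeration():
    # complete binary division to generation 2: 2^3 - 1 = 7 cells/colony
    flt = build_flt(binary_movie(generations=2, n_colonies=2))
    fdt = build_fdt(flt)
    assert fdt.n_cells() == 14
    per_gen = {}
    for c in fdt.cell_nodes():
        per_gen[fdt.graph.nodes[c]["generation"]] = per_gen.get(
            fdt.graph.nodes[c]["generation"], 0
        ) + 1
    assert per_gen == {0: 2, 1: 4, 2: 8}
    # lifespans tile the instance count
    total = sum(fdt.graph.nodes[c]["lifespan_frames"] for c in fdt.cell_nodes())
    assert total == flt.n_instances()


def test_fdt_min_life_filter():
    cells = CellList(
        frame_period=1.0,
        n_frames=10,
        cells=[make_cell("short", [1, 2, 3]), make_cell("long", range(1, 9), colony="colony_2")],
    )
    fdt = build_fdt(build_flt(cells), min_life_frames=5)
    assert fdt.cell_nodes() == ["long"]
    with pytest.raises(ValueError):
        build_fdt(build_flt(cells), min_life_frames=0)


def test_fdt_require_complete_drops_leaf_trajectories():
    flt = build_flt(binary_movie(generations=2))
    fdt = build_fdt(flt, require_complete=True)
    # last generation never divides -> only generations 0 and 1 remain
    gens = {fdt.graph.nodes[c]["generation"] for c in fdt.cell_nodes()}
    assert gens == {0, 1}
    assert fdt.n_cells() == 3


def test_fdt_exclusion_cascades_to_descendants():
    cells = CellList(
        frame_period=1.0,
        n_frames=8,
        cells=[
            make_cell("m", [1, 2]),  # too short
            make_cell("d1", range(3, 9), mother="m"),
            make_cell("d2", range(3, 9), mother="m"),
        ],
    )
    fdt = build_fdt(build_flt(cells), min_life_frames=3)
    assert fdt.cell_nodes() == []
    assert sorted(fdt.orphaned) == ["d1", "d2"]


def test_corruption_fills_motherless_store(sim_movie):
    cells, _ = sim_movie
    bad, log = corrupt_tracking(cells, 3, seed=7)
    flt = build_flt(bad)
    assert len(flt.motherless_store) == 3
    lost = {e["daughter"] for e in log.lost_links}
    assert {b.root_cell_id for b in flt.motherless_store} == lost


def test_extract_leaf_and_subtree():
    flt = build_flt(binary_movie(generations=1))
    n_before = flt.graph.number_of_nodes()
    leaf = instance_key("c1.1", 6)
    flt, branch = extract_branch(flt, leaf)
    assert branch.size() == 1
    assert flt.graph.number_of_nodes() == n_before - 1
    # extracting a daughter's first instance moves the whole remaining subtree
    flt, branch2 = extract_branch(flt, instance_key("c1.2", 4))
    assert branch2.size() == 3
    assert len(flt.motherless_store) == 2


def test_surgery_roundtrip_identity(sim_forest):
    flt = sim_forest[0].copy()
    original = flt.copy()
    rng = np.random.default_rng(3)
    nodes = sorted(flt.instance_nodes())
    for i in rng.choice(len(nodes), size=25, replace=False):
        node = nodes[i]
        preds = [p for p in flt.graph.predecessors(node) if not is_synthetic(p)]
        if not preds:
            continue
        flt, branch = extract_branch(flt, node)
        add_branch(flt, branch, preds[0])
    assert forests_equal(flt, original)
    assert len(flt.motherless_store) == 0


def test_add_branch_errors():
    flt = build_flt(binary_movie(generations=1))
    flt, branch = extract_branch(flt, instance_key("c1.1", 4))
    with pytest.raises(ValueError, match="frame"):
        add_branch(flt, branch, instance_key("c1", 2))  # root frame 4 needs target frame 3
    with pytest.raises(KeyError):
        add_branch(flt, branch, MASTER)
    flt2 = build_flt(binary_movie(generations=1))
    flt2, b2 = extract_branch(flt2, instance_key("c1.2", 4))
    with pytest.raises(ValueError, match="cycle|inside"):
        add_branch(flt2, b2, instance_key("c1.2", 5))


def test_add_branch_recovers_division():
    """Gluing an orphan under the mother's last instance restores the division."""
    cells, _ = simulate_movie(SimulationConfig(seed=4, n_progenitors=2, n_frames=50))
    bad, log = corrupt_tracking(cells, 1, seed=1)
    flt = build_flt(bad)
    entry = log.lost_links[0]
    branch = flt.motherless_store[0]
    target = flt.last_instance(entry["true_mother"])
    add_branch(flt, branch, target)
    assert flt.graph.out_degree(target) == 2
    clean = build_flt(cells)
    assert forests_equal(flt, clean)
    fdt = build_fdt(flt)
    assert entry["daughter"] in fdt.daughters(entry["true_mother"])


def test_cell_life_table():
    flt = build_flt(binary_movie(generations=1, frames_per_gen=5))
    table = cell_life_table(flt, "c1")
    assert len(table) == 5
    assert table.iloc[0].is_birth and not table.iloc[0].is_division
    assert table.iloc[-1].is_division
    assert table.attrs["daughters"] == ["c1.1", "c1.2"]
    assert table.attrs["mother"] is None and not table.attrs["motherless"]
    with pytest.raises(KeyError):
        cell_life_table(flt, "nope")


def test_cell_life_table_flags_motherless(sim_movie):
    cells, _ = sim_movie
    bad, log = corrupt_tracking(cells, 1, seed=2)
    flt = build_flt(bad)
    table = cell_life_table(flt, log.lost_links[0]["daughter"])
    assert table.attrs["motherless"]
    assert table.attrs["mother"] is None


def test_merged_corruption_shows_length_drop(sim_movie):
    """A fused mother+daughter track drops in length at the missed division."""
    cells, _ = sim_movie
    bad, log = corrupt_tracking(cells, 1, seed=3, mode="merged")
    entry = log.lost_links[0]
    flt = build_flt(bad)
    table = cell_life_table(flt, entry["true_mother"])
    lengths = table["length"].to_numpy()
    drops = np.diff(lengths) / lengths[:-1]
    assert drops.min() < -0.25  # roughly halves at the division frame
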