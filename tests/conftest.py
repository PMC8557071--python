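import pytest

from scmovie import (
    CellList,
    CellRecord,
    SimulationConfig,
    build_fdt,
    build_flt,
    simulate_movie,
)


def make_cell(cell_id, frames, mother=None, colony="colony_1", length=None, **bools):
    """Hand-built cell record with an optional length series."""
    if length is None:
        length = [1.0 + 0.1 * i for i in range(len(frames))]
    return CellRecord(
        cell_id=cell_id,
        colony_id=colony,
        mother_id=mother,
        frames=list(frames),
        numeric_attrs={"length": list(length)},
        boolean_attrs={k: list(v) for k, v in bools.items()},
    )


def binary_movie(generations=2, frames_per_gen=3, frame_period=5.0, n_colonies=1):
    """Complete synchronous binary-division movie.

    Every cell lives exactly ``frames_per_gen`` frames and splits in two;
    the last generation runs to the movie end without dividing.
    """
    cells = []
    n_frames = frames_per_gen * (generations + 1)
    for c in range(1, n_colonies + 1):
        colony = f"colony_{c}"
        roots = [(f"c{c}", None, 0)]
        for cell_id, mother, gen in roots:
            first = gen * frames_per_gen + 1
            frames = list(range(first, first + frames_per_gen))
            cells.append(make_cell(cell_id, frames, mother=mother, colony=colony))
            if gen < generations:
                for d in (1, 2):
                    roots.append((f"{cell_id}.{d}", cell_id, gen + 1))
    return CellList(frame_period=frame_period, n_frames=n_frames, cells=cells)


@pytest.fixture(scope="session")
def sim_movie():
    """Small clean simulated movie used across the suite."""
    cells, truth = simulate_movie(SimulationConfig(seed=11, n_progenitors=3, n_frames=60))
    return cells, truth


@pytest.fixture(scope="session")
def sim_forest(sim_movie):
    cells, _ = sim_movie
    flt = build_flt(cells)
    fdt = build_fdt(flt)
    return flt, fdt
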