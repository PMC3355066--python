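"""Shared fixtures: small synthetic arrays reused across the suite."""

import numpy as np
import pytest

import mechinverse as mi


@pytest.fixture(scope="session")
def hex64():
    """Regular hexagonal lattice, 64 cells on a torus."""
    return mi.hexagonal_lattice(8, 8)


@pytest.fixture(scope="session")
def tissue64():
    """Relaxed random-tension tissue (64 cells) with its true state."""
    cfg = mi.SimulationConfig(n_cells=64, seed=3)
    return mi.generate_voronoi_tissue(cfg)


@pytest.fixture(scope="session")
def tissue400():
    """Benchmark-sized tissue (400 cells), shared across expensive tests."""
    cfg = mi.SimulationConfig(n_cells=400, seed=1)
    return mi.generate_voronoi_tissue(cfg)


@pytest.fixture(scope="session")
def closed24():
    """Random closed planar array of 24 cells (threefold vertices)."""
    return mi.generate_planar_array(24, seed=5, topology_kind="closed")


@pytest.fixture(scope="session")
def open24():
    """The same tiling treated as an open field-of-view patch."""
    return mi.generate_planar_array(24, seed=5, topology_kind="open")


def two_triangle_dict():
    """Smallest two-cell tiling: two triangles sharing one edge (open)."""
    return {
        "topology": "open",
        "box": None,
        "vertices": [
            {"id": 0, "x": 0.0, "y": 0.0},
            {"id": 1, "x": 1.0, "y": 0.0},
            {"id": 2, "x": 0.5, "y": 1.0},
            {"id": 3, "x": 0.5, "y": -1.0},
        ],
        "edges": [
            {"id": 0, "v1": 0, "v2": 1, "cell_left": 0, "cell_right": 1,
             "curvature": None},
            {"id": 1, "v1": 1, "v2": 2, "cell_left": 0, "cell_right": -1,
             "curvature": None},
            {"id": 2, "v1": 2, "v2": 0, "cell_left": 0, "cell_right": -1,
             "curvature": None},
            {"id": 3, "v1": 0, "v2": 3, "cell_left": 1, "cell_right": -1,
             "curvature": None},
            {"id": 4, "v1": 3, "v2": 1, "cell_left": 1, "cell_right": -1,
             "curvature": None},
        ],
        "cells": [
            {"id": 0, "vertices": [0, 1, 2], "boundary": True, "label": None},
            {"id": 1, "vertices": [0, 3, 1], "boundary": True, "label": None},
        ],
    }
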