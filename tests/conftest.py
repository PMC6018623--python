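"""Shared fixtures: small synthetic worlds reused across test modules."""

import numpy as np
import pytest

import lesionlab as ll


@pytest.fixture(scope="session")
def small_grid():
    """16^3 grid, 2 mm isotropic, spherical brain mask (~900 voxels)."""
    shape = (16, 16, 16)
    return ll.make_grid(shape, 2.0, brain_mask=ll.spherical_mask(shape, 6))


@pytest.fixture(scope="session")
def tree_world():
    """A 24^3 structured-lesion cohort with its vascular tree (200 lesions)."""
    shape = (24, 24, 24)
    grid = ll.make_grid(shape, 2.0, brain_mask=ll.spherical_mask(shape, 9))
    cfg = ll.LesionGeneratorConfig(mode="tree_structured", n_lesions=200, seed=42)
    tree = ll.grow_vascular_tree(grid, cfg)
    stack = ll.generate_lesions(grid, cfg, tree=tree)
    return grid, cfg, tree, stack


@pytest.fixture(scope="session")
def uniform_cohort(small_grid):
    """Dense uniform single-voxel cohort on the small grid."""
    cfg = ll.LesionGeneratorConfig(
        mode="uniform_single_voxel", n_lesions=6000, seed=7
    )
    return ll.generate_lesions(small_grid, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
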