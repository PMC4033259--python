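"""Shared fixtures: small synthetic phantoms and DICOM trees.

Heavy artifacts (segmentable phantoms, emitted DICOM trees) are built once
per session; tests that mutate files copy what they need into tmp_path.
"""

import numpy as np
import pytest

from scanshare.dicom_io import VolumeStack
from scanshare.synthgen import (PhantomSpec, SIX_DIRECTIONS, generate,
                                make_structural_phantom)

# A small but fully segmentable structural phantom (defaults scaled down).
SMALL_STRUCT = dict(kind="structural", shape=(48, 48, 36),
                    brain_axes=(14.0, 14.0, 11.0))


@pytest.fixture(scope="session")
def struct_phantom():
    """(VolumeStack, ground-truth masks, truth dict) for the default
    structural phantom."""
    spec = PhantomSpec(**SMALL_STRUCT, seed=11)
    array, masks, truth = make_structural_phantom(
        spec, np.random.default_rng(11))
    return VolumeStack(data=array, voxel_size=spec.voxel_size), masks, truth


@pytest.fixture(scope="session")
def dicom_tree(tmp_path_factory):
    """2 subjects x 2 sessions of a tiny structural scan, PHI-rich."""
    out = tmp_path_factory.mktemp("tree")
    spec = PhantomSpec(kind="structural", shape=(16, 16, 8),
                       brain_axes=(5.0, 5.0, 3.0), n_subjects=2,
                       sessions_per_subject=2, seed=21)
    paths, truth = generate(spec, out)
    return out, paths, truth


@pytest.fixture(scope="session")
def dwi_tree(tmp_path_factory):
    """One 7-volume diffusion series (1 b0 + 6 unit directions, b=1000)."""
    out = tmp_path_factory.mktemp("dwi")
    spec = PhantomSpec(kind="diffusion", shape=(12, 12, 4),
                       brain_axes=(4.0, 4.0, 1.5),
                       bvals=(0.0,) + (1000.0,) * 6,
                       bvecs=((0.0, 0.0, 0.0),) + SIX_DIRECTIONS, seed=31)
    paths, truth = generate(spec, out)
    return out, paths, truth


def as_stack(array, voxel_size=(1.0, 1.0, 1.0)) -> VolumeStack:
    return VolumeStack(data=np.asarray(array), voxel_size=voxel_size)
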