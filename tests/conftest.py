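import numpy as np
import pytest

from follimetrics.lattice import LabelImage, build_lattice, segment_cells
from follimetrics.surface import extract_pointcloud, fit_surface
from follimetrics.synthgen import SynthParams, make_epithelium, make_spheroid


@pytest.fixture(scope="session")
def sphere_epithelium():
    """Isotropic epithelium on a 10 μm sphere, 200 cells (closed chart)."""
    return make_epithelium(
        SynthParams(semi_axis_ap=10.0, semi_axis_eq=10.0, n_cells=200, seed=7)
    )


@pytest.fixture(scope="session")
def aniso_epithelium():
    """Anisotropic epithelium: 220 cells at target eccentricity 0.7,
    uniformly distributed long-axis orientations."""
    return make_epithelium(
        SynthParams(
            semi_axis_ap=10.0, semi_axis_eq=10.0, n_cells=220,
            target_eccentricity=0.7, orientation_bias="uniform", seed=11,
        )
    )


@pytest.fixture(scope="session")
def sphere_fit():
    """Voxelized 10 μm sphere (0.2 μm voxels) with fitted surface."""
    params = SynthParams(semi_axis_ap=10.0, semi_axis_eq=10.0,
                         voxel_size=(0.2, 0.2, 0.2), seed=1, noise_sd=0.02)
    mask, membrane, truth = make_spheroid(params)
    cloud = extract_pointcloud(membrane, params.voxel_size, 0.5)
    param, metric = fit_surface(cloud)
    return {"params": params, "mask": mask, "membrane": membrane,
            "truth": truth, "cloud": cloud, "param": param, "metric": metric}


@pytest.fixture(scope="session")
def prolate_fit():
    """Voxelized 2:1 prolate spheroid (a=20, b=10 μm) with fitted surface."""
    params = SynthParams(semi_axis_ap=20.0, semi_axis_eq=10.0,
                         voxel_size=(0.2, 0.2, 0.2), seed=1, noise_sd=0.02)
    mask, membrane, truth = make_spheroid(params)
    cloud = extract_pointcloud(membrane, params.voxel_size, 0.5)
    param, metric = fit_surface(cloud)
    return {"params": params, "mask": mask, "membrane": membrane,
            "truth": truth, "cloud": cloud, "param": param, "metric": metric}


@pytest.fixture(scope="session")
def segmented_sphere(sphere_epithelium):
    """Segmentation + lattice of the isotropic sphere epithelium."""
    seg = segment_cells(sphere_epithelium.pullback, expected_cells=200)
    lat = build_lattice(seg)
    return seg, lat


def match_segmentation_to_truth(seg_labels: np.ndarray, truth_labels: np.ndarray) -> dict:
    """Map each segmented label to the ground-truth label it overlaps most."""
    match = {}
    for lab in np.unique(seg_labels[seg_labels > 0]):
        overlap = truth_labels[seg_labels == lab]
        overlap = overlap[overlap > 0]
        if overlap.size:
            match[int(lab)] = int(np.bincount(overlap).argmax())
    return match


@pytest.fixture(scope="session")
def truth_lattice(sphere_epithelium):
    """Lattice built directly from the ground-truth label field."""
    li = LabelImage(labels=sphere_epithelium.labels, wraps_phi=True, closed=True)
    return build_lattice(li)
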