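"""Shared fixtures: small deterministic phantoms used across the suite."""

import numpy as np
import pytest

from fixtract.synthetic import (BundleSpec, CohortConfig, build_phantom,
                                metrics_from_eigenvalues)


def straight_bundle(name, axis, length_mm, offset_mm, radius=4.0,
                    lambdas=(1.7e-3, 0.4e-3), fraction=0.5):
    """A straight tube along one coordinate axis through ``offset_mm``."""
    t = np.linspace(0.0, length_mm, 17)
    line = np.tile(np.asarray(offset_mm, dtype=float), (17, 1))
    line[:, axis] = offset_mm[axis] - length_mm / 2 + t
    return BundleSpec(name, line, radius=radius,
                      baseline_metrics=metrics_from_eigenvalues(*lambdas),
                      fraction_profile=fraction)


@pytest.fixture(scope="session")
def crossing_phantom():
    """Two orthogonal straight bundles crossing at the grid centre.

    Bundle "along_x" has AD = 1.7e-3, the transverse "along_y" AD = 1.0e-3
    mm^2/s; zero noise.  Used for the crossing-fibre decontamination checks.
    """
    cfg = CohortConfig(n_aud=2, n_control=2, grid_shape=(31, 31, 11),
                       voxel_size=2.0)
    centre = np.array([30.0, 30.0, 10.0])
    bundles = [
        straight_bundle("along_x", 0, 48.0, centre, lambdas=(1.7e-3, 0.4e-3),
                        fraction=0.5),
        straight_bundle("along_y", 1, 48.0, centre, lambdas=(1.0e-3, 0.3e-3),
                        fraction=0.4),
    ]
    return build_phantom(cfg, bundles), bundles


@pytest.fixture(scope="session")
def single_bundle_phantom():
    """One straight 64 mm bundle along x on a 2 mm grid (8 sections of 8 mm)."""
    cfg = CohortConfig(n_aud=2, n_control=2, grid_shape=(44, 15, 15),
                       voxel_size=2.0)
    centre = np.array([43.0, 14.0, 14.0])
    bundle = straight_bundle("bundle", 0, 64.0, centre, radius=4.0)
    return build_phantom(cfg, [bundle]), bundle
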