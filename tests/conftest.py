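import numpy as np
import pandas as pd
import pytest

from thyrodose.phantom import OrganRecord, VoxelPhantom, generate_synthetic_phantom
from thyrodose.synthetic import make_toy_phantom
from thyrodose.transport import CrossSectionTable


@pytest.fixture(scope="session")
def xs():
    return CrossSectionTable.from_package()


@pytest.fixture(scope="session")
def toy():
    """16^3 two-organ phantom: source core + target shell."""
    return make_toy_phantom(16)


@pytest.fixture(scope="session")
def male_phantom():
    return generate_synthetic_phantom("male", 4.0, 1.0)


@pytest.fixture(scope="session")
def female_phantom():
    return generate_synthetic_phantom("female", 4.0, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def uniform_box_phantom(n=16, voxel_mm=4.0, material=1):
    """Single-organ box filling the whole grid (escape-proof with periodic runs)."""
    d = voxel_mm / 10.0
    labels = np.ones((n, n, n), dtype=np.uint16)
    return VoxelPhantom(
        labels=labels,
        voxel_size_cm=(d, d, d),
        organs=[OrganRecord(1, "medium", material)],
        gender="none",
        name="box",
    )


def layered_slab_phantom(layers, voxel_mm=5.0, nxy=40):
    """Slab of per-voxel-thick z layers; ``layers`` = list of material ids.

    Each z layer is its own organ (id = z index + 1) so depth-resolved energy
    deposition can be read off the organ tallies.
    """
    d = voxel_mm / 10.0
    nz = len(layers)
    labels = np.zeros((nxy, nxy, nz), dtype=np.uint16)
    organs = []
    for iz, mat in enumerate(layers):
        labels[:, :, iz] = iz + 1
        organs.append(OrganRecord(iz + 1, f"layer_{iz:03d}", mat))
    return VoxelPhantom(labels=labels, voxel_size_cm=(d, d, d), organs=organs,
                        gender="none", name="slab")


def flat_absorber_xs(mu_over_rho_by_material: dict[str, float]):
    """Cross-section table with energy-flat, photoelectric-only attenuation.

    Every real interaction absorbs the photon on the spot, so the organ where
    energy lands is the first-real-interaction site — the analytic-attenuation
    oracle geometry.
    """
    E = np.geomspace(1e-3, 3.0, 8)
    frames = {}
    for name in ("soft_tissue", "lung", "bone", "air"):
        mu = mu_over_rho_by_material.get(name, 1e-8)
        frames[name] = pd.DataFrame({
            "energy_MeV": E,
            "mu_over_rho": np.full_like(E, mu),
            "mu_en_over_rho": np.full_like(E, mu),
            "pe_fraction": np.ones_like(E),
            "S_over_rho": np.full_like(E, 2.0),
            "csda_range": E / 2.0,
        })
    return CrossSectionTable.from_frames(frames)


def monoline_spectrum(energy_mev=0.3645, kind="photon", half_life_h=192.48):
    from thyrodose.nuclear import ElectronComponent, NuclideSpectrum
    if kind == "photon":
        return NuclideSpectrum("mono", half_life_h, ((energy_mev, 1.0),), ())
    return NuclideSpectrum("mono", half_life_h, (),
                           (ElectronComponent("conversion", energy_mev, 1.0),))
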