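"""Generation of every input the pipeline needs, with a manifest.

``generate_bundle`` writes a complete, deterministic fixture set — male and
female synthetic phantoms, the three nuclide spectra, biokinetic scenario
files for iodide (seven uptake levels) and pertechnetate (three
administration routes), the four per-material cross-section tables and the
ICRP-103 weight table — plus a JSON manifest with SHA-256 checksums of every
file.  Regeneration with equal parameters is byte-identical.

``make_toy_phantom`` provides the two-organ (source sphere inside a target
shell) geometry used by the transport and chord-length oracles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from . import biokinetics as bk
from .phantom import OrganRecord, VoxelPhantom, generate_synthetic_phantom, write_phantom
from .transport import CrossSectionTable

__all__ = ["FixtureBundle", "generate_bundle", "make_toy_phantom"]


@dataclass(frozen=True)
class FixtureBundle:
    root: Path
    files: tuple[Path, ...]
    manifest_path: Path

    def checksums(self) -> dict[str, str]:
        return json.loads(self.manifest_path.read_text())["checksums"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_bundle(
    output_dir: str | Path,
    uptakes: tuple[float, ...] = bk.UPTAKE_LEVELS,
    voxel_size_mm: float = 4.0,
    scale: float = 1.0,
) -> FixtureBundle:
    """Write phantoms, spectra, scenarios, cross sections and weights + manifest."""
    root = Path(output_dir)
    root.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    for gender in ("male", "female"):
        ph = generate_synthetic_phantom(gender, voxel_size_mm, scale)
        grid = root / f"phantom_{gender}.raw"
        organs = root / f"phantom_{gender}.organs.csv"
        write_phantom(ph, grid, organs)
        files += [grid, grid.with_suffix(grid.suffix + ".json"), organs]

    spectra_dir = root / "spectra"
    spectra_dir.mkdir(exist_ok=True)
    for fn in ("i131.csv", "i123.csv", "tc99m.csv"):
        src = resources.files("thyrodose").joinpath("data/spectra").joinpath(fn)
        dst = spectra_dir / fn
        dst.write_text(src.read_text())
        files.append(dst)

    scen_dir = root / "biokinetics"
    scen_dir.mkdir(exist_ok=True)
    for u in uptakes:
        for nuc, tag in (("I-131", "i131"), ("I-123", "i123")):
            scn = bk.build_scenario("iodide", nuc, uptake=u)
            f = scen_dir / f"iodide_{tag}_u{int(round(u * 100)):03d}.json"
            bk.save_scenario(scn, f)
            files.append(f)
    for admin, blocking, tag in (("iv", False, "iv"), ("iv", True, "iv_blocked"), ("oral", False, "oral")):
        scn = bk.build_scenario("pertechnetate", "Tc-99m", administration=admin, blocking=blocking)
        f = scen_dir / f"pertechnetate_{tag}.json"
        bk.save_scenario(scn, f)
        files.append(f)

    xs_dir = root / "xs"
    files += CrossSectionTable.build_default().write_dir(xs_dir)

    wt = root / "icrp103_weights.csv"
    wt.write_text(resources.files("thyrodose").joinpath("data/weights").joinpath("icrp103.csv").read_text())
    files.append(wt)

    manifest_path = root / "manifest.json"
    manifest = {
        "parameters": {
            "uptakes": list(uptakes),
            "voxel_size_mm": voxel_size_mm,
            "scale": scale,
        },
        "files": sorted(str(f.relative_to(root)) for f in files),
        "checksums": {str(f.relative_to(root)): _sha256(f) for f in sorted(files)},
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return FixtureBundle(root=root, files=tuple(sorted(files)), manifest_path=manifest_path)


def make_toy_phantom(n: int = 16, voxel_size_mm: float = 4.0) -> VoxelPhantom:
    """Two-organ unit-test geometry in an n^3 grid: a central source sphere
    (label 1) wrapped by a concentric target shell (label 2), air outside."""
    if not (4 <= n <= 32):
        raise ValueError("n must be within [4, 32]")
    d = voxel_size_mm / 10.0
    half = n * d / 2.0
    ax = (np.arange(n) + 0.5) * d - half
    X, Y, Z = ax[:, None, None], ax[None, :, None], ax[None, None, :]
    r2 = X**2 + Y**2 + Z**2
    r_core = 0.30 * half
    r_shell = 0.75 * half
    labels = np.zeros((n, n, n), dtype=np.uint16)
    labels[r2 <= r_shell**2] = 2
    labels[r2 <= r_core**2] = 1
    organs = [
        OrganRecord(1, "core", 1),
        OrganRecord(2, "shell", 1),
    ]
    return VoxelPhantom(labels=labels, voxel_size_cm=(d, d, d), organs=organs,
                        gender="none", name=f"toy_{n}")
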