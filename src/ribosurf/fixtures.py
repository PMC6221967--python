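"""Synthetic multi-chain assemblies with known surface/internal ground truth.

These generators stand in for deposited ribosome structures in tests and
demos: geometrically separable "internal" chains (compact atom blobs inside a
core ball) and "surface" chains (blobs centred on an outer shell), a burial
cage for exercising the SASA machinery, and Poisson count matrices for the
read-depth power metric.  Chains are poly-alanine Cα traces so the polymer
classifier sees protein and the radii table stays trivial; entity
descriptions are assignable so the nomenclature cascade can be exercised.

Everything is seeded and byte-reproducible, and fixtures are written as real
PDB text so the parsers are always on the tested path.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import InputError
from .exposure import sphere_points
from .structure_io import Atom, Chain, Residue, Structure, write_pdb

_CHAIN_IDS = [chr(c) for c in (*range(65, 91), *range(97, 123), *range(48, 58))]


@dataclass
class FixtureSpec:
    """Geometry of a synthetic shell assembly."""

    n_internal: int = 2
    n_surface: int = 6
    core_radius: float = 10.0
    shell_radius: float = 60.0
    atoms_per_chain: int = 20
    jitter_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_internal < 1 or self.n_surface < 1:
            raise InputError("n_internal and n_surface must be >= 1")
        if not self.shell_radius > self.core_radius > 0:
            raise InputError("need shell_radius > core_radius > 0")
        if self.atoms_per_chain < 1:
            raise InputError("atoms_per_chain must be >= 1")
        if self.jitter_sd < 0:
            raise InputError("jitter_sd must be >= 0")


def _blob_chain(
    chain_id: str,
    centroid: np.ndarray,
    n_atoms: int,
    jitter_sd: float,
    rng: np.random.Generator,
    description: str,
) -> Chain:
    coords = centroid[None, :] + rng.normal(0.0, jitter_sd, size=(n_atoms, 3))
    residues = [
        Residue("ALA", i + 1, [Atom("CA", "C", coords[i])], "protein")
        for i in range(n_atoms)
    ]
    return Chain(chain_id, residues, entity_description=description)


def make_shell_assembly(
    spec: FixtureSpec, entity_names: list[str] | None = None
) -> tuple[Structure, dict[str, str]]:
    """Internal blobs inside the core ball, surface blobs on the outer shell.

    Returns the structure and the per-chain ground-truth labels.  Internal
    chains come first (ids A, B, ...), then surface chains.  Entity
    descriptions cycle through *entity_names* when given.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_internal + spec.n_surface
    if n_total > len(_CHAIN_IDS):
        raise InputError(f"at most {len(_CHAIN_IDS)} chains supported")
    # surface chains sit on direction-balanced (golden-spiral) shell points
    # under a random rotation: like a real particle, the surface coat
    # surrounds the core, so the assembly centroid stays near the true origin
    # and the shell/core separation guarantee actually holds at small n
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    rotation = q * np.sign(np.diag(r))
    shell_dirs = sphere_points(spec.n_surface) @ rotation.T
    chains: list[Chain] = []
    truth: dict[str, str] = {}
    for k in range(n_total):
        internal = k < spec.n_internal
        if internal:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = spec.core_radius * rng.uniform() ** (1.0 / 3.0)
        else:
            direction = shell_dirs[k - spec.n_internal]
            radius = spec.shell_radius
        cid = _CHAIN_IDS[k]
        desc = (
            entity_names[k % len(entity_names)]
            if entity_names
            else f"synthetic test protein {k + 1}"
        )
        chains.append(_blob_chain(
            cid, radius * direction, spec.atoms_per_chain, spec.jitter_sd, rng, desc
        ))
        truth[cid] = "internal" if internal else "surface"
    return Structure(id=f"SYNTH-SHELL-{spec.seed}", chains=chains), truth


def make_burial_fixture(
    seed: int = 0,
    cage_points: int = 400,
    cage_radius: float = 4.0,
    include_cage: bool = True,
) -> Structure:
    """A tiny target chain fully enclosed in a dense spherical carbon cage.

    With the default covering density every solvent sample point of the
    target falls inside a cage atom's probe-inflated sphere, so the target's
    assembly exposure ratio is ~0; thinning the cage (small *cage_points*)
    re-exposes it.
    """
    rng = np.random.default_rng(seed)
    target_coords = rng.normal(0.0, 0.3, size=(3, 3))
    target = Chain(
        "T",
        [
            Residue("ALA", i + 1, [Atom("CA", "C", target_coords[i])], "protein")
            for i in range(3)
        ],
        entity_description="synthetic buried target",
    )
    chains = [target]
    if include_cage:
        cage_coords = cage_radius * sphere_points(cage_points)
        # unique atom names: the loader collapses same-named atoms as altlocs
        cage_atoms = [
            Atom(f"C{i}", "C", xyz, is_hetero=True)
            for i, xyz in enumerate(cage_coords)
        ]
        chains.append(Chain("Z", [Residue("CAG", 1, cage_atoms, "other")]))
    return Structure(id=f"SYNTH-CAGE-{seed}", chains=chains)


def make_count_matrix(
    n_genes: int, n_cells: int, mean_depth: float, seed: int = 0
) -> np.ndarray:
    """Poisson gene x cell read-count matrix with the stated mean depth."""
    if n_genes < 1 or n_cells < 1:
        raise InputError("n_genes and n_cells must be >= 1")
    if mean_depth < 0:
        raise InputError("mean_depth must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.poisson(mean_depth, size=(n_genes, n_cells))


# ---------------------------------------------------------------------------
# demo assembly with named ribosomal-protein entities (synthetic!)
# ---------------------------------------------------------------------------

#: gene symbols used by the synthetic demo; 9 placed on the shell, 4 in the core
DEMO_SURFACE_GENES = [
    "Rpl4", "Rpl6", "Rpl7", "Rpl13", "Rpl18", "Rpl22", "Rps6", "Rps7", "Rps19",
]
DEMO_INTERNAL_GENES = ["Rpl8", "Rps3", "Rps14", "Rps29"]

_DEMO_LEGACY = {
    "Rpl4": "60S ribosomal protein L4",
    "Rpl6": "60S ribosomal protein L6",
    "Rpl7": "60S ribosomal protein L7",
    "Rpl13": "60S ribosomal protein L13",
    "Rpl18": "60S ribosomal protein L18",
    "Rpl22": "60S ribosomal protein L22",
    "Rps6": "40S ribosomal protein S6",
    "Rps7": "40S ribosomal protein S7",
    "Rps19": "40S ribosomal protein S19",
    "Rpl8": "60S ribosomal protein L8",
    "Rps3": "40S ribosomal protein S3",
    "Rps14": "40S ribosomal protein S14",
    "Rps29": "40S ribosomal protein S29",
}


def make_synthetic_ribosome_demo(seed: int = 0) -> tuple[Structure, list[str], dict[str, str]]:
    """A synthetic 13-chain stand-in assembly with real RP entity names.

    NOT a deposited ribosome: a shell fixture whose chains carry the legacy
    entity descriptions of 13 mouse ribosomal-protein genes, 9 of them placed
    on the assembly surface and 4 in the core.  Returns (structure, gene
    list, ground-truth per-gene labels); used by the worked example and the
    end-to-end pipeline checks.
    """
    spec = FixtureSpec(
        n_internal=len(DEMO_INTERNAL_GENES),
        n_surface=len(DEMO_SURFACE_GENES),
        core_radius=12.0,
        shell_radius=55.0,
        atoms_per_chain=25,
        jitter_sd=1.5,
        seed=seed,
    )
    names = [_DEMO_LEGACY[g] for g in DEMO_INTERNAL_GENES + DEMO_SURFACE_GENES]
    structure, _ = make_shell_assembly(spec, entity_names=names)
    genes = DEMO_SURFACE_GENES + DEMO_INTERNAL_GENES
    expected = {g: "surface" for g in DEMO_SURFACE_GENES}
    expected.update({g: "internal" for g in DEMO_INTERNAL_GENES})
    return structure, genes, expected


def write_fixture(spec: FixtureSpec, out_dir: str | Path, stem: str = "fixture") -> dict[str, Path]:
    """Write a shell fixture as PDB + ground-truth TSV + spec JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    structure, truth = make_shell_assembly(spec)
    paths = {
        "pdb": out_dir / f"{stem}.pdb",
        "truth": out_dir / f"{stem}.truth.tsv",
        "spec": out_dir / f"{stem}.spec.json",
    }
    write_pdb(structure, paths["pdb"])
    lines = ["chain_id\tlabel"] + [f"{cid}\t{lab}" for cid, lab in sorted(truth.items())]
    paths["truth"].write_text("\n".join(lines) + "\n")
    paths["spec"].write_text(json.dumps(asdict(spec), indent=2, sort_keys=True) + "\n")
    return paths
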