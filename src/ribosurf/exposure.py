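"""Radial burial scoring and solvent accessibility of chains in an assembly.

The classifier scores every protein chain by how far it sits from the core of
the assembly.  The core is a reference centroid (of the whole particle, of the
rRNA only, or one centroid per ribosomal subunit found by 2-means over chain
centroids).  A chain's radial score is the median distance of its residues'
representative atoms (Cα for protein, P for nucleic acids) to the nearest
core center, normalised by the assembly's 95th-percentile radius, so ~0 means
deeply buried and ~1 means at the particle surface.  Chains are labelled
``surface`` when the score reaches a threshold, either fixed or found
automatically by 1-D 2-means over the observed scores.

Solvent-accessible surface area (Shrake–Rupley: deterministic golden-spiral
sampling on each atom's probe-inflated sphere) provides an independent
confirmation: the exposure ratio is the chain's SASA inside the full assembly
divided by its SASA in isolation, so 0 means completely occluded by the rest
of the particle and 1 means as exposed as the free chain.

All SASA sampling is done in a canonical molecule frame (principal axes of
the context atoms, signs fixed by coordinate skewness) so results are
invariant under rigid-body motion of the input to ~1e-9, not merely to the
angular resolution of the point set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ConfigurationError,
    DegenerateSeparationError,
    RadiusLookupError,
    ScoringError,
)
from .structure_io import Atom, Chain, Structure, classify_polymers

CoreMode = Literal["assembly", "rna_only", "per_subunit"]

#: default van der Waals radii, Å; "*" is the generic fallback
DEFAULT_RADII: dict[str, float] = {
    "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8, "*": 1.7,
}


@dataclass
class SasaParams:
    """Parameters of the Shrake–Rupley accessibility computation."""

    probe_radius: float = 1.4
    n_points: int = 100
    radii_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ConfigurationError("probe_radius must be >= 0")
        if self.n_points < 12:
            raise ConfigurationError("n_points must be >= 12")

    def radius_of(self, element: str) -> float:
        el = element.strip().upper()
        if el in self.radii_table:
            return self.radii_table[el]
        if "*" in self.radii_table:
            return self.radii_table["*"]
        raise RadiusLookupError(f"no van der Waals radius for element {element!r}")


@dataclass
class CoreModel:
    """Reference center(s) and normalisation radius of the assembly."""

    mode: CoreMode
    centers: np.ndarray  # (k, 3) Å
    norm_radius: float  # Å, 95th percentile of representative-atom distances

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        k = 2 if self.mode == "per_subunit" else 1
        if self.centers.shape != (k, 3):
            raise ConfigurationError(
                f"mode {self.mode!r} requires {k} center(s), got {self.centers.shape}"
            )
        if not self.norm_radius > 0:
            raise ConfigurationError("norm_radius must be > 0")


@dataclass
class ChainExposure:
    """Per-chain result of surface/internal classification."""

    chain_id: str
    entity_description: str
    n_residues: int
    radial_score: float
    exposure_ratio: float
    label: Literal["surface", "internal"]
    margin: float


class ExposureSet(list):
    """List of :class:`ChainExposure` carrying the threshold and core used."""

    def __init__(self, items, threshold: float, core: CoreModel):
        super().__init__(items)
        self.threshold = threshold
        self.core = core


# ---------------------------------------------------------------------------
# representative atoms & core
# ---------------------------------------------------------------------------

def chain_polymer_class(chain: Chain) -> str:
    counts = {"protein": 0, "rna": 0, "dna": 0}
    for r in chain.residues:
        if r.polymer_class in counts:
            counts[r.polymer_class] += 1
    if sum(counts.values()) < 3:
        return "other"
    return max(counts, key=lambda k: (counts[k], k))


def representative_atoms(chain: Chain) -> list[Atom]:
    """One atom per polymer residue: Cα for protein, P for nucleic acids.

    Falls back to the residue's first heavy atom when the canonical
    representative is missing (common for terminal nucleotides).
    """
    want = {"protein": "CA", "rna": "P", "dna": "P"}
    out: list[Atom] = []
    for res in chain.residues:
        name = want.get(res.polymer_class)
        if name is None:
            continue
        rep = next((a for a in res.atoms if a.name.strip() == name), None)
        out.append(rep if rep is not None else res.atoms[0])
    return out


def _heavy_coords(chains: Sequence[Chain]) -> np.ndarray:
    coords = [a.coord for c in chains for a in c.atoms]
    return np.array(coords, dtype=float).reshape(-1, 3)


def _polymer_coords(chains: Sequence[Chain], classes: tuple[str, ...]) -> np.ndarray:
    coords = [
        a.coord
        for c in chains
        for r in c.residues
        if r.polymer_class in classes
        for a in r.atoms
    ]
    return np.array(coords, dtype=float).reshape(-1, 3)


def _chain_centroid(chain: Chain) -> np.ndarray:
    return _heavy_coords([chain]).mean(axis=0)


def _farthest_pair_2means(points: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 2-means: initialised at the two mutually farthest points."""
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    centers = points[[i, j]].astype(float)
    for _ in range(max_iter):
        assign = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(-1).argmin(1)
        new = np.array([
            points[assign == k].mean(0) if np.any(assign == k) else centers[k]
            for k in (0, 1)
        ])
        if np.allclose(new, centers, atol=1e-12):
            break
        centers = new
    return centers


def compute_core(structure: Structure, mode: CoreMode = "assembly") -> CoreModel:
    """Locate the assembly core and its normalisation radius.

    assembly: centroid of all polymer heavy atoms.  rna_only: centroid of the
    rRNA heavy atoms.  per_subunit: 2-means over polymer chain centroids
    (deterministic farthest-pair initialisation), one center per subunit.
    The normalisation radius is the 95th percentile of representative-atom
    distances to the nearest center.
    """
    polymer_chains = [
        c for c in structure.chains
        if any(r.polymer_class != "other" for r in c.residues)
    ]
    if not polymer_chains:
        raise ConfigurationError("structure has no polymer chains to define a core")

    if mode == "assembly":
        centers = _polymer_coords(polymer_chains, ("protein", "rna", "dna")).mean(axis=0)[None, :]
    elif mode == "rna_only":
        rna = _polymer_coords(polymer_chains, ("rna",))
        if rna.size == 0:
            raise ConfigurationError("rna_only core requested but structure has no RNA chains")
        centers = rna.mean(axis=0)[None, :]
    elif mode == "per_subunit":
        if len(polymer_chains) < 2:
            raise ConfigurationError("per_subunit core requires at least 2 polymer chains")
        centroids = np.array([_chain_centroid(c) for c in polymer_chains])
        centers = _farthest_pair_2means(centroids)
    else:
        raise ConfigurationError(f"unknown core mode {mode!r}")

    rep = np.array(
        [a.coord for c in polymer_chains for a in representative_atoms(c)]
    ).reshape(-1, 3)
    if rep.size == 0:
        raise ConfigurationError("no representative atoms to normalise against")
    dist = np.sqrt(((rep[:, None, :] - centers[None, :, :]) ** 2).sum(-1)).min(axis=1)
    norm_radius = float(np.percentile(dist, 95))
    if norm_radius <= 0:
        norm_radius = max(float(dist.max()), 1e-6)
    return CoreModel(mode=mode, centers=centers, norm_radius=norm_radius)


def radial_score(
    chain: Chain, core: CoreModel, rep_mode: Literal["representative", "all"] = "representative"
) -> float:
    """Median residue distance to the (assigned) core center, normalised.

    In per_subunit mode the chain is first assigned to its nearest center by
    chain centroid, and all residue distances are measured to that center.
    """
    if rep_mode == "all":
        per_res = [np.array([a.coord for a in r.atoms]) for r in chain.residues
                   if r.polymer_class in ("protein", "rna", "dna")]
        if not per_res:
            raise ScoringError(f"chain {chain.chain_id}: no polymer residues to score")
    else:
        reps = representative_atoms(chain)
        if not reps:
            raise ScoringError(f"chain {chain.chain_id}: no representative atoms")
        per_res = [a.coord[None, :] for a in reps]

    if core.mode == "per_subunit":
        centroid = _chain_centroid(chain)
        k = int(((core.centers - centroid) ** 2).sum(1).argmin())
        centers = core.centers[[k]]
    else:
        centers = core.centers

    dists = np.array([
        float(np.sqrt(((coords[:, None, :] - centers[None, :, :]) ** 2).sum(-1)).min(1).mean())
        if len(coords) > 1 else
        float(np.sqrt(((coords[0][None, :] - centers) ** 2).sum(-1)).min())
        for coords in per_res
    ])
    return float(np.median(dists) / core.norm_radius)


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit vectors, shape (n, 3)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rigid-motion-canonical copy of *coords*.

    Centers at the centroid and rotates onto principal axes with signs fixed
    by the third moment (falling back to the largest-|projection| point when
    the skewness vanishes), right-handedness enforced.  Any proper rigid
    transform of the input yields the same output to floating-point accuracy.
    """
    coords = np.asarray(coords, dtype=float)
    X = coords - coords.mean(axis=0)
    if len(X) < 3:
        return X
    cov = X.T @ X / len(X)
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1].copy()  # descending variance
    scale = max(float(np.abs(X).max()), 1e-9)
    for k in range(2):
        proj = X @ vecs[:, k]
        s = float((proj ** 3).sum())
        if abs(s) < 1e-9 * scale ** 3:
            s = float(proj[int(np.argmax(np.abs(proj)))])
        if s < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return X @ vecs


def _sasa_per_atom(
    coords: np.ndarray,
    radii: np.ndarray,
    params: SasaParams,
    neighbor_lists: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Per-atom SASA (Å²) of every atom in its own context.

    A point on atom *i*'s probe-inflated sphere counts as accessible when it
    lies strictly outside every other atom's inflated sphere.  *neighbor_lists*
    lets the naive all-pairs oracle reuse the identical arithmetic path.
    """
    n = len(coords)
    pts = sphere_points(params.n_points)
    probe = params.probe_radius
    areas = np.empty(n)
    if neighbor_lists is None:
        tree = cKDTree(coords)
        cutoff = radii + probe + radii.max() + probe
        raw = tree.query_ball_point(coords, r=cutoff)
        neighbor_lists = [np.array([j for j in raw[i] if j != i], dtype=int) for i in range(n)]
    for i in range(n):
        big_r = radii[i] + probe
        sample = coords[i] + big_r * pts
        free = np.ones(params.n_points, dtype=bool)
        nbrs = neighbor_lists[i]
        if len(nbrs):
            diff = sample[:, None, :] - coords[nbrs][None, :, :]
            d2 = (diff * diff).sum(-1)
            inflated = (radii[nbrs] + probe) ** 2
            free &= ~(d2 < inflated[None, :]).any(axis=1)
        areas[i] = free.sum() / params.n_points * 4.0 * math.pi * big_r * big_r
    return areas


def shrake_rupley_sasa(
    atoms: Sequence[Atom],
    context: Sequence[Atom],
    params: SasaParams | None = None,
    canonicalize: bool = True,
) -> np.ndarray:
    """SASA (Å²) of *atoms*, occluded by *context* (which must include them).

    Query atoms are matched to context atoms by object identity, with an
    exact-coordinate fallback, so each atom is never occluded by itself.
    """
    params = params or SasaParams()
    coords = np.array([a.coord for a in context], dtype=float).reshape(-1, 3)
    radii = np.array([params.radius_of(a.element) for a in context])
    if canonicalize and len(coords):
        coords = canonical_frame(coords)
    areas = _sasa_per_atom(coords, radii, params)

    index_by_id = {id(a): i for i, a in enumerate(context)}
    index_by_key = {
        (round(a.coord[0], 9), round(a.coord[1], 9), round(a.coord[2], 9), a.element): i
        for i, a in enumerate(context)
    }
    out = np.empty(len(atoms))
    for q, atom in enumerate(atoms):
        i = index_by_id.get(id(atom))
        if i is None:
            key = (round(atom.coord[0], 9), round(atom.coord[1], 9),
                   round(atom.coord[2], 9), atom.element)
            i = index_by_key.get(key)
        if i is None:
            raise ScoringError("query atom not found in SASA context")
        out[q] = areas[i]
    return out


def exposure_ratio(
    chain: Chain, structure: Structure, params: SasaParams | None = None
) -> float:
    """Chain SASA in the full assembly divided by its SASA in isolation.

    1.0 means the chain is as exposed as the free chain, 0 means fully
    occluded by the rest of the particle.  Clamped to [0, 1] against
    point-sampling noise.
    """
    params = params or SasaParams()
    chain_atoms = chain.atoms
    if not chain_atoms:
        raise ScoringError(f"chain {chain.chain_id}: no atoms for SASA")
    iso = float(shrake_rupley_sasa(chain_atoms, chain_atoms, params).sum())
    if iso <= 0:
        raise ScoringError(f"chain {chain.chain_id}: isolated SASA is zero")
    all_atoms = [a for c in structure.chains for a in c.atoms]
    full = float(shrake_rupley_sasa(chain_atoms, all_atoms, params).sum())
    return float(min(1.0, max(0.0, full / iso)))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _two_means_1d(values: np.ndarray, max_iter: int = 200) -> tuple[float, float]:
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 1e-12 * max(1.0, abs(hi)):
        raise DegenerateSeparationError(
            "all radial scores are identical; auto-thresholding cannot separate "
            "surface from internal — supply a fixed threshold"
        )
    c = np.array([lo, hi])
    for _ in range(max_iter):
        assign = np.abs(values[:, None] - c[None, :]).argmin(1)
        new = np.array([
            values[assign == k].mean() if np.any(assign == k) else c[k] for k in (0, 1)
        ])
        if np.allclose(new, c, atol=1e-14):
            break
        c = new
    return float(c.min()), float(c.max())


def auto_threshold(scores: Sequence[float]) -> float:
    """Midpoint of the two 1-D 2-means cluster centers over radial scores."""
    values = np.asarray(list(scores), dtype=float)
    if len(values) < 2:
        raise ConfigurationError("auto threshold requires at least 2 protein chains")
    c_lo, c_hi = _two_means_1d(values)
    return 0.5 * (c_lo + c_hi)


def classify_chains(
    structure: Structure,
    core_mode: CoreMode = "assembly",
    threshold: float | str = "auto",
    params: SasaParams | None = None,
    rep_mode: Literal["representative", "all"] = "representative",
    compute_sasa: bool = True,
) -> ExposureSet:
    """Label every protein chain of the assembly surface or internal.

    ``surface`` iff radial_score >= threshold (ties surface).  The exposure
    ratio is reported alongside as an independent accessibility confirmation
    (NaN when *compute_sasa* is off).  Output sorted by chain_id.
    """
    params = params or SasaParams()
    proteins = sorted(classify_polymers(structure)["protein"], key=lambda c: c.chain_id)
    if not proteins:
        raise ScoringError("structure has no protein chains to classify")
    if threshold == "auto" and len(proteins) < 2:
        raise ConfigurationError("auto threshold requires at least 2 protein chains")

    core = compute_core(structure, core_mode)
    scores = {c.chain_id: radial_score(c, core, rep_mode) for c in proteins}

    if threshold == "auto":
        thr = auto_threshold(list(scores.values()))
    else:
        thr = float(threshold)

    ratios: dict[str, float] = {}
    if compute_sasa:
        # one full-assembly pass: per-atom SASA of everything, summed per chain
        all_atoms = [a for c in structure.chains for a in c.atoms]
        coords = np.array([a.coord for a in all_atoms], dtype=float)
        radii = np.array([params.radius_of(a.element) for a in all_atoms])
        full_areas = _sasa_per_atom(canonical_frame(coords), radii, params)
        offsets: dict[str, slice] = {}
        pos = 0
        for c in structure.chains:
            n = len(c.atoms)
            offsets[c.chain_id] = slice(pos, pos + n)
            pos += n
        for c in proteins:
            iso = float(shrake_rupley_sasa(c.atoms, c.atoms, params).sum())
            if iso <= 0:
                raise ScoringError(f"chain {c.chain_id}: isolated SASA is zero")
            full = float(full_areas[offsets[c.chain_id]].sum())
            ratios[c.chain_id] = float(min(1.0, max(0.0, full / iso)))

    exposures = [
        ChainExposure(
            chain_id=c.chain_id,
            entity_description=c.entity_description,
            n_residues=len(c.residues),
            radial_score=scores[c.chain_id],
            exposure_ratio=ratios.get(c.chain_id, float("nan")),
            label="surface" if scores[c.chain_id] >= thr else "internal",
            margin=abs(scores[c.chain_id] - thr),
        )
        for c in proteins
    ]
    return ExposureSet(exposures, threshold=thr, core=core)
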