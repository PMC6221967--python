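"""Reading and writing macromolecular structures.

Structures are read with gemmi (PDB and mmCIF dialects) into a small uniform
in-memory model: ``Structure -> Chain -> Residue -> Atom``.  Only the first
model is kept, hydrogens and waters are dropped, and alternate locations are
collapsed to the highest-occupancy conformer.  Author chain identifiers are
the primary key throughout (they are what PyMOL selections address); entity
identifiers and the free-text molecule descriptions from the file are kept as
chain metadata because the nomenclature resolver matches against them.

A minimal PDB writer (ATOM/HETATM/TER/END plus COMPND for the molecule
descriptions) is provided so synthetic fixtures flow through the same reader
as deposited structures.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import gemmi
import numpy as np

from .errors import (
    CoordinateRangeError,
    EmptyStructureError,
    FormatError,
    InputError,
)

logger = logging.getLogger(__name__)

PolymerClass = Literal["protein", "rna", "dna", "other"]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: chain-id pool for PDB single-character remapping, in deterministic order
_CHAIN_ID_POOL = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass
class Atom:
    """A heavy atom with Cartesian coordinates in Å."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise InputError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise InputError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass
class Residue:
    name: str
    seq_id: int
    atoms: list[Atom]
    polymer_class: PolymerClass = "other"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise InputError(f"residue {self.name} {self.seq_id}: needs at least one atom")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]
    entity_id: str = ""
    entity_description: str = ""

    def __post_init__(self) -> None:
        if not self.chain_id:
            raise InputError("chain_id must be non-empty")

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    model_index: int = 0

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise InputError("duplicate chain_id within model")

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def iter_atoms(self) -> Iterator[Atom]:
        for c in self.chains:
            yield from c.atoms


# ---------------------------------------------------------------------------
# residue chemistry
# ---------------------------------------------------------------------------

def residue_polymer_class(name: str) -> PolymerClass:
    """Classify a residue name as protein / rna / dna / other.

    Uses gemmi's tabulated chemical-component info; unknown names are other.
    """
    info = gemmi.find_tabulated_residue(name.strip().upper())
    if info is None or not info.found():
        return "other"
    if info.is_amino_acid():
        return "protein"
    if info.is_nucleic_acid():
        # DNA components are the D-prefixed ones (DA/DC/DG/DT/DU)
        if name.strip().upper() in {"DA", "DC", "DG", "DT", "DU", "DI"}:
            return "dna"
        return "rna"
    return "other"


def _infer_element(atom_name: str, gemmi_element: gemmi.Element) -> str:
    if gemmi_element is not None and gemmi_element.name not in ("X", ""):
        return gemmi_element.name
    stripped = atom_name.strip(string.digits + "'\" *")
    return (stripped[:1] or "C").upper()


# ---------------------------------------------------------------------------
# COMPND / entity descriptions
# ---------------------------------------------------------------------------

def _parse_compnd(text: str) -> dict[str, tuple[str, str]]:
    """Parse PDB COMPND records into chain_id -> (mol_id, description)."""
    payload: list[str] = []
    for line in text.splitlines():
        if line.startswith("COMPND"):
            payload.append(line[10:].rstrip())
    blob = " ".join(p.strip() for p in payload)
    result: dict[str, tuple[str, str]] = {}
    mol_id, molecule = "", ""
    for spec in blob.split(";"):
        if ":" not in spec:
            continue
        key, _, value = spec.partition(":")
        key, value = key.strip().upper(), value.strip()
        if key == "MOL_ID":
            mol_id, molecule = value, ""
        elif key == "MOLECULE":
            molecule = value
        elif key == "CHAIN":
            for cid in (v.strip() for v in value.split(",")):
                if cid:
                    result[cid] = (mol_id, molecule)
    return result


def _mmcif_entity_descriptions(path: str | Path) -> dict[str, str]:
    """entity_id -> _entity.pdbx_description from an mmCIF file."""
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    out: dict[str, str] = {}
    for row in block.find("_entity.", ["id", "?pdbx_description"]):
        if row.has(1):
            desc = gemmi.cif.as_string(row[1])
            if desc and desc != "?":
                out[gemmi.cif.as_string(row[0])] = desc
    return out


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _sniff_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in (".cif", ".mmcif"):
        return "mmcif"
    if ext in (".pdb", ".ent"):
        return "pdb"
    try:
        head = path.read_text(errors="replace")[:4096]
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    if re.search(r"^(ATOM|HETATM|HEADER|COMPND)", head, re.M):
        return "pdb"
    raise FormatError(f"cannot determine structure format of {path}")


def load_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    First model only; hydrogens and waters excluded; altlocs collapsed to the
    highest-occupancy conformer (ties broken by altloc letter); hetero small
    molecules retained with ``is_hetero=True``.  Entity descriptions are taken
    from ``_entity.pdbx_description`` (mmCIF) or COMPND records (PDB).
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such file: {path}")
    if format == "auto":
        format = _sniff_format(path)
    if format not in ("pdb", "mmcif"):
        raise FormatError(f"unknown format {format!r} (expected pdb/mmcif/auto)")

    coord_format = gemmi.CoorFormat.Pdb if format == "pdb" else gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(str(path), format=coord_format)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")

    if format == "mmcif":
        entity_desc = _mmcif_entity_descriptions(path)
        compnd: dict[str, tuple[str, str]] = {}
    else:
        entity_desc = {}
        compnd = _parse_compnd(path.read_text(errors="replace"))

    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        chain_entity_id = ""
        for gres in gchain:
            rname = gres.name.strip()
            if rname.upper() in _WATER_NAMES:
                continue
            is_het = gres.het_flag == "H"
            # altloc collapse: per atom name keep highest occupancy
            best: dict[str, gemmi.Atom] = {}
            for ga in gres:
                el = _infer_element(ga.name, ga.element)
                if el in ("H", "D"):
                    continue
                prev = best.get(ga.name)
                if prev is None or ga.occ > prev.occ or (
                    ga.occ == prev.occ and (ga.altloc or "~") < (prev.altloc or "~")
                ):
                    best[ga.name] = ga
            atoms = [
                Atom(
                    name=ga.name,
                    element=_infer_element(ga.name, ga.element),
                    coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    altloc=(ga.altloc if ga.altloc not in ("\x00",) else ""),
                    is_hetero=is_het,
                )
                for ga in best.values()
            ]
            if not atoms:
                logger.warning(
                    "dropping residue %s %s/%s: no heavy atoms after filtering",
                    gchain.name, rname, gres.seqid.num,
                )
                continue
            pclass = residue_polymer_class(rname)
            residues.append(Residue(rname, gres.seqid.num, atoms, pclass))
            if not chain_entity_id and pclass != "other":
                chain_entity_id = gres.entity_id or ""
        if not residues:
            continue
        residues.sort(key=lambda r: r.seq_id)
        eid, desc = chain_entity_id, entity_desc.get(chain_entity_id, "")
        if gchain.name in compnd:
            eid, desc = compnd[gchain.name]
        chains.append(Chain(gchain.name, residues, entity_id=eid, entity_description=desc))

    structure = Structure(id=st.name or path.stem, chains=chains, model_index=0)
    if not any(
        r.polymer_class != "other" for c in structure.chains for r in c.residues
    ):
        raise EmptyStructureError(f"{path}: empty structure (no polymer chains)")
    return structure


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _remap_chain_ids(structure: Structure) -> dict[str, str]:
    """Deterministic mapping to single-character PDB chain ids."""
    mapping: dict[str, str] = {}
    used = {c.chain_id for c in structure.chains if len(c.chain_id) == 1}
    pool = iter(cid for cid in _CHAIN_ID_POOL if cid not in used)
    for chain in structure.chains:
        if len(chain.chain_id) == 1:
            mapping[chain.chain_id] = chain.chain_id
        else:
            try:
                mapping[chain.chain_id] = next(pool)
            except StopIteration:
                raise InputError(
                    "more chains than single-character PDB chain ids available"
                ) from None
    return mapping


def _format_atom_name(name: str) -> str:
    # standard convention: 1-3 char names start one column in
    return name if len(name) >= 4 else f" {name:<3s}"


def _compnd_lines(structure: Structure, remap: dict[str, str]) -> list[str]:
    specs: list[str] = []
    mol = 0
    for chain in structure.chains:
        if not chain.entity_description:
            continue
        mol += 1
        specs += [
            f"MOL_ID: {mol};",
            f"MOLECULE: {chain.entity_description};",
            f"CHAIN: {remap[chain.chain_id]};",
        ]
    lines: list[str] = []
    cont = 0
    for spec in specs:
        # wrap long specs at word boundaries within the 70-column payload
        words, cur = spec.split(" "), ""
        pieces: list[str] = []
        for w in words:
            if cur and len(cur) + 1 + len(w) > 60:
                pieces.append(cur)
                cur = w
            else:
                cur = f"{cur} {w}".strip()
        pieces.append(cur)
        for piece in pieces:
            cont += 1
            if cont == 1:
                lines.append(f"COMPND    {piece}")
            else:
                lines.append(f"COMPND{cont:>4d} {piece}")
    return lines


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a minimal fixed-column PDB file (COMPND/ATOM/HETATM/TER/END).

    Coordinates are lossless to 3 decimals; chain ids longer than one
    character are remapped deterministically.
    """
    if not structure.chains:
        raise InputError("cannot write a structure with no chains")
    remap = _remap_chain_ids(structure)
    lines = _compnd_lines(structure, remap)
    serial = 0
    for chain in structure.chains:
        cid = remap[chain.chain_id]
        for res in chain.residues:
            for atom in res.atoms:
                x, y, z = atom.coord
                for v in (x, y, z):
                    if not -999.999 <= v <= 9999.999:
                        raise CoordinateRangeError(
                            f"coordinate {v:.3f} does not fit PDB 8.3 column"
                        )
                serial += 1
                record = "HETATM" if atom.is_hetero else "ATOM  "
                lines.append(
                    f"{record}{min(serial, 99999):>5d} "
                    f"{_format_atom_name(atom.name):<4s}"
                    f" {res.name:>3s} {cid}{res.seq_id:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        serial += 1
        lines.append(f"TER   {min(serial, 99999):>5d}      {chain.residues[-1].name:>3s} {cid}{chain.residues[-1].seq_id:>4d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# polymer classification
# ---------------------------------------------------------------------------

def classify_polymers(structure: Structure) -> dict[PolymerClass, list[Chain]]:
    """Partition chains into protein / rna / dna / other by majority residue class.

    Chains with fewer than 3 polymer residues go to ``other``.
    """
    out: dict[PolymerClass, list[Chain]] = {"protein": [], "rna": [], "dna": [], "other": []}
    for chain in structure.chains:
        counts = {"protein": 0, "rna": 0, "dna": 0}
        for res in chain.residues:
            if res.polymer_class in counts:
                counts[res.polymer_class] += 1
        n_polymer = sum(counts.values())
        if n_polymer < 3:
            out["other"].append(chain)
            continue
        winner = max(counts, key=lambda k: (counts[k], k))  # deterministic tie-break
        out[winner].append(chain)
    return out
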