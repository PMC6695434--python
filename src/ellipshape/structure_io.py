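"""Structure and table I/O.

Reads atomic structures from PDB files into :class:`AtomCloud`, the universal
structural input of the package, assigning van der Waals radii by element
(C 1.7, N 1.55, O 1.52, S 1.8, H 1.2 Å; anything else 1.7 Å).  Also reads and
writes per-residue scalar tables (evolutionary rates, surface propensities)
as two-column TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: van der Waals radii (Å) by element symbol; unknown elements fall back to
#: the carbon value with a logged warning.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_RADIUS = 1.70

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed or contains no atoms."""


def vdw_radius(element: str) -> float:
    """vdW radius (Å) for an element symbol; pure table lookup."""
    el = element.strip().upper()
    if el in VDW_RADII:
        return VDW_RADII[el]
    logger.warning("unknown element %r: using default radius %.2f Å", element, DEFAULT_RADIUS)
    return DEFAULT_RADIUS


@dataclass
class AtomCloud:
    """A set of atoms with coordinates, vdW radii and residue annotations.

    Arrays are parallel over atoms.  Coordinates are in Å.  ``is_ca`` flags
    alpha carbons (one per residue in well-formed inputs).
    """

    elements: np.ndarray          # dtype=object, element symbols
    coords: np.ndarray            # (N, 3) float
    radii: np.ndarray             # (N,) float
    res_index: np.ndarray         # (N,) int
    res_name: np.ndarray          # dtype=object, 3-letter codes
    chain_id: np.ndarray          # dtype=object
    is_ca: np.ndarray             # (N,) bool
    source: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float)
        self.res_index = np.asarray(self.res_index, dtype=int)
        self.is_ca = np.asarray(self.is_ca, dtype=bool)
        for name in ("elements", "res_name", "chain_id"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in AtomCloud")
        if np.any(self.radii <= 0):
            raise ValueError("non-positive vdW radius in AtomCloud")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self)

    def subset(self, mask: np.ndarray) -> "AtomCloud":
        return AtomCloud(
            self.elements[mask], self.coords[mask], self.radii[mask],
            self.res_index[mask], self.res_name[mask], self.chain_id[mask],
            self.is_ca[mask], source=self.source,
        )

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(c)
        return list(seen)

    def ca_cloud(self) -> "AtomCloud":
        """The alpha-carbon subset."""
        return self.subset(self.is_ca)


@dataclass
class ResidueScalarTable:
    """Per-residue scalar values (unitless), e.g. evolutionary rates.

    ``values`` maps residue index -> value.  ``res_types`` optionally carries
    the 3-letter type of each residue for per-type aggregation.
    """

    values: pd.Series
    res_types: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        self.values.index = self.values.index.astype(int)
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("non-finite scalar values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate residue indices in scalar table")

    def __len__(self) -> int:
        return len(self.values)

    def per_type_mean(self) -> pd.Series:
        if not self.res_types:
            raise ValueError("no residue types attached; pass res_types")
        types = pd.Series({i: self.res_types.get(i, "UNK") for i in self.values.index})
        return self.values.groupby(types).mean()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueScalarTable":
        df = pd.read_csv(path, sep="\t")
        if "residue_index" not in df.columns or "value" not in df.columns:
            raise ValueError(f"{path}: expected header 'residue_index<TAB>value'")
        return cls(pd.Series(df["value"].to_numpy(), index=df["residue_index"].to_numpy()))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"residue_index": self.values.index, "value": self.values.to_numpy()})
        df.to_csv(path, sep="\t", index=False)


def _dedupe_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer of each atom name."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def read_structure(
    path: str | Path,
    include_hydrogens: bool = False,
    include_hetatm: bool = False,
) -> AtomCloud:
    """Read a PDB file into an :class:`AtomCloud`.

    Hydrogens are dropped unless ``include_hydrogens``; waters are always
    excluded and other HETATM groups are excluded unless ``include_hetatm``.
    Only the first MODEL is read, and for alternate locations only the
    highest-occupancy conformer is kept.
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise StructureParseError(f"{path}: no models")

    model = structure[0]
    elements, coords, radii, res_idx, res_nm, chains, is_ca = [], [], [], [], [], [], []
    for chain in model:
        for residue in chain:
            if residue.name in _WATER_NAMES or residue.is_water():
                continue
            if residue.het_flag == "H" and not include_hetatm:
                continue
            for atom in _dedupe_altlocs(residue):
                el = atom.element.name.upper() if atom.element else ""
                if not el:
                    el = "".join(ch for ch in atom.name if ch.isalpha())[:1]
                    logger.info("element inferred from atom name %r -> %r", atom.name, el)
                if el == "H" and not include_hydrogens:
                    continue
                elements.append(el)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                radii.append(vdw_radius(el))
                res_idx.append(residue.seqid.num)
                res_nm.append(residue.name)
                chains.append(chain.name)
                is_ca.append(atom.name == "CA" and el == "C")
    if not elements:
        raise StructureParseError(f"{path}: no ATOM records after filtering")
    return AtomCloud(
        np.array(elements, dtype=object), np.array(coords, float), np.array(radii, float),
        np.array(res_idx, int), np.array(res_nm, dtype=object),
        np.array(chains, dtype=object), np.array(is_ca, bool), source=str(path),
    )


def write_fixture(cloud: AtomCloud, path: str | Path) -> None:
    """Write an :class:`AtomCloud` as PDB text re-readable by read_structure.

    Alpha carbons get the atom name CA; other atoms are named by element.
    """
    if len(cloud) == 0:
        raise ValueError("cannot write empty AtomCloud")
    # gemmi add_* methods copy their argument, so build bottom-up
    structure = gemmi.Structure()
    structure.name = cloud.source or "fixture"
    model = gemmi.Model("1")
    for chain_name in cloud.chains():
        chain = gemmi.Chain(chain_name)
        sub = cloud.subset(cloud.chain_id == chain_name)
        order = np.argsort(sub.res_index, kind="stable")
        current = None
        residue = None
        for k in order:
            idx = int(sub.res_index[k])
            if idx != current:
                if residue is not None:
                    chain.add_residue(residue)
                residue = gemmi.Residue()
                residue.name = str(sub.res_name[k])
                residue.seqid = gemmi.SeqId(idx, " ")
                residue.het_flag = "A"
                current = idx
                serial = 0
            atom = gemmi.Atom()
            el = str(sub.elements[k])
            serial += 1
            # unique within-residue names (altloc dedup keys on atom name)
            atom.name = "CA" if sub.is_ca[k] else f"{el}{serial}"
            atom.element = gemmi.Element(el)
            atom.pos = gemmi.Position(*sub.coords[k])
            atom.occ = 1.0
            residue.add_atom(atom)
        if residue is not None:
            chain.add_residue(residue)
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))
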