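"""RNA chain I/O: PDB parsing, anchor-atom access, and score reports.

The universal input object is :class:`RNAStructure` — a single ordered RNA
chain with per-nucleotide heavy-atom coordinates. Parsing goes through
biotite; residues are bucketed into A/C/G/U plus ``X`` for anything
nonstandard (T, modified nucleotides). Hydrogens are dropped everywhere:
predicted models rarely carry them and the lDDT convention uses heavy atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from biotite.structure.io.pdb import PDBFile

STANDARD_CODES = ("A", "C", "G", "U")

# residue-name aliases that still mean a standard ribonucleotide
_NAME_MAP = {
    "A": "A", "RA": "A", "ADE": "A",
    "C": "C", "RC": "C", "CYT": "C",
    "G": "G", "RG": "G", "GUA": "G",
    "U": "U", "RU": "U", "URA": "U",
}

_PURINE_N = "N9"
_PYRIMIDINE_N = "N1"


class EmptyChainError(ValueError):
    """No RNA residues found in the requested chain."""


class ChainNotFoundError(ValueError):
    """Requested chain id absent from the file."""


class MissingAnchorError(ValueError):
    """A nucleotide lacks a required anchor atom (C4' or glycosidic N)."""


class ScoreMismatchError(ValueError):
    """Score vector length disagrees with the structure length."""


@dataclass(frozen=True)
class Atom:
    name: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        object.__setattr__(self, "coords", c)


@dataclass
class Nucleotide:
    """One residue: 1-based ``index``, code in {A,C,G,U,X}, atom-name map."""

    index: int
    code: str
    atoms: dict[str, Atom] = field(default_factory=dict)
    label: str = ""  # original "resseq[icode]" from the file, for reports

    def has(self, name: str) -> bool:
        return name in self.atoms

    def coord(self, name: str) -> np.ndarray:
        return self.atoms[name].coords


@dataclass
class RNAStructure:
    id: str
    chain: str
    nucleotides: list[Nucleotide]

    @property
    def L(self) -> int:
        return len(self.nucleotides)

    @property
    def sequence(self) -> str:
        return "".join(nt.code for nt in self.nucleotides)

    def c4_coords(self) -> np.ndarray:
        """(L, 3) array of C4' positions in Angstrom."""
        return np.stack([nt.coord("C4'") for nt in self.nucleotides])

    def anchor_triple(self, nt: Nucleotide) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x1, x2, x3) = (P-or-fallback, C4', glycosidic N) in Angstrom.

        5'-terminal residues without P fall back to O5', then to the C4'
        position itself (the frame builder resolves that degeneracy).
        """
        if not nt.has("C4'"):
            raise MissingAnchorError(f"residue {nt.label or nt.index}: missing anchor atom C4'")
        x2 = nt.coord("C4'")
        if nt.has("P"):
            x1 = nt.coord("P")
        elif nt.has("O5'"):
            x1 = nt.coord("O5'")
        else:
            x1 = x2
        x3 = glycosidic_nitrogen(nt).coords
        return x1, x2, x3

    def transformed(self, R: np.ndarray, t: np.ndarray, id_suffix: str = "_moved") -> "RNAStructure":
        """Copy with every atom under the global rigid motion ``x -> R x + t``."""
        nts = []
        for nt in self.nucleotides:
            atoms = {
                name: Atom(name, np.asarray(R) @ a.coords + np.asarray(t))
                for name, a in nt.atoms.items()
            }
            nts.append(Nucleotide(nt.index, nt.code, atoms, nt.label))
        return RNAStructure(self.id + id_suffix, self.chain, nts)


def glycosidic_nitrogen(nt: Nucleotide) -> Atom:
    """Base nitrogen bonded to the sugar: N9 for purines (A, G), N1 for
    pyrimidines (C, U); for the nonstandard bucket X, N9 if present else N1."""
    if nt.code in ("A", "G"):
        order = (_PURINE_N,)
    elif nt.code in ("C", "U"):
        order = (_PYRIMIDINE_N,)
    else:
        order = (_PURINE_N, _PYRIMIDINE_N)
    for name in order:
        if nt.has(name):
            return nt.atoms[name]
    raise MissingAnchorError(
        f"residue {nt.label or nt.index}: missing anchor atom (glycosidic N)"
    )


def _is_hydrogen(element: str, name: str) -> bool:
    el = element.strip().upper()
    if el in ("H", "D"):
        return True
    if not el:
        stripped = name.strip().lstrip("0123456789")
        return stripped[:1].upper() in ("H", "D")
    return False


def read_structure(path, chain: str | None = None, structure_id: str | None = None) -> RNAStructure:
    """Read one RNA chain from a PDB file.

    Uses MODEL 1 of multi-model files; altlocs resolve to highest occupancy
    (ties: first seen); residue order follows file order of (resseq, icode).
    Residues that carry no ribose atoms and no standard base name (waters,
    ions, ligands) are skipped; a nucleotide-like residue without C4'
    raises :class:`MissingAnchorError`.
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1, altloc="occupancy", extra_fields=["occupancy"])

    chain_ids = list(dict.fromkeys(arr.chain_id.tolist()))
    if chain is None:
        if not chain_ids:
            raise EmptyChainError(f"{path}: empty chain (no atoms)")
        chain = chain_ids[0]
    elif chain not in chain_ids:
        raise ChainNotFoundError(f"{path}: chain not found: {chain!r}")
    arr = arr[arr.chain_id == chain]

    # group into residues preserving file order of (res_id, ins_code)
    ins = arr.ins_code if "ins_code" in arr.get_annotation_categories() else [""] * arr.array_length()
    groups: dict[tuple, dict[str, Atom]] = {}
    names: dict[tuple, str] = {}
    order: list[tuple] = []
    for i in range(arr.array_length()):
        if _is_hydrogen(str(arr.element[i]), str(arr.atom_name[i])):
            continue
        key = (int(arr.res_id[i]), str(ins[i]).strip())
        if key not in groups:
            groups[key] = {}
            names[key] = str(arr.res_name[i]).strip()
            order.append(key)
        aname = str(arr.atom_name[i]).strip()
        if aname not in groups[key]:  # first altloc survivor wins duplicates
            groups[key][aname] = Atom(aname, arr.coord[i])

    nucleotides: list[Nucleotide] = []
    idx = 0
    for key in order:
        atoms = groups[key]
        resname = names[key]
        is_candidate = (
            resname.upper() in _NAME_MAP
            or any(a in atoms for a in ("C4'", "C1'", "O4'"))
        )
        if not is_candidate:
            continue
        if "C4'" not in atoms:
            label = f"{key[0]}{key[1]}"
            raise MissingAnchorError(f"{path}: residue {resname} {label}: missing anchor atom C4'")
        idx += 1
        code = _NAME_MAP.get(resname.upper(), "X")
        nucleotides.append(Nucleotide(idx, code, atoms, label=f"{key[0]}{key[1]}"))

    if not nucleotides:
        raise EmptyChainError(f"{path}: empty chain (no RNA residues in chain {chain!r})")

    if structure_id is None:
        import os

        structure_id = os.path.splitext(os.path.basename(str(path)))[0]
    return RNAStructure(structure_id, chain, nucleotides)


def write_pdb(structure: RNAStructure, path) -> None:
    """Write the structure as fixed-width ATOM records (one chain, one model)."""
    lines = []
    serial = 0
    for nt in structure.nucleotides:
        for atom in nt.atoms.values():
            serial += 1
            x, y, z = atom.coords
            element = atom.name.strip().lstrip("0123456789")[0]
            lines.append(
                f"ATOM  {serial:5d} {atom.name:<4s} {nt.code:>3s} {structure.chain:1s}"
                f"{nt.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
    lines.append("END")
    with open(str(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_scores(structure: RNAStructure, prediction, path) -> None:
    """Plain-text score report: ``pMoL <value>`` header, then one line per
    nucleotide ``chain resindex code pNuL`` at 4 decimals."""
    pnul = np.asarray(getattr(prediction, "pnul", prediction), dtype=float)
    if pnul.shape != (structure.L,):
        raise ScoreMismatchError(
            f"score/structure mismatch: {pnul.size} scores for L={structure.L}"
        )
    pmol = getattr(prediction, "pmol", float(pnul.mean()))
    with open(str(path), "w") as fh:
        fh.write(f"pMoL {pmol:.4f}\n")
        for nt, s in zip(structure.nucleotides, pnul):
            fh.write(f"{structure.chain} {nt.index} {nt.code} {s:.4f}\n")


def read_scores(path) -> tuple[float, np.ndarray]:
    """Round-trip reader for :func:`write_scores`: returns (pMoL, pNuL)."""
    with open(str(path)) as fh:
        header = fh.readline().split()
        if len(header) != 2 or header[0] != "pMoL":
            raise ValueError(f"{path}: not a score report")
        pmol = float(header[1])
        pnul = [float(line.split()[3]) for line in fh if line.strip()]
    return pmol, np.asarray(pnul)
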