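"""Superposition-free lDDT between a model and a native RNA structure.

The local distance difference test collects every heavy-atom pair that is
closer than an inclusion radius (15 Angstrom by default) in the native
structure and lies in two *different* nucleotides, then asks what fraction
of those distances the model preserves within tolerances of 0.5, 1, 2 and
4 Angstrom, averaged over the four tolerances. No superposition is ever
computed, so the score is exactly invariant under rigid motions of either
structure. Stereochemical quality checks are disabled: every heavy atom
participates, none is removed or penalised.

Atom matching is by (residue position, atom name). Model atoms with no
native counterpart are ignored; native atoms missing from the model count
every pair they form as not preserved. Nucleotides that touch no reference
pair get an undefined (masked) score rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import RNAStructure

INCLUSION_RADIUS = 15.0
THRESHOLDS = (0.5, 1.0, 2.0, 4.0)


class StructureMismatchError(ValueError):
    """Model and native cannot be aligned positionally."""


class NoContactsError(ValueError):
    """The native structure has no reference pairs within the radius."""


@dataclass(frozen=True)
class AtomPair:
    res_i: int  # 1-based nucleotide indices, res_i < res_j
    res_j: int
    name_i: str
    name_j: str
    d_ref: float


@dataclass(frozen=True)
class LddtScores:
    """Per-nucleotide scores (NaN where undefined), a defined-mask, and the
    pooled global score (preserved fraction over all pairs, then averaged
    over thresholds — not a mean of per-nucleotide values)."""

    per_nucleotide: np.ndarray
    defined: np.ndarray
    global_: float


def _flat_atoms(s: RNAStructure):
    res_idx, names, coords = [], [], []
    for i, nt in enumerate(s.nucleotides):
        for name, atom in nt.atoms.items():
            res_idx.append(i)
            names.append(name)
            coords.append(atom.coords)
    return np.asarray(res_idx), names, np.asarray(coords, dtype=float)


def reference_pairs(native: RNAStructure, radius: float = INCLUSION_RADIUS) -> list[AtomPair]:
    """All unordered heavy-atom pairs from different nucleotides with native
    distance strictly below ``radius``, each listed once."""
    res, names, xyz = _flat_atoms(native)
    pairs = []
    if len(names) >= 2:
        tree = cKDTree(xyz)
        for a, b in sorted(tree.query_pairs(radius)):
            if res[a] == res[b]:
                continue
            if np.linalg.norm(xyz[a] - xyz[b]) >= radius:
                continue  # query_pairs is inclusive at the boundary
            i, j = (a, b) if res[a] < res[b] else (b, a)
            pairs.append(
                AtomPair(int(res[i]) + 1, int(res[j]) + 1, names[i], names[j],
                         float(np.linalg.norm(xyz[i] - xyz[j])))
            )
    return pairs


def _check_alignment(model: RNAStructure, native: RNAStructure) -> None:
    if model.L != native.L:
        raise StructureMismatchError(
            f"model/native mismatch: L={model.L} vs L={native.L}"
        )
    for m, n in zip(model.nucleotides, native.nucleotides):
        if m.code != n.code and "X" not in (m.code, n.code):
            raise StructureMismatchError(
                f"model/native mismatch at position {m.index}: {m.code} vs {n.code}"
            )


def _pair_scores(model: RNAStructure, native: RNAStructure, radius: float):
    """For each reference pair: (res_i0, res_j0, preserved-threshold fraction)."""
    pairs = reference_pairs(native, radius)
    model_atoms = [
        {name: atom.coords for name, atom in nt.atoms.items()} for nt in model.nucleotides
    ]
    n_thr = len(THRESHOLDS)
    out = np.empty((len(pairs), 3))
    for p, pair in enumerate(pairs):
        ai = model_atoms[pair.res_i - 1].get(pair.name_i)
        bj = model_atoms[pair.res_j - 1].get(pair.name_j)
        if ai is None or bj is None:
            frac = 0.0
        else:
            dev = abs(float(np.linalg.norm(ai - bj)) - pair.d_ref)
            frac = sum(dev < t for t in THRESHOLDS) / n_thr
        out[p] = (pair.res_i - 1, pair.res_j - 1, frac)
    return out


def per_nucleotide_lddt(
    model: RNAStructure, native: RNAStructure, radius: float = INCLUSION_RADIUS
) -> LddtScores:
    """Nucleotide-wise and pooled lDDT of ``model`` against ``native``."""
    _check_alignment(model, native)
    ps = _pair_scores(model, native, radius)
    L = native.L
    totals = np.zeros(L)
    counts = np.zeros(L)
    for i, j, frac in ps:
        totals[int(i)] += frac
        counts[int(i)] += 1
        totals[int(j)] += frac
        counts[int(j)] += 1
    defined = counts > 0
    per = np.full(L, np.nan)
    per[defined] = totals[defined] / counts[defined]
    glob = float(ps[:, 2].mean()) if len(ps) else float("nan")
    return LddtScores(per_nucleotide=per, defined=defined, global_=glob)


def global_lddt(
    model: RNAStructure, native: RNAStructure, radius: float = INCLUSION_RADIUS
) -> float:
    """Pooled preserved fraction over all reference pairs, averaged over the
    four thresholds."""
    _check_alignment(model, native)
    ps = _pair_scores(model, native, radius)
    if len(ps) == 0:
        raise NoContactsError("no contacts: native has no reference pairs within radius")
    return float(ps[:, 2].mean())
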