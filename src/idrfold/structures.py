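"""Structure models: reading, pLDDT extraction, secondary structure, RMSD, contacts.

AFDB model files store the per-residue pLDDT confidence in the B-factor
column of every atom; experimental PDB entries store crystallographic or
NMR B-factors there instead.  This module reads both kinds of files (PDB
or mmCIF, via gemmi) into a single lightweight :class:`StructureModel`,
and implements the structure-level analyses used downstream:

* 3-state secondary-structure assignment (H/E/C) with Kabsch–Sander
  hydrogen-bond energies,
* least-squares rigid-body superposition (Kabsch algorithm) with
  heavy-atom RMSD,
* hydrophobic (apolar carbon) contact counting within a distance cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .tracks import PLDDT_BIN_EDGES, PLDDT_BIN_NAMES

__all__ = [
    "StructureModel",
    "SuperpositionResult",
    "ContactReport",
    "StructureParseError",
    "read_structure",
    "write_pdb",
    "plddt_from_bfactor",
    "assign_ss3",
    "ss_content_by_bin",
    "superpose_rmsd",
    "hydrophobic_contacts",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Kabsch-Sander electrostatic H-bond model: E = q1*q2*(1/rON + 1/rCH - 1/rOH
# - 1/rCN)*f with q1*q2*f = 0.084*332 kcal/mol; a bond is called below -0.5.
_KS_COUPLING = 0.084 * 332.0
_KS_CUTOFF = -0.5

# Single-bond covalent radii (A) for bond inference by distance.
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
    "P": 1.07, "SE": 1.20, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
}
_BOND_TOLERANCE = 0.45


class StructureParseError(ValueError):
    """File could not be parsed as a structure."""


@dataclass
class StructureModel:
    """Atoms of one chain of one model, in file order.

    ``res_ids`` follow the author (PDB) numbering and are 1-based; within a
    chain they must be non-decreasing.  ``b_factors`` hold pLDDT values for
    AFDB files.
    """

    chain_id: str
    res_ids: np.ndarray          # (n_atoms,) int
    res_names: np.ndarray        # (n_atoms,) 3-letter codes
    atom_names: np.ndarray       # (n_atoms,) str
    elements: np.ndarray         # (n_atoms,) upper-case element symbols
    coords: np.ndarray           # (n_atoms, 3) float, A
    b_factors: np.ndarray        # (n_atoms,) float
    icodes: np.ndarray | None = None
    model_number: int = 1

    def __post_init__(self) -> None:
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.b_factors = np.asarray(self.b_factors, dtype=float)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        if self.icodes is None:
            self.icodes = np.full(len(self.res_ids), "", dtype=object)
        if len(self.res_ids) == 0:
            raise StructureParseError("structure contains no atoms")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if np.any(np.diff(self.res_ids) < 0):
            raise ValueError("residue indices decrease within the chain")

    def __len__(self) -> int:
        return len(self.res_ids)

    @property
    def is_hydrogen(self) -> np.ndarray:
        """Hydrogens are retained on reading but flagged for exclusion."""
        return np.array([e in ("H", "D") for e in self.elements])

    @property
    def residue_order(self) -> list[int]:
        """Unique residue ids in chain order."""
        seen: dict[int, None] = {}
        for r in self.res_ids:
            seen.setdefault(int(r), None)
        return list(seen)

    @property
    def n_residues(self) -> int:
        return len(self.residue_order)

    def atom_index(self, res_id: int, atom_name: str) -> int | None:
        hits = np.flatnonzero((self.res_ids == res_id) & (self.atom_names == atom_name))
        return int(hits[0]) if len(hits) else None

    def residue_atoms(self, res_id: int) -> np.ndarray:
        return np.flatnonzero(self.res_ids == res_id)

    def residue_name(self, res_id: int) -> str:
        idx = self.residue_atoms(res_id)
        if len(idx) == 0:
            raise KeyError(f"no residue {res_id}")
        return str(self.res_names[idx[0]])


def read_structure(
    path: str | Path,
    format: str | None = None,
    model_number: int = 1,
    chain_id: str | None = None,
) -> StructureModel:
    """Read one chain of one model from a PDB or mmCIF file.

    Hetero (non-polymer) residues and waters are skipped.  For multi-model
    NMR entries only ``model_number`` is returned.
    """
    path = Path(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    model = None
    for m in st:
        if m.num == model_number:
            model = m
            break
    if model is None:
        raise KeyError(
            f"model {model_number} not in {path.name}; "
            f"available: {[m.num for m in st]}"
        )
    chain = None
    for ch in model:
        if chain_id is None or ch.name == chain_id:
            chain = ch
            break
    if chain is None:
        if chain_id is None:
            raise StructureParseError(f"{path.name}: no chains with atoms")
        raise KeyError(f"chain {chain_id!r} not in model {model_number}")

    rows: list[tuple] = []
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is not None and not info.is_amino_acid():
            continue
        for atom in res:
            rows.append((
                res.seqid.num, res.name, atom.name,
                atom.element.name.upper(),
                (atom.pos.x, atom.pos.y, atom.pos.z),
                atom.b_iso, res.seqid.icode.strip(),
            ))
    if not rows:
        raise StructureParseError(f"{path.name}: no protein ATOM records")
    return StructureModel(
        chain_id=chain.name,
        res_ids=np.array([r[0] for r in rows]),
        res_names=np.array([r[1] for r in rows], dtype=object),
        atom_names=np.array([r[2] for r in rows], dtype=object),
        elements=np.array([r[3] for r in rows], dtype=object),
        coords=np.array([r[4] for r in rows]),
        b_factors=np.array([r[5] for r in rows]),
        icodes=np.array([r[6] for r in rows], dtype=object),
        model_number=model_number,
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a single-chain PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = "idrfold"
    gm = gemmi.Model(model.model_number)
    ch = gemmi.Chain(model.chain_id or "A")
    current = None
    res = None
    for i in range(len(model)):
        rid = int(model.res_ids[i])
        if rid != current:
            if res is not None:
                ch.add_residue(res)
            res = gemmi.Residue()
            res.name = str(model.res_names[i])
            res.seqid = gemmi.SeqId(rid, model.icodes[i] or " ")
            current = rid
        atom = gemmi.Atom()
        atom.name = str(model.atom_names[i])
        atom.element = gemmi.Element(str(model.elements[i]).capitalize())
        atom.pos = gemmi.Position(*model.coords[i])
        atom.b_iso = float(model.b_factors[i])
        atom.occ = 1.0
        res.add_atom(atom)
    if res is not None:
        ch.add_residue(res)
    gm.add_chain(ch)
    st.add_model(gm)
    st.write_pdb(str(path))


def plddt_from_bfactor(model: StructureModel) -> np.ndarray:
    """Per-residue pLDDT read from the CA atom's B-factor column.

    AFDB writes the same pLDDT on every atom of a residue; the CA value is
    taken as the per-residue representative.
    """
    values = []
    for rid in model.residue_order:
        idx = model.atom_index(rid, "CA")
        if idx is None:
            raise ValueError(f"residue {rid} has no CA atom")
        b = float(model.b_factors[idx])
        if not 0.0 <= b <= 100.0:
            raise ValueError(f"residue {rid}: B-factor {b} outside pLDDT range [0, 100]")
        values.append(b)
    return np.array(values)


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch-Sander, collapsed to 3 states)
# ---------------------------------------------------------------------------

def _backbone_coords(model: StructureModel) -> tuple[list[int], dict[str, np.ndarray]]:
    res_order = model.residue_order
    bb: dict[str, np.ndarray] = {}
    for name in BACKBONE_ATOMS:
        arr = np.empty((len(res_order), 3))
        for k, rid in enumerate(res_order):
            idx = model.atom_index(rid, name)
            if idx is None:
                raise ValueError(f"residue {rid} is missing backbone atom {name}")
            arr[k] = model.coords[idx]
        bb[name] = arr
    return res_order, bb


def _amide_hydrogens(bb: dict[str, np.ndarray], res_names: Sequence[str]) -> np.ndarray:
    """Ideal amide H: 1.0 A from N, opposite the bisector of C(i-1)-N-CA.

    The first residue and prolines have no amide hydrogen (NaN rows).
    """
    n = len(bb["N"])
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        if res_names[i] == "PRO":
            continue
        d1 = bb["N"][i] - bb["C"][i - 1]
        d2 = bb["N"][i] - bb["CA"][i]
        d1 /= np.linalg.norm(d1)
        d2 /= np.linalg.norm(d2)
        d = d1 + d2
        nrm = np.linalg.norm(d)
        if nrm < 1e-9:
            continue
        H[i] = bb["N"][i] + d / nrm
    return H


def _hbond_matrix(model: StructureModel) -> tuple[list[int], np.ndarray]:
    """hb[i, j] is True when the C=O of residue i accepts the N-H of residue j."""
    res_order, bb = _backbone_coords(model)
    res_names = [model.residue_name(r) for r in res_order]
    H = _amide_hydrogens(bb, res_names)
    n = len(res_order)
    hb = np.zeros((n, n), dtype=bool)
    C, O, N = bb["C"], bb["O"], bb["N"]
    for i in range(n):
        for j in range(n):
            if abs(i - j) < 2 or np.isnan(H[j]).any():
                continue
            r_on = np.linalg.norm(O[i] - N[j])
            if r_on > 5.2:  # beyond any plausible H-bond; skip the full formula
                continue
            r_ch = np.linalg.norm(C[i] - H[j])
            r_oh = np.linalg.norm(O[i] - H[j])
            r_cn = np.linalg.norm(C[i] - N[j])
            energy = _KS_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _KS_CUTOFF:
                hb[i, j] = True
    return res_order, hb


def assign_ss3(model: StructureModel) -> str:
    """Assign H/E/C per residue with Kabsch-Sander hydrogen bonds.

    Helices (3-10, alpha and pi collapsed to H) arise from two consecutive
    i -> i+n turns (n = 3, 4, 5); strands (bridge and extended collapsed to
    E) from parallel or antiparallel bridge patterns.  Everything else is
    coil.  Alpha-helix takes precedence over strand, strand over the short
    helix types, matching the DSSP ordering.
    """
    res_order, hb = _hbond_matrix(model)
    n = len(res_order)
    ss = np.full(n, "C", dtype=object)

    def turns(step: int) -> np.ndarray:
        t = np.zeros(n, dtype=bool)
        for i in range(n - step):
            if hb[i, i + step]:
                t[i] = True
        return t

    t4 = turns(4)
    for i in range(1, n - 4):
        if t4[i - 1] and t4[i]:
            ss[i : i + 4] = "H"

    # bridges
    for i in range(n):
        for j in range(i + 3, n):
            para = (
                (0 < i and i + 1 < n and hb[i - 1, j] and hb[j, i + 1])
                or (0 < j and j + 1 < n and hb[j - 1, i] and hb[i, j + 1])
            )
            anti = (
                (hb[i, j] and hb[j, i])
                or (0 < i and j + 1 < n and 0 < j and i + 1 < n
                    and hb[i - 1, j + 1] and hb[j - 1, i + 1])
            )
            if para or anti:
                for k in (i, j):
                    if ss[k] == "C":
                        ss[k] = "E"

    for step in (3, 5):
        t = turns(step)
        for i in range(1, n - step):
            if t[i - 1] and t[i]:
                for k in range(i, i + step):
                    if ss[k] == "C":
                        ss[k] = "H"
    return "".join(ss)


def ss_content_by_bin(
    ss: str,
    plddt: Sequence[float],
    bin_edges: Sequence[float] = PLDDT_BIN_EDGES,
    bin_names: Sequence[str] = PLDDT_BIN_NAMES,
) -> pd.DataFrame:
    """Percentage of H/E/C per pLDDT confidence bin.

    Rows are the non-empty bins; columns pct_H/pct_E/pct_C sum to 100.
    """
    plddt = np.asarray(plddt, dtype=float)
    if len(ss) != len(plddt):
        raise ValueError(f"ss length {len(ss)} != pLDDT length {len(plddt)}")
    idx = np.digitize(plddt, np.asarray(bin_edges)[1:-1], right=False)
    rows = {}
    ss_arr = np.array(list(ss))
    for b, name in enumerate(bin_names):
        sel = ss_arr[idx == b]
        if sel.size == 0:
            continue
        rows[name] = {
            "n": int(sel.size),
            **{f"pct_{s}": 100.0 * float((sel == s).mean()) for s in "HEC"},
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    rmsd: float
    rotation: np.ndarray     # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,), applied after rotation
    n_atoms: int


def _select_atoms(
    model: StructureModel,
    residue_selection: Iterable[int] | None,
    atom_selection: str,
) -> dict[tuple[int, str], np.ndarray]:
    wanted = set(int(r) for r in residue_selection) if residue_selection is not None else None
    is_h = model.is_hydrogen
    out: dict[tuple[int, str], np.ndarray] = {}
    for i in range(len(model)):
        rid = int(model.res_ids[i])
        if wanted is not None and rid not in wanted:
            continue
        name = str(model.atom_names[i])
        if atom_selection == "CA" and name != "CA":
            continue
        if atom_selection == "heavy" and is_h[i]:
            continue
        out[(rid, name)] = model.coords[i]
    return out


def superpose_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    residue_selection: Iterable[int] | None = None,
    atom_selection: str = "heavy",
    residue_offset: int | Mapping[int, int] = 0,
) -> SuperpositionResult:
    """Least-squares rigid superposition of b onto a; RMSD over paired atoms.

    Atoms are paired by (residue id, atom name); ``residue_offset`` maps
    residue ids of ``model_a`` onto ``model_b`` (AFDB and PDB author
    numbering often differ by a constant).  ``residue_selection`` names
    residues of ``model_a``.  Raises if any selected atom of a has no
    partner in b.
    """
    if atom_selection not in ("heavy", "CA", "all"):
        raise ValueError(f"unknown atom selection {atom_selection!r}")
    atoms_a = _select_atoms(model_a, residue_selection, atom_selection)
    if not atoms_a:
        raise ValueError("empty atom selection in model_a")

    def map_res(rid: int) -> int:
        if isinstance(residue_offset, Mapping):
            return int(residue_offset.get(rid, rid))
        return rid + int(residue_offset)

    sel_b = None if residue_selection is None else [map_res(r) for r in residue_selection]
    atoms_b = _select_atoms(model_b, sel_b, atom_selection)
    pairs_a, pairs_b, missing = [], [], []
    for (rid, name), xyz in atoms_a.items():
        key_b = (map_res(rid), name)
        if key_b in atoms_b:
            pairs_a.append(xyz)
            pairs_b.append(atoms_b[key_b])
        else:
            missing.append(f"{rid}/{name}")
    if missing:
        raise ValueError(
            f"{len(missing)} atoms of model_a have no partner in model_b: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    P = np.asarray(pairs_a)  # target
    Q = np.asarray(pairs_b)  # mobile
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    U, _, Vt = np.linalg.svd(Q0.T @ P0)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T  # rotation applied to mobile coordinates
    Q_fit = Q0 @ R.T
    rmsd = float(np.sqrt(((Q_fit - P0) ** 2).sum() / len(P)))
    translation = pc - qc @ R.T
    return SuperpositionResult(
        rmsd=rmsd, rotation=R, translation=translation, n_atoms=len(P)
    )


# ---------------------------------------------------------------------------
# Hydrophobic contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactReport:
    focal_residue: int
    pairs: list = field(default_factory=list)  # (focal atom, partner res, partner atom, distance)
    threshold: float = 4.5

    @property
    def count(self) -> int:
        return len(self.pairs)


def _bond_adjacency(model: StructureModel) -> list[list[int]]:
    radii = np.array([
        _COVALENT_RADII.get(str(e), 0.77) for e in model.elements
    ])
    tree = cKDTree(model.coords)
    maxdist = 2 * radii.max() + _BOND_TOLERANCE
    neighbors: list[list[int]] = [[] for _ in range(len(model))]
    for i, j in tree.query_pairs(maxdist):
        d = np.linalg.norm(model.coords[i] - model.coords[j])
        if d <= radii[i] + radii[j] + _BOND_TOLERANCE and d > 0.4:
            neighbors[i].append(j)
            neighbors[j].append(i)
    return neighbors


def _hydrophobic_mask(model: StructureModel, include_sulfur: bool = False) -> np.ndarray:
    """Apolar atom typing: carbons bonded only to carbon or hydrogen.

    With ``include_sulfur``, sulfur atoms bonded only to C/H/S also count
    and sulfur neighbors do not disqualify a carbon.
    """
    neighbors = _bond_adjacency(model)
    allowed = {"C", "H", "D"} | ({"S"} if include_sulfur else set())
    mask = np.zeros(len(model), dtype=bool)
    for i in range(len(model)):
        elem = str(model.elements[i])
        if elem == "C" or (include_sulfur and elem == "S"):
            mask[i] = all(str(model.elements[j]) in allowed for j in neighbors[i])
    return mask


def hydrophobic_contacts(
    model: StructureModel,
    focal_residue: int,
    partner_range: tuple[int, int],
    threshold: float = 4.5,
    include_sulfur: bool = False,
) -> ContactReport:
    """Count apolar-carbon contacts between a focal side chain and its neighbors.

    Pairs (a, b) are counted when a is a side-chain atom of ``focal_residue``,
    b belongs to a different residue with id in ``partner_range`` (1-based,
    inclusive), both atoms are typed hydrophobic, and |a-b| <= threshold A.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    focal_idx = model.residue_atoms(focal_residue)
    if len(focal_idx) == 0:
        raise KeyError(f"focal residue {focal_residue} not in structure")
    hydrophobic = _hydrophobic_mask(model, include_sulfur)
    is_h = model.is_hydrogen
    backbone = set(BACKBONE_ATOMS) | {"OXT"}
    focal_side = [
        i for i in focal_idx
        if str(model.atom_names[i]) not in backbone and not is_h[i] and hydrophobic[i]
    ]
    lo, hi = partner_range
    partner_idx = [
        i for i in range(len(model))
        if lo <= model.res_ids[i] <= hi
        and model.res_ids[i] != focal_residue
        and hydrophobic[i] and not is_h[i]
    ]
    report = ContactReport(focal_residue=focal_residue, threshold=threshold)
    for a in focal_side:
        for b in partner_idx:
            d = float(np.linalg.norm(model.coords[a] - model.coords[b]))
            if d <= threshold:
                report.pairs.append((
                    str(model.atom_names[a]),
                    int(model.res_ids[b]),
                    str(model.atom_names[b]),
                    d,
                ))
    return report
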