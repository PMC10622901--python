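"""Secondary-structure propensity (SSP) from Ca/Cb secondary chemical shifts.

NMR 13Ca and 13Cb chemical shifts report on secondary structure: relative
to the random-coil reference for the residue type, Ca shifts move upfield
and Cb downfield in strands, and the reverse in helices.  The SSP score
averages the secondary-shift difference (dCa - dCb) over a sliding window
and normalizes it by the residue-specific value expected for fully formed
structure, so that a fully stabilized helix scores +1, a fully formed
strand -1, and an ideal random coil 0; fractional populations interpolate
linearly.

The random-coil and full-structure constants ship as an editable TSV
(``data/ssp_reference_shifts.tsv``); any table with the same columns can
be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "reference_shifts",
    "read_shift_table",
    "read_nmr_star_shifts",
    "write_shift_table",
    "secondary_shifts",
    "ssp_track",
    "ssp_vs_structure",
    "SSPAgreement",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@lru_cache(maxsize=None)
def _builtin_reference() -> pd.DataFrame:
    with resources.files("idrfold").joinpath("data/ssp_reference_shifts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return df.set_index("aa")


def reference_shifts(path: str | Path | None = None) -> pd.DataFrame:
    """Reference table indexed by one-letter residue type.

    Columns: rc_ca, rc_cb (random coil, ppm) and helix_dca/helix_dcb/
    strand_dca/strand_dcb (full-structure secondary shifts, ppm).
    """
    if path is None:
        return _builtin_reference().copy()
    return pd.read_csv(path, sep="\t", comment="#").set_index("aa")


def read_shift_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of (residue index, residue type, Ca shift, Cb shift)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["resi", "aa", "ca", "cb"],
        dtype={"resi": int, "aa": str, "ca": float, "cb": float},
    )
    observed = df[["ca", "cb"]].to_numpy()
    if np.nanmin(observed) <= 0:
        raise ValueError("chemical shifts must be positive ppm values")
    return df


def read_nmr_star_shifts(path: str | Path) -> pd.DataFrame:
    """Minimal reader for a BMRB-style NMR-STAR chemical-shift loop.

    Extracts residue index, residue type and the Ca/Cb shift values from
    the ``_Atom_chem_shift`` loop of an NMR-STAR 3 file, returning the
    same (resi, aa, ca, cb) table as :func:`read_shift_table`.  Only the
    columns needed for SSP are read; everything else is ignored.
    """
    lines = Path(path).read_text().splitlines()
    header: list[str] = []
    rows: list[list[str]] = []
    in_loop = in_header = in_body = False
    for raw in lines:
        line = raw.strip()
        if line == "loop_":
            in_loop, in_header, in_body = True, True, False
            header, loop_rows = [], []
            continue
        if not in_loop:
            continue
        if in_header and line.startswith("_"):
            header.append(line.split(".")[-1] if "." in line else line.lstrip("_"))
            continue
        if in_header:
            in_header, in_body = False, True
        if not line:
            continue
        if line == "stop_":
            if "Comp_index_ID" in header and "Atom_ID" in header:
                rows.extend(loop_rows)
            in_loop = in_body = False
            continue
        if in_body:
            loop_rows.append(line.split())
    if not rows:
        raise ValueError(f"{path}: no _Atom_chem_shift loop found")
    idx = {name: k for k, name in enumerate(header)}
    for needed in ("Comp_index_ID", "Comp_ID", "Atom_ID", "Val"):
        if needed not in idx:
            raise ValueError(f"{path}: shift loop lacks column {needed}")
    shifts: dict[int, dict] = {}
    for row in rows:
        if len(row) < len(header):
            continue
        atom = row[idx["Atom_ID"]].upper()
        if atom not in ("CA", "CB"):
            continue
        resi = int(row[idx["Comp_index_ID"]])
        aa3 = row[idx["Comp_ID"]].upper()
        entry = shifts.setdefault(
            resi, {"resi": resi, "aa": THREE_TO_ONE.get(aa3, "X"),
                   "ca": np.nan, "cb": np.nan},
        )
        entry[atom.lower()] = float(row[idx["Val"]])
    table = pd.DataFrame(sorted(shifts.values(), key=lambda e: e["resi"]))
    return table[["resi", "aa", "ca", "cb"]]


def write_shift_table(table: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# chemical shifts: residue index, residue type, Ca ppm, Cb ppm\n")
        table.to_csv(fh, sep="\t", header=False, index=False, na_rep="nan")


def secondary_shifts(
    table: pd.DataFrame, reference: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Secondary shifts: observed minus random-coil reference, per nucleus.

    Missing observations (e.g. glycine Cb) stay missing.  Raises when a
    residue type present in the table has no random-coil reference.
    """
    ref = reference if reference is not None else _builtin_reference()
    missing_types = set(table["aa"]) - set(ref.index)
    if missing_types:
        raise KeyError(
            f"no random-coil reference for residue type(s) {sorted(missing_types)}"
        )
    rc = ref.loc[table["aa"], ["rc_ca", "rc_cb"]].to_numpy()
    out = table[["resi", "aa"]].copy()
    out["dca"] = table["ca"].to_numpy() - rc[:, 0]
    out["dcb"] = table["cb"].to_numpy() - rc[:, 1]
    return out


def ssp_track(
    deltas: pd.DataFrame,
    window: int = 5,
    min_data: int = 3,
    reference: pd.DataFrame | None = None,
) -> np.ndarray:
    """Windowed, normalized SSP score per residue.

    For each residue, the secondary-shift differences (dCa - dCb, or dCa
    alone where Cb is unobserved) are summed over the centred window and
    divided by the same sum of full-structure constants — helix constants
    when the windowed sum is positive, strand constants otherwise — giving
    +1 for a fully formed helix and -1 for a fully formed strand.
    Residues whose window holds fewer than ``min_data`` observations are
    NaN (undefined), never silently 0.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    ref = reference if reference is not None else _builtin_reference()
    n = len(deltas)
    half = window // 2
    aa = deltas["aa"].to_numpy()
    dca = deltas["dca"].to_numpy(dtype=float)
    dcb = deltas["dcb"].to_numpy(dtype=float)
    helix_ca = ref.loc[aa, "helix_dca"].to_numpy(dtype=float)
    helix_cb = ref.loc[aa, "helix_dcb"].to_numpy(dtype=float)
    strand_ca = ref.loc[aa, "strand_dca"].to_numpy(dtype=float)
    strand_cb = ref.loc[aa, "strand_dcb"].to_numpy(dtype=float)

    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        num = 0.0
        den_helix = 0.0
        den_strand = 0.0
        n_obs = 0
        for j in range(lo, hi):
            has_ca = not np.isnan(dca[j])
            has_cb = not np.isnan(dcb[j])
            if has_ca and has_cb:
                num += dca[j] - dcb[j]
                den_helix += helix_ca[j] - helix_cb[j]
                den_strand += abs(strand_ca[j] - strand_cb[j])
                n_obs += 1
            elif has_ca:
                num += dca[j]
                den_helix += helix_ca[j]
                den_strand += abs(strand_ca[j])
                n_obs += 1
        if n_obs < min_data:
            continue
        den = den_helix if num >= 0 else den_strand
        if den > 0:
            out[i] = num / den
    return out


@dataclass
class SSPAgreement:
    mean_residual: float       # mean |SSP - target|
    residuals: np.ndarray      # NaN where SSP undefined
    n_compared: int


def ssp_vs_structure(ssp: np.ndarray, ss: str) -> SSPAgreement:
    """Compare an SSP track with a 3-state secondary-structure string.

    The target is +1 for H, -1 for E, 0 for C; the summary is the mean
    absolute residual over residues where SSP is defined.
    """
    ssp = np.asarray(ssp, dtype=float)
    if len(ssp) != len(ss):
        raise ValueError(f"SSP length {len(ssp)} != structure length {len(ss)}")
    target = np.array([{"H": 1.0, "E": -1.0, "C": 0.0}[s] for s in ss])
    residuals = np.abs(ssp - target)
    defined = ~np.isnan(residuals)
    if not defined.any():
        raise ValueError("no residues with defined SSP to compare")
    return SSPAgreement(
        mean_residual=float(residuals[defined].mean()),
        residuals=residuals,
        n_compared=int(defined.sum()),
    )
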