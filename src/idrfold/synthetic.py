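"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators here produce every input the analysis consumes — per-residue
pLDDT/disorder tracks, variant lists, MSAs, chemical-shift tables, and
ideal-geometry structures — with known ground truth, so that parameter
recovery can be tested end to end without any downloads.

The proteome generator emulates the empirical picture that motivates the
method: the per-residue pLDDT histogram of a real AFDB proteome is bimodal
with modes near 100 (ordered regions) and 35 (most disordered regions),
while a minority of disordered segments — the conditionally folded ones —
score high despite being disordered.  Three truncated-normal pLDDT
distributions on [0, 100] model the ordered, disordered non-folding and
disordered conditionally-folding residue classes, with default means
92, 35 and 85.

Determinism: every generator takes an explicit seed and uses one private
``numpy.random.Generator``; fixed seed means bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .structures import StructureModel, _hbond_matrix
from .tracks import ResidueTrack

__all__ = [
    "SyntheticProteomeSpec",
    "TruthLabels",
    "gen_proteome_tracks",
    "gen_variant_set",
    "gen_msa",
    "gen_shift_table",
    "gen_helix_structure",
    "gen_extended_structure",
    "gen_beta_sheet",
    "build_backbone",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

RESIDUE_CLASSES = ("ordered", "disordered_non_cf", "disordered_cf")


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """Study conditions for a synthetic proteome.

    ``plddt_params`` maps each residue class to (mean, sd) of its
    truncated-normal pLDDT distribution on [0, 100].  ``frac_disordered``
    is the fraction of residues that are disordered; of those,
    ``frac_cf_of_disordered`` sit in conditionally folded segments.
    Disordered residues are laid out in contiguous runs with a minimum
    length (default 10) plus a geometric tail (default mean 40 in total),
    so segmentation sees realistic IDR-sized stretches.  Conditionally
    folded runs get a higher floor (default 20): conditional folders are
    binding domains or motifs that fold as units — homeodomains are ~60
    residues, the phospho-stabilized 4E-BP2 fold ~37 — and are rarely as
    short as the 10-residue detection limit.
    """

    n_proteins: int = 200
    length_range: tuple[int, int] = (300, 700)
    frac_disordered: float = 0.30
    frac_cf_of_disordered: float = 0.15
    plddt_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ordered": (92.0, 6.0),
            "disordered_non_cf": (35.0, 10.0),
            "disordered_cf": (85.0, 8.0),
        }
    )
    segment_min_len: int = 10
    segment_mean_len: float = 40.0
    cf_segment_min_len: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        for name, frac in (
            ("frac_disordered", self.frac_disordered),
            ("frac_cf_of_disordered", self.frac_cf_of_disordered),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if self.length_range[0] < 1 or self.length_range[1] < self.length_range[0]:
            raise ValueError(f"bad length_range {self.length_range}")
        for cls in RESIDUE_CLASSES:
            if cls not in self.plddt_params:
                raise ValueError(f"plddt_params missing class {cls!r}")
            mu, sd = self.plddt_params[cls]
            if sd <= 0:
                raise ValueError(f"{cls}: pLDDT sd must be > 0")
            if not 0 <= mu <= 100:
                raise ValueError(f"{cls}: pLDDT mean outside [0, 100]")
        if self.segment_min_len < 1 or self.segment_mean_len < self.segment_min_len:
            raise ValueError("segment_mean_len must be >= segment_min_len >= 1")
        if self.cf_segment_min_len < self.segment_min_len:
            raise ValueError("cf_segment_min_len must be >= segment_min_len")


@dataclass
class TruthLabels:
    """Ground truth for a synthetic proteome.

    ``disordered`` / ``cf`` are per-protein boolean arrays (CF implies
    disordered); ``segments`` lists (start, end, is_cf) per protein with
    1-based inclusive coordinates.
    """

    disordered: dict[str, np.ndarray] = field(default_factory=dict)
    cf: dict[str, np.ndarray] = field(default_factory=dict)
    segments: dict[str, list[tuple[int, int, bool]]] = field(default_factory=dict)

    def residue_class(self, protein_id: str) -> np.ndarray:
        dis, cf = self.disordered[protein_id], self.cf[protein_id]
        out = np.full(len(dis), "ordered", dtype=object)
        out[dis & ~cf] = "disordered_non_cf"
        out[dis & cf] = "disordered_cf"
        return out


def _truncnorm_sample(rng, mu, sd, size):
    a, b = (0.0 - mu) / sd, (100.0 - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _partition_runs(n: int, min_len: int, mean_len: float, rng) -> list[int]:
    """Split n residues into run lengths = min_len + geometric tail."""
    if n == 0:
        return []
    tail_mean = max(mean_len - min_len, 0.0)
    lengths = []
    remaining = n
    while remaining > 0:
        if remaining < 2 * min_len:
            lengths.append(remaining)
            break
        length = min_len
        if tail_mean > 0:
            length += int(rng.geometric(1.0 / (tail_mean + 1.0))) - 1
        length = min(length, remaining)
        if remaining - length < min_len:
            length = remaining
        lengths.append(length)
        remaining -= length
    return lengths


def gen_proteome_tracks(
    spec: SyntheticProteomeSpec,
) -> tuple[list[ResidueTrack], TruthLabels]:
    """Generate per-residue pLDDT + disorder tracks with known truth.

    Disorder scores are drawn so that thresholding at 0.5 recovers the
    disordered class exactly (uniform on [0.5, 1] for disordered residues,
    [0, 0.5) otherwise).  Disordered/CF residue counts are allocated per
    protein by rounded quota, so realized proteome fractions track the spec
    tightly.
    """
    rng = np.random.default_rng(spec.seed)
    tracks: list[ResidueTrack] = []
    labels = TruthLabels()
    for p in range(spec.n_proteins):
        pid = f"SYN{p:05d}"
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        n_dis = round(spec.frac_disordered * length)
        n_cf = round(spec.frac_cf_of_disordered * n_dis)
        cf_runs = [(l, True) for l in _partition_runs(
            n_cf, spec.cf_segment_min_len,
            max(spec.segment_mean_len, spec.cf_segment_min_len), rng)]
        ncf_runs = [(l, False) for l in _partition_runs(
            n_dis - n_cf, spec.segment_min_len, spec.segment_mean_len, rng)]
        runs = cf_runs + ncf_runs
        rng.shuffle(runs)
        n_ord = length - n_dis
        # merge runs if there are not enough ordered residues to separate them
        while len(runs) > 1 and n_ord < len(runs) - 1:
            merged = runs.pop()
            runs[-1] = (runs[-1][0] + merged[0], runs[-1][1] or merged[1])
        k = len(runs)
        gaps = np.zeros(k + 1, dtype=int)
        if k:
            gaps[1:k] = 1
            extra = n_ord - (k - 1)
            gaps += rng.multinomial(extra, np.full(k + 1, 1.0 / (k + 1)))
        dis = np.zeros(length, dtype=bool)
        cf = np.zeros(length, dtype=bool)
        segments: list[tuple[int, int, bool]] = []
        pos = int(gaps[0])
        for g, (run_len, is_cf) in enumerate(runs):
            dis[pos : pos + run_len] = True
            cf[pos : pos + run_len] = is_cf
            segments.append((pos + 1, pos + run_len, is_cf))
            pos += run_len + int(gaps[g + 1])
        assert pos <= length

        plddt = np.empty(length)
        for cls, mask in (
            ("ordered", ~dis),
            ("disordered_non_cf", dis & ~cf),
            ("disordered_cf", cf),
        ):
            mu, sd = spec.plddt_params[cls]
            plddt[mask] = _truncnorm_sample(rng, mu, sd, int(mask.sum()))
        disorder = np.where(
            dis, rng.uniform(0.5, 1.0, length), rng.uniform(0.0, 0.5, length)
        )
        # avoid the (measure-zero but inclusive) upper boundary of the ordered band
        disorder[~dis] = np.minimum(disorder[~dis], np.nextafter(0.5, 0.0))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        tracks.append(ResidueTrack(
            protein_id=pid, sequence=seq, plddt=plddt, disorder=disorder,
            labels={"cf_truth": cf.copy(), "disordered_truth": dis.copy()},
        ))
        labels.disordered[pid] = dis
        labels.cf[pid] = cf
        labels.segments[pid] = segments
    return tracks, labels


def gen_variant_set(
    labels: TruthLabels,
    rates: Mapping[str, float],
    seed: int = 0,
    variant_label: str = "variant",
) -> pd.DataFrame:
    """Bernoulli-sample one variant per residue at its class rate.

    ``rates`` maps residue classes (``ordered``, ``disordered_non_cf``,
    ``disordered_cf``) to per-residue mutation probabilities; classes not
    listed get rate 0.  Returns a (protein_id, pos, label) table.
    """
    for cls, rate in rates.items():
        if cls not in RESIDUE_CLASSES:
            raise ValueError(f"unknown residue class {cls!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {cls} must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    rows = []
    for pid in labels.disordered:
        classes = labels.residue_class(pid)
        p = np.array([rates.get(c, 0.0) for c in classes])
        hits = np.flatnonzero(rng.random(len(p)) < p)
        for h in hits:
            rows.append((pid, int(h) + 1, variant_label))
    return pd.DataFrame(rows, columns=["protein_id", "pos", "label"])


def gen_msa(
    reference_seq: str,
    n_seqs: int,
    conservation: float,
    gap_rate: float,
    seed: int = 0,
):
    """Generate an MSA around a reference sequence.

    Each non-reference row copies the reference per column with probability
    ``conservation`` and substitutes a uniformly random *different* residue
    otherwise; independently, each entry is gapped with probability
    ``gap_rate``.  The reference row itself is ungapped.
    """
    from .conserve import MSA  # deferred: conserve imports nothing from here

    if not reference_seq:
        raise ValueError("reference sequence must be non-empty")
    if n_seqs < 2:
        raise ValueError("an alignment needs at least 2 sequences")
    for name, frac in (("conservation", conservation), ("gap_rate", gap_rate)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ref = np.array(list(reference_seq))
    rows = [reference_seq]
    ids = ["reference"]
    alphabet = np.array(list(AMINO_ACIDS))
    for s in range(n_seqs - 1):
        keep = rng.random(len(ref)) < conservation
        row = ref.copy()
        for i in np.flatnonzero(~keep):
            choices = alphabet[alphabet != ref[i]]
            row[i] = rng.choice(choices)
        gapped = rng.random(len(ref)) < gap_rate
        row[gapped] = "-"
        rows.append("".join(row))
        ids.append(f"homolog{s:04d}")
    return MSA(ids=ids, rows=rows, reference_index=0)


def gen_shift_table(
    ss_pattern: str,
    population: float,
    noise_ppm: float = 0.0,
    seed: int = 0,
    sequence: str | None = None,
) -> pd.DataFrame:
    """Synthesize a Cα/Cβ chemical-shift table for a secondary-structure pattern.

    Observed shift = random-coil reference + population x full-structure
    secondary-shift constant for the residue's class (H/E; C adds nothing)
    + Gaussian noise.  Returns columns (resi, aa, ca, cb); glycine has no
    Cβ and gets a missing value there.
    """
    from .ssp import reference_shifts

    if not 0.0 <= population <= 1.0:
        raise ValueError("population must lie in [0, 1]")
    bad = set(ss_pattern) - set("HEC")
    if bad:
        raise ValueError(f"unknown secondary-structure symbols {sorted(bad)}")
    rng = np.random.default_rng(seed)
    ref = reference_shifts()
    if sequence is None:
        sequence = "".join(rng.choice(list(AMINO_ACIDS), size=len(ss_pattern)))
    if len(sequence) != len(ss_pattern):
        raise ValueError("sequence and ss_pattern lengths differ")
    rows = []
    for i, (aa, ss) in enumerate(zip(sequence, ss_pattern), start=1):
        r = ref.loc[aa]
        ca = r["rc_ca"]
        cb = r["rc_cb"]
        if ss == "H":
            ca += population * r["helix_dca"]
            cb = cb + population * r["helix_dcb"] if pd.notna(cb) else cb
        elif ss == "E":
            ca += population * r["strand_dca"]
            cb = cb + population * r["strand_dcb"] if pd.notna(cb) else cb
        if noise_ppm > 0:
            ca += rng.normal(0.0, noise_ppm)
            if pd.notna(cb):
                cb += rng.normal(0.0, noise_ppm)
        rows.append((i, aa, ca, cb))
    return pd.DataFrame(rows, columns=["resi", "aa", "ca", "cb"])


# ---------------------------------------------------------------------------
# Ideal backbone geometry (internal-coordinate chain builder)
# ---------------------------------------------------------------------------

_BOND = {"N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231}
_ANGLE = {"N_CA_C": 111.2, "CA_C_N": 116.2, "C_N_CA": 121.7, "CA_C_O": 120.8}


def _place(a, b, c, r, theta_deg, chi_deg):
    """NeRF atom placement: bond length r from c, angle theta at c, torsion chi."""
    theta = np.deg2rad(theta_deg)
    chi = np.deg2rad(chi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -r * np.cos(theta),
        r * np.sin(theta) * np.cos(chi),
        r * np.sin(theta) * np.sin(chi),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(
    phis: Sequence[float],
    psis: Sequence[float],
    omega: float = 180.0,
    res_name: str = "ALA",
    first_res_id: int = 1,
    b_factor: float = 100.0,
) -> StructureModel:
    """Build an N/CA/C/O backbone from phi/psi torsions with ideal geometry."""
    n_res = len(phis)
    if n_res != len(psis):
        raise ValueError("phi and psi lists differ in length")
    if n_res < 1:
        raise ValueError("need at least one residue")
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_BOND["N_CA"], 0.0, 0.0)
    ang = np.deg2rad(180.0 - _ANGLE["N_CA_C"])
    C[0] = CA[0] + _BOND["CA_C"] * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1],
                      _BOND["C_N"], _ANGLE["CA_C_N"], psis[i - 1])
        CA[i] = _place(CA[i - 1], C[i - 1], N[i],
                       _BOND["N_CA"], _ANGLE["C_N_CA"], omega)
        C[i] = _place(C[i - 1], N[i], CA[i],
                      _BOND["CA_C"], _ANGLE["N_CA_C"], phis[i])
    for i in range(n_res):
        O[i] = _place(N[i], CA[i], C[i],
                      _BOND["C_O"], _ANGLE["CA_C_O"], psis[i] + 180.0)
    names, rids, coords = [], [], []
    for i in range(n_res):
        for name, xyz in (("N", N[i]), ("CA", CA[i]), ("C", C[i]), ("O", O[i])):
            names.append(name)
            rids.append(first_res_id + i)
            coords.append(xyz)
    elements = [n[0] for n in names]
    return StructureModel(
        chain_id="A",
        res_ids=np.array(rids),
        res_names=np.array([res_name] * len(names), dtype=object),
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        coords=np.array(coords),
        b_factors=np.full(len(names), b_factor),
    )


def gen_helix_structure(n_res: int) -> StructureModel:
    """Ideal alpha-helix backbone (phi = -57.8, psi = -47.0), B-factors 100."""
    if n_res < 4:
        raise ValueError("a helix fixture needs at least 4 residues")
    return build_backbone([-57.8] * n_res, [-47.0] * n_res)


def gen_extended_structure(n_res: int) -> StructureModel:
    """Fully extended chain (phi = psi = 180): no hydrogen-bond partners."""
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    return build_backbone([180.0] * n_res, [180.0] * n_res)


def _concat_models(a: StructureModel, b: StructureModel) -> StructureModel:
    return StructureModel(
        chain_id=a.chain_id,
        res_ids=np.concatenate([a.res_ids, b.res_ids]),
        res_names=np.concatenate([a.res_names, b.res_names]),
        atom_names=np.concatenate([a.atom_names, b.atom_names]),
        elements=np.concatenate([a.elements, b.elements]),
        coords=np.vstack([a.coords, b.coords]),
        b_factors=np.concatenate([a.b_factors, b.b_factors]),
    )


def gen_beta_sheet(n_res_per_strand: int = 8) -> StructureModel:
    """Two-strand antiparallel beta-sheet fixture.

    The second strand is a 180-degree rotation of the first placed next to
    it; the relative placement is chosen by a deterministic grid search
    that maximizes the number of Kabsch-Sander inter-strand hydrogen
    bonds, which is what the bridge criteria of the assignment need.
    """
    if n_res_per_strand < 4:
        raise ValueError("strands need at least 4 residues")
    strand = build_backbone([-139.0] * n_res_per_strand, [135.0] * n_res_per_strand)
    # principal strand direction, used to orient the search grid
    ca = strand.coords[strand.atom_names == "CA"]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    center = ca.mean(axis=0)

    best = None
    for flip_axis in (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0])):
        R = _rotation_matrix(flip_axis, 180.0)
        base = (strand.coords - center) @ R.T + center
        perp = np.cross(axis, flip_axis)
        nrm = np.linalg.norm(perp)
        if nrm < 1e-9:
            continue
        perp /= nrm
        for offset in np.arange(4.0, 6.01, 0.2):
            for shift in np.arange(-3.0, 3.01, 0.25):
                coords2 = base + offset * perp + shift * axis
                partner = replace_coords(strand, coords2, first_res_id=n_res_per_strand + 1)
                combo = _concat_models(strand, partner)
                _, hb = _hbond_matrix(combo)
                inter = int(hb[:n_res_per_strand, n_res_per_strand:].sum()
                            + hb[n_res_per_strand:, :n_res_per_strand].sum())
                if best is None or inter > best[0]:
                    best = (inter, combo)
    assert best is not None
    return best[1]


def replace_coords(
    model: StructureModel, coords: np.ndarray, first_res_id: int | None = None
) -> StructureModel:
    rids = model.res_ids
    if first_res_id is not None:
        rids = rids - rids.min() + first_res_id
    return StructureModel(
        chain_id=model.chain_id,
        res_ids=rids.copy(),
        res_names=model.res_names.copy(),
        atom_names=model.atom_names.copy(),
        elements=model.elements.copy(),
        coords=np.asarray(coords, dtype=float),
        b_factors=model.b_factors.copy(),
    )


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
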