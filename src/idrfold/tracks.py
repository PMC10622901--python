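"""Per-residue disorder/pLDDT tracks, confidence bins, and IDR segmentation.

The central object is a :class:`ResidueTrack`: one protein's amino-acid
sequence together with its per-residue AlphaFold2 pLDDT confidence (0-100)
and a per-residue disorder propensity in [0, 1].  Residues with disorder
propensity >= 0.5 are treated as disordered; maximal runs of such residues
are *IDR segments*.  Segments that additionally contain a long enough run
of confident pLDDT scores are candidates for conditional folding.

All residue coordinates are 1-based and inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PLDDT_BIN_EDGES",
    "PLDDT_BIN_NAMES",
    "ResidueTrack",
    "DisorderSegment",
    "plddt_bin_labels",
    "read_disorder_track",
    "merge_tracks",
    "bin_residues",
    "extract_idr_segments",
    "filter_segments_high_plddt",
    "proteome_summary",
    "write_segments_tsv",
    "write_disorder_track_tsv",
]

# pLDDT confidence bins: left-closed, right-open, except the last which
# includes 100.  Named after the AFDB confidence vocabulary.
PLDDT_BIN_EDGES = (0.0, 50.0, 70.0, 90.0, 100.0)
PLDDT_BIN_NAMES = ("very_low", "low", "confident", "very_confident")

DISORDER_THRESHOLD = 0.5


@dataclass
class ResidueTrack:
    """Per-residue scores for one protein.

    Attributes
    ----------
    protein_id:
        Identifier (e.g. a UniProt accession).
    sequence:
        One-letter amino-acid sequence; may be empty if unknown.
    plddt:
        Per-residue pLDDT in [0, 100].
    disorder:
        Per-residue disorder propensity in [0, 1].
    labels:
        Optional per-residue annotation arrays (e.g. ground-truth
        conditional-folding flags from a synthetic proteome, or database
        provenance strings).
    """

    protein_id: str
    sequence: str
    plddt: np.ndarray
    disorder: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.disorder = np.asarray(self.disorder, dtype=float)
        n = len(self.plddt)
        if len(self.disorder) != n:
            raise ValueError(
                f"{self.protein_id}: pLDDT length {n} != disorder length "
                f"{len(self.disorder)}"
            )
        if self.sequence and len(self.sequence) != n:
            raise ValueError(
                f"{self.protein_id}: sequence length {len(self.sequence)} != "
                f"track length {n}"
            )
        if n and (np.nanmin(self.plddt) < 0 or np.nanmax(self.plddt) > 100):
            raise ValueError(f"{self.protein_id}: pLDDT outside [0, 100]")
        if n and (np.nanmin(self.disorder) < 0 or np.nanmax(self.disorder) > 1):
            raise ValueError(f"{self.protein_id}: disorder score outside [0, 1]")

    def __len__(self) -> int:
        return len(self.plddt)

    def disordered_mask(self, threshold: float = DISORDER_THRESHOLD) -> np.ndarray:
        """Boolean mask of residues with disorder propensity >= threshold."""
        return self.disorder >= threshold


@dataclass(frozen=True)
class DisorderSegment:
    """A maximal run of consecutive disordered residues (1-based, inclusive)."""

    protein_id: str
    start: int
    end: int
    mean_plddt: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad segment bounds {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def plddt_values(self, track: ResidueTrack) -> np.ndarray:
        return track.plddt[self.start - 1 : self.end]

    def max_confident_run(self, track: ResidueTrack, min_plddt: float = 70.0) -> int:
        """Longest run of consecutive residues with pLDDT >= ``min_plddt``."""
        return _longest_true_run(self.plddt_values(track) >= min_plddt)


def _longest_true_run(mask: np.ndarray) -> int:
    best = cur = 0
    for flag in mask:
        cur = cur + 1 if flag else 0
        best = max(best, cur)
    return best


def plddt_bin_labels(plddt: np.ndarray) -> np.ndarray:
    """Assign each pLDDT value to a named confidence bin.

    Bins are [0,50), [50,70), [70,90), [90,100]; 100 falls in the last bin.
    """
    plddt = np.asarray(plddt, dtype=float)
    if plddt.size and (plddt.min() < 0 or plddt.max() > 100):
        raise ValueError("pLDDT outside [0, 100]")
    idx = np.digitize(plddt, PLDDT_BIN_EDGES[1:-1], right=False)
    return np.array(PLDDT_BIN_NAMES, dtype=object)[idx]


def read_disorder_track(path: str | Path) -> dict[str, np.ndarray]:
    """Read per-residue disorder scores from a TSV of (protein id, pos, score).

    Positions must be contiguous from 1 within each protein and scores must
    lie in [0, 1].  Lines starting with '#' are ignored.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["protein_id", "pos", "score"],
        dtype={"protein_id": str, "pos": int, "score": float},
    )
    tracks: dict[str, np.ndarray] = {}
    for pid, sub in df.groupby("protein_id", sort=False):
        pos = sub["pos"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(f"{pid}: positions not contiguous from 1")
        scores = sub["score"].to_numpy()
        if scores.min() < 0 or scores.max() > 1:
            raise ValueError(f"{pid}: disorder score outside [0, 1]")
        tracks[pid] = scores
    return tracks


def write_disorder_track_tsv(tracks: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# disorder track: protein_id, 1-based position, score in [0,1]\n")
        for pid, scores in tracks.items():
            for i, s in enumerate(scores, start=1):
                fh.write(f"{pid}\t{i}\t{s:.4f}\n")


def merge_tracks(
    plddt: Sequence[float],
    disorder: Sequence[float],
    sequence: str = "",
    protein_id: str = "",
    labels: dict | None = None,
) -> ResidueTrack:
    """Combine a pLDDT track and a disorder track of equal length."""
    if len(plddt) != len(disorder):
        raise ValueError(
            f"length mismatch: pLDDT has {len(plddt)} residues, "
            f"disorder has {len(disorder)}"
        )
    return ResidueTrack(
        protein_id=protein_id,
        sequence=sequence,
        plddt=np.asarray(plddt, dtype=float),
        disorder=np.asarray(disorder, dtype=float),
        labels=dict(labels or {}),
    )


def bin_residues(
    tracks: Iterable[ResidueTrack],
    disorder_threshold: float = DISORDER_THRESHOLD,
) -> pd.DataFrame:
    """Count residues per (order class x pLDDT confidence bin).

    Returns a DataFrame indexed by (order_class, plddt_bin) with columns
    ``count``, ``fraction_of_class`` and ``fraction_of_total``.  Fractions
    within each order class sum to 1; counts sum to the total residue count.
    """
    tracks = list(tracks)
    if not tracks or sum(len(t) for t in tracks) == 0:
        raise ValueError("no residues to bin")
    rows = []
    for t in tracks:
        mask = t.disordered_mask(disorder_threshold)
        bins = plddt_bin_labels(t.plddt)
        rows.append(pd.DataFrame({
            "order_class": np.where(mask, "disordered", "ordered"),
            "plddt_bin": bins,
        }))
    df = pd.concat(rows, ignore_index=True)
    counts = (
        df.groupby(["order_class", "plddt_bin"], sort=False).size().rename("count")
    )
    full_index = pd.MultiIndex.from_product(
        [["ordered", "disordered"], list(PLDDT_BIN_NAMES)],
        names=["order_class", "plddt_bin"],
    )
    counts = counts.reindex(full_index, fill_value=0)
    out = counts.to_frame()
    class_totals = out.groupby(level="order_class")["count"].transform("sum")
    with np.errstate(invalid="ignore"):
        out["fraction_of_class"] = np.where(
            class_totals > 0, out["count"] / class_totals, np.nan
        )
    out["fraction_of_total"] = out["count"] / out["count"].sum()
    return out


def extract_idr_segments(
    track: ResidueTrack,
    disorder_threshold: float = DISORDER_THRESHOLD,
    min_len: int = 1,
) -> list[DisorderSegment]:
    """Maximal runs of consecutive disordered residues, length >= min_len.

    Segments are returned sorted by start and never overlap; their union is
    exactly the set of residues at or above the disorder threshold (before
    the length filter).
    """
    mask = track.disordered_mask(disorder_threshold)
    segments: list[DisorderSegment] = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                segments.append(DisorderSegment(
                    protein_id=track.protein_id,
                    start=i + 1,
                    end=j + 1,
                    mean_plddt=float(track.plddt[i : j + 1].mean()),
                ))
            i = j + 1
        else:
            i += 1
    return segments


def filter_segments_high_plddt(
    segments: Iterable[DisorderSegment],
    tracks: Mapping[str, ResidueTrack] | Iterable[ResidueTrack],
    min_plddt: float = 70.0,
    min_consecutive: int = 10,
) -> list[DisorderSegment]:
    """Keep segments containing >= min_consecutive consecutive residues with
    pLDDT >= min_plddt (the conditional-folding candidate filter)."""
    track_map = _as_track_map(tracks)
    kept = []
    for seg in segments:
        track = track_map[seg.protein_id]
        if seg.max_confident_run(track, min_plddt) >= min_consecutive:
            kept.append(seg)
    return kept


def _as_track_map(tracks) -> Mapping[str, ResidueTrack]:
    if isinstance(tracks, Mapping):
        return tracks
    return {t.protein_id: t for t in tracks}


def proteome_summary(
    tracks: Iterable[ResidueTrack],
    thresholds: Sequence[float] = (70.0, 90.0),
    disorder_threshold: float = DISORDER_THRESHOLD,
) -> dict:
    """Proteome-scale disorder / conditional-folding fractions.

    Reports the percentage of residues that are disordered, the percentage
    of *disordered* residues at or above each pLDDT threshold, and the
    product of the two (percentage of all residues in confidently predicted
    IDRs, an upper bound on the conditionally folded residue fraction).
    """
    tracks = list(tracks)
    total = sum(len(t) for t in tracks)
    if total == 0:
        raise ValueError("no residues")
    dis_plddt = np.concatenate(
        [t.plddt[t.disordered_mask(disorder_threshold)] for t in tracks]
    ) if tracks else np.array([])
    n_dis = len(dis_plddt)
    summary: dict = {
        "n_residues": int(total),
        "n_disordered": int(n_dis),
        "pct_disordered": 100.0 * n_dis / total,
    }
    for thr in thresholds:
        key = f"pct_disordered_plddt_ge_{thr:g}"
        if n_dis == 0:
            summary[key] = None
            summary[f"pct_total_cf_plddt_ge_{thr:g}"] = None
        else:
            frac = float((dis_plddt >= thr).mean())
            summary[key] = 100.0 * frac
            summary[f"pct_total_cf_plddt_ge_{thr:g}"] = (
                100.0 * frac * n_dis / total
            )
    return summary


def write_segments_tsv(
    segments: Iterable[DisorderSegment],
    tracks,
    path: str | Path,
    min_plddt: float = 70.0,
) -> None:
    """Write segments as TSV; coordinates are 1-based inclusive (see header)."""
    track_map = _as_track_map(tracks)
    with open(path, "w") as fh:
        fh.write("# IDR segments; start/end are 1-based inclusive residue positions\n")
        fh.write(
            "protein_id\tstart\tend\tlength\tmean_plddt\t"
            f"max_run_plddt_ge_{min_plddt:g}\n"
        )
        for seg in segments:
            run = seg.max_confident_run(track_map[seg.protein_id], min_plddt)
            fh.write(
                f"{seg.protein_id}\t{seg.start}\t{seg.end}\t{seg.length}\t"
                f"{seg.mean_plddt:.2f}\t{run}\n"
            )


def write_summary_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
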