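"""Per-residue mutational burden of pLDDT-classified regions.

Variants (e.g. disease-associated mutations versus population
polymorphisms) are mapped onto each protein's residue classes — ordered
or disordered, the latter split by pLDDT confidence bin — and summarized
as per-residue burdens (mutations / residues).  Class contrasts are
expressed as burden fold-ratios and tested with a two-sided Fisher exact
test computed by exact integer hypergeometric enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb, inf
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks import ResidueTrack, plddt_bin_labels

__all__ = [
    "FisherResult",
    "read_variants_tsv",
    "write_variants_tsv",
    "residue_region_classes",
    "map_variants_to_classes",
    "map_variants_to_intervals",
    "burden_table",
    "fold_ratio",
    "fisher_exact",
]


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    """Read a variant table of (protein id, 1-based position, class label)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["protein_id", "pos", "label"],
        dtype={"protein_id": str, "pos": int, "label": str},
    )
    return df


def write_variants_tsv(variants: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# variants: protein_id, 1-based position, class label\n")
        variants.to_csv(fh, sep="\t", header=False, index=False)


def residue_region_classes(
    track: ResidueTrack, disorder_threshold: float = 0.5
) -> np.ndarray:
    """Region class per residue: 'ordered' or 'idr_<plddt bin>'."""
    bins = plddt_bin_labels(track.plddt)
    dis = track.disordered_mask(disorder_threshold)
    return np.where(dis, np.char.add("idr_", bins.astype(str)), "ordered")


def map_variants_to_classes(
    variants: pd.DataFrame,
    tracks: Mapping[str, ResidueTrack] | Iterable[ResidueTrack],
    disorder_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each variant to its residue's region class.

    Returns (counts, excluded): ``counts`` has one row per (region class x
    variant label) with the number of variants; ``excluded`` lists
    variants with unknown protein ids or out-of-range positions.  Every
    input variant lands in exactly one of the two tables.
    """
    if not isinstance(tracks, Mapping):
        tracks = {t.protein_id: t for t in tracks}
    class_cache = {
        pid: residue_region_classes(t, disorder_threshold) for pid, t in tracks.items()
    }
    assigned_rows = []
    excluded_rows = []
    for row in variants.itertuples(index=False):
        pid, pos, label = row.protein_id, int(row.pos), row.label
        if pid not in class_cache:
            excluded_rows.append((pid, pos, label, "unknown protein"))
            continue
        classes = class_cache[pid]
        if not 1 <= pos <= len(classes):
            excluded_rows.append((pid, pos, label, "position out of range"))
            continue
        assigned_rows.append((str(classes[pos - 1]), label))
    if excluded_rows:
        warnings.warn(f"excluded {len(excluded_rows)} variants", stacklevel=2)
    counts = (
        pd.DataFrame(assigned_rows, columns=["region_class", "label"])
        .groupby(["region_class", "label"]).size().rename("count").reset_index()
    )
    excluded = pd.DataFrame(
        excluded_rows, columns=["protein_id", "pos", "label", "reason"]
    )
    return counts, excluded


def map_variants_to_intervals(
    variants: pd.DataFrame, intervals: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign variants to region classes given as intervals.

    ``intervals`` has columns (protein_id, start, end, region_class) with
    1-based inclusive coordinates — e.g. domain annotations instead of
    disorder tracks.  A variant outside every interval is excluded with
    a reason; overlapping intervals assign the first match in file order.
    """
    by_protein: dict[str, list] = {}
    for row in intervals.itertuples(index=False):
        by_protein.setdefault(str(row.protein_id), []).append(
            (int(row.start), int(row.end), str(row.region_class))
        )
    assigned, excluded = [], []
    for row in variants.itertuples(index=False):
        pid, pos, label = str(row.protein_id), int(row.pos), row.label
        hit = None
        for start, end, cls in by_protein.get(pid, []):
            if start <= pos <= end:
                hit = cls
                break
        if hit is None:
            excluded.append((pid, pos, label, "no covering interval"))
        else:
            assigned.append((hit, label))
    counts = (
        pd.DataFrame(assigned, columns=["region_class", "label"])
        .groupby(["region_class", "label"]).size().rename("count").reset_index()
    )
    return counts, pd.DataFrame(
        excluded, columns=["protein_id", "pos", "label", "reason"]
    )


def residue_totals(
    tracks: Mapping[str, ResidueTrack] | Iterable[ResidueTrack],
    disorder_threshold: float = 0.5,
) -> pd.Series:
    """Number of residues per region class across the whole track set."""
    if not isinstance(tracks, Mapping):
        tracks = {t.protein_id: t for t in tracks}
    all_classes = np.concatenate([
        residue_region_classes(t, disorder_threshold) for t in tracks.values()
    ])
    values, counts = np.unique(all_classes, return_counts=True)
    return pd.Series(counts, index=values, name="n_residues")


def burden_table(counts: pd.DataFrame, totals: pd.Series) -> pd.DataFrame:
    """Per-residue burden per (region class x variant label).

    burden = mutation count / residue count of the region class.  Classes
    with zero residues are reported absent rather than dividing by zero.
    """
    rows = []
    for row in counts.itertuples(index=False):
        total = totals.get(row.region_class, 0)
        if total <= 0:
            continue
        rows.append((
            row.region_class, row.label, int(row.count), int(total),
            row.count / total,
        ))
    return pd.DataFrame(
        rows, columns=["region_class", "label", "n_mutations", "n_residues", "burden"]
    )


def fold_ratio(table: pd.DataFrame, class_a: str, class_b: str, label: str) -> float:
    """Burden fold-ratio of class_a over class_b for one variant label."""
    sub = table[table["label"] == label].set_index("region_class")["burden"]
    if class_a not in sub.index or class_b not in sub.index:
        raise KeyError(f"classes {class_a!r}/{class_b!r} not both present")
    if sub[class_b] == 0:
        return inf
    return float(sub[class_a] / sub[class_b])


@dataclass
class FisherResult:
    p: float
    odds_ratio: float  # ad/bc; inf when bc = 0, nan for 0/0
    table: tuple[int, int, int, int]


def fisher_exact(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    p is the total hypergeometric probability of all tables with the same
    margins whose probability does not exceed that of the observed table.
    Computed in exact rational arithmetic, so the "not exceed" comparison
    is free of floating-point fuzz.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells) or any(x != int(x) for x in cells):
        raise ValueError("table entries must be non-negative integers")
    if sum(cells) == 0:
        raise ValueError("all-zero table")
    a, b, c, d = (int(x) for x in cells)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    p = float(sum(pr for pr in probs.values() if pr <= p_obs))
    if b * c == 0:
        odds = float("nan") if a * d == 0 else inf
    else:
        odds = a * d / (b * c)
    return FisherResult(p=min(p, 1.0), odds_ratio=odds, table=(a, b, c, d))
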