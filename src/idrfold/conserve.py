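"""Positional conservation and alignment depth on MSAs; rank-sum comparisons.

The conservation statistic follows the "identity to reference, ignoring
gaps" convention: for every column where the reference has a residue, the
fraction of non-gap entries in the other rows that match the reference
residue.  A column-majority variant is available for sensitivity analysis.

Alignment depth is the fraction of rows with a residue (non-gap) in each
reference column.  Both statistics are compared across pLDDT classes with
a Mann-Whitney rank-sum test (exact enumeration for small samples,
tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO
from scipy.stats import norm, rankdata

__all__ = [
    "MSA",
    "ConservationResult",
    "RankTestResult",
    "read_msa",
    "write_msa_fasta",
    "positional_conservation",
    "alignment_depth",
    "mann_whitney_u",
]

GAP = "-"


@dataclass
class MSA:
    """Aligned rows of equal length with a designated reference row."""

    ids: list[str]
    rows: list[str]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        ref = self.rows[self.reference_index]
        if set(ref) == {GAP}:
            raise ValueError("reference row is all gaps")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def reference(self) -> str:
        return self.rows[self.reference_index]

    def as_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="<U1")


def read_msa(path: str | Path, format: str = "fasta", reference_id: str | None = None) -> MSA:
    """Read an aligned FASTA (or Stockholm) file.

    The reference row is the first record unless ``reference_id`` names
    another one.
    """
    aln = AlignIO.read(str(path), format)
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper() for rec in aln]
    ref_idx = 0
    if reference_id is not None:
        try:
            ref_idx = ids.index(reference_id)
        except ValueError:
            raise KeyError(f"reference id {reference_id!r} not in alignment") from None
    return MSA(ids=ids, rows=rows, reference_index=ref_idx)


def write_msa_fasta(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")


@dataclass
class ConservationResult:
    per_column: np.ndarray  # NaN where undefined / reference-gap
    mean: float
    n_columns: int          # reference non-gap columns
    n_excluded: int         # columns with no non-reference residue


def positional_conservation(msa: MSA, mode: str = "reference") -> ConservationResult:
    """Per-column and mean conservation over reference non-gap columns.

    ``mode='reference'`` (default): fraction of non-gap, non-reference
    entries equal to the reference residue.  ``mode='majority'``: fraction
    equal to the column's most common residue (gaps excluded).  Columns
    where no other row has a residue are excluded from the mean.
    """
    if mode not in ("reference", "majority"):
        raise ValueError(f"unknown conservation mode {mode!r}")
    arr = msa.as_array()
    others = np.delete(arr, msa.reference_index, axis=0)
    ref = arr[msa.reference_index]
    per_col = np.full(msa.n_cols, np.nan)
    n_excluded = 0
    n_ref_cols = 0
    for c in range(msa.n_cols):
        if ref[c] == GAP:
            continue
        n_ref_cols += 1
        col = others[:, c]
        col = col[col != GAP]
        if col.size == 0:
            n_excluded += 1
            continue
        if mode == "reference":
            target = ref[c]
        else:
            residues, counts = np.unique(col, return_counts=True)
            target = residues[counts.argmax()]
        per_col[c] = float((col == target).mean())
    defined = per_col[~np.isnan(per_col)]
    mean = float(defined.mean()) if defined.size else float("nan")
    return ConservationResult(
        per_column=per_col, mean=mean, n_columns=n_ref_cols, n_excluded=n_excluded
    )


def alignment_depth(msa: MSA) -> ConservationResult:
    """Fraction of rows with a residue, per reference non-gap column."""
    arr = msa.as_array()
    ref = arr[msa.reference_index]
    per_col = np.full(msa.n_cols, np.nan)
    n_ref_cols = 0
    for c in range(msa.n_cols):
        if ref[c] == GAP:
            continue
        n_ref_cols += 1
        per_col[c] = float((arr[:, c] != GAP).mean())
    defined = per_col[~np.isnan(per_col)]
    mean = float(defined.mean()) if defined.size else float("nan")
    return ConservationResult(
        per_column=per_col, mean=mean, n_columns=n_ref_cols, n_excluded=0
    )


@dataclass
class RankTestResult:
    u: float           # U statistic of sample_a (rank-sum convention)
    z: float | None    # normal approximation; None in exact mode
    p: float           # two-sided
    n1: int
    n2: int
    method: str


_EXACT_LIMIT = 20


def mann_whitney_u(sample_a, sample_b, mode: str = "auto") -> RankTestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    ``mode='exact'`` enumerates all rank assignments (n1 + n2 <= 20);
    ``mode='normal'`` uses the tie-corrected normal approximation with
    continuity correction; ``mode='auto'`` picks exact when feasible.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    if mode == "auto":
        mode = "exact" if n1 + n2 <= _EXACT_LIMIT else "normal"
    if mode not in ("exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if mode == "exact":
        if n1 + n2 > _EXACT_LIMIT:
            raise ValueError(
                f"exact mode limited to n1+n2 <= {_EXACT_LIMIT}; use mode='normal'"
            )
        mu = n1 * n2 / 2.0
        obs_dev = abs(u - mu)
        total = 0
        extreme = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u_perm = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                extreme += 1
        p = extreme / total
        return RankTestResult(u=u, z=None, p=p, n1=n1, n2=n2, method="exact")

    # tie-corrected normal approximation with continuity correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankTestResult(u=u, z=0.0, p=1.0, n1=n1, n2=n2, method="normal")
    mu = n1 * n2 / 2.0
    dev = abs(u - mu)
    z = (dev - 0.5) / math.sqrt(var) if dev > 0.5 else 0.0
    p = float(min(1.0, 2.0 * norm.sf(z)))
    return RankTestResult(u=u, z=z, p=p, n1=n1, n2=n2, method="normal")
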