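"""Amino-acid composition, charge-hydropathy features, and PDB hit rates.

Composition contrasts between residue classes (ordered regions, IDRs with
low pLDDT, IDRs with high pLDDT) are expressed as percent changes of the
relative amino-acid percentages.  Charge-hydropathy (CH) features place a
sequence on the Uversky plane: mean Kyte-Doolittle hydropathy rescaled to
[0, 1] versus mean absolute net charge, with the empirical boundary line
<R> = 2.785 <H> - 1.151 separating ordered from disordered sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STANDARD_AA",
    "KYTE_DOOLITTLE",
    "CHFeatures",
    "aa_frequencies",
    "composition_delta",
    "delta_difference",
    "ch_features",
    "pdb_hit_rate",
    "read_fasta_sequences",
]

STANDARD_AA = tuple("ACDEFGHIKLMNPQRSTVWY")

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Uversky boundary in the (mean hydropathy, mean net charge) plane.
CH_BOUNDARY_SLOPE = 2.785
CH_BOUNDARY_INTERCEPT = -1.151

POSITIVE_AA = ("K", "R")
NEGATIVE_AA = ("D", "E")


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def aa_frequencies(sequences: str | Iterable[str]) -> pd.Series:
    """Percentage of each of the 20 standard amino acids.

    Non-standard letters (X, B, Z, U, ...) are dropped with a warning
    carrying the count.  Raises if nothing usable remains.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = pd.Series(0, index=list(STANDARD_AA), dtype=float)
    n_dropped = 0
    for seq in sequences:
        for aa in seq.upper():
            if aa in counts.index:
                counts[aa] += 1
            else:
                n_dropped += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no standard residues in input")
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} non-standard residues", stacklevel=2
        )
    return 100.0 * counts / total


def composition_delta(f_ref: pd.Series, f_other: pd.Series) -> pd.Series:
    """Percent change of amino-acid percentages of f_ref relative to f_other.

    delta(aa) = 100 * (f_ref - f_other) / f_other; positive means the
    amino acid is enriched in the reference class.  Amino acids absent
    from f_other get NaN (undefined) rather than raising.
    """
    f_ref = f_ref.reindex(list(STANDARD_AA))
    f_other = f_other.reindex(list(STANDARD_AA))
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 100.0 * (f_ref - f_other) / f_other
    return delta.where(f_other > 0)


def delta_difference(delta_a: pd.Series, delta_b: pd.Series) -> pd.Series:
    """Elementwise delta_a - delta_b; NaN entries propagate."""
    return delta_a.reindex(list(STANDARD_AA)) - delta_b.reindex(list(STANDARD_AA))


@dataclass
class CHFeatures:
    mean_hydropathy: float  # <H>, Kyte-Doolittle rescaled to [0, 1]
    mean_net_charge: float  # <R> = |#(K,R) - #(D,E)| / length
    boundary_side: str      # "disordered" if above the Uversky line
    n_residues: int
    n_dropped: int


def ch_features(sequence: str) -> CHFeatures:
    """Charge-hydropathy features of a sequence.

    <H> is the mean Kyte-Doolittle hydropathy mapped to [0, 1] via
    (KD + 4.5) / 9, without window smoothing.  <R> counts K/R as +1 and
    D/E as -1 (H and other titratable residues neutral) and takes the
    absolute mean.  The sequence is called disordered when <R> lies above
    the boundary line.
    """
    seq = [aa for aa in sequence.upper() if aa in KYTE_DOOLITTLE]
    n_dropped = len(sequence) - len(seq)
    if not seq:
        raise ValueError("no standard residues in sequence")
    h = float(np.mean([(KYTE_DOOLITTLE[aa] + 4.5) / 9.0 for aa in seq]))
    net = sum(aa in POSITIVE_AA for aa in seq) - sum(aa in NEGATIVE_AA for aa in seq)
    r = abs(net) / len(seq)
    boundary = CH_BOUNDARY_SLOPE * h + CH_BOUNDARY_INTERCEPT
    side = "disordered" if r > boundary else "ordered"
    return CHFeatures(
        mean_hydropathy=h, mean_net_charge=r, boundary_side=side,
        n_residues=len(seq), n_dropped=n_dropped,
    )


def pdb_hit_rate(
    blast_hits: pd.DataFrame | str | Path,
    query_classes: Mapping[str, str],
    evalue_cutoffs: Sequence[float] = (1e-3, 1e-6),
    query_col: int = 0,
    evalue_col: int = 10,
) -> pd.DataFrame:
    """Fraction of queries per class with a BLAST hit below each E-value cutoff.

    ``blast_hits`` is an outfmt-6-style tab-separated table (or a path to
    one); only the query-id and E-value columns are used and their
    positions are configurable.  Queries appearing in the hit table but
    not in ``query_classes`` are excluded with a warning.  Queries with no
    hits count in the denominator of their class.
    """
    if not isinstance(blast_hits, pd.DataFrame):
        path = Path(blast_hits)
        if path.stat().st_size == 0:
            blast_hits = pd.DataFrame(columns=[query_col, evalue_col])
        else:
            blast_hits = pd.read_csv(path, sep="\t", header=None, comment="#")
    if len(blast_hits):
        hits = blast_hits[[blast_hits.columns[query_col], blast_hits.columns[evalue_col]]]
        hits.columns = ["query", "evalue"]
        hits = hits.astype({"query": str, "evalue": float})
        unknown = set(hits["query"]) - set(query_classes)
        if unknown:
            warnings.warn(
                f"{len(unknown)} queries not in the class map; excluded",
                stacklevel=2,
            )
            hits = hits[hits["query"].isin(query_classes)]
        best = hits.groupby("query")["evalue"].min()
    else:
        best = pd.Series(dtype=float)

    classes = pd.Series(query_classes, dtype=str)
    rows = {}
    for cls, members in classes.groupby(classes):
        queries = members.index
        n = len(queries)
        best_e = best.reindex(queries)
        rows[cls] = {
            "n_queries": n,
            **{
                f"hit_rate_evalue_lt_{cut:g}": float((best_e < cut).sum()) / n
                for cut in evalue_cutoffs
            },
        }
    return pd.DataFrame.from_dict(rows, orient="index")
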