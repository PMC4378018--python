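"""Normalized dinucleotide content (O/E ratios) of coding sequences.

The observed/expected ratio of a dinucleotide XpY over a sequence window is

    O/E = (n_XY / D) / ((n_X / L') * (n_Y / L'))

where n_XY counts overlapping XpY occurrences, D is the number of
dinucleotide positions whose two bases are both unambiguous, and n_X, n_Y
are mononucleotide counts over the L' unambiguous positions.  For CpG the
ratio is a sequence-level signature of historical germline methylation:
methylated cytosines deaminate to thymine over evolutionary time, so
heavily methylated gene bodies become CpG-depleted (low CpG O/E) while
gaining TpG.  GpC, which is not a methylation target, serves as a control.

Gene-level profiles are computed on the 5' window of each coding sequence
(default 1 kb), with short sequences and extreme CpG O/E values flagged so
they can be excluded downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "CodingSequence",
    "DinucleotideProfile",
    "ProfileStatus",
    "read_fasta",
    "analysis_window",
    "normalized_dinucleotide_content",
    "compute_profiles",
    "profiles_to_frame",
    "write_profiles",
    "read_profiles",
]

# A/C/G/T -> 0..3 (U treated as T); anything else (IUPAC ambiguity, N, gaps) -> 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("U")] = _CODE[ord("u")] = 3

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


class ProfileStatus(str, Enum):
    PASS = "PASS"
    TOO_SHORT = "TOO_SHORT"
    OUT_OF_BOUNDS = "OUT_OF_BOUNDS"
    UNDEFINED = "UNDEFINED"


@dataclass(frozen=True)
class CodingSequence:
    """One coding sequence record: unique gene id plus nucleotide string."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.gene_id}: sequence must be non-empty")


@dataclass(frozen=True)
class DinucleotideProfile:
    """Per-gene O/E statistics on the analysis window, with a filter flag.

    ``None`` marks an undefined ratio (a zero count in the denominator).
    Only ``status == PASS`` genes enter downstream analyses; other genes
    carry their computed values for reporting.
    """

    gene_id: str
    length_used: int
    cpg_oe: float | None
    gpc_oe: float | None
    tpg_oe: float | None
    status: ProfileStatus


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read coding sequences from a FASTA file.

    The gene id is the first whitespace-delimited token of the header and
    sequences are upper-cased.  Raises on duplicate ids and on files that
    do not start with a header line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA, line {lineno} is not a header: "
                    f"{line.strip()[:60]!r}"
                )
            break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records = [
        CodingSequence(gene_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.gene_id] = seen.get(rec.gene_id, 0) + 1
    dups = sorted(g for g, c in seen.items() if c > 1)
    if dups:
        raise ValueError(f"{path}: duplicate gene ids: {', '.join(dups)}")
    return records


def analysis_window(sequence: str, window_length: int = 1000) -> str:
    """Return the 5'-most ``min(len, window_length)`` bases of a sequence."""
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    return sequence[:window_length]


def _encode(window: str) -> np.ndarray:
    return _CODE[np.frombuffer(window.encode("ascii"), dtype=np.uint8)]


def _oe_from_codes(codes: np.ndarray, x: int, y: int) -> float | None:
    valid = codes < 4
    l_prime = int(valid.sum())
    pair_valid = valid[:-1] & valid[1:]
    d = int(pair_valid.sum())
    n_x = int(np.count_nonzero(codes == x))
    n_y = int(np.count_nonzero(codes == y))
    if n_x == 0 or n_y == 0 or d == 0:
        return None
    n_xy = int(np.count_nonzero((codes[:-1] == x) & (codes[1:] == y)))
    return (n_xy / d) / ((n_x / l_prime) * (n_y / l_prime))


def normalized_dinucleotide_content(window: str, first: str, second: str) -> float | None:
    """O/E ratio of the dinucleotide ``first``+``second`` over a window.

    Returns ``None`` when a required mononucleotide count, or the number of
    unambiguous dinucleotide positions, is zero.
    """
    if len(window) < 2:
        raise ValueError("window must be at least 2 bases long")
    try:
        x = _BASE_INDEX[first.upper()]
        y = _BASE_INDEX[second.upper()]
    except KeyError as exc:
        raise ValueError(f"unrecognized base: {exc.args[0]!r}") from None
    return _oe_from_codes(_encode(window), x, y)


def compute_profiles(
    records: Iterable[CodingSequence],
    window_length: int = 1000,
    min_length: int = 300,
    lower_bound: float = 0.001,
    upper_bound: float = 2.0,
) -> list[DinucleotideProfile]:
    """Compute CpG, GpC and TpG O/E profiles for a set of coding sequences.

    Filtering rules: sequences shorter than ``min_length`` are flagged
    TOO_SHORT; genes whose CpG O/E is undefined (zero C or G count in the
    window) are flagged UNDEFINED; genes with CpG O/E outside the inclusive
    interval [``lower_bound``, ``upper_bound``] are flagged OUT_OF_BOUNDS.
    """
    if window_length < 2 or min_length < 1:
        raise ValueError("window_length and min_length must be positive")
    if not (0 < lower_bound < upper_bound):
        raise ValueError("require 0 < lower_bound < upper_bound")
    records = list(records)
    if not records:
        raise ValueError("no input records")

    profiles: list[DinucleotideProfile] = []
    for rec in records:
        seq = rec.sequence
        if len(seq) < min_length:
            profiles.append(
                DinucleotideProfile(rec.gene_id, len(seq), None, None, None,
                                    ProfileStatus.TOO_SHORT)
            )
            continue
        window = analysis_window(seq, window_length)
        codes = _encode(window)
        cpg = _oe_from_codes(codes, 1, 2)
        gpc = _oe_from_codes(codes, 2, 1)
        tpg = _oe_from_codes(codes, 3, 2)
        if cpg is None:
            status = ProfileStatus.UNDEFINED
        elif cpg < lower_bound or cpg > upper_bound:
            status = ProfileStatus.OUT_OF_BOUNDS
        else:
            status = ProfileStatus.PASS
        profiles.append(
            DinucleotideProfile(rec.gene_id, len(window), cpg, gpc, tpg, status)
        )
    return profiles


def profiles_to_frame(profiles: Sequence[DinucleotideProfile]) -> pd.DataFrame:
    """Tabulate profiles; O/E columns are NaN where undefined."""
    return pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in profiles],
            "length_used": [p.length_used for p in profiles],
            "cpg_oe": [math.nan if p.cpg_oe is None else p.cpg_oe for p in profiles],
            "gpc_oe": [math.nan if p.gpc_oe is None else p.gpc_oe for p in profiles],
            "tpg_oe": [math.nan if p.tpg_oe is None else p.tpg_oe for p in profiles],
            "status": [p.status.value for p in profiles],
        }
    )


def write_profiles(profiles: Sequence[DinucleotideProfile], path: str | Path) -> None:
    frame = profiles_to_frame(profiles)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="NA")


def read_profiles(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    required = {"gene_id", "length_used", "cpg_oe", "gpc_oe", "tpg_oe", "status"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def pass_frame(profiles: Sequence[DinucleotideProfile]) -> pd.DataFrame:
    """Profiles with PASS status, indexed by gene id — the analysis set."""
    frame = profiles_to_frame(profiles)
    return frame[frame["status"] == ProfileStatus.PASS.value].set_index("gene_id")
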