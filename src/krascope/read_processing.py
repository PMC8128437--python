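"""Pre-calling read manipulations for amplicon and MDS libraries.

Covers the four steps every downstream caller relies on: overlap merging of
read pairs, base-quality filtering, demultiplexing on 0-7 nt sample indexes
at either read end, and extraction of fixed sub-regions from the amplicon
layout.  Quality strings are Phred+33 throughout; anything else is rejected.

Merging is ungapped: the largest suffix/prefix overlap between read 1 and the
reverse complement of read 2 whose mismatch percentage is within tolerance is
accepted (defaults 20% / 10 nt).  At disagreeing overlap positions the
higher-quality base wins and the merged quality is the larger of the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .refmodel import revcomp

PHRED_OFFSET = 33
_MAX_PHRED = 60


class FastqFormatError(ValueError):
    """Malformed FASTQ record or non-Phred+33 quality string."""


class IndexTableError(ValueError):
    """Sample-index table violates its invariants."""


@dataclass(slots=True)
class SequencedRead:
    """A read with its Phred+33 quality string.

    ``mate`` is "1", "2" or "merged".
    """

    read_id: str
    sequence: str
    qualities: str
    mate: str = "merged"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FastqFormatError(
                f"read {self.read_id}: sequence and quality lengths differ"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def phred(self) -> np.ndarray:
        """Per-base Phred scores as an integer array."""
        scores = (
            np.frombuffer(self.qualities.encode("ascii"), dtype=np.uint8).astype(int)
            - PHRED_OFFSET
        )
        if len(scores) and (scores.min() < 0 or scores.max() > _MAX_PHRED):
            raise FastqFormatError(
                f"read {self.read_id}: quality scores outside Phred+33 [0, 60]"
            )
        return scores


def read_fastq(path: str | Path, mate: str = "merged") -> list[SequencedRead]:
    """Read a FASTQ file (Phred+33) into :class:`SequencedRead` records."""
    reads = []
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            reads.append(SequencedRead(title.split()[0], seq.upper(), qual, mate))
    return reads


def write_fastq(reads: Iterable[SequencedRead], path: str | Path) -> int:
    """Write reads as 4-line FASTQ records; returns the record count."""
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.qualities}\n")
            n += 1
    return n


# -- pair merging ------------------------------------------------------------


def merge_pairs(
    r1: SequencedRead,
    r2: SequencedRead,
    max_diff_pct: float = 20.0,
    min_overlap: int = 10,
) -> SequencedRead | None:
    """Overlap-merge a read pair; returns None if no qualifying overlap.

    Read 2 is reverse-complemented, then the longest ungapped suffix(r1)/
    prefix(rc r2) overlap with mismatch percentage <= ``max_diff_pct`` and
    length >= ``min_overlap`` is merged.
    """
    if not len(r1) or not len(r2):
        raise ValueError("cannot merge an empty read")
    seq2 = revcomp(r2.sequence)
    qual2 = r2.qualities[::-1]
    b1 = r1.sequence.encode("ascii")
    b2 = seq2.encode("ascii")
    n1, n2 = len(b1), len(b2)

    for overlap in range(min(n1, n2), min_overlap - 1, -1):
        allowed = int(overlap * max_diff_pct / 100.0)
        start1 = n1 - overlap
        mismatches = 0
        for i in range(overlap):
            if b1[start1 + i] != b2[i]:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            merged_seq = []
            merged_qual = []
            for i in range(overlap):
                q1, q2c = r1.qualities[start1 + i], qual2[i]
                if b1[start1 + i] == b2[i] or q1 >= q2c:
                    merged_seq.append(r1.sequence[start1 + i])
                else:
                    merged_seq.append(seq2[i])
                merged_qual.append(max(q1, q2c))
            return SequencedRead(
                read_id=r1.read_id,
                sequence=r1.sequence[:start1] + "".join(merged_seq) + seq2[overlap:],
                qualities=r1.qualities[:start1] + "".join(merged_qual) + qual2[overlap:],
                mate="merged",
            )
    return None


# -- quality filtering -------------------------------------------------------


@dataclass
class FilterReport:
    n_kept: int = 0
    n_dropped: int = 0

    @property
    def n_input(self) -> int:
        return self.n_kept + self.n_dropped


def quality_filter(
    reads: Iterable[SequencedRead], min_q: int = 20, min_fraction: float = 0.75
) -> tuple[list[SequencedRead], FilterReport]:
    """Keep reads where >= ``min_fraction`` of bases have Q >= ``min_q``.

    Both thresholds are inclusive (a read at exactly the fraction passes).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    threshold = min_q + PHRED_OFFSET
    kept: list[SequencedRead] = []
    report = FilterReport()
    for read in reads:
        n = len(read)
        good = int(
            (np.frombuffer(read.qualities.encode("ascii"), np.uint8) >= threshold).sum()
        )
        if n and good / n >= min_fraction:
            kept.append(read)
            report.n_kept += 1
        else:
            report.n_dropped += 1
    return kept, report


def filter_by_length(
    reads: Iterable[SequencedRead], min_len: int, max_len: int
) -> tuple[list[SequencedRead], FilterReport]:
    """Keep reads whose length falls in the inclusive [min_len, max_len] window."""
    if max_len < min_len:
        raise ValueError("inverted length window")
    kept = []
    report = FilterReport()
    for read in reads:
        if min_len <= len(read) <= max_len:
            kept.append(read)
            report.n_kept += 1
        else:
            report.n_dropped += 1
    return kept, report


# -- demultiplexing ----------------------------------------------------------


class SampleIndexTable:
    """Sample index assignments: 0-7 nt indexes at the 5' and/or 3' read end.

    The 3' index is stored in read orientation, i.e. as the literal suffix it
    forms on the (merged) read.
    """

    COLUMNS = ("sample_id", "five_prime_index", "three_prime_index")

    def __init__(self, rows: pd.DataFrame | Sequence[tuple[str, str, str]]):
        if not isinstance(rows, pd.DataFrame):
            rows = pd.DataFrame(rows, columns=self.COLUMNS)
        df = rows.copy()
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise IndexTableError(f"index table missing columns: {sorted(missing)}")
        df["five_prime_index"] = df["five_prime_index"].fillna("").str.upper()
        df["three_prime_index"] = df["three_prime_index"].fillna("").str.upper()
        for col in ("five_prime_index", "three_prime_index"):
            for value in df[col]:
                if not 0 <= len(value) <= 7:
                    raise IndexTableError(f"index {value!r} longer than 7 nt")
                if set(value) - set("ACGT"):
                    raise IndexTableError(f"index {value!r} contains non-ACGT bases")
        pairs = list(zip(df["five_prime_index"], df["three_prime_index"]))
        if len(set(pairs)) != len(pairs):
            raise IndexTableError("index pairs are not unique across samples")
        if df["sample_id"].duplicated().any():
            raise IndexTableError("duplicate sample_id in index table")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleIndexTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def _unique_end_map(self, column: str) -> dict[str, str]:
        mapping: dict[str, str] = {}
        for _, row in self.df.iterrows():
            idx = row[column]
            if idx in mapping and mapping[idx] != row["sample_id"]:
                raise IndexTableError(
                    f"{column} {idx!r} maps to multiple samples; demultiplex "
                    "on both ends instead"
                )
            mapping[idx] = row["sample_id"]
        return mapping


@dataclass
class DemuxResult:
    by_sample: dict[str, list[SequencedRead]]
    unmatched: list[SequencedRead]

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.by_sample.values())

    def report(self) -> pd.DataFrame:
        rows = [
            {"sample_id": sid, "n_assigned": len(reads)}
            for sid, reads in sorted(self.by_sample.items())
        ]
        rows.append({"sample_id": "unmatched", "n_assigned": len(self.unmatched)})
        return pd.DataFrame(rows)


def _warn_prefix_shadowing(indexes: Sequence[str], where: str) -> None:
    nonempty = [i for i in indexes if i]
    for a in nonempty:
        for b in nonempty:
            if a != b and b.startswith(a):
                warnings.warn(
                    f"{where} index {a!r} is a prefix of {b!r}; "
                    "longest-match rule applies",
                    stacklevel=3,
                )
                return


def demultiplex(
    reads: Iterable[SequencedRead],
    table: SampleIndexTable,
    end: str = "both",
) -> DemuxResult:
    """Assign reads to samples by exact index match at the requested end(s).

    Matching is exact (0 mismatches); the longest index is tried first, so a
    zero-length index only claims reads no non-empty index matches.  Matched
    index bases are trimmed off the assigned read.
    """
    if end not in ("five_prime", "three_prime", "both"):
        raise ValueError(f"unknown demultiplex end {end!r}")

    by_sample: dict[str, list[SequencedRead]] = {
        sid: [] for sid in table.df["sample_id"]
    }
    unmatched: list[SequencedRead] = []

    if end in ("five_prime", "three_prime"):
        column = "five_prime_index" if end == "five_prime" else "three_prime_index"
        mapping = table._unique_end_map(column)
        _warn_prefix_shadowing(list(mapping), end)
        candidates = sorted(mapping, key=len, reverse=True)
        for read in reads:
            for idx in candidates:
                if end == "five_prime":
                    hit = read.sequence.startswith(idx)
                else:
                    hit = read.sequence.endswith(idx) if idx else True
                if hit:
                    n = len(idx)
                    if end == "five_prime":
                        seq, qual = read.sequence[n:], read.qualities[n:]
                    else:
                        stop = len(read) - n if n else len(read)
                        seq, qual = read.sequence[:stop], read.qualities[:stop]
                    by_sample[mapping[idx]].append(
                        SequencedRead(read.read_id, seq, qual, read.mate)
                    )
                    break
            else:
                unmatched.append(read)
        return DemuxResult(by_sample, unmatched)

    # both ends: resolve the 5' index first, then the 3' suffix among samples
    # sharing that 5' index.
    five_groups: dict[str, list[tuple[str, str]]] = {}
    for _, row in table.df.iterrows():
        five_groups.setdefault(row["five_prime_index"], []).append(
            (row["three_prime_index"], row["sample_id"])
        )
    _warn_prefix_shadowing(list(five_groups), "five_prime")
    five_candidates = sorted(five_groups, key=len, reverse=True)
    for group in five_groups.values():
        group.sort(key=lambda pair: len(pair[0]), reverse=True)

    for read in reads:
        assigned = False
        for fidx in five_candidates:
            if not read.sequence.startswith(fidx):
                continue
            for tidx, sid in five_groups[fidx]:
                if read.sequence.endswith(tidx) if tidx else True:
                    start = len(fidx)
                    stop = len(read) - len(tidx) if tidx else len(read)
                    if stop < start:
                        continue
                    by_sample[sid].append(
                        SequencedRead(
                            read.read_id,
                            read.sequence[start:stop],
                            read.qualities[start:stop],
                            read.mate,
                        )
                    )
                    assigned = True
                    break
            if assigned:
                break
        if not assigned:
            unmatched.append(read)
    return DemuxResult(by_sample, unmatched)


# -- region extraction -------------------------------------------------------


def extract_region(
    read: SequencedRead | str, interval: tuple[int, int]
) -> str | None:
    """Extract a 1-based inclusive interval from a read; None if too short."""
    start, end = interval
    if end < start or start < 1:
        raise ValueError(f"invalid extraction interval {interval}")
    seq = read if isinstance(read, str) else read.sequence
    if len(seq) < end:
        return None
    return seq[start - 1 : end]
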