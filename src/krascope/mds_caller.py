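"""Maximum-depth-sequencing consensus calling and mutation-frequency tables.

MDS tags each template molecule with a 14-nt random barcode before
amplification, so true mutations propagate to every read of a barcode family
while polymerase/sequencer errors scatter across reads.  A family is trusted
only if it contains at least 2 reads of which at least 90% are identical; its
modal sequence becomes the molecule's consensus.  Consensus sequences are
compared exactly against the reference and the set of all single-nucleotide
substitutions over the target region: a consensus matching one substitution
counts toward that substitution's numerator, a consensus with two or more
differences is "complex" and counts only in the denominator.

The per-substitution mutation frequency is mutant families / total accepted
families, so the detection floor is the reciprocal of the accepted-family
count (1e-5 at a recovery of 1e5 families); that floor is added before the
log10 transform used for heatmap matrices.

Libraries sequence the non-transcribed strand; consensus sequences are
reverse-complemented onto the coding strand before comparison so that all
reported substitutions use coding-strand nomenclature (A>T at CDS 182 etc.).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .read_processing import (
    SampleIndexTable,
    SequencedRead,
    demultiplex,
    filter_by_length,
    quality_filter,
)
from .refmodel import ReferenceLocus, TargetRegion, revcomp

DEFAULT_BARCODE_LENGTH = 14
DEFAULT_MIN_READS = 2
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_FLOOR = 1e-5


def detection_floor(n_families: int) -> float:
    """Smallest observable mutation frequency: 1 / accepted families."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    return 1.0 / n_families


# -- family grouping and consensus -------------------------------------------


@dataclass
class BarcodeFamily:
    """Reads sharing one molecular barcode (target-region portions only)."""

    barcode: str
    reads: list[str]

    def _modal(self) -> tuple[str, int, bool]:
        counts = Counter(self.reads)
        top = max(counts.values())
        candidates = sorted(seq for seq, n in counts.items() if n == top)
        return candidates[0], top, len(candidates) > 1

    @property
    def modal_sequence(self) -> str:
        """Most frequent member sequence (lexicographic tie-break)."""
        return self._modal()[0]

    @property
    def modal_fraction(self) -> float:
        return self._modal()[1] / len(self.reads)

    @property
    def tie(self) -> bool:
        return self._modal()[2]


@dataclass(frozen=True)
class ConsensusRecord:
    """Accepted family consensus (read-strand orientation)."""

    barcode: str
    sequence: str
    n_reads: int
    modal_fraction: float
    tie: bool


def group_families(
    reads: Iterable[SequencedRead | str], barcode_length: int = DEFAULT_BARCODE_LENGTH
) -> tuple[list[BarcodeFamily], int]:
    """Group index-stripped reads by their leading barcode.

    Barcodes are opaque keys (N and other characters allowed).  Returns the
    families ordered by barcode plus the count of reads shorter than the
    barcode, which are dropped.
    """
    groups: dict[str, list[str]] = {}
    n_short = 0
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        if len(seq) < barcode_length:
            n_short += 1
            continue
        groups.setdefault(seq[:barcode_length], []).append(seq[barcode_length:])
    families = [
        BarcodeFamily(barcode, members)
        for barcode, members in sorted(groups.items())
    ]
    return families, n_short


def select_consensus(
    family: BarcodeFamily,
    min_reads: int = DEFAULT_MIN_READS,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> ConsensusRecord | None:
    """Accept a family if it has >= min_reads reads, >= min_identity identical.

    Both thresholds are inclusive; identity is the modal-sequence fraction.
    Returns None for rejected families.
    """
    n = len(family.reads)
    if n < min_reads:
        return None
    modal, top, tie = family._modal()
    fraction = top / n
    if fraction < min_identity:
        return None
    return ConsensusRecord(family.barcode, modal, n, fraction, tie)


# -- mutation assignment and frequencies -------------------------------------


@dataclass(frozen=True)
class FamilyCall:
    """Classification of one accepted consensus against the reference."""

    status: str  # "reference", "mutant" or "complex"
    substitution: tuple[str, str, str] | None = None  # (position label, ref, alt)


def assign_family_mutations(
    consensus: str, region: TargetRegion, strand: str = "non_transcribed"
) -> FamilyCall:
    """Compare a consensus to the region reference (coding strand).

    Exactly one mismatch yields a mutant call with its coding-strand
    substitution; zero mismatches is reference; anything else (two or more
    differences, length mismatch) is complex and never enters a numerator.
    """
    if strand == "non_transcribed":
        consensus = revcomp(consensus)
    elif strand != "coding":
        raise ValueError(f"unknown strand {strand!r}")
    reference = region.sequence
    if consensus == reference:
        return FamilyCall("reference")
    if len(consensus) != len(reference):
        return FamilyCall("complex")
    diff = None
    for i, (a, b) in enumerate(zip(reference, consensus)):
        if a != b:
            if diff is not None:
                return FamilyCall("complex")
            diff = i
    return FamilyCall(
        "mutant", (region.labels[diff], reference[diff], consensus[diff])
    )


@dataclass
class MutationFrequencyTable:
    """Per-substitution mutant-family counts and frequencies for one sample.

    ``entries`` covers every single-nucleotide substitution in the region
    (3 alternates per position) with columns position, cds_position, ref,
    alt, five_prime, three_prime, count, frequency.  ``total_families`` is
    the accepted-family denominator; when it is zero the table is flagged
    (``zero_denominator``) and frequencies are reported as zero.
    """

    sample_id: str
    region_name: str
    total_families: int
    n_reference: int
    n_complex: int
    entries: pd.DataFrame

    @property
    def zero_denominator(self) -> bool:
        return self.total_families == 0

    def frequency_of(self, position: int | str, alt: str) -> float:
        rows = self.entries[
            (self.entries["position"] == str(position)) & (self.entries["alt"] == alt)
        ]
        if rows.empty:
            raise KeyError(f"no substitution {position}>{alt} in region")
        return float(rows["frequency"].iloc[0])

    def to_tsv(self, path) -> None:
        out = self.entries.copy()
        out.insert(0, "sample_id", self.sample_id)
        out["total_families"] = self.total_families
        out.to_csv(path, sep="\t", index=False)


def mutation_frequencies(
    consensus_records: Sequence[ConsensusRecord],
    region: TargetRegion,
    sample_id: str = "",
    strand: str = "non_transcribed",
) -> MutationFrequencyTable:
    """Tabulate per-substitution frequencies over accepted families.

    Frequency = families carrying exactly that substitution / total accepted
    families; complex families inflate only the denominator.
    """
    counts: Counter[tuple[str, str, str]] = Counter()
    n_reference = 0
    n_complex = 0
    for record in consensus_records:
        call = assign_family_mutations(record.sequence, region, strand=strand)
        if call.status == "reference":
            n_reference += 1
        elif call.status == "complex":
            n_complex += 1
        else:
            counts[call.substitution] += 1
    total = len(consensus_records)

    rows = []
    for offset, label, cds_position, ref, alt, five, three in (
        region.enumerate_substitutions()
    ):
        count = counts.get((label, ref, alt), 0)
        rows.append(
            {
                "position": label,
                "cds_position": cds_position,
                "ref": ref,
                "alt": alt,
                "five_prime": five,
                "three_prime": three,
                "count": count,
                "frequency": count / total if total else 0.0,
            }
        )
    entries = pd.DataFrame(rows)
    return MutationFrequencyTable(
        sample_id=sample_id,
        region_name=region.name,
        total_families=total,
        n_reference=n_reference,
        n_complex=n_complex,
        entries=entries,
    )


# -- signature summarisation --------------------------------------------------


def _parse_class(substitution_class: str) -> tuple[str, str]:
    try:
        ref, alt = substitution_class.split(">")
    except ValueError:
        raise ValueError(
            f"substitution class {substitution_class!r} must look like 'A>T'"
        ) from None
    return ref.strip().upper(), alt.strip().upper()


def build_signature_matrix(
    tables: Mapping[str, MutationFrequencyTable],
    substitution_class: str = "A>T",
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Sample x position matrix of log10(frequency + floor) for one class.

    Columns are every position whose coding-strand reference base matches the
    class (one column per site, labelled "<5'><ref><3'>@<position>" with the
    5'UTR "-" and intron "111+" position conventions); rows are samples.
    """
    ref_base, alt_base = _parse_class(substitution_class)
    regions = {t.region_name for t in tables.values()}
    if len(regions) > 1:
        raise ValueError(f"tables span multiple regions: {sorted(regions)}")
    matrix_rows = {}
    columns: list[str] | None = None
    for sample_id, table in tables.items():
        sub = table.entries[
            (table.entries["ref"] == ref_base) & (table.entries["alt"] == alt_base)
        ]
        labels = [
            f"{r.five_prime}{r.ref}{r.three_prime}@{r.position}"
            for r in sub.itertuples()
        ]
        if columns is None:
            columns = labels
        elif labels != columns:
            raise ValueError("inconsistent position columns across samples")
        matrix_rows[sample_id] = np.log10(sub["frequency"].to_numpy(float) + floor)
    return pd.DataFrame(matrix_rows, index=columns).T


def class_mean_frequency(
    table: MutationFrequencyTable, five_prime: str, ref: str, alt: str
) -> float:
    """Mean frequency over all sites of a 5'-context substitution class.

    Zero-count sites are included in the mean, so a single nonzero site
    contributes its frequency divided by the number of class sites.
    """
    sub = table.entries[
        (table.entries["five_prime"] == five_prime)
        & (table.entries["ref"] == ref)
        & (table.entries["alt"] == alt)
    ]
    if sub.empty:
        return math.nan
    return float(sub["frequency"].mean())


@dataclass
class AggregateSignatureResult:
    per_sample: pd.DataFrame  # sample_id, group, ca_ct_exon2, gg_ga_exon1
    comparisons: dict  # class name -> quant_stats.ComparisonResult


def aggregate_signature(
    exon2_tables: Mapping[str, MutationFrequencyTable],
    exon1_tables: Mapping[str, MutationFrequencyTable],
    groups: Mapping[str, str],
) -> AggregateSignatureResult:
    """Per-sample CA>CT (exon 2) and GG>GA (exon 1) class means + group test.

    The two classes are the carcinogen-consensus substitutions producing the
    Q61L and G12D/G13D drivers.  Groups with fewer than two samples holding a
    finite value are excluded from the ANOVA with a warning by quant_stats.
    """
    from . import quant_stats  # deferred: avoids a cycle at import time

    rows = []
    for sample_id in sorted(set(exon2_tables) | set(exon1_tables)):
        ca_ct = (
            class_mean_frequency(exon2_tables[sample_id], "C", "A", "T")
            if sample_id in exon2_tables
            else math.nan
        )
        gg_ga = (
            class_mean_frequency(exon1_tables[sample_id], "G", "G", "A")
            if sample_id in exon1_tables
            else math.nan
        )
        rows.append(
            {
                "sample_id": sample_id,
                "group": groups.get(sample_id, "ungrouped"),
                "ca_ct_exon2": ca_ct,
                "gg_ga_exon1": gg_ga,
            }
        )
    per_sample = pd.DataFrame(rows)

    comparisons = {}
    for column in ("ca_ct_exon2", "gg_ga_exon1"):
        values_by_group = {
            g: sub[column].dropna().to_numpy(float)
            for g, sub in per_sample.groupby("group")
        }
        values_by_group = {g: v for g, v in values_by_group.items() if len(v) >= 2}
        if len(values_by_group) >= 2:
            comparisons[column] = quant_stats.compare_groups(
                values_by_group, test="anova_holm_sidak"
            )
    return AggregateSignatureResult(per_sample=per_sample, comparisons=comparisons)


# -- end-to-end pipeline -----------------------------------------------------


def run_mds_pipeline(
    reads: Sequence[SequencedRead],
    locus: ReferenceLocus,
    index_table: SampleIndexTable,
    region_name: str = "exon2",
    min_q: int = 20,
    min_q_fraction: float = 0.90,
    barcode_length: int = DEFAULT_BARCODE_LENGTH,
    min_reads: int = DEFAULT_MIN_READS,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    utr_flank: int = 6,
    intron_flank: int = 6,
    length_window: tuple[int, int] | None = None,
) -> dict[str, MutationFrequencyTable]:
    """Quality-filter, demultiplex, group and call one MDS library.

    ``length_window`` defaults to the exact expected read length after index
    stripping (barcode + region), an inclusive [min, max] window.
    """
    region = locus.mds_region(region_name, utr_flank, intron_flank)
    filtered, _ = quality_filter(reads, min_q=min_q, min_fraction=min_q_fraction)
    demux = demultiplex(filtered, index_table, end="five_prime")
    expected = barcode_length + len(region)
    window = length_window or (expected, expected)

    tables: dict[str, MutationFrequencyTable] = {}
    for sample_id, sample_reads in demux.by_sample.items():
        sized, _ = filter_by_length(sample_reads, *window)
        families, _ = group_families(sized, barcode_length=barcode_length)
        accepted = [
            rec
            for fam in families
            if (rec := select_consensus(fam, min_reads, min_identity)) is not None
        ]
        tables[sample_id] = mutation_frequencies(
            accepted, region, sample_id=sample_id
        )
    return tables
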