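"""Allele-resolved hotspot variant calling from processed amplicon reads.

Each merged, index-stripped read is reduced to its informative sub-regions
(codons 12/13/61, the strain SNP at CDS 96 and the 8-nt exon-3 allele
discriminator in cDNA mode) and assigned by exact sequence comparison against
the enumerated missense variant set: every codon at reference means wildtype,
exactly one codon equal to one enumerated variant codon means that variant,
anything else (two mutated codons, a non-enumerated codon such as a nonsense
change) lands in an explicit "unassigned" bucket.

Sample-level filtering follows the published rules: samples with fewer than
30 total reads are excluded, variant categories below an 8% fraction of the
sample total (wildtype and unassigned included in the denominator) are
dropped.  For cDNA libraries the mutant:wildtype read-count ratio estimates
allelic expression imbalance and is binned at 1.5 (high > 1.5, low <= 1.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .read_processing import (
    DemuxResult,
    SampleIndexTable,
    SequencedRead,
    demultiplex,
    extract_region,
    merge_pairs,
    quality_filter,
)
from .refmodel import ReferenceLocus, VariantReference, enumerate_missense_variants

RATIO_BIN_THRESHOLD = 1.5
MIN_TOTAL_READS = 30
MIN_VARIANT_FRACTION = 0.08


@dataclass(frozen=True)
class VariantCall:
    """Read counts for one (variant, allele, strain) category in a sample."""

    sample_id: str
    variant_label: str  # variant label, "WT" or "unassigned"
    allele: str  # "nat", "ex3op" or "NA"
    strain: str  # "129", "B6" or "NA"
    read_count: int
    fraction: float


@dataclass
class MutantWtRatio:
    """Mutant:wildtype cDNA read-count ratio for one tumor."""

    mutant_reads: int
    wt_reads: int
    ratio: float  # inf when wt_reads == 0
    log10_ratio: float | None  # None when the ratio is infinite or zero
    bin: str  # "high" (> threshold) or "low"

    @property
    def infinite(self) -> bool:
        return math.isinf(self.ratio)


@dataclass
class TumorCallSummary:
    """Per-sample calling outcome after depth and fraction filters."""

    sample_id: str
    total_reads: int
    calls: list[VariantCall]
    excluded: bool
    exclusion_reason: str | None
    passing_variants: list[VariantCall]
    wt_reads: int
    unassigned_reads: int
    hotspot_site: str  # "G12", "G13", "Q61" or "none"
    multi_variant: bool
    mutant_wt_ratio: MutantWtRatio | None = None


# -- read-level assignment ---------------------------------------------------


def assign_read(
    regions: Mapping[str, str | None],
    variant_set: Sequence[VariantReference],
    locus: ReferenceLocus,
) -> tuple[str, str, str]:
    """Assign one read's extracted regions to (variant label, allele, strain).

    ``regions`` maps "codon12"/"codon13"/"codon61" to the observed 3-mers and
    optionally "nt96"/"discriminator" to the observed SNP base and 8-mer
    (cDNA mode).  A failed extraction (None) makes the read unassigned.
    """
    if not variant_set:
        raise ValueError("variant_set is empty")
    by_codon_seq = {(v.codon_index, v.expected_codon): v.label for v in variant_set}
    # only codons actually extracted for this library mode are interrogated
    hotspots = sorted(
        c for c in {v.codon_index for v in variant_set} if f"codon{c}" in regions
    )
    if not hotspots:
        raise ValueError("no codon regions provided for assignment")

    observed = {c: regions.get(f"codon{c}") for c in hotspots}
    if any(obs is None for obs in observed.values()):
        label = "unassigned"
    else:
        mutated = [c for c in hotspots if observed[c] != locus.codon(c)]
        if not mutated:
            label = "WT"
        elif len(mutated) == 1:
            c = mutated[0]
            label = by_codon_seq.get((c, observed[c]), "unassigned")
        else:
            label = "unassigned"

    disc = regions.get("discriminator")
    if disc == locus.discriminator.native:
        allele = "nat"
    elif disc == locus.discriminator.ex3op:
        allele = "ex3op"
    else:
        allele = "NA"

    nt96 = regions.get("nt96")
    if nt96 == locus.strain_snp.base_129:
        strain = "129"
    elif nt96 == locus.strain_snp.base_b6:
        strain = "B6"
    else:
        strain = "NA"
    return label, allele, strain


def tabulate_sample(
    sample_id: str, assignments: Iterable[tuple[str, str, str]]
) -> list[VariantCall]:
    """Count reads per (variant, allele, strain); fractions over all reads."""
    counts: dict[tuple[str, str, str], int] = {}
    total = 0
    for key in assignments:
        counts[key] = counts.get(key, 0) + 1
        total += 1
    calls = [
        VariantCall(
            sample_id=sample_id,
            variant_label=label,
            allele=allele,
            strain=strain,
            read_count=count,
            fraction=count / total if total else 0.0,
        )
        for (label, allele, strain), count in sorted(counts.items())
    ]
    return calls


def apply_filters(
    calls: list[VariantCall],
    min_total: int = MIN_TOTAL_READS,
    min_fraction: float = MIN_VARIANT_FRACTION,
) -> TumorCallSummary:
    """Apply the depth and variant-fraction exclusion rules to one sample.

    Samples with total reads < ``min_total`` are excluded outright; variant
    categories with fraction < ``min_fraction`` are dropped (strictly less
    than: a variant at exactly the threshold is retained).  Wildtype and
    unassigned reads are never dropped — they anchor the denominator and the
    mutant:wildtype ratio.
    """
    sample_id = calls[0].sample_id if calls else ""
    total = sum(c.read_count for c in calls)
    wt_reads = sum(c.read_count for c in calls if c.variant_label == "WT")
    unassigned = sum(c.read_count for c in calls if c.variant_label == "unassigned")

    if total < min_total:
        return TumorCallSummary(
            sample_id=sample_id,
            total_reads=total,
            calls=calls,
            excluded=True,
            exclusion_reason="low depth",
            passing_variants=[],
            wt_reads=wt_reads,
            unassigned_reads=unassigned,
            hotspot_site="none",
            multi_variant=False,
        )

    variant_calls = [
        c for c in calls if c.variant_label not in ("WT", "unassigned")
    ]
    passing = [c for c in variant_calls if c.fraction >= min_fraction]

    # one row per surviving variant label (a label may span strains)
    by_label: dict[str, int] = {}
    for c in passing:
        by_label[c.variant_label] = by_label.get(c.variant_label, 0) + c.read_count
    if by_label:
        top_label = max(by_label, key=lambda k: by_label[k])
        site_codon = "".join(ch for ch in top_label if ch.isdigit())
        site = f"{top_label[0]}{site_codon}"
    else:
        site = "none"
    return TumorCallSummary(
        sample_id=sample_id,
        total_reads=total,
        calls=calls,
        excluded=False,
        exclusion_reason=None,
        passing_variants=passing,
        wt_reads=wt_reads,
        unassigned_reads=unassigned,
        hotspot_site=site,
        multi_variant=len(by_label) > 1,
    )


def mutant_wt_ratio(
    summary: TumorCallSummary, threshold: float = RATIO_BIN_THRESHOLD
) -> MutantWtRatio:
    """Mutant:wildtype read-count ratio for a sample with one passing variant.

    Only reads with a resolved allele contribute (a read whose discriminator
    matched neither allele counts toward totals but not toward the ratio).
    A zero wildtype count yields an infinite ratio, flagged rather than
    raised so callers can exclude it from log-scale plots.
    """
    if summary.excluded:
        raise ValueError(f"sample {summary.sample_id} was excluded from analysis")
    labels = {c.variant_label for c in summary.passing_variants}
    if len(labels) != 1:
        raise ValueError(
            f"sample {summary.sample_id} has {len(labels)} passing variants; "
            "the ratio is defined for exactly one"
        )
    label = labels.pop()
    mutant = sum(
        c.read_count
        for c in summary.calls
        if c.variant_label == label and c.allele != "NA"
    )
    wt = sum(
        c.read_count
        for c in summary.calls
        if c.variant_label == "WT" and c.allele != "NA"
    )
    ratio = mutant / wt if wt else math.inf
    log10_ratio = math.log10(ratio) if 0 < ratio < math.inf else None
    return MutantWtRatio(
        mutant_reads=mutant,
        wt_reads=wt,
        ratio=ratio,
        log10_ratio=log10_ratio,
        bin="high" if ratio > threshold else "low",
    )


# -- end-to-end pipeline -----------------------------------------------------

_MODES = ("cdna", "gdna-exon1", "gdna-exon2")


@dataclass
class HotspotResult:
    summaries: dict[str, TumorCallSummary]
    n_pairs_in: int
    n_merged: int
    n_quality_kept: int
    demux: DemuxResult

    def to_frame(self) -> pd.DataFrame:
        """Per-sample per-category table (TSV-ready)."""
        rows = []
        for sid, summary in sorted(self.summaries.items()):
            ratio = summary.mutant_wt_ratio
            for c in summary.calls:
                rows.append(
                    {
                        "sample_id": sid,
                        "variant": c.variant_label,
                        "allele": c.allele,
                        "strain": c.strain,
                        "count": c.read_count,
                        "fraction": c.fraction,
                        "excluded": summary.excluded,
                        "hotspot_site": summary.hotspot_site,
                        "ratio": ratio.ratio if ratio else float("nan"),
                        "log10_ratio": (
                            ratio.log10_ratio
                            if ratio and ratio.log10_ratio is not None
                            else float("nan")
                        ),
                        "bin": ratio.bin if ratio else "",
                    }
                )
        return pd.DataFrame(rows)


def _cdna_regions(locus: ReferenceLocus) -> dict[str, tuple[int, int]]:
    d = locus.discriminator
    s = locus.strain_snp
    intervals = {f"codon{c}": locus.codon_span(c) for c in locus.hotspot_codons}
    intervals["nt96"] = (s.position, s.position)
    intervals["discriminator"] = (d.start, d.end)
    return intervals


def _mode_intervals(locus: ReferenceLocus, mode: str) -> dict[str, tuple[int, int]]:
    if mode == "cdna":
        return _cdna_regions(locus)
    if mode == "gdna-exon1":
        return {f"codon{c}": locus.codon_span(c) for c in (12, 13)}
    if mode == "gdna-exon2":
        return {"codon61": locus.codon_span(61)}
    raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")


def run_hotspot_pipeline(
    reads1: Sequence[SequencedRead],
    reads2: Sequence[SequencedRead] | None,
    locus: ReferenceLocus,
    index_table: SampleIndexTable,
    mode: str = "cdna",
    min_q: int = 20,
    min_q_fraction: float = 0.75,
    max_diff_pct: float = 20.0,
    min_overlap: int = 10,
    min_total: int = MIN_TOTAL_READS,
    min_fraction: float = MIN_VARIANT_FRACTION,
    cds_offset: int = 0,
) -> HotspotResult:
    """Process raw read pairs into per-sample tumor call summaries.

    cDNA and exon-2 genomic libraries are pair-merged; exon-1 genomic
    libraries use read 1 only.  ``cds_offset`` shifts extraction intervals
    when the amplicon does not start at CDS position 1.
    """
    if mode == "gdna-exon1":
        merged: list[SequencedRead] = list(reads1)
    else:
        if reads2 is None:
            raise ValueError(f"mode {mode!r} requires read 2")
        merged = []
        for r1, r2 in zip(reads1, reads2):
            m = merge_pairs(r1, r2, max_diff_pct=max_diff_pct, min_overlap=min_overlap)
            if m is not None:
                merged.append(m)
    filtered, qreport = quality_filter(merged, min_q=min_q, min_fraction=min_q_fraction)
    # read-1-only exon-1 libraries never reach the 3' index, so demultiplex
    # on the 5' index alone there; merged reads expose both indexes
    demux_end = "five_prime" if mode == "gdna-exon1" else "both"
    demux = demultiplex(filtered, index_table, end=demux_end)

    intervals = {
        name: (start + cds_offset, end + cds_offset)
        for name, (start, end) in _mode_intervals(locus, mode).items()
    }
    variants = enumerate_missense_variants(locus)
    summaries: dict[str, TumorCallSummary] = {}
    for sample_id, reads in demux.by_sample.items():
        assignments = []
        for read in reads:
            regions = {
                name: extract_region(read, interval)
                for name, interval in intervals.items()
            }
            assignments.append(assign_read(regions, variants, locus))
        calls = tabulate_sample(sample_id, assignments)
        summary = apply_filters(calls, min_total=min_total, min_fraction=min_fraction)
        if (
            mode == "cdna"
            and not summary.excluded
            and len({c.variant_label for c in summary.passing_variants}) == 1
        ):
            summary.mutant_wt_ratio = mutant_wt_ratio(summary)
        summaries[sample_id] = summary
    return HotspotResult(
        summaries=summaries,
        n_pairs_in=len(reads1),
        n_merged=len(merged),
        n_quality_kept=qreport.n_kept,
        demux=demux,
    )
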