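"""Synthetic inputs for every pipeline stage, with controlled ground truth.

Four generators mirror the data the analysis consumes:

* tumor cDNA amplicon read pairs carrying a hotspot variant at a set mutant
  fraction on a chosen allele/strain background,
* single-end MDS libraries ([5' index][14-nt random barcode][target region])
  with barcode families, per-family true mutations and per-read errors,
* qPCR Ct tables (Ct = baseline - log2(relative abundance) + noise),
* tumor cohorts (per-mouse tumor length/width lists per arm).

All randomness flows through one ``numpy`` generator seeded from the truth
object, so identical truth + seed reproduces byte-identical output.  The
sequencing error model is uniform substitution to the three alternate bases
over the target-region bases, with a constant Q30 quality string; sample
indexes and molecular barcodes are emitted as drawn (a barcode read error
would move a read between families — a distinct failure mode from the
consensus-suppression behaviour the error rate controls).  Barcodes are drawn
uniformly over 4^14 with collisions allowed (collisions merge families, as in
real libraries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .read_processing import SequencedRead, SampleIndexTable, write_fastq
from .refmodel import (
    ReferenceLocus,
    TargetRegion,
    enumerate_missense_variants,
    revcomp,
)

DEFAULT_QUALITY_CHAR = "?"  # Phred 30 at +33 offset
BARCODE_LENGTH = 14
_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationConfigError(ValueError):
    """A truth object or distribution specification is invalid."""


def default_index_table() -> SampleIndexTable:
    """Synthetic sample-index table (4-7 nt indexes at both ends)."""
    return SampleIndexTable(
        [
            ("S1", "ACGTAC", "TGCA"),
            ("S2", "GGATCCA", "CATG"),
            ("S3", "TTGCA", "GGTAC"),
            ("S4", "CAGT", "ACCGT"),
        ]
    )


# -- tumor amplicon ----------------------------------------------------------


@dataclass(frozen=True)
class AmpliconTruth:
    """Ground truth for one simulated tumor cDNA amplicon library."""

    sample_id: str
    allele: str  # "nat" or "ex3op"
    strain_base: str  # base at CDS position 96
    variant_label: str  # e.g. "Q61L", or "WT"
    mutant_fraction: float
    n_read_pairs: int
    per_base_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.allele not in ("nat", "ex3op"):
            raise SimulationConfigError(f"unknown allele {self.allele!r}")
        if not 0.0 <= self.mutant_fraction <= 1.0:
            raise SimulationConfigError("mutant_fraction must be in [0, 1]")
        if self.n_read_pairs < 0:
            raise SimulationConfigError("n_read_pairs must be >= 0")
        if not 0.0 <= self.per_base_error <= 0.25:
            raise SimulationConfigError("per_base_error must be in [0, 0.25]")


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Substitute bases i.i.d. at ``rate`` (uniform over the 3 alternates)."""
    if rate <= 0.0:
        return seq
    k = int(rng.binomial(len(seq), rate))
    if k == 0:
        return seq
    positions = rng.choice(len(seq), size=k, replace=False)
    shifts = rng.integers(1, 4, size=k)
    out = list(seq)
    for pos, shift in zip(positions, shifts):
        out[pos] = _BASES[(_BASES.index(out[pos]) + shift) % 4]
    return "".join(out)


def _amplicon_template(locus: ReferenceLocus, allele: str, strain_base: str) -> str:
    seq = list(locus.coding_sequence)
    seq[locus.strain_snp.position - 1] = strain_base
    if allele == "ex3op":
        d = locus.discriminator
        seq[d.start - 1 : d.end] = locus.discriminator.ex3op
    return "".join(seq)


def simulate_tumor_amplicon(
    locus: ReferenceLocus,
    truth: AmpliconTruth,
    index_table: SampleIndexTable,
    read_length: int = 250,
    out_r1: str | Path | None = None,
    out_r2: str | Path | None = None,
) -> tuple[list[SequencedRead], list[SequencedRead]]:
    """Simulate paired-end reads over the full-CDS cDNA amplicon.

    The amplicon is ``[5' index][CDS][3' index]``; read 1 is its first
    ``read_length`` bases, read 2 the reverse complement of its last
    ``read_length`` bases.  The first random draw is the Binomial
    (n_read_pairs, mutant_fraction) count of mutant molecules; the first
    that-many pairs then carry the variant.  When output paths are given the
    FASTQ files are written together with a ``<r1>.truth.tsv`` manifest.
    """
    row = index_table.df[index_table.df["sample_id"] == truth.sample_id]
    if row.empty:
        raise KeyError(f"sample {truth.sample_id!r} not in index table")
    five_idx = row["five_prime_index"].iloc[0]
    three_idx = row["three_prime_index"].iloc[0]

    wt_template = _amplicon_template(locus, truth.allele, truth.strain_base)
    if truth.variant_label == "WT":
        mut_template = wt_template
    else:
        by_label = {
            v.label: v for v in enumerate_missense_variants(locus)
        }
        try:
            variant = by_label[truth.variant_label]
        except KeyError:
            raise KeyError(
                f"variant {truth.variant_label!r} is not an enumerated hotspot "
                "missense variant"
            ) from None
        tmp = list(wt_template)
        tmp[variant.cds_position - 1] = variant.alt_base
        mut_template = "".join(tmp)

    rng = np.random.default_rng(truth.seed)
    n_mutant = (
        int(rng.binomial(truth.n_read_pairs, truth.mutant_fraction))
        if truth.variant_label != "WT"
        else 0
    )

    reads1: list[SequencedRead] = []
    reads2: list[SequencedRead] = []
    for i in range(truth.n_read_pairs):
        template = mut_template if i < n_mutant else wt_template
        amplicon = five_idx + template + three_idx
        r1 = amplicon[:read_length]
        r2 = revcomp(amplicon[-read_length:] if read_length < len(amplicon) else amplicon)
        r1 = _apply_errors(r1, rng, truth.per_base_error)
        r2 = _apply_errors(r2, rng, truth.per_base_error)
        rid = f"{truth.sample_id}:{i}"
        reads1.append(SequencedRead(rid, r1, DEFAULT_QUALITY_CHAR * len(r1), "1"))
        reads2.append(SequencedRead(rid, r2, DEFAULT_QUALITY_CHAR * len(r2), "2"))

    if out_r1 is not None and out_r2 is not None:
        write_fastq(reads1, out_r1)
        write_fastq(reads2, out_r2)
        manifest = pd.DataFrame(
            [
                {
                    "sample_id": truth.sample_id,
                    "allele": truth.allele,
                    "strain_base": truth.strain_base,
                    "variant_label": truth.variant_label,
                    "mutant_fraction": truth.mutant_fraction,
                    "n_read_pairs": truth.n_read_pairs,
                    "n_mutant_molecules": n_mutant,
                    "per_base_error": truth.per_base_error,
                    "seed": truth.seed,
                }
            ]
        )
        manifest.to_csv(f"{out_r1}.truth.tsv", sep="\t", index=False)
    return reads1, reads2


# -- MDS library -------------------------------------------------------------


@dataclass(frozen=True)
class MdsTruth:
    """Ground truth for one simulated MDS library.

    ``true_mutation_frequencies`` maps (position, alt base) to the per-molecule
    frequency; positions are CDS integers or flank labels ("-1", "111+2").
    ``signature_bias`` multiplies the frequency of entries matching the
    urethane consensus (ref A with 5' C, alt T or G) before simulation.
    """

    true_mutation_frequencies: Mapping[tuple[int | str, str], float] = field(
        default_factory=dict
    )
    n_families: int = 1000
    family_size_distribution: Mapping[str, float | int | str] = field(
        default_factory=lambda: {"kind": "truncated_geometric", "mean": 4, "min": 1}
    )
    per_base_error: float = 0.0
    signature_bias: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise SimulationConfigError("n_families must be >= 1")
        if not 0.0 <= self.per_base_error <= 0.25:
            raise SimulationConfigError("per_base_error must be in [0, 0.25]")
        if self.signature_bias < 0:
            raise SimulationConfigError("signature_bias must be >= 0")
        for key, freq in self.true_mutation_frequencies.items():
            if not 0.0 <= freq <= 1.0:
                raise SimulationConfigError(
                    f"true mutation frequency for {key} outside [0, 1]"
                )


def _draw_family_sizes(
    rng: np.random.Generator, dist: Mapping, n: int
) -> np.ndarray:
    kind = dist.get("kind")
    if kind == "fixed":
        return np.full(n, int(dist["size"]), dtype=np.int64)
    if kind == "truncated_geometric":
        minimum = int(dist.get("min", 1))
        mean = float(dist["mean"])
        if mean < minimum:
            raise SimulationConfigError("family size mean below minimum")
        p = 1.0 / (mean - minimum + 1.0)
        return minimum - 1 + rng.geometric(p, size=n)
    raise SimulationConfigError(f"unknown family size distribution {kind!r}")


def effective_frequencies(
    truth: MdsTruth, region: TargetRegion
) -> dict[tuple[str, str], float]:
    """Resolve truth frequencies to region labels, applying signature bias.

    The bias multiplies entries at urethane-consensus sites (ref A preceded
    by C, alt T or G); results are clipped to 1.
    """
    resolved: dict[tuple[str, str], float] = {}
    for (position, alt), freq in truth.true_mutation_frequencies.items():
        offset = region.offset_of(position)
        ref = region.sequence[offset]
        if alt == ref:
            raise SimulationConfigError(
                f"truth entry at {position} has alt equal to the reference base"
            )
        five, _ = region.context(offset)
        if ref == "A" and five == "C" and alt in ("T", "G"):
            freq = min(1.0, freq * truth.signature_bias)
        resolved[(region.labels[offset], alt)] = freq
    return resolved


def _draw_family_plan(
    rng: np.random.Generator, truth: MdsTruth, region: TargetRegion
) -> tuple[np.ndarray, list[str], dict[int, list[tuple[int, str]]]]:
    """Draw (sizes, barcodes, per-family mutation lists) for a library.

    Draw order is fixed: sizes, then barcodes, then one carrier vector per
    truth entry (entries in sorted label order), so tests can replay it.
    """
    sizes = _draw_family_sizes(rng, truth.family_size_distribution, truth.n_families)
    codes = rng.integers(0, 4, size=(truth.n_families, BARCODE_LENGTH))
    flat = _BASE_BYTES[codes].tobytes().decode("ascii")
    barcodes = [
        flat[i * BARCODE_LENGTH : (i + 1) * BARCODE_LENGTH]
        for i in range(truth.n_families)
    ]
    mutations: dict[int, list[tuple[int, str]]] = {}
    for (label, alt), freq in sorted(effective_frequencies(truth, region).items()):
        carriers = np.flatnonzero(rng.random(truth.n_families) < freq)
        offset = region.offset_of(label)
        for fam in carriers:
            mutations.setdefault(int(fam), []).append((offset, alt))
    return sizes, barcodes, mutations


def simulate_mds_library(
    locus: ReferenceLocus,
    truth: MdsTruth,
    region_name: str = "exon2",
    five_prime_index: str = "",
    out_fastq: str | Path | None = None,
    utr_flank: int = 6,
    intron_flank: int = 6,
) -> list[SequencedRead]:
    """Simulate a single-end MDS library for one sample.

    Each molecule gets a unique plan entry ``[index][barcode][target]`` where
    the target is the region sequence on the **non-transcribed strand**
    (reverse complement of the coding strand) carrying that family's true
    mutations; every read of the family is then perturbed independently at
    ``per_base_error`` over the target portion.
    """
    region = locus.mds_region(region_name, utr_flank, intron_flank)
    rng = np.random.default_rng(truth.seed)
    sizes, barcodes, mutations = _draw_family_plan(rng, truth, region)

    coding = region.sequence
    read_template = revcomp(coding)
    L = len(read_template)
    reads: list[SequencedRead] = []
    for fam in range(truth.n_families):
        if fam in mutations:
            mutated = list(coding)
            for offset, alt in mutations[fam]:
                mutated[offset] = alt
            target = revcomp("".join(mutated))
        else:
            target = read_template
        barcode = barcodes[fam]
        for j in range(int(sizes[fam])):
            observed = _apply_errors(target, rng, truth.per_base_error)
            seq = five_prime_index + barcode + observed
            reads.append(
                SequencedRead(
                    f"fam{fam}:{j}", seq, DEFAULT_QUALITY_CHAR * len(seq), "merged"
                )
            )
    if out_fastq is not None:
        write_fastq(reads, out_fastq)
        manifest = pd.DataFrame(
            [
                {"position": pos, "alt": alt, "frequency": freq}
                for (pos, alt), freq in sorted(
                    effective_frequencies(truth, region).items()
                )
            ]
        )
        manifest.to_csv(f"{out_fastq}.truth.tsv", sep="\t", index=False)
    return reads


# -- qPCR tables -------------------------------------------------------------


def simulate_qpcr_table(
    design: pd.DataFrame | Sequence[Mapping],
    noise_sd: float = 0.0,
    baseline_ct: float = 25.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Turn a (sample_id, target, relative_abundance) design into Ct values.

    Ct = baseline - log2(relative abundance) + Gaussian(0, noise_sd); a
    doubling of abundance lowers Ct by exactly one cycle.  Reference genes
    are design rows with relative_abundance 1.
    """
    if noise_sd < 0:
        raise SimulationConfigError("noise_sd must be >= 0")
    df = pd.DataFrame(design).copy()
    required = {"sample_id", "target", "relative_abundance"}
    missing = required - set(df.columns)
    if missing:
        raise SimulationConfigError(f"design missing columns: {sorted(missing)}")
    if (df["relative_abundance"] <= 0).any():
        raise SimulationConfigError("relative abundances must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(df)) if noise_sd > 0 else 0.0
    df["ct"] = baseline_ct - np.log2(df["relative_abundance"].to_numpy(float)) + noise
    return df[["sample_id", "target", "ct"]]


def recombination_design(
    fractions: Mapping[str, float],
    wt_target: str = "Trp53_WT",
    del_target: str = "Trp53_Del",
    reference: str = "Tflc",
) -> pd.DataFrame:
    """Design with a recombined-allele fraction per sample (Del/(Del+WT))."""
    rows = []
    for sample_id, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise SimulationConfigError("recombined fraction must be in [0, 1]")
        rows.append({"sample_id": sample_id, "target": del_target,
                     "relative_abundance": max(f, 1e-12)})
        rows.append({"sample_id": sample_id, "target": wt_target,
                     "relative_abundance": max(1.0 - f, 1e-12)})
        rows.append({"sample_id": sample_id, "target": reference,
                     "relative_abundance": 1.0})
    return pd.DataFrame(rows)


# -- tumor cohorts -----------------------------------------------------------


@dataclass(frozen=True)
class ArmSpec:
    """One cohort arm: how many mice, tumors per mouse, and tumor sizes."""

    label: str
    n_mice: int
    count_distribution: Mapping = field(
        default_factory=lambda: {"kind": "poisson", "mean": 5.0}
    )
    size_distribution: Mapping = field(
        default_factory=lambda: {
            "kind": "lognormal", "mean_log": 1.0, "sd_log": 0.6,
            "width_ratio": (0.5, 0.9),
        }
    )

    def __post_init__(self) -> None:
        if self.n_mice < 0:
            raise SimulationConfigError("n_mice must be >= 0")


def _draw_counts(rng: np.random.Generator, dist: Mapping, n: int) -> np.ndarray:
    kind = dist.get("kind")
    if kind == "fixed":
        return np.full(n, int(dist["n"]), dtype=np.int64)
    if kind == "poisson":
        return rng.poisson(float(dist["mean"]), size=n)
    raise SimulationConfigError(f"unknown tumor count distribution {kind!r}")


def _draw_sizes(rng: np.random.Generator, dist: Mapping, n: int) -> np.ndarray:
    """Return an (n, 2) array of (length, width) in mm."""
    kind = dist.get("kind")
    if kind == "fixed":
        return np.tile([float(dist["length"]), float(dist["width"])], (n, 1))
    if kind == "lognormal":
        lengths = rng.lognormal(float(dist["mean_log"]), float(dist["sd_log"]), n)
        low, high = dist.get("width_ratio", (0.5, 0.9))
        widths = lengths * rng.uniform(low, high, n)
        return np.column_stack([lengths, widths])
    if kind == "two_class":
        frac = float(dist["frac_large"])
        large = rng.random(n) < frac
        out = np.empty((n, 2))
        for cls, mask in (("small", ~large), ("large", large)):
            spec = dist[cls]
            out[mask, 0] = float(spec["length"])
            out[mask, 1] = float(spec["width"])
        return out
    raise SimulationConfigError(f"unknown tumor size distribution {kind!r}")


def simulate_tumor_cohort(arms: Sequence[ArmSpec], seed: int = 0) -> pd.DataFrame:
    """Simulate per-mouse tumor length/width tables for the given arms.

    Returns a tidy frame (mouse_id, arm, tumor_id, length_mm, width_mm); a
    mouse with no tumors contributes no rows but still exists in the
    mouse_id sequence of its arm.
    """
    if not arms:
        raise SimulationConfigError("at least one cohort arm is required")
    rng = np.random.default_rng(seed)
    rows = []
    for arm in arms:
        counts = _draw_counts(rng, arm.count_distribution, arm.n_mice)
        for m, count in enumerate(counts):
            mouse_id = f"{arm.label}_m{m + 1}"
            sizes = _draw_sizes(rng, arm.size_distribution, int(count))
            for t in range(int(count)):
                length, width = sizes[t]
                if width > length:  # convention: length >= width
                    length, width = width, length
                rows.append(
                    {
                        "mouse_id": mouse_id,
                        "arm": arm.label,
                        "tumor_id": f"{mouse_id}_t{t + 1}",
                        "length_mm": float(length),
                        "width_mm": float(width),
                    }
                )
    return pd.DataFrame(
        rows, columns=["mouse_id", "arm", "tumor_id", "length_mm", "width_mm"]
    )
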