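"""Reference model for a Kras-like locus with mutational hotspots.

This module owns the coordinate conventions shared by the amplicon hotspot
caller and the maximum-depth-sequencing (MDS) caller:

* CDS coordinates are 1-based and inclusive, anchored at the A of the ATG
  start codon, so codon ``n`` occupies positions ``3n-2 .. 3n`` (codon 12 at
  34-36, codon 61 at 181-183).
* Positions upstream of the ATG (5'UTR) are labelled ``-1, -2, ...`` counting
  away from the start codon; positions in the intron downstream of exon 1
  are labelled ``111+1, 111+2, ...``.
* All variants are reported on the coding strand.  MDS libraries sequence the
  non-transcribed strand; callers reverse-complement before comparison.

The locus model also records the two sequence features used to resolve reads
to a specific *Kras* allele and mouse strain: an 8-nt stretch in the middle
of exon 3 that differs between the native and codon-optimised (ex3op)
versions of the gene, and a strain-discriminating SNP at CDS position 96
(129 versus C57BL/6).  Neither sequence is published, so both are mandatory
configuration; :func:`synthetic_locus` provides a documented synthetic
default used by the simulators and the test-suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(sequence: str) -> str:
    """Reverse-complement a nucleotide string (N-safe)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon ('*' for stop), standard code."""
    return str(Seq(codon).translate())


class LocusConfigError(ValueError):
    """A locus configuration file is missing keys or internally inconsistent."""


class SequenceFormatError(ValueError):
    """A sequence contains characters outside A/C/G/T."""


class DegenerateSubstitutionError(ValueError):
    """Requested substitution where the alternate base equals the reference."""


def _check_acgt(seq: str, what: str) -> None:
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise SequenceFormatError(
            f"{what} contains non-ACGT characters: {sorted(bad)!r}"
        )


@dataclass(frozen=True)
class StrainSNP:
    """Single CDS position whose base differs between 129 and B6 strains."""

    position: int
    base_129: str
    base_b6: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise LocusConfigError("strain SNP position must be >= 1")
        for b in (self.base_129, self.base_b6):
            _check_acgt(b, "strain SNP base")
        if self.base_129 == self.base_b6:
            raise LocusConfigError("strain SNP bases for 129 and B6 are identical")


@dataclass(frozen=True)
class AlleleDiscriminator:
    """8-nt exon-3 interval whose sequence differs between Kras alleles."""

    start: int
    end: int
    native: str
    ex3op: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise LocusConfigError("discriminator interval is inverted")
        width = self.end - self.start + 1
        if len(self.native) != width or len(self.ex3op) != width:
            raise LocusConfigError(
                "discriminator sequences must match the interval width "
                f"({width} nt)"
            )
        _check_acgt(self.native, "native discriminator")
        _check_acgt(self.ex3op, "ex3op discriminator")
        if self.native == self.ex3op:
            raise LocusConfigError(
                "native and ex3op discriminator sequences are identical"
            )


@dataclass(frozen=True)
class TargetRegion:
    """A contiguous sequenced region on the coding strand with position labels.

    ``sequence`` may extend beyond the CDS into the 5'UTR or the intron
    downstream of exon 1; ``labels`` gives the per-base position label
    ("-3", "35", "111+2", ...) and ``cds_positions`` the integer CDS
    coordinate where one exists (None in flanks).
    """

    name: str
    sequence: str
    labels: tuple[str, ...]
    cds_positions: tuple[int | None, ...]
    _offset_by_label: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.sequence) == len(self.labels) == len(self.cds_positions)):
            raise ValueError("sequence, labels and cds_positions lengths differ")
        self._offset_by_label.update({lab: i for i, lab in enumerate(self.labels)})

    def __len__(self) -> int:
        return len(self.sequence)

    def offset_of(self, position: int | str) -> int:
        """0-based offset within the region of a CDS position or label."""
        label = str(position)
        try:
            return self._offset_by_label[label]
        except KeyError:
            raise KeyError(f"position {position!r} not in region {self.name}") from None

    def context(self, offset: int) -> tuple[str, str]:
        """(5' base, 3' base) around an offset; 'N' beyond the region edge."""
        five = self.sequence[offset - 1] if offset > 0 else "N"
        three = self.sequence[offset + 1] if offset + 1 < len(self.sequence) else "N"
        return five, three

    def enumerate_substitutions(self):
        """Yield every single-nucleotide substitution in the region.

        Yields ``(offset, label, cds_position, ref, alt, five, three)`` in
        deterministic order (position, then alt base alphabetical).
        """
        for offset, ref in enumerate(self.sequence):
            five, three = self.context(offset)
            for alt in NUCLEOTIDES:
                if alt != ref:
                    yield (
                        offset,
                        self.labels[offset],
                        self.cds_positions[offset],
                        ref,
                        alt,
                        five,
                        three,
                    )


@dataclass(frozen=True)
class VariantReference:
    """One enumerated single-nucleotide missense variant at a hotspot codon."""

    codon_index: int
    cds_position: int
    ref_base: str
    alt_base: str
    ref_aa: str
    alt_aa: str
    label: str
    expected_codon: str

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("variant is not missense (same amino acid)")
        if self.ref_base == self.alt_base:
            raise DegenerateSubstitutionError("ref and alt base are identical")


@dataclass(frozen=True)
class Substitution:
    """A single-nucleotide substitution with local sequence context."""

    cds_position: int
    ref_base: str
    alt_base: str
    five_prime: str
    three_prime: str
    codon_index: int | None
    consequence: str | None  # e.g. "Q61L"; None outside the CDS


@dataclass
class ReferenceLocus:
    """Validated reference model of the locus (coding strand, native allele).

    The stored ``coding_sequence`` is the native-allele, 129-strain reference:
    the discriminator interval must read as the native 8-mer and position 96
    as the 129 base.  Simulators substitute the alternates when emitting
    ex3op/B6 templates.
    """

    name: str
    coding_sequence: str
    exon_intervals: tuple[tuple[str, int, int], ...]
    hotspot_codons: tuple[int, ...]
    discriminator: AlleleDiscriminator
    strain_snp: StrainSNP
    utr5: str = ""
    intron1: str = ""

    def __post_init__(self) -> None:
        _check_acgt(self.coding_sequence, "coding sequence")
        if self.utr5:
            _check_acgt(self.utr5, "5'UTR")
        if self.intron1:
            _check_acgt(self.intron1, "intron 1")
        if len(self.coding_sequence) < 3 * 61:
            raise LocusConfigError(
                "coding sequence shorter than 183 nt cannot contain codon 61"
            )
        for codon in self.hotspot_codons:
            if 3 * codon > len(self.coding_sequence):
                raise LocusConfigError(f"hotspot codon {codon} beyond CDS end")
        d = self.discriminator
        if d.end > len(self.coding_sequence):
            raise LocusConfigError("discriminator interval beyond CDS end")
        if self.coding_sequence[d.start - 1 : d.end] != d.native:
            raise LocusConfigError(
                "reference coding sequence does not carry the native "
                "discriminator sequence at the configured interval"
            )
        s = self.strain_snp
        if s.position > len(self.coding_sequence):
            raise LocusConfigError("strain SNP position beyond CDS end")
        if self.coding_sequence[s.position - 1] != s.base_129:
            raise LocusConfigError(
                "reference coding sequence does not carry the 129 base at the "
                "strain SNP position"
            )
        for label, start, end in self.exon_intervals:
            if not (1 <= start <= end <= len(self.coding_sequence)):
                raise LocusConfigError(f"exon interval {label} out of range")

    # -- coordinate helpers -------------------------------------------------

    def codon_span(self, codon_index: int) -> tuple[int, int]:
        """1-based inclusive CDS interval of a codon: (3n-2, 3n)."""
        if codon_index < 1 or 3 * codon_index > len(self.coding_sequence):
            raise IndexError(f"codon {codon_index} outside the coding sequence")
        return 3 * codon_index - 2, 3 * codon_index

    def codon(self, codon_index: int) -> str:
        start, end = self.codon_span(codon_index)
        return self.coding_sequence[start - 1 : end]

    @staticmethod
    def codon_index_of(cds_position: int) -> int:
        return (cds_position + 2) // 3

    def base(self, cds_position: int) -> str:
        if not 1 <= cds_position <= len(self.coding_sequence):
            raise IndexError(f"CDS position {cds_position} out of range")
        return self.coding_sequence[cds_position - 1]

    def exon_interval(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.exon_intervals:
            if lab == label:
                return start, end
        raise KeyError(f"no exon labelled {label!r}")

    def mds_region(
        self, name: str, utr_flank: int = 6, intron_flank: int = 6
    ) -> TargetRegion:
        """Build the MDS target region for an exon, with flanks for exon 1.

        The exon-1 region extends ``utr_flank`` bases into the 5'UTR
        (labels "-1", "-2", ... reading away from the ATG) and
        ``intron_flank`` bases into the downstream intron (labels "111+1",
        ...); exon 2 is taken without flanks.
        """
        start, end = self.exon_interval(name)
        seq = self.coding_sequence[start - 1 : end]
        labels: list[str] = [str(p) for p in range(start, end + 1)]
        cds: list[int | None] = list(range(start, end + 1))
        if name == "exon1":
            utr_flank = min(utr_flank, len(self.utr5))
            intron_flank = min(intron_flank, len(self.intron1))
            utr = self.utr5[len(self.utr5) - utr_flank :]
            seq = utr + seq + self.intron1[:intron_flank]
            labels = (
                [f"-{utr_flank - i}" for i in range(utr_flank)]
                + labels
                + [f"{end}+{i + 1}" for i in range(intron_flank)]
            )
            cds = [None] * utr_flank + cds + [None] * intron_flank
        return TargetRegion(name, seq, tuple(labels), tuple(cds))


# -- operations --------------------------------------------------------------

_REQUIRED_CONFIG_KEYS = (
    "exons",
    "hotspot_codons",
    "discriminator_interval",
    "discriminator_native",
    "discriminator_ex3op",
    "strain_snp_position",
    "strain_snp_base_129",
    "strain_snp_base_b6",
)


def _parse_interval(text: str) -> tuple[int, int]:
    start, _, end = text.partition("-")
    return int(start), int(end)


def load_reference(fasta_path: str | Path, config_path: str | Path) -> ReferenceLocus:
    """Load a validated :class:`ReferenceLocus` from FASTA + key/value config.

    The FASTA holds the coding-strand CDS (native allele).  The config is a
    two-column TSV of ``key<TAB>value`` pairs ('#' comments allowed) with keys
    ``exons`` (e.g. ``exon1:1-111,exon2:112-290,exon3:291-321``),
    ``hotspot_codons``, ``discriminator_interval``, ``discriminator_native``,
    ``discriminator_ex3op``, ``strain_snp_position``, ``strain_snp_base_129``,
    ``strain_snp_base_b6`` and optionally ``name``, ``utr5``, ``intron1``.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise SequenceFormatError(f"no FASTA records in {fasta_path}")
    record = records[0]
    cds = str(record.seq).upper()
    _check_acgt(cds, "FASTA coding sequence")

    config: dict[str, str] = {}
    for line in Path(config_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("\t")
        config[key.strip()] = value.strip()
    missing = [k for k in _REQUIRED_CONFIG_KEYS if k not in config]
    if missing:
        raise LocusConfigError(f"locus config missing required keys: {missing}")

    exons = []
    for part in config["exons"].split(","):
        label, _, interval = part.strip().partition(":")
        exons.append((label, *_parse_interval(interval)))
    disc_start, disc_end = _parse_interval(config["discriminator_interval"])
    return ReferenceLocus(
        name=config.get("name", record.id),
        coding_sequence=cds,
        exon_intervals=tuple(exons),
        hotspot_codons=tuple(
            int(c) for c in config["hotspot_codons"].split(",") if c.strip()
        ),
        discriminator=AlleleDiscriminator(
            disc_start,
            disc_end,
            config["discriminator_native"].upper(),
            config["discriminator_ex3op"].upper(),
        ),
        strain_snp=StrainSNP(
            int(config["strain_snp_position"]),
            config["strain_snp_base_129"].upper(),
            config["strain_snp_base_b6"].upper(),
        ),
        utr5=config.get("utr5", "").upper(),
        intron1=config.get("intron1", "").upper(),
    )


def enumerate_missense_variants(
    locus: ReferenceLocus, codons: Sequence[int] | None = None
) -> list[VariantReference]:
    """All single-nucleotide missense variants at the given codons.

    Synonymous and nonsense changes are excluded; ordering is deterministic
    (CDS position, then alt base alphabetically).
    """
    if codons is None:
        codons = locus.hotspot_codons
    variants: list[VariantReference] = []
    for codon_index in codons:
        start, _ = locus.codon_span(codon_index)  # raises on out-of-range
        ref_codon = locus.codon(codon_index)
        ref_aa = translate_codon(ref_codon)
        for within, alt in itertools.product(range(3), NUCLEOTIDES):
            ref_base = ref_codon[within]
            if alt == ref_base:
                continue
            mutated = ref_codon[:within] + alt + ref_codon[within + 1 :]
            alt_aa = translate_codon(mutated)
            if alt_aa == ref_aa or alt_aa == "*":
                continue
            variants.append(
                VariantReference(
                    codon_index=codon_index,
                    cds_position=start + within,
                    ref_base=ref_base,
                    alt_base=alt,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    label=f"{ref_aa}{codon_index}{alt_aa}",
                    expected_codon=mutated,
                )
            )
    variants.sort(key=lambda v: (v.cds_position, v.alt_base))
    return variants


def variant_from_substitution(
    locus: ReferenceLocus, cds_position: int, alt_base: str
) -> Substitution:
    """Describe a coding-strand substitution with context and consequence."""
    ref = locus.base(cds_position)
    alt_base = alt_base.upper()
    _check_acgt(alt_base, "alt base")
    if alt_base == ref:
        raise DegenerateSubstitutionError(
            f"alt base {alt_base} equals the reference at CDS {cds_position}"
        )
    if cds_position > 1:
        five = locus.coding_sequence[cds_position - 2]
    else:
        five = locus.utr5[-1] if locus.utr5 else "N"
    if cds_position < len(locus.coding_sequence):
        three = locus.coding_sequence[cds_position]
    else:
        three = "N"
    codon_index = locus.codon_index_of(cds_position)
    within = cds_position - (3 * codon_index - 2)
    ref_codon = locus.codon(codon_index)
    mutated = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    consequence = (
        f"{translate_codon(ref_codon)}{codon_index}{translate_codon(mutated)}"
    )
    return Substitution(
        cds_position=cds_position,
        ref_base=ref,
        alt_base=alt_base,
        five_prime=five,
        three_prime=three,
        codon_index=codon_index,
        consequence=consequence,
    )


def write_variant_table(
    variants: Iterable[VariantReference], path: str | Path, locus_name: str
) -> None:
    """Export enumerated variants as a minimal VCF-like TSV."""
    with open(path, "w") as handle:
        handle.write("CHROM\tPOS\tREF\tALT\tINFO\n")
        for v in variants:
            handle.write(
                f"{locus_name}\t{v.cds_position}\t{v.ref_base}\t{v.alt_base}\t"
                f"label={v.label};codon={v.codon_index}\n"
            )


# -- synthetic default locus --------------------------------------------------

# Synthetic stand-in for the unpublished mouse Kras amplicon reference: a
# deterministic, stop-free 321-nt ORF with the real coordinate landmarks
# (GGT at codon 12, GGC at codon 13, CAA at codon 61, a strain SNP at nt 96,
# an 8-nt allele discriminator in exon 3) but otherwise arbitrary sequence.
_SYNTHETIC_CDS = (
    "ATGGTTCTTCCCGGACAGTTCTTTCGGTTACAAGGTGGCTTTCTGTTCTGTACGAATTCCAATGGTCTCG"
    "GAATCAATAGGTACAGTGGAGTAGTTTGGGTGCGATGGACTTCTAAGTCTTGTGGCCTCTCGTATTATAT"
    "CCACACGCTTTCCTGCGCCAGAACCCCTTCCATTTCAGCGCAACTCTTGGCGGCGGTGGGCCCTCAGAGG"
    "TGTGTTACTAGAGGAGGTAGTGTCGCAGACGTAGATCAACCTCCGCACATCTGTCAGTCGACTCCCGGCC"
    "ATTCGATGACCACGGAAGTGTCAGTGTTTCCCAGAGCTCCA"
)
_SYNTHETIC_UTR5 = "AAAACCTCTTGA"
_SYNTHETIC_INTRON1 = "TTCCAGCGTTTT"


def synthetic_locus() -> ReferenceLocus:
    """Synthetic Kras-like reference locus (test/simulation default).

    Carries GGT/GGC at codons 12/13, CAA at codon 61 (so G12D is a
    G(G35)T>GAT change, G13D a G(G38)C>GAC change, and Q61L a C(A182)A>CTA
    change, all with the real local contexts), a T(129)/C(B6) strain SNP at
    CDS 96, and an 8-nt native/ex3op discriminator at CDS 299-306.  The
    surrounding sequence is synthetic and carries no other meaning.
    """
    return ReferenceLocus(
        name="Kras_synthetic",
        coding_sequence=_SYNTHETIC_CDS,
        exon_intervals=(("exon1", 1, 111), ("exon2", 112, 290), ("exon3", 291, 321)),
        hotspot_codons=(12, 13, 61),
        discriminator=AlleleDiscriminator(299, 306, "TGTCAGTG", "CGCCGGCG"),
        strain_snp=StrainSNP(96, "T", "C"),
        utr5=_SYNTHETIC_UTR5,
        intron1=_SYNTHETIC_INTRON1,
    )
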