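"""Independent brute-force oracles used to cross-check the callers.

These deliberately avoid the library's own data structures and hashing:
grouping is quadratic over the read list, consensus selection re-counts
sequences by linear scans, and missense enumeration tries all nine
substitutions per codon with Biopython translation.
"""

from Bio.Seq import Seq

BASES = "ACGT"


def brute_force_missense(codon_seq: str, codon_index: int, cds_start: int):
    """All 9 single-nt substitutions of a codon, filtered to missense."""
    ref_aa = str(Seq(codon_seq).translate())
    out = []
    for i in range(3):
        for alt in BASES:
            if alt == codon_seq[i]:
                continue
            mutated = codon_seq[:i] + alt + codon_seq[i + 1 :]
            alt_aa = str(Seq(mutated).translate())
            if alt_aa != ref_aa and alt_aa != "*":
                out.append((cds_start + i, codon_seq[i], alt, ref_aa, alt_aa, mutated))
    out.sort(key=lambda t: (t[0], t[2]))
    return out


def quadratic_consensus_frequencies(
    read_seqs, reference_coding, barcode_length=14, min_reads=2, min_identity=0.90
):
    """Hash-free re-implementation of grouping, consensus and frequencies.

    Returns (total_accepted, {(offset, ref, alt): count}) with offsets into
    the coding-strand reference; reads are on the non-transcribed strand.
    """
    complement = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

    reads = [s for s in read_seqs if len(s) >= barcode_length]
    used = [False] * len(reads)
    families = []
    for i in range(len(reads)):
        if used[i]:
            continue
        barcode = reads[i][:barcode_length]
        members = []
        for j in range(i, len(reads)):
            if not used[j] and reads[j][:barcode_length] == barcode:
                members.append(reads[j][barcode_length:])
                used[j] = True
        families.append(members)

    total_accepted = 0
    counts = {}
    for members in families:
        if len(members) < min_reads:
            continue
        # modal sequence by linear scanning, smallest-sequence tie-break
        best_seq, best_n = None, 0
        for candidate in members:
            n = sum(1 for m in members if m == candidate)
            if n > best_n or (n == best_n and candidate < best_seq):
                best_seq, best_n = candidate, n
        if best_n / len(members) < min_identity:
            continue
        total_accepted += 1
        coding = "".join(complement[b] for b in reversed(best_seq))
        if len(coding) != len(reference_coding):
            continue  # complex: counted in the denominator only
        diffs = [
            k for k in range(len(coding)) if coding[k] != reference_coding[k]
        ]
        if len(diffs) == 1:
            k = diffs[0]
            key = (k, reference_coding[k], coding[k])
            counts[key] = counts.get(key, 0) + 1
    return total_accepted, counts
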