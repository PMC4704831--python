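"""In-silico bisulfite conversion and pyrosequencing-assay utilities.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as
thymine after PCR) while 5-methylcytosine is protected, so a converted
template retains C only at methylated CpG positions.  PCR/sequencing primers
for bisulfite assays are designed against the fully converted strand; a
primer containing C at a non-CpG position can never anneal to a converted
template, which gives a simple composition check.

Coordinates are 0-based on the top strand throughout.  Full conversion
efficiency is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

VALID_BASES = frozenset("ACGT")


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what} is empty")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return str(Seq(_check_dna(seq, "sequence")).reverse_complement())


def all_cpg_positions(sequence: str) -> list[int]:
    """0-based positions of the C of every CpG dinucleotide."""
    sequence = _check_dna(sequence, "sequence")
    return [i for i in range(len(sequence) - 1)
            if sequence[i] == "C" and sequence[i + 1] == "G"]


@dataclass
class AssayDesign:
    """Primer set of a pyrosequencing assay (biotinylated reverse primer)."""

    forward_primer: str
    reverse_primer: str
    sequencing_primer: str
    target_cpg_count: int = 4
    reverse_biotinylated: bool = True

    def __post_init__(self) -> None:
        self.forward_primer = _check_dna(self.forward_primer, "forward primer")
        self.reverse_primer = _check_dna(self.reverse_primer, "reverse primer")
        self.sequencing_primer = _check_dna(self.sequencing_primer, "sequencing primer")
        if self.target_cpg_count < 0:
            raise ValueError("target_cpg_count must be >= 0")


def bisulfite_convert(sequence: str, methylation: frozenset[int] | set[int] = frozenset(),
                      ) -> str:
    """Convert a top-strand sequence: every unmethylated C becomes T.

    ``methylation`` holds the 0-based positions of methylated CpG cytosines;
    each must actually be a C followed by G in ``sequence``.
    """
    sequence = _check_dna(sequence, "sequence")
    cpgs = set(all_cpg_positions(sequence))
    bad = set(methylation) - cpgs
    if bad:
        raise ValueError(
            f"methylation positions {sorted(bad)[:5]} are not CpG cytosines")
    out = []
    for i, base in enumerate(sequence):
        if base == "C" and i not in methylation:
            out.append("T")
        else:
            out.append(base)
    return "".join(out)


@dataclass
class CompatibilityReport:
    compatible: bool
    forward_found: bool
    reverse_found: bool
    sequencing_found: bool
    amplicon: tuple[int, int] | None  # [start, end) on the converted strand
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


def _composition_problem(primer: str, converted: str, name: str) -> str | None:
    """If a primer is absent but its C->T image is present, the primer's C at
    a converted (non-CpG) position is the cause."""
    if "C" in primer and primer.replace("C", "T") in converted:
        return (f"{name} contains C at a position that is T on the fully "
                f"converted template")
    return None


def check_primer_compatibility(design: AssayDesign, converted_top_strand: str,
                               reference: str | None = None,
                               ) -> CompatibilityReport:
    """Check the three assay primers against a converted top strand.

    The forward and sequencing primers must occur as exact substrings; the
    reverse primer anneals to the top strand via its reverse complement.
    If the unconverted ``reference`` is supplied, a warning is issued for any
    primer footprint covering a CpG position (its conversion state is
    ambiguous, so the primer may bias amplification).
    """
    converted = _check_dna(converted_top_strand, "converted strand")
    warnings: list[str] = []
    errors: list[str] = []

    fwd = design.forward_primer
    rev_rc = reverse_complement(design.reverse_primer)
    seqp = design.sequencing_primer

    fwd_pos = converted.find(fwd)
    rev_pos = converted.find(rev_rc)
    seq_pos = converted.find(seqp)

    for name, primer, pos in (("forward primer", fwd, fwd_pos),
                              ("reverse primer (revcomp)", rev_rc, rev_pos),
                              ("sequencing primer", seqp, seq_pos)):
        if pos < 0:
            problem = _composition_problem(primer, converted, name)
            errors.append(problem or f"{name} not found in converted strand")

    amplicon = None
    if fwd_pos >= 0 and rev_pos >= 0:
        start, end = fwd_pos, rev_pos + len(rev_rc)
        if end <= start:
            errors.append("reverse primer site upstream of forward primer site")
        else:
            amplicon = (start, end)
            if seq_pos >= 0 and not (start <= seq_pos < end):
                warnings.append("sequencing primer anneals outside the amplicon")

    if reference is not None:
        reference = _check_dna(reference, "reference")
        if len(reference) != len(converted):
            raise ValueError("reference and converted strand lengths differ")
        cpgs = set(all_cpg_positions(reference))
        for name, primer, pos in (("forward primer", fwd, fwd_pos),
                                  ("reverse primer", rev_rc, rev_pos),
                                  ("sequencing primer", seqp, seq_pos)):
            if pos >= 0 and any(p in cpgs for p in range(pos, pos + len(primer))):
                warnings.append(f"{name} footprint covers a CpG position "
                                "(conversion-state ambiguity under the primer)")

    return CompatibilityReport(
        compatible=not errors,
        forward_found=fwd_pos >= 0,
        reverse_found=rev_pos >= 0,
        sequencing_found=seq_pos >= 0,
        amplicon=amplicon,
        warnings=warnings,
        errors=errors,
    )


def enumerate_cpgs(reference: str, amplicon: tuple[int, int],
                   sequencing_primer: str) -> list[int]:
    """CpG positions read by the assay: strictly downstream of the sequencing
    primer's 3' end, within the amplicon.

    The primer is located within the amplicon on the reference directly or,
    failing that, on its bisulfite-converted images (all-CpG-methylated
    first, then fully unmethylated).
    """
    reference = _check_dna(reference, "reference")
    sequencing_primer = _check_dna(sequencing_primer, "sequencing primer")
    start, end = amplicon
    if not 0 <= start < end <= len(reference):
        raise ValueError(f"amplicon {amplicon} outside the reference")
    region = reference[start:end]
    candidates = [region,
                  bisulfite_convert(region, set(all_cpg_positions(region))),
                  bisulfite_convert(region)]
    pos = -1
    for template in candidates:
        pos = template.find(sequencing_primer)
        if pos >= 0:
            break
    if pos < 0:
        raise ValueError("sequencing primer not found within the amplicon")
    three_prime_end = start + pos + len(sequencing_primer)
    return [p for p in all_cpg_positions(reference)
            if three_prime_end <= p < end]


def quantify_methylation(read_counts: list[tuple[int, int]]) -> list[float]:
    """Percent methylation per CpG from (methylated, total) read counts."""
    out = []
    for i, (meth, total) in enumerate(read_counts, start=1):
        if total < 1:
            raise ValueError(f"CpG {i}: total read count must be >= 1")
        if not 0 <= meth <= total:
            raise ValueError(f"CpG {i}: methylated count {meth} outside [0, {total}]")
        out.append(100.0 * meth / total)
    return out
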