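"""Published sugar pine (Pinus lambertiana) rescaffolding statistics.

Per-library sequencing accounting for the five GemCode read-cloud
libraries used to rescaffold the 31 Gbp sugar pine draft assembly, and
the contiguity statistics of the assembly before and after
rescaffolding.  These printed values serve as inputs for consistency
checks of the coverage and contiguity arithmetic implemented here; they
are not recomputed from raw sequence.
"""

from __future__ import annotations

import dataclasses

GENOME_SIZE = 31_000_000_000  # haploid sugar pine genome, bp

#: Physical-coverage scaling factor: all aligned reads over reads
#: aligned to the >500 kb scaffolds used for cloud demarcation.
CLOUD_SCALING_FACTOR = 3.1


@dataclasses.dataclass(frozen=True, slots=True)
class LibraryAccounting:
    """One library's read accounting as published."""

    library: int
    paired_reads: int
    read_lengths: tuple[int, int]  # post-trimming read1 + read2, bp
    raw_coverage: float  # printed, x
    aligned_reads: int
    filtered_aligned_reads: int


#: The five GemCode libraries (library 1 without size selection,
#: libraries 2-5 size-selected at 40 kb).
LIBRARIES: tuple[LibraryAccounting, ...] = (
    LibraryAccounting(1, 232_879_210, (88, 98), 0.70, 181_462_035, 111_854_014),
    LibraryAccounting(2, 232_329_746, (88, 98), 0.70, 195_340_154, 125_001_615),
    LibraryAccounting(3, 311_708_094, (91, 101), 0.97, 288_643_022, 177_242_573),
    LibraryAccounting(4, 297_865_798, (91, 101), 0.92, 274_488_516, 168_110_243),
    LibraryAccounting(5, 310_580_224, (91, 101), 0.96, 286_623_246, 177_826_361),
)

#: Published totals across the five libraries.
TOTAL_READS = 1_385_363_072
TOTAL_ALIGNED = 1_226_556_973
TOTAL_FILTERED = 760_034_806
TOTAL_RAW_COVERAGE = 4.25  # x, printed

#: Contiguity of the draft (v1.0) and rescaffolded (v1.5) assemblies,
#: with and without counting N padding, in bp.
ASSEMBLY_CONTIGUITY = {
    "original_with_n": {
        "max_length": 4_064_336,
        "n50": 324_201,
        "n10": 959_930,
        "n90": 72_460,
    },
    "original_no_n": {
        "max_length": 3_809_096,
        "n50": 306_897,
        "n10": 904_501,
        "n90": 69_664,
    },
    "rescaffolded_with_n": {
        "max_length": 23_976_851,
        "n50": 2_668_366,
        "n10": 8_710_993,
        "n90": 406_554,
    },
    "rescaffolded_no_n": {
        "max_length": 22_367_058,
        "n50": 2_509_905,
        "n10": 8_182_563,
        "n90": 399_889,
    },
}

#: Scaffold NG50 before and after rescaffolding (31 Gbp genome size).
NG50_ORIGINAL = 247_000
NG50_RESCAFFOLDED = 1_940_000

#: Final calibration-run linking error rates, percent.
FINAL_TYPE1_ERROR = 4.85
FINAL_TYPE2_ERROR = 8.69

#: Calibration split of the draft: children cut from >=500 kb parents.
N_CALIBRATION_PARENTS = 10_403
N_CALIBRATION_CHILDREN = 157_873

#: Estimated genome-wide physical coverage in HMW fragments, x.
TOTAL_PHYSICAL_COVERAGE = 23.8
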