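"""Small shared helpers: sequence operations and interval conversions."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Reference 22-nt spliced-leader sequence used when none is configured; only
# its length and TCAAG 3' pentamer are semantically meaningful.
DEFAULT_SL = "GCTATTTCGGCTATGCGTCAAG"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction over non-N bases; 0.0 for empty/all-N sequences."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open (BED)."""
    return start - 1, end


def from_bed(bed_start: int, bed_end: int) -> tuple[int, int]:
    """0-based half-open (BED) -> 1-based inclusive."""
    return bed_start + 1, bed_end
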