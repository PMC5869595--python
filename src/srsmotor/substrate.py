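"""Linear DNA substrate specifications for the lattice model.

A substrate is a 1D lattice of ``length_bp`` sites (1 site = 1 bp) carrying
zero or more SRS (SpoIIIE Recognition Sequence) intervals, each with an
orientation (the DNA end the motif points toward), optionally a
triplex-forming oligonucleotide at one end, and — on non-specific control
substrates — a window marking the position the SRS would occupy.

Coordinates are 0-based, half-open throughout.  The left end is position 0
and is the 5' (triplex) end of the canonical SRS substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

#: The SRS 8-mer repeated three times in the experimental DNA_SRS oligo.
SRS_MOTIF = "GAGAAGGG"
SRS_OLIGO = "GAGAAGGGAGAAGGGAGAAGGG"
#: GC-matched scrambled control cloned into the non-specific substrate.
NS_CONTROL_OLIGO = "GGAGGCGGGAGGCGGGAGGCGG"

TOWARD_LEFT_END = "toward_left_end"
TOWARD_RIGHT_END = "toward_right_end"

_VALID_ORIENTATIONS = (TOWARD_LEFT_END, TOWARD_RIGHT_END)
_VALID_TRIPLEX = ("left", "right", "none")


class SubstrateError(ValueError):
    """Raised when a substrate specification is geometrically invalid."""


@dataclass(frozen=True)
class SubstrateSpec:
    """Geometry of one linear DNA molecule.

    Parameters
    ----------
    length_bp
        Number of lattice sites (1 site = 1 bp).
    srs_intervals
        ``(start, end, orientation)`` tuples, 0-based half-open, pairwise
        disjoint, orientation in ``{toward_left_end, toward_right_end}``.
    triplex_end
        ``"left"``, ``"right"`` or ``"none"``.
    control_window
        ``(start, end)`` marking the SRS-equivalent region on a substrate
        without SRS (the AFM control), or ``None``.
    """

    length_bp: int
    srs_intervals: tuple = ()
    triplex_end: str = "none"
    control_window: tuple | None = None
    label: str = ""
    _site_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.length_bp < 2:
            raise SubstrateError(f"substrate needs >= 2 sites, got {self.length_bp}")
        if self.triplex_end not in _VALID_TRIPLEX:
            raise SubstrateError(f"triplex_end must be one of {_VALID_TRIPLEX}")
        ivals = tuple(tuple(iv) for iv in self.srs_intervals)
        object.__setattr__(self, "srs_intervals", ivals)
        for start, end, orient in ivals:
            if not (0 <= start < end <= self.length_bp):
                raise SubstrateError(
                    f"SRS interval [{start}, {end}) outside [0, {self.length_bp}]"
                )
            if orient not in _VALID_ORIENTATIONS:
                raise SubstrateError(f"bad orientation {orient!r}")
        for (s1, e1, _), (s2, e2, _) in zip(sorted(ivals), sorted(ivals)[1:]):
            if s2 < e1:
                raise SubstrateError(
                    f"SRS intervals [{s1},{e1}) and [{s2},{e2}) overlap"
                )
        if self.control_window is not None:
            s, e = self.control_window
            if not (0 <= s < e <= self.length_bp):
                raise SubstrateError(f"control window [{s}, {e}) out of range")
            object.__setattr__(self, "control_window", (int(s), int(e)))

    # -- derived lattice annotations -------------------------------------

    @property
    def has_srs(self) -> bool:
        return bool(self.srs_intervals)

    def srs_union_window(self) -> tuple | None:
        """Smallest window covering all SRS intervals (or the control window)."""
        if self.srs_intervals:
            starts = [iv[0] for iv in self.srs_intervals]
            ends = [iv[1] for iv in self.srs_intervals]
            return (min(starts), max(ends))
        return self.control_window

    def is_srs_array(self) -> np.ndarray:
        """Boolean site mask, True on SRS sites."""
        key = "is_srs"
        if key not in self._site_cache:
            mask = np.zeros(self.length_bp, dtype=bool)
            for start, end, _ in self.srs_intervals:
                mask[start:end] = True
            self._site_cache[key] = mask
        return self._site_cache[key]

    def srs_direction_array(self) -> np.ndarray:
        """Per-site dictated translocation direction: -1 toward the left end,
        +1 toward the right end, 0 on non-specific sites."""
        key = "srs_dir"
        if key not in self._site_cache:
            arr = np.zeros(self.length_bp, dtype=np.int8)
            for start, end, orient in self.srs_intervals:
                arr[start:end] = -1 if orient == TOWARD_LEFT_END else 1
            self._site_cache[key] = arr
        return self._site_cache[key]

    def validate_triplex_orientation(self) -> None:
        """On an SRS substrate with a triplex, the triplex must sit at the end
        the SRS orientation points toward."""
        if self.triplex_end == "none" or not self.srs_intervals:
            return
        want = TOWARD_LEFT_END if self.triplex_end == "left" else TOWARD_RIGHT_END
        for start, end, orient in self.srs_intervals:
            if orient != want:
                raise SubstrateError(
                    f"SRS interval [{start},{end}) points {orient} but the "
                    f"triplex is at the {self.triplex_end} end"
                )

    def with_triplex(self, end: str) -> "SubstrateSpec":
        spec = replace(self, triplex_end=end, _site_cache={})
        spec.validate_triplex_orientation()
        return spec


# -- constructors ---------------------------------------------------------

#: Frozen default geometry: ~3 kb linear substrate (pBS SK(+) derivative),
#: one 22-bp SRS triple-repeat with its proximal edge 300 bp from the
#: triplex (left, 5') end, oriented toward that end.
DEFAULT_LENGTH_BP = 3000
DEFAULT_SRS_OFFSET_BP = 300
DEFAULT_SRS_LENGTH_BP = len(SRS_OLIGO)


def make_dna_srs(
    length_bp: int = DEFAULT_LENGTH_BP,
    srs_offset_bp: int = DEFAULT_SRS_OFFSET_BP,
    srs_length_bp: int = DEFAULT_SRS_LENGTH_BP,
    triplex: str = "none",
    label: str = "",
) -> SubstrateSpec:
    """Build the canonical SRS substrate (or its non-specific control).

    The SRS interval of ``srs_length_bp`` sites is placed ``srs_offset_bp``
    from the left end and oriented toward the left end, matching the
    experimental design where the SRS repeats point at the nearest DNA end
    (the 5' end that carries the triplex when present).  ``srs_length_bp = 0``
    yields a pure non-specific control whose ``control_window`` marks the
    SRS-equivalent region.
    """
    if length_bp < 2:
        raise SubstrateError(f"length_bp must be >= 2, got {length_bp}")
    if srs_offset_bp < 0:
        raise SubstrateError("srs_offset_bp must be >= 0")
    window_len = srs_length_bp if srs_length_bp > 0 else DEFAULT_SRS_LENGTH_BP
    if srs_offset_bp + window_len >= length_bp:
        raise SubstrateError(
            f"SRS interval [{srs_offset_bp}, {srs_offset_bp + window_len}) "
            f"does not fit strictly inside a {length_bp}-bp substrate"
        )
    if triplex not in _VALID_TRIPLEX:
        raise SubstrateError(f"triplex must be one of {_VALID_TRIPLEX}")
    if srs_length_bp > 0:
        spec = SubstrateSpec(
            length_bp=length_bp,
            srs_intervals=((srs_offset_bp, srs_offset_bp + srs_length_bp,
                            TOWARD_LEFT_END),),
            triplex_end=triplex,
            label=label or "DNA_SRS",
        )
        spec.validate_triplex_orientation()
        return spec
    return SubstrateSpec(
        length_bp=length_bp,
        srs_intervals=(),
        triplex_end=triplex,
        control_window=(srs_offset_bp, srs_offset_bp + window_len),
        label=label or "DNA_NS",
    )


def make_dna_ns(
    length_bp: int = DEFAULT_LENGTH_BP,
    window_offset_bp: int = DEFAULT_SRS_OFFSET_BP,
    window_length_bp: int = DEFAULT_SRS_LENGTH_BP,
    triplex: str = "none",
    label: str = "DNA_NS",
) -> SubstrateSpec:
    """Non-specific control substrate: no SRS, control window at the
    SRS-equivalent position, optional triplex at the SRS-equivalent end."""
    return make_dna_srs(length_bp, window_offset_bp, 0, triplex=triplex,
                        label=label)


# -- motif scanning -------------------------------------------------------

_NUCLEOTIDES = set("ACGTN")


def scan_sequence_for_srs(sequence: str, motif: str = SRS_MOTIF) -> list:
    """Exact-match scan of a DNA sequence for a motif on both strands.

    Returns ``(start, end, orientation)`` tuples, 0-based half-open, with
    overlapping matches all reported.  Forward-strand hits are oriented
    ``toward_left_end`` (the convention of :func:`make_dna_srs`, where the
    printed SRS repeat points at the 5' end); reverse-complement hits get the
    opposite orientation.
    """
    sequence = sequence.upper()
    if not motif:
        raise SubstrateError("motif must be non-empty")
    motif = motif.upper()
    bad = set(sequence) - _NUCLEOTIDES
    if bad:
        raise SubstrateError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    rc = str(Seq(motif).reverse_complement())
    hits = []
    for needle, orient in ((motif, TOWARD_LEFT_END), (rc, TOWARD_RIGHT_END)):
        start = sequence.find(needle)
        while start != -1:
            hits.append((start, start + len(needle), orient))
            start = sequence.find(needle, start + 1)
    hits.sort()
    return hits


def scan_fasta_for_srs(fasta_path, motif: str = SRS_MOTIF) -> dict:
    """Scan every record of a FASTA file; returns {record id: hit list}."""
    from Bio import SeqIO

    out = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        out[record.id] = scan_sequence_for_srs(str(record.seq), motif)
    return out


def spec_from_fasta(fasta_path, motif: str = SRS_MOTIF,
                    triplex: str = "none") -> SubstrateSpec:
    """Build a SubstrateSpec from the first record of a FASTA file by
    merging touching/overlapping motif hits into SRS intervals."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(fasta_path), "fasta"), None)
    if record is None:
        raise SubstrateError(f"no FASTA records in {fasta_path}")
    hits = scan_sequence_for_srs(str(record.seq), motif)
    merged = []
    for start, end, orient in hits:
        if merged and start <= merged[-1][1] and orient == merged[-1][2]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end, orient])
    return SubstrateSpec(
        length_bp=len(record.seq),
        srs_intervals=tuple((s, e, o) for s, e, o in merged),
        triplex_end=triplex,
        label=record.id,
    )


def intervals_to_bed(spec: SubstrateSpec, path) -> None:
    """Write SRS intervals as BED6 (chrom = substrate label, strand from
    orientation: '+' toward the right end, '-' toward the left end)."""
    chrom = spec.label or "substrate"
    with open(path, "w") as fh:
        for i, (start, end, orient) in enumerate(spec.srs_intervals):
            strand = "-" if orient == TOWARD_LEFT_END else "+"
            fh.write(f"{chrom}\t{start}\t{end}\tSRS_{i}\t0\t{strand}\n")
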