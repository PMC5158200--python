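"""pLKO.1-style shRNA hairpin oligo parsing and stem analysis.

A pLKO.1 sense-strand cloning oligo reads, 5'->3':

    CCGG | sense arm | CTCGAG | antisense arm | TTTTT(T)

i.e. an AgeI-compatible cloning prefix, a stem arm (21 nt in the constructs
shipped with this package), the XhoI loop, the opposing stem arm, and a
poly-T Pol III terminator of at least five Ts.  The parser recovers this
decomposition exactly: it requires the prefix, then searches jointly over
loop placements and terminator lengths for the unique segmentation with
equal-length arms and an all-T terminator of length >= 5.  If no placement
or more than one placement satisfies the constraints, parsing fails loudly
rather than guessing.

The first arm is labelled "sense" by pLKO.1 convention; no guide/passenger
assignment is made.  A transcribed reference table of the 30 constructs
this package was developed around ships as packaged data
(``load_reference_oligos``), including seven mutant hairpins derived from
the parental PIAS2 constructs by stem substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .errors import ParseError

__all__ = [
    "ShrnaOligo",
    "parse_plko_oligo",
    "reverse_complement",
    "stem_complementarity",
    "arm_mismatches",
    "gc_content",
    "load_reference_oligos",
    "read_oligos",
    "parse_oligo_table",
    "oligo_structure_table",
]

PREFIX = "CCGG"
LOOP = "CTCGAG"
MIN_TERMINATOR = 5
_DNA = set("ACGT")


def _check_dna(seq: str, context: str = "sequence") -> str:
    bad = set(seq) - _DNA
    if bad:
        raise ParseError(f"{context} contains non-ACGT characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class ShrnaOligo:
    """A decomposed hairpin oligo; joining the parts reproduces full_seq."""

    name: str
    full_seq: str
    prefix: str
    sense: str
    loop: str
    antisense: str
    terminator: str

    def __post_init__(self):
        parts = self.prefix + self.sense + self.loop + self.antisense + self.terminator
        if parts != self.full_seq:
            raise ParseError(f"'{self.name}': parts do not reconstruct full_seq")
        if len(self.sense) != len(self.antisense):
            raise ParseError(f"'{self.name}': unequal arm lengths")

    @property
    def arm_length(self) -> int:
        return len(self.sense)

    @property
    def terminator_length(self) -> int:
        return len(self.terminator)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string."""
    _check_dna(seq)
    return str(Seq(seq).reverse_complement())


def gc_content(seq: str) -> float:
    """Fraction of G+C in a non-empty DNA sequence."""
    if not seq:
        raise ParseError("gc_content of empty sequence is undefined")
    _check_dna(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


def parse_plko_oligo(
    name: str,
    seq: str,
    prefix: str = PREFIX,
    loop: str = LOOP,
    min_terminator: int = MIN_TERMINATOR,
) -> ShrnaOligo:
    """Decompose a pLKO.1 hairpin oligo into its structural parts.

    Searches all loop-motif occurrences for the segmentation with
    equal-length arms followed by an all-T terminator of >= min_terminator
    nucleotides.  Exactly one such segmentation must exist.
    """
    seq = seq.strip().upper()
    _check_dna(seq, context=f"'{name}'")
    if not seq.startswith(prefix):
        raise ParseError(f"'{name}': missing cloning prefix '{prefix}'")
    body = seq[len(prefix):]
    if loop not in body:
        raise ParseError(f"'{name}': loop motif '{loop}' not found")

    placements = []
    start = 0
    while (i := body.find(loop, start)) != -1:
        start = i + 1
        sense = body[:i]
        rest = body[i + len(loop):]
        antisense, terminator = rest[: len(sense)], rest[len(sense):]
        if (
            len(sense) > 0
            and len(antisense) == len(sense)
            and len(terminator) >= min_terminator
            and set(terminator) <= {"T"}
        ):
            placements.append((sense, antisense, terminator))
    if not placements:
        raise ParseError(
            f"'{name}': no loop placement yields equal arms and a "
            f">= {min_terminator}-nt poly-T terminator"
        )
    if len(placements) > 1:
        raise ParseError(f"'{name}': ambiguous loop placement ({len(placements)} valid)")
    sense, antisense, terminator = placements[0]
    return ShrnaOligo(
        name=name, full_seq=seq, prefix=prefix, sense=sense, loop=loop,
        antisense=antisense, terminator=terminator,
    )


def stem_complementarity(o: ShrnaOligo) -> tuple[bool, tuple[int, ...]]:
    """Compare the antisense arm to the reverse complement of the sense arm.

    Returns (is_perfect, 0-based mismatch positions along the antisense arm).
    The mismatch count is unchanged if the arm labels are swapped.
    """
    expected = reverse_complement(o.sense)
    positions = tuple(i for i, (x, y) in enumerate(zip(o.antisense, expected)) if x != y)
    return (len(positions) == 0, positions)


def arm_mismatches(a: ShrnaOligo, b: ShrnaOligo) -> tuple[int, tuple[int, ...]]:
    """Positionwise Hamming distance between two oligos' sense arms."""
    if a.arm_length != b.arm_length:
        raise ParseError(
            f"arm lengths differ: '{a.name}' {a.arm_length} vs '{b.name}' {b.arm_length}"
        )
    positions = tuple(i for i, (x, y) in enumerate(zip(a.sense, b.sense)) if x != y)
    return (len(positions), positions)


# ---------------------------------------------------------------------------
# I/O

def load_reference_oligos() -> pd.DataFrame:
    """The packaged reference table of 30 hairpin constructs
    (name, gene, catalog, sequence)."""
    with resources.files("shrnakit.data").joinpath("shrna_oligos.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def read_oligos(path) -> pd.DataFrame:
    """Read oligos from TSV (columns incl. name, sequence) or FASTA."""
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ParseError(f"'{path}': no FASTA records")
        return pd.DataFrame(
            {"name": [r.id for r in records], "sequence": [str(r.seq) for r in records]}
        )
    df = pd.read_csv(path, sep="\t")
    missing = {"name", "sequence"} - set(df.columns)
    if missing:
        raise ParseError(f"'{path}': missing columns {sorted(missing)}")
    return df


def parse_oligo_table(df: pd.DataFrame) -> list[ShrnaOligo]:
    """Parse every (name, sequence) row of an oligo table."""
    return [parse_plko_oligo(row["name"], row["sequence"]) for _, row in df.iterrows()]


def oligo_structure_table(oligos: list[ShrnaOligo]) -> pd.DataFrame:
    """Parsed-structure summary: arms, terminator, GC, stem perfection."""
    rows = []
    for o in oligos:
        perfect, mismatches = stem_complementarity(o)
        rows.append(
            {
                "name": o.name,
                "sense": o.sense,
                "loop": o.loop,
                "antisense": o.antisense,
                "terminator_len": o.terminator_length,
                "arm_len": o.arm_length,
                "gc_sense": gc_content(o.sense),
                "perfect_stem": perfect,
                "stem_mismatch_positions": ";".join(map(str, mismatches)),
            }
        )
    return pd.DataFrame(rows)
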