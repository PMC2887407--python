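"""Genetic-code machinery, in-frame codon alignments, and composition statistics.

The standard nuclear genetic code is the only code supported: every analysis in
this package (site counting, codon likelihoods, codon-usage bias) runs over the
61 sense codons.  Alignments are nucleotide strings constrained to a reading
frame: the length is a multiple of three, gaps are whole-codon ``---`` and any
IUPAC ambiguity code is collapsed to ``N`` on input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneticCode",
    "STANDARD_CODE",
    "CodonAlignment",
    "CompositionSummary",
    "AlignmentError",
    "FrameError",
    "read_codon_fasta",
    "write_codon_fasta",
    "gc_content",
    "count_informative_sites",
]

NUCLEOTIDES = "TCAG"

_CODON_TABLE = {}
_AMINO = (
    "FFLLSSSSYY**CC*W"  # TTT..TGG
    "LLLLPPPPHHQQRRRR"  # CTT..CGG
    "IIIMTTTTNNKKSSRR"  # ATT..AGG
    "VVVVAAAADDEEGGGG"  # GTT..GGG
)
_i = 0
for _n1 in NUCLEOTIDES:
    for _n2 in NUCLEOTIDES:
        for _n3 in NUCLEOTIDES:
            _CODON_TABLE[_n1 + _n2 + _n3] = _AMINO[_i]
            _i += 1


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, bad frame length...)."""


class FrameError(AlignmentError):
    """Raised when a sequence contains an in-frame stop codon."""


@dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code over the 61 sense codons.

    Attributes
    ----------
    codon_to_aa
        Map from all 64 codons to one-letter amino acid, ``*`` for stops.
    sense_codons
        The 61 non-stop codons in fixed TCAG order; this ordering indexes the
        rate matrices of the likelihood engine.
    degeneracy_class
        Map codon -> size of its synonymous family (1, 2, 3, 4 or 6).
    """

    codon_to_aa: dict = field(default_factory=lambda: dict(_CODON_TABLE))

    @property
    def sense_codons(self) -> list[str]:
        return [c for c in _iter_codons() if self.codon_to_aa[c] != "*"]

    @property
    def stop_codons(self) -> list[str]:
        return [c for c in _iter_codons() if self.codon_to_aa[c] == "*"]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == "*"

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    @property
    def degeneracy_class(self) -> dict[str, int]:
        fam: dict[str, int] = {}
        for aa in set(self.codon_to_aa.values()):
            if aa == "*":
                continue
            fam[aa] = sum(1 for c, a in self.codon_to_aa.items() if a == aa)
        return {c: fam[a] for c, a in self.codon_to_aa.items() if a != "*"}

    def codon_index(self) -> dict[str, int]:
        """Sense codon -> position in the canonical 61-codon ordering."""
        return {c: i for i, c in enumerate(self.sense_codons)}


def _iter_codons() -> Iterable[str]:
    for n1 in NUCLEOTIDES:
        for n2 in NUCLEOTIDES:
            for n3 in NUCLEOTIDES:
                yield n1 + n2 + n3


STANDARD_CODE = GeneticCode()

_VALID_CHARS = set("ACGTN-")
_AMBIGUITY = set("RYSWKMBDHVU")


def _normalize_sequence(seq: str, name: str) -> str:
    """Uppercase, collapse ambiguity codes to N, normalize partial-codon gaps.

    A codon containing any gap character becomes ``---`` (frame integrity);
    a warning is emitted when a partial-codon gap was patched.
    """
    s = seq.upper().replace("U", "T")
    s = "".join("N" if ch in _AMBIGUITY else ch for ch in s)
    bad = set(s) - _VALID_CHARS
    if bad:
        raise AlignmentError(f"sequence {name!r}: invalid characters {sorted(bad)}")
    out = []
    patched = False
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        if "-" in codon and codon != "---":
            codon = "---"
            patched = True
        out.append(codon)
    if patched:
        warnings.warn(
            f"sequence {name!r}: partial-codon gaps normalized to full-codon '---'",
            stacklevel=3,
        )
    return "".join(out)


@dataclass
class CodonAlignment:
    """An in-frame codon alignment: equal-length sequences over ACGTN-.

    Coordinates are 0-based half-open internally; user-facing reports are
    1-based.
    """

    names: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise AlignmentError("names and sequences differ in count")
        if not self.sequences:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        (n,) = lengths
        if n % 3 != 0:
            raise AlignmentError(f"alignment length {n} is not a multiple of 3")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("duplicate sequence names")
        self.sequences = [
            _normalize_sequence(s, nm) for nm, s in zip(self.names, self.sequences)
        ]

    @property
    def length_nt(self) -> int:
        return len(self.sequences[0])

    @property
    def codon_columns(self) -> int:
        return self.length_nt // 3

    @property
    def n_sequences(self) -> int:
        return len(self.names)

    def codon(self, seq_index: int, codon_index: int) -> str:
        return self.sequences[seq_index][3 * codon_index : 3 * codon_index + 3]

    def codons(self, seq_index: int) -> list[str]:
        s = self.sequences[seq_index]
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def sequence(self, name: str) -> str:
        return self.sequences[self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "CodonAlignment":
        idx = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in idx]
        if missing:
            raise AlignmentError(f"unknown sequence names: {missing}")
        return CodonAlignment(
            names=list(names), sequences=[self.sequences[idx[n]] for n in names]
        )

    def window(self, start_nt: int, end_nt: int) -> "CodonAlignment":
        """Slice columns [start_nt, end_nt), both multiples of 3."""
        if start_nt % 3 or end_nt % 3:
            raise AlignmentError("window bounds must be codon-aligned")
        return CodonAlignment(
            names=list(self.names),
            sequences=[s[start_nt:end_nt] for s in self.sequences],
        )

    def check_frame(self, code: GeneticCode = STANDARD_CODE) -> None:
        """Raise FrameError on the first in-frame stop codon in any sequence."""
        for name, seq in zip(self.names, self.sequences):
            for j in range(0, len(seq), 3):
                codon = seq[j : j + 3]
                if code.is_stop(codon):
                    raise FrameError(
                        f"sequence {name!r}: stop codon {codon} at codon "
                        f"{j // 3 + 1} (1-based)"
                    )


def read_codon_fasta(path, frame_check: bool = True) -> CodonAlignment:
    """Read a FASTA file as a validated in-frame codon alignment.

    Sequence order is preserved from the file.  With ``frame_check`` on, any
    in-frame stop codon raises :class:`FrameError` naming the sequence and the
    1-based codon index.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    aln = CodonAlignment(
        names=[r.id for r in records], sequences=[str(r.seq) for r in records]
    )
    if frame_check:
        aln.check_frame()
    return aln


def write_codon_fasta(aln: CodonAlignment, path) -> None:
    """Write the alignment as FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s), id=n, description="")
        for n, s in zip(aln.names, aln.sequences)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


@dataclass
class CompositionSummary:
    """Per-sequence GC composition; fractions exclude gaps and N entirely."""

    seq_id: str
    gc_total: float
    gc1: float
    gc2: float
    gc3: float
    defined: bool = True


def _gc_fraction(chars: str) -> tuple[int, int]:
    counted = sum(1 for c in chars if c in "ACGT")
    gc = sum(1 for c in chars if c in "GC")
    return gc, counted


def gc_content(aln: CodonAlignment) -> list[CompositionSummary]:
    """GC fraction overall and at each codon position, per sequence.

    Gaps and N are excluded from numerator and denominator.  A sequence with
    no countable bases gets ``defined=False`` and NaN fractions.
    """
    out = []
    for name, seq in zip(aln.names, aln.sequences):
        pos = [seq[k::3] for k in range(3)]
        counts = [_gc_fraction(p) for p in pos]
        total_gc = sum(g for g, _ in counts)
        total_n = sum(n for _, n in counts)
        if total_n == 0:
            out.append(
                CompositionSummary(name, float("nan"), float("nan"), float("nan"),
                                   float("nan"), defined=False)
            )
            continue
        fracs = [g / n if n else float("nan") for g, n in counts]
        out.append(CompositionSummary(name, total_gc / total_n, *fracs))
    return out


def count_informative_sites(aln: CodonAlignment) -> int:
    """Number of parsimony-informative nucleotide columns.

    A column is informative iff at least two distinct residues each occur in
    at least two sequences; gaps and N never count as residues.  Requires at
    least four sequences.
    """
    if aln.n_sequences < 4:
        raise AlignmentError("parsimony informativeness needs >= 4 sequences")
    count = 0
    for j in range(aln.length_nt):
        tally: dict[str, int] = {}
        for s in aln.sequences:
            ch = s[j]
            if ch in "ACGT":
                tally[ch] = tally.get(ch, 0) + 1
        if sum(1 for v in tally.values() if v >= 2) >= 2:
            count += 1
    return count
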