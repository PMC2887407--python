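"""Codon-usage bias via Wright's effective number of codons (ENC).

ENC ranges from 20 (one codon per amino acid: maximal bias) to 61 (uniform
synonymous usage).  Per amino acid with k synonymous codons and n observed
occurrences, the codon homozygosity is estimated as

    F = (n * sum(p_i^2) - 1) / (n - 1),

and ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, with Fk the mean homozygosity of
the k-fold degenerate amino acid class.  Met and Trp contribute the constant
2.  The 6-fold families (Leu, Ser, Arg) are kept intact rather than split.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .genetics import STANDARD_CODE, CodonAlignment, GeneticCode

__all__ = ["ENCResult", "enc", "enc_table"]

# amino acids per degeneracy class under the standard code (Met, Trp excluded)
_CLASS_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass
class ENCResult:
    """ENC for one sequence.

    ``enc`` is clamped to the [20, 61] range (``clamped`` flags when the raw
    formula exceeded 61, which happens by sampling noise on short
    sequences); ``defined`` is False when no amino acid family had at least
    two observations.
    """

    enc: float
    F_bar: dict[int, float] = field(default_factory=dict)
    n_codons_used: dict[int, int] = field(default_factory=dict)
    defined: bool = True
    clamped: bool = False
    imputed_classes: tuple[int, ...] = ()


def _family_F(counts: Counter) -> float | None:
    """Wright's homozygosity for one amino acid; None when n < 2 or F <= 0."""
    n = sum(counts.values())
    if n < 2:
        return None
    s = sum((c / n) ** 2 for c in counts.values())
    F = (n * s - 1.0) / (n - 1.0)
    if F <= 0.0:
        return None
    return F


def enc(seq: str, code: GeneticCode = STANDARD_CODE) -> ENCResult:
    """Wright's ENC of one in-frame coding sequence.

    Codons containing gaps or N are skipped.  A degeneracy class with no
    usable amino acid is imputed: the 3-fold class from the mean of the
    2- and 4-fold classes (Wright's rule), any other missing class from the
    weighted mean of the available classes (reduced-formula fallback);
    imputed classes are reported.
    """
    if len(seq) % 3:
        raise ValueError("sequence length not a multiple of 3")
    degen_of_aa = {}
    for codon, aa in code.codon_to_aa.items():
        if aa != "*":
            degen_of_aa[aa] = degen_of_aa.get(aa, 0) + 1
    by_aa: dict[str, Counter] = defaultdict(Counter)
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if any(c not in "ACGT" for c in codon) or code.is_stop(codon):
            continue
        by_aa[code.translate(codon)][codon] += 1

    class_F: dict[int, list[float]] = defaultdict(list)
    class_n: dict[int, int] = defaultdict(int)
    for aa, counts in by_aa.items():
        k = degen_of_aa[aa]
        if k == 1:
            continue
        class_n[k] += sum(counts.values())
        F = _family_F(counts)
        if F is not None:
            class_F[k].append(F)

    F_bar = {k: sum(v) / len(v) for k, v in class_F.items() if v}
    if not F_bar:
        return ENCResult(enc=float("nan"), defined=False,
                         n_codons_used=dict(class_n))

    imputed = []
    if 3 not in F_bar and 2 in F_bar and 4 in F_bar:
        F_bar[3] = 0.5 * (F_bar[2] + F_bar[4])
        imputed.append(3)
    for k in _CLASS_WEIGHTS:
        if k not in F_bar:
            wsum = sum(_CLASS_WEIGHTS[j] for j in F_bar if j in _CLASS_WEIGHTS)
            F_bar[k] = (
                sum(_CLASS_WEIGHTS[j] * F_bar[j] for j in F_bar
                    if j in _CLASS_WEIGHTS) / wsum
            )
            imputed.append(k)

    value = 2.0 + sum(_CLASS_WEIGHTS[k] / F_bar[k] for k in _CLASS_WEIGHTS)
    clamped = value > 61.0
    value = min(value, 61.0)
    value = max(value, 20.0)
    return ENCResult(
        enc=value,
        F_bar=dict(F_bar),
        n_codons_used=dict(class_n),
        clamped=clamped,
        imputed_classes=tuple(sorted(imputed)),
    )


def enc_table(aln: CodonAlignment, code: GeneticCode = STANDARD_CODE):
    """Per-sequence (seq_id, ENCResult) pairs for an alignment."""
    return [(n, enc(s, code)) for n, s in zip(aln.names, aln.sequences)]
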