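"""Counting-based sequence divergence.

Implements the Nei–Gojobori (1986) method: fractional synonymous and
nonsynonymous site counts per codon, pathway-averaged difference counts for
multi-hit codons, and Jukes–Cantor multiple-hit correction

    d = -(3/4) * ln(1 - 4p/3).

Also provides plain JC nucleotide distances, sliding-window divergence
profiles along a coding sequence, within-group mean dN/dS summaries, and a
neighbor-joining classifier that places query sequences into labeled
reference clades (used to sort sequences into the two paralog lineages of a
gene duplication).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .genetics import STANDARD_CODE, CodonAlignment, GeneticCode

__all__ = [
    "PairwiseDivergence",
    "WindowProfile",
    "GroupDivergence",
    "SaturationError",
    "ng86_sites",
    "ng86_pair",
    "jc_distance",
    "jc_correct",
    "sliding_window",
    "mean_divergence",
    "nj_classify",
]


class SaturationError(ValueError):
    """Raised when a proportion of differences is >= 3/4 (JC undefined)."""


def jc_correct(p: float) -> float:
    """Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3); requires p < 3/4."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4: distance undefined")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# NG86 site and difference counting


def ng86_sites(codon: str, code: GeneticCode = STANDARD_CODE) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one sense codon.

    Each of the three positions contributes one site, split according to the
    fraction of its three single-nucleotide changes that are synonymous.
    Changes creating stop codons are excluded from the denominator, so
    syn + nonsyn = 3 exactly for every sense codon.
    """
    return _ng86_sites_cached(codon)


@lru_cache(maxsize=None)
def _ng86_sites_cached(codon: str) -> tuple[float, float]:
    code = STANDARD_CODE
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = code.translate(codon)
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_counted = 0
        for nt in "TCAG":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if code.is_stop(mut):
                continue
            n_counted += 1
            if code.translate(mut) == aa:
                n_syn += 1
        if n_counted:
            syn += n_syn / n_counted
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _ng86_diffs_cached(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) differences for one codon
    pair, or None when every minimal pathway passes through a stop codon."""
    code = STANDARD_CODE
    diff_pos = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if code.translate(nxt) == code.translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


@dataclass
class PairwiseDivergence:
    """NG86 divergence between one pair of coding sequences.

    ``omega`` is None when dS is zero or undefined (never infinity);
    ``saturated`` flags a pS or pN at or beyond the JC limit of 3/4, in which
    case the corresponding distance is NaN.
    """

    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    n_codons: int
    pS: float
    pN: float
    dS: float
    dN: float
    K: float
    omega: float | None
    saturated: bool = False
    dropped_codons: int = 0

    @property
    def total_differences(self) -> float:
        return self.Sd + self.Nd


def _codon_ok(codon: str) -> bool:
    return all(c in "ACGT" for c in codon)


def ng86_pair(
    seq_a: str,
    seq_b: str,
    code: GeneticCode = STANDARD_CODE,
) -> PairwiseDivergence:
    """NG86 dN/dS between two equal-length in-frame sequences.

    Codons containing gaps or N in either sequence are dropped pairwise.
    Multi-hit codons are averaged over all minimal substitution pathways with
    equal weights, excluding pathways that traverse stop codons; a codon pair
    whose pathways are all blocked is dropped with a warning.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if len(seq_a) % 3:
        raise ValueError("sequence length not a multiple of 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    dropped = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (_codon_ok(ca) and _codon_ok(cb)):
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            raise ValueError(f"stop codon in compared pair at codon {i // 3 + 1}")
        diffs = _ng86_diffs_cached(ca, cb)
        if diffs is None:
            dropped += 1
            warnings.warn(
                f"codon {i // 3 + 1}: all substitution pathways pass through "
                "stops; codon dropped",
                stacklevel=2,
            )
            continue
        sa, na = ng86_sites(ca, code)
        sb, nb = ng86_sites(cb, code)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        Sd += diffs[0]
        Nd += diffs[1]
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons between the two sequences")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    saturated = pS >= 0.75 or pN >= 0.75
    dS = float("nan") if pS >= 0.75 else jc_correct(pS)
    dN = float("nan") if pN >= 0.75 else jc_correct(pN)
    K = jc_distance(seq_a, seq_b)
    if saturated or dS == 0.0 or math.isnan(dS):
        omega = None
    else:
        omega = dN / dS
    return PairwiseDivergence(
        S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, n_codons=n_codons,
        pS=pS, pN=pN, dS=dS, dN=dN, K=K, omega=omega,
        saturated=saturated, dropped_codons=dropped,
    )


def jc_distance(seq_a: str, seq_b: str) -> float:
    """JC-corrected nucleotide distance; gap/N positions dropped pairwise.

    Returns NaN when the mismatch proportion reaches the 3/4 saturation
    limit or no sites are comparable.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    n = mm = 0
    for x, y in zip(seq_a, seq_b):
        if x in "ACGT" and y in "ACGT":
            n += 1
            if x != y:
                mm += 1
    if n == 0:
        return float("nan")
    p = mm / n
    if p >= 0.75:
        return float("nan")
    return jc_correct(p)


# ---------------------------------------------------------------------------
# Sliding windows


@dataclass
class WindowProfile:
    """Per-window mean divergence over a set of sequence pairs.

    Starts are 0-based nucleotide offsets; reports add 1.  Ratio entries are
    NaN where no pair in the window had a defined dN/dS (dS = 0 pairs are
    excluded from the window mean, never treated as zero).
    """

    window_nt: int
    step_nt: int
    starts: list[int]
    K_series: list[float]
    dN_series: list[float]
    ratio_series: list[float]

    def to_rows(self) -> list[tuple[int, int, float, float, float]]:
        """(start_1based, end_1based, K, dN, dN_dS) rows for TSV output."""
        return [
            (s + 1, s + self.window_nt, k, dn, r)
            for s, k, dn, r in zip(
                self.starts, self.K_series, self.dN_series, self.ratio_series
            )
        ]


def sliding_window(
    aln: CodonAlignment,
    pairs: Sequence[tuple[str, str]],
    window_nt: int = 30,
    step_nt: int = 9,
    code: GeneticCode = STANDARD_CODE,
) -> WindowProfile:
    """Mean K, dN and dN/dS in overlapping windows along the alignment.

    The defaults (30 nt window, 9 nt step — ten amino acids stepped by
    three) suit short, conserved coding genes.
    """
    if window_nt % 3 or step_nt % 3:
        raise ValueError("window and step must be multiples of 3")
    if window_nt > aln.length_nt:
        raise ValueError("window longer than alignment")
    if not pairs:
        raise ValueError("empty pair set")
    starts = list(range(0, aln.length_nt - window_nt + 1, step_nt))
    K_series, dN_series, ratio_series = [], [], []
    seq = {n: s for n, s in zip(aln.names, aln.sequences)}
    for s0 in starts:
        Ks, dNs, ratios = [], [], []
        for a, b in pairs:
            wa, wb = seq[a][s0 : s0 + window_nt], seq[b][s0 : s0 + window_nt]
            try:
                d = ng86_pair(wa, wb, code)
            except ValueError:
                continue
            if not math.isnan(d.K):
                Ks.append(d.K)
            if not math.isnan(d.dN):
                dNs.append(d.dN)
            if d.omega is not None:
                ratios.append(d.omega)
        K_series.append(float(np.mean(Ks)) if Ks else float("nan"))
        dN_series.append(float(np.mean(dNs)) if dNs else float("nan"))
        ratio_series.append(float(np.mean(ratios)) if ratios else float("nan"))
    return WindowProfile(window_nt, step_nt, starts, K_series, dN_series, ratio_series)


# ---------------------------------------------------------------------------
# Group summaries


class GroupDivergence(NamedTuple):
    """Within-group mean pairwise dN, dS and their ratio."""

    mean_dN: float
    mean_dS: float
    overall_omega: float | None


def mean_divergence(
    aln: CodonAlignment,
    group: Sequence[str],
    code: GeneticCode = STANDARD_CODE,
) -> GroupDivergence:
    """Arithmetic mean of all within-group pairwise dN and dS.

    ``overall_omega`` is the ratio of the two means (None when mean dS is
    zero).  Saturated pairs are excluded; if every pair is saturated an
    error is raised.
    """
    if len(group) < 2:
        raise ValueError("group needs at least two sequences")
    sub = aln.subset(group)
    dNs, dSs = [], []
    for i, j in itertools.combinations(range(sub.n_sequences), 2):
        d = ng86_pair(sub.sequences[i], sub.sequences[j], code)
        if d.saturated:
            continue
        dNs.append(d.dN)
        dSs.append(d.dS)
    if not dNs:
        raise ValueError("all pairs saturated: no usable distances")
    mean_dN = float(np.mean(dNs))
    mean_dS = float(np.mean(dSs))
    omega = mean_dN / mean_dS if mean_dS > 0 else None
    return GroupDivergence(mean_dN, mean_dS, omega)


def pairwise_table(
    aln: CodonAlignment, code: GeneticCode = STANDARD_CODE
) -> list[tuple[str, str, PairwiseDivergence]]:
    """NG86 divergence for every sequence pair of the alignment."""
    out = []
    for i, j in itertools.combinations(range(aln.n_sequences), 2):
        out.append(
            (
                aln.names[i],
                aln.names[j],
                ng86_pair(aln.sequences[i], aln.sequences[j], code),
            )
        )
    return out


# ---------------------------------------------------------------------------
# NJ classification into labeled reference clades


def nj_classify(
    aln: CodonAlignment,
    reference_labels: dict[str, str],
    queries: Iterable[str] | None = None,
    min_overlap: float = 0.5,
    return_tree: bool = False,
):
    """Assign each query sequence to a labeled reference clade.

    Builds a neighbor-joining tree from JC distances over queries plus
    references and considers every tree bipartition that perfectly
    separates the reference labels.  A query that falls on the same
    label's side of *all* separating bipartitions nests within that clade
    and takes its label; a query that switches sides (attached along the
    inter-clade path) is resolved by mean patristic distance to the two
    reference sets, and labeled ``"ambiguous"`` when those distances are
    within a 2% relative margin (or when no separating bipartition
    exists).  Queries sharing fewer than ``min_overlap`` of comparable
    sites with the references are excluded with a warning.  Exactly two
    labels are supported.  With ``return_tree`` the NJ tree is also
    returned as a Newick string.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    labels = sorted(set(reference_labels.values()))
    if len(labels) != 2:
        raise ValueError("need exactly two reference labels")
    for lab in labels:
        if not any(v == lab for v in reference_labels.values()):
            raise ValueError(f"label {lab!r} has no reference sequences")
    if queries is None:
        queries = [n for n in aln.names if n not in reference_labels]
    queries = list(queries)
    refs = [n for n in aln.names if n in reference_labels]

    seq = {n: s for n, s in zip(aln.names, aln.sequences)}

    def overlap(a: str, b: str) -> float:
        n = sum(1 for x, y in zip(seq[a], seq[b]) if x in "ACGT" and y in "ACGT")
        return n / aln.length_nt

    usable, result = [], {}
    for q in queries:
        if max(overlap(q, r) for r in refs) < min_overlap:
            warnings.warn(f"query {q!r}: <{min_overlap:.0%} overlap with "
                          "references; excluded", stacklevel=2)
            result[q] = "excluded"
        else:
            usable.append(q)
    taxa = refs + usable
    if len(taxa) < 3:
        raise ValueError("too few sequences for a NJ tree")
    n = len(taxa)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jc_distance(seq[taxa[i]], seq[taxa[j]])
            if math.isnan(d):
                d = 5.0  # saturated or incomparable: large finite distance
            dm[i, j] = dm[j, i] = max(d, 0.0)
    tree = nj(DistanceMatrix(dm, ids=taxa))

    all_leaves = frozenset(taxa)
    lab_a, lab_b = labels
    set_a = {n_ for n_, l_ in reference_labels.items()
             if l_ == lab_a and n_ in taxa}
    set_b = {n_ for n_, l_ in reference_labels.items()
             if l_ == lab_b and n_ in taxa}

    a_sides: list[frozenset] = []
    for node in tree.non_tips(include_self=False):
        under = frozenset(t.name for t in node.tips())
        for side in (under, all_leaves - under):
            if set_a <= side and not (set_b & side):
                a_sides.append(side)

    patristic = tree.tip_tip_distances()

    def mean_patristic(q: str, refset: set) -> float:
        return float(np.mean([patristic[q, r] for r in refset]))

    for q in usable:
        if not a_sides:
            result[q] = "ambiguous"
            continue
        votes = [q in side for side in a_sides]
        if all(votes):
            result[q] = lab_a
        elif not any(votes):
            result[q] = lab_b
        else:
            da, db = mean_patristic(q, set_a), mean_patristic(q, set_b)
            scale = max(da, db, 1e-12)
            if abs(da - db) / scale < 0.02:
                result[q] = "ambiguous"
            else:
                result[q] = lab_a if da < db else lab_b
    if return_tree:
        return result, str(tree)
    return result
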