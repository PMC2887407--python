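"""Simulation of codon alignments with known truth.

Generates data shaped like a duplicated-gene study: a phylogeny with two
paralog clades descending from one duplication node plus pre-duplication
outgroup lineages, strong purifying selection with branch-class-specific
omega, transition bias, and GC3-rich biased codon usage.  Simulated
alignments carry a truth manifest (all generating parameters and per-site
class assignments) so every downstream estimator can be tested against
known values.

Evolution is sampled per branch with one categorical draw per site from
the transition matrix P(t) — exact for the model, since only endpoint
states are needed.  Identical spec + seed gives identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize as sopt

from .divergence import _ng86_diffs_cached, jc_correct, ng86_sites
from .genetics import STANDARD_CODE, CodonAlignment
from .likelihood import (
    SENSE_CODONS,
    _eigen_decompose,
    f3x4_from_nucleotide_freqs,
    substitution_rate,
)
from .trees import LabeledTree, TreeNode

__all__ = [
    "SiteRegime",
    "SimulationSpec",
    "simulate",
    "make_duplication_tree",
    "biased_frequencies",
    "path_length_for_ds",
    "expected_ng86_ds",
    "preset_spec",
    "PRESETS",
]


@dataclass(frozen=True)
class SiteRegime:
    """A site-mixture regime for simulation.

    Site classes are drawn once at the root from ``proportions`` and
    inherited unchanged down the tree.  With ``foreground_classes`` set,
    branches of those classes substitute ``foreground_omegas`` for
    ``omegas`` (the branch-site structure: selected site classes switch
    omega only on foreground branches).
    """

    proportions: tuple[float, ...]
    omegas: tuple[float, ...]
    foreground_classes: tuple[str, ...] = ()
    foreground_omegas: tuple[float, ...] | None = None

    def __post_init__(self):
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if len(self.proportions) != len(self.omegas):
            raise ValueError("proportions and omegas differ in length")
        if self.foreground_omegas is not None and len(
            self.foreground_omegas
        ) != len(self.omegas):
            raise ValueError("foreground_omegas length mismatch")


@dataclass
class SimulationSpec:
    """Generative parameters for one synthetic alignment."""

    tree: LabeledTree
    kappa: float
    pi: np.ndarray
    omega_by_class: dict[str, float] = field(default_factory=dict)
    site_regime: SiteRegime | None = None
    n_codons: int = 87
    seed: int = 0

    def validate(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.site_regime is None:
            missing = self.tree.classes - set(self.omega_by_class)
            if missing:
                raise ValueError(
                    f"tree branch classes without omega: {sorted(missing)}"
                )


def _sample_transitions(states, P, u):
    """Categorical draw of child states given parent states and P rows."""
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0  # guard roundoff
    C = cum[states]
    return np.minimum((C < u[:, np.newaxis]).sum(axis=1), P.shape[0] - 1)


def simulate(spec: SimulationSpec) -> tuple[CodonAlignment, dict]:
    """Evolve codon sequences down the tree; returns alignment + truth.

    Root codons are drawn from the stationary distribution; each branch
    applies one transition-matrix draw per site using that branch's class
    omega (and site-class omega under a site regime, with the same joint
    rate scaling the likelihood engine uses for mixtures).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_codons
    pi = np.asarray(spec.pi, dtype=float)
    tree = spec.tree
    eig_cache: dict[float, object] = {}

    def eig(w):
        if w not in eig_cache:
            eig_cache[w] = _eigen_decompose(spec.kappa, w, pi)
        return eig_cache[w]

    regime = spec.site_regime
    if regime is None:
        site_class = np.zeros(n, dtype=int)
        class_sets = {
            cls: ((w,), (w,)) for cls, w in spec.omega_by_class.items()
        }
        rate_factor = {cls: (1.0,) for cls in spec.omega_by_class}
    else:
        site_class = rng.choice(
            len(regime.proportions), size=n, p=np.asarray(regime.proportions)
        )
        bg = tuple(regime.omegas)
        fg = tuple(
            regime.foreground_omegas
            if regime.foreground_omegas is not None
            else regime.omegas
        )
        props = np.asarray(regime.proportions)
        r_bg = np.array([substitution_rate(spec.kappa, w, pi) for w in bg])
        r_fg = np.array([substitution_rate(spec.kappa, w, pi) for w in fg])
        c_bg = float(props @ r_bg)
        c_fg = float(props @ r_fg)
        class_sets = {}
        rate_factor = {}
        for cls in tree.classes:
            if cls in regime.foreground_classes:
                class_sets[cls] = (fg, fg)
                rate_factor[cls] = tuple(r / c_fg for r in r_fg)
            else:
                class_sets[cls] = (bg, bg)
                rate_factor[cls] = tuple(r / c_bg for r in r_bg)

    root_states = rng.choice(len(SENSE_CODONS), size=n, p=pi)
    states = {id(tree.root): root_states}
    for node in _preorder(tree.root):
        if node is tree.root:
            continue
        parent_states = states[_parent_id(tree.root, node)]
        t = node.length or 0.0
        child = parent_states.copy()
        if t > 0:
            omegas = class_sets[node.cls][0]
            factors = rate_factor[node.cls]
            u = rng.random(n)
            for k, (w, fac) in enumerate(zip(omegas, factors)):
                mask = site_class == k if regime is not None else slice(None)
                P = eig(w).P(t * fac)
                sub = parent_states[mask]
                child_k = _sample_transitions(sub, P, u[mask])
                if regime is None:
                    child = child_k
                else:
                    child[mask] = child_k
        states[id(node)] = child

    names, seqs = [], []
    for node in tree.root.postorder():
        if node.is_leaf():
            names.append(node.name)
            seqs.append(
                "".join(SENSE_CODONS[s] for s in states[id(node)])
            )
    aln = CodonAlignment(names=names, sequences=seqs)
    truth = {
        "kappa": spec.kappa,
        "omega_by_class": dict(spec.omega_by_class),
        "site_regime": None
        if regime is None
        else {
            "proportions": list(regime.proportions),
            "omegas": list(regime.omegas),
            "foreground_classes": list(regime.foreground_classes),
            "foreground_omegas": None
            if regime.foreground_omegas is None
            else list(regime.foreground_omegas),
            "site_classes": site_class.tolist(),
        },
        "n_codons": n,
        "seed": spec.seed,
        "tree": tree.to_newick(classes=True),
        "pi": np.asarray(spec.pi).tolist(),
    }
    return aln, truth


def _preorder(root: TreeNode):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def _parent_id(root: TreeNode, target: TreeNode) -> int:
    # small trees: linear search is fine
    for node in root.postorder():
        if target in node.children:
            return id(node)
    raise ValueError("node not in tree")


# ---------------------------------------------------------------------------
# Tree construction


def make_duplication_tree(
    n_per_clade: int,
    stem_depth: float,
    crown_depth: float | tuple[float, float],
    n_outgroup: int = 1,
    outgroup_depth: float | None = None,
    pre_depth: float = 0.05,
) -> LabeledTree:
    """A duplication-shaped labeled tree.

    Two ultrametric paralog clades (classes ``g1`` and ``g5``) of
    ``n_per_clade`` species each hang off a duplication node via stem
    branches (``stem_g1``, ``stem_g5``); ``n_outgroup`` pre-duplication
    lineages (class ``pre``) attach successively below it.  ``crown_depth``
    may be one value or a (g1, g5) pair.
    """
    if n_per_clade < 2:
        raise ValueError("need at least two species per clade")
    if n_outgroup < 1:
        raise ValueError("need at least one outgroup lineage")
    if isinstance(crown_depth, (tuple, list)):
        crown_g1, crown_g5 = crown_depth
    else:
        crown_g1 = crown_g5 = crown_depth
    if outgroup_depth is None:
        outgroup_depth = stem_depth + max(crown_g1, crown_g5)

    def clade(tips: list[str], depth: float, cls: str) -> TreeNode:
        """Ultrametric balanced subtree: every tip at distance ``depth``
        below the returned node (whose own edge the caller assigns)."""
        if len(tips) == 1:
            return TreeNode(name=tips[0], cls=cls)
        half = len(tips) // 2
        children = []
        for part in (tips[:half], tips[half:]):
            child = clade(part, depth / 2, cls)
            child.length = depth if child.is_leaf() else depth / 2
            children.append(child)
        return TreeNode(cls=cls, children=children)

    g1 = clade([f"g1_sp{i + 1}" for i in range(n_per_clade)], crown_g1, "g1")
    g5 = clade([f"g5_sp{i + 1}" for i in range(n_per_clade)], crown_g5, "g5")
    g1.length, g1.cls = stem_depth, "stem_g1"
    g5.length, g5.cls = stem_depth, "stem_g5"
    node = TreeNode(length=pre_depth, cls="pre", children=[g1, g5])
    for i in range(n_outgroup):
        og = TreeNode(
            name=f"outgroup{i + 1}", length=outgroup_depth, cls="pre"
        )
        node = TreeNode(
            length=pre_depth if i < n_outgroup - 1 else None,
            cls="pre",
            children=[node, og],
        )
    return LabeledTree(node)


# ---------------------------------------------------------------------------
# Frequency and divergence calibration


def biased_frequencies(
    gc3_target: float,
    gc12: float = 0.5,
) -> np.ndarray:
    """F3x4-style codon frequencies with a prescribed stationary GC3.

    Position-3 G+C is solved by bisection so that the *sense-codon*
    stationary distribution (stops removed and renormalized) realizes the
    requested third-position G+C fraction; positions 1-2 get ``gc12`` G+C.
    """
    if not 0.0 < gc3_target < 1.0:
        raise ValueError("gc3_target must be strictly between 0 and 1")

    def freqs_for(g3: float) -> np.ndarray:
        # TCAG order
        f12 = np.array([(1 - gc12) / 2, gc12 / 2, (1 - gc12) / 2, gc12 / 2])
        f3 = np.array([(1 - g3) / 2, g3 / 2, (1 - g3) / 2, g3 / 2])
        return f3x4_from_nucleotide_freqs(np.vstack([f12, f12, f3]))

    def realized_gc3(pi: np.ndarray) -> float:
        return float(
            sum(p for p, c in zip(pi, SENSE_CODONS) if c[2] in "GC")
        )

    lo, hi = 1e-4, 1 - 1e-4
    g3 = sopt.brentq(
        lambda g: realized_gc3(freqs_for(g)) - gc3_target, lo, hi, xtol=1e-10
    )
    return freqs_for(g3)


def expected_ng86_ds(
    segments: Sequence[tuple[float, float]],
    kappa: float,
    pi: np.ndarray,
) -> float:
    """Expected NG86 dS between stationary endpoints of a path.

    ``segments`` is a list of (omega, length) pieces; the path transition
    matrix is the product of the per-segment matrices (each scaled to one
    substitution per codon per unit length).  The expectation uses the
    pathway-averaged NG86 difference counts over the joint codon-pair
    distribution.
    """
    pi = np.asarray(pi, dtype=float)
    n = len(SENSE_CODONS)
    P = np.eye(n)
    for w, t in segments:
        P = P @ _eigen_decompose(kappa, w, pi).P(t)
    sd_table = np.zeros((n, n))
    usable = np.ones((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            d = _ng86_diffs_cached(ci, cj)
            if d is None:
                usable[i, j] = False
            else:
                sd_table[i, j] = d[0]
    joint = pi[:, np.newaxis] * P
    joint = np.where(usable, joint, 0.0)
    joint /= joint.sum()
    e_sd = float((joint * sd_table).sum())
    s_sites = float(sum(p * ng86_sites(c)[0] for p, c in zip(pi, SENSE_CODONS)))
    ps = e_sd / s_sites
    if ps >= 0.75:
        # beyond the JC limit: return a large finite value so bracketing
        # root-finders stay monotone
        return 1e3
    return jc_correct(ps)


def path_length_for_ds(
    target_ds: float,
    kappa: float,
    pi: np.ndarray,
    omega: float,
) -> float:
    """Total path length (subs/codon) giving an expected NG86 dS."""
    return sopt.brentq(
        lambda t: expected_ng86_ds([(omega, t)], kappa, pi) - target_ds,
        1e-6,
        30.0,
        xtol=1e-8,
    )


def _within_clade_paths(tree: LabeledTree, cls: str) -> list[float]:
    """Tip-to-tip path lengths among all leaves of one branch class."""
    import itertools

    depths: dict[str, float] = {}
    ancestors: dict[str, list[TreeNode]] = {}

    def walk(node: TreeNode, depth: float, path: list[TreeNode]) -> None:
        if node.is_leaf():
            if node.cls == cls:
                depths[node.name] = depth
                ancestors[node.name] = list(path)
            return
        for c in node.children:
            walk(c, depth + (c.length or 0.0), path + [c])

    walk(tree.root, 0.0, [])
    if len(depths) < 2:
        raise ValueError(f"fewer than two leaves of class {cls!r}")
    out = []
    for a, b in itertools.combinations(depths, 2):
        shared = 0.0
        for x, y in zip(ancestors[a], ancestors[b]):
            if x is y:
                shared += x.length or 0.0
            else:
                break
        out.append(depths[a] + depths[b] - 2.0 * shared)
    return out


# ---------------------------------------------------------------------------
# Presets: the default study-shaped fixtures


def _default_duplication_spec(
    seed: int,
    n_codons: int,
    omega_by_class: dict[str, float],
    kappa: float = 2.0,
    gc3: float = 0.759,
    ds_within: tuple[float, float] = (0.155, 0.131),
    ds_paralog: float = 0.55,
    n_per_clade: int = 6,
    n_outgroup: int = 2,
) -> SimulationSpec:
    """Duplication-shaped spec with depths calibrated to dS targets.

    Crown depths are solved so the maximal within-clade path realizes each
    clade's target dS; the stem depth so a cross-clade tip-to-tip path
    realizes the paralog dS target.
    """
    pi = biased_frequencies(gc3)
    w_g1 = omega_by_class["g1"]
    w_g5 = omega_by_class["g5"]

    # relative tip-to-tip path lengths within a balanced ultrametric clade
    # of unit depth scale linearly with the crown depth
    unit = make_duplication_tree(n_per_clade, 0.1, 1.0, n_outgroup=1)
    rel_paths = _within_clade_paths(unit, "g1")

    def crown_for(target: float, w: float) -> float:
        def mean_ds(depth: float) -> float:
            return float(
                np.mean(
                    [
                        expected_ng86_ds([(w, depth * f)], kappa, pi)
                        for f in rel_paths
                    ]
                )
            )

        return sopt.brentq(lambda dd: mean_ds(dd) - target, 1e-4, 10.0,
                           xtol=1e-6)

    crown_g1 = crown_for(ds_within[0], w_g1)
    crown_g5 = crown_for(ds_within[1], w_g5)

    def paralog_ds(stem: float) -> float:
        segs = [
            (w_g1, crown_g1),
            (omega_by_class["stem_g1"], stem),
            (omega_by_class["stem_g5"], stem),
            (w_g5, crown_g5),
        ]
        return expected_ng86_ds(segs, kappa, pi)

    stem = sopt.brentq(
        lambda s: paralog_ds(s) - ds_paralog, 1e-6, 20.0, xtol=1e-8
    )
    tree = make_duplication_tree(
        n_per_clade=n_per_clade,
        stem_depth=stem,
        crown_depth=(crown_g1, crown_g5),
        n_outgroup=n_outgroup,
    )
    return SimulationSpec(
        tree=tree,
        kappa=kappa,
        pi=pi,
        omega_by_class=dict(omega_by_class),
        n_codons=n_codons,
        seed=seed,
    )


def preset_spec(name: str, seed: int = 1, n_codons: int = 87) -> SimulationSpec:
    """Named study-shaped simulation presets.

    ``three_ratio``: asymmetric post-duplication selection (omega 0.044
    before the duplication, 0.118 on the faster paralog lineage, 0.060 on
    the slower one), GC3-biased frequencies, dS-calibrated depths — the
    default fixture emulating a duplicated, strongly constrained nuclear
    gene in a grass-like sampling (two clades of six species plus two
    outgroups, 87 codons by default).

    ``one_ratio``: same shape with a single omega of 0.055 everywhere.

    ``neutral``: omega 1 on all branches, equal codon frequencies.

    ``site_mixture``: three-class discrete omega regime on the one-ratio
    tree shape.
    """
    if name == "three_ratio":
        return _default_duplication_spec(
            seed,
            n_codons,
            {
                "pre": 0.044,
                "stem_g1": 0.118,
                "g1": 0.118,
                "stem_g5": 0.060,
                "g5": 0.060,
            },
        )
    if name == "one_ratio":
        return _default_duplication_spec(
            seed, n_codons, {c: 0.055 for c in
                             ("pre", "stem_g1", "stem_g5", "g1", "g5")}
        )
    if name == "neutral":
        tree = make_duplication_tree(3, 0.2, 0.2)
        pi = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
        return SimulationSpec(
            tree=tree,
            kappa=1.0,
            pi=pi,
            omega_by_class={c: 1.0 for c in tree.classes},
            n_codons=n_codons,
            seed=seed,
        )
    if name == "site_mixture":
        spec = _default_duplication_spec(
            seed, n_codons, {c: 0.055 for c in
                             ("pre", "stem_g1", "stem_g5", "g1", "g5")}
        )
        return SimulationSpec(
            tree=spec.tree,
            kappa=spec.kappa,
            pi=spec.pi,
            site_regime=SiteRegime(
                proportions=(0.714, 0.224, 0.062),
                omegas=(0.008, 0.124, 0.480),
            ),
            n_codons=n_codons,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("three_ratio", "one_ratio", "neutral", "site_mixture")


def write_simulation(aln: CodonAlignment, truth: dict, spec: SimulationSpec,
                     outdir) -> None:
    """Write FASTA, Newick, labels TSV and the truth manifest."""
    import os

    from .genetics import write_codon_fasta

    os.makedirs(outdir, exist_ok=True)
    write_codon_fasta(aln, os.path.join(outdir, "alignment.fasta"))
    spec.tree.write(
        os.path.join(outdir, "tree.nwk"), os.path.join(outdir, "labels.tsv")
    )
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
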