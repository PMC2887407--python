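"""Goldman–Yang codon substitution likelihoods.

The rate matrix over the 61 sense codons has off-diagonal entries

    q_ij = 0                     codons differing at more than one position
         = pi_j                  synonymous transversion
         = kappa * pi_j          synonymous transition
         = omega * pi_j          nonsynonymous transversion
         = omega * kappa * pi_j  nonsynonymous transition

scaled so that branch lengths are expected substitutions per codon.  The
chain is reversible, so P(t) = exp(Qt) is computed through the symmetric
eigendecomposition of diag(pi)^1/2 Q diag(pi)^-1/2, and tree likelihoods by
Felsenstein pruning over compressed site patterns.  Branch-length gradients
are computed analytically with an inside-outside pass; the handful of
global parameters (kappa, omegas, mixture proportions, beta shapes) use
central finite differences.

The user-facing objects follow the statsmodels convention: a
:class:`CodonModel` is built from data (alignment + labeled tree + model
specification) and :meth:`CodonModel.fit` returns a
:class:`CodonModelResults` carrying estimates, convergence diagnostics and
a ``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg as sla
from scipy import optimize as sopt
from scipy import stats as sps

from .genetics import STANDARD_CODE, CodonAlignment, GeneticCode
from .models import (
    OMEGA_MAX,
    OMEGA_MIN,
    OMEGA_UNBOUNDED,
    BranchModelSpec,
    SiteModelSpec,
)
from .trees import LabeledTree

__all__ = [
    "build_rate_matrix",
    "transition_probabilities",
    "equal_frequencies",
    "f3x4_frequencies",
    "empirical_codon_frequencies",
    "CodonModel",
    "CodonModelResults",
    "SitePosterior",
]

N_CODONS = 61
_FREQ_FLOOR = 1e-10

# ---------------------------------------------------------------------------
# Structural tables for the standard code


def _build_structure(code: GeneticCode):
    sense = code.sense_codons
    idx = {c: i for i, c in enumerate(sense)}
    n = len(sense)
    neighbor = np.zeros((n, n), dtype=bool)
    is_ts = np.zeros((n, n), dtype=bool)
    is_syn = np.zeros((n, n), dtype=bool)
    purines = {"A", "G"}
    pyrimidines = {"C", "T"}
    for i, ci in enumerate(sense):
        for j, cj in enumerate(sense):
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            (k,) = diffs
            neighbor[i, j] = True
            pair = {ci[k], cj[k]}
            is_ts[i, j] = pair <= purines or pair <= pyrimidines
            is_syn[i, j] = code.translate(ci) == code.translate(cj)
    return sense, idx, neighbor, is_ts, is_syn


SENSE_CODONS, CODON_INDEX, _NEIGHBOR, _IS_TS, _IS_SYN = _build_structure(STANDARD_CODE)


# ---------------------------------------------------------------------------
# Rate matrices and transition probabilities


def build_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, scale: bool = True
) -> np.ndarray:
    """GY94 generator over the 61 sense codons.

    With ``scale`` the matrix is normalized so the expected substitution
    rate at stationarity is one per codon (sum_i pi_i * sum_{j!=i} q_ij = 1).
    """
    if kappa < 0 or omega < 0:
        raise ValueError("kappa and omega must be nonnegative")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"pi must have length {N_CODONS}")
    Q = np.where(_NEIGHBOR, np.broadcast_to(pi, (N_CODONS, N_CODONS)), 0.0).copy()
    Q[_IS_TS] *= kappa
    Q[~_IS_SYN & _NEIGHBOR] *= omega
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        rate = -float(pi @ np.diag(Q))
        if rate > 0:
            Q /= rate
    return Q


def substitution_rate(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Stationary substitution rate of the *unscaled* GY94 generator."""
    Q = build_rate_matrix(kappa, omega, pi, scale=False)
    return -float(np.asarray(pi) @ np.diag(Q))


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to one, entries clamped at zero."""
    if not np.isfinite(t):
        raise ValueError("branch length must be finite")
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    P = sla.expm(Q * t)
    return np.clip(P, 0.0, None)


@dataclass
class _Eigen:
    """Symmetric eigendecomposition of a reversible scaled generator."""

    w: np.ndarray        # eigenvalues
    A: np.ndarray        # diag(pi)^-1/2 U
    Ainv: np.ndarray     # U^T diag(pi)^1/2

    def P(self, t: float) -> np.ndarray:
        P = (self.A * np.exp(self.w * t)) @ self.Ainv
        return np.clip(P, 0.0, None)

    def QP(self, t: float, rate_factor: float = 1.0) -> np.ndarray:
        """d/dt exp(Q r t) = r Q P(rt); returned for the *scaled* time."""
        return rate_factor * (self.A * (self.w * np.exp(self.w * t))) @ self.Ainv


def _eigen_decompose(kappa: float, omega: float, pi: np.ndarray) -> _Eigen:
    Q = build_rate_matrix(kappa, omega, pi, scale=True)
    sq = np.sqrt(pi)
    B = (Q / sq[np.newaxis, :]) * sq[:, np.newaxis]
    B = 0.5 * (B + B.T)  # symmetrize against roundoff
    w, U = np.linalg.eigh(B)
    return _Eigen(w=w, A=U / sq[:, np.newaxis], Ainv=U.T * sq[np.newaxis, :])


# ---------------------------------------------------------------------------
# Codon frequency models


def equal_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def _floor_and_normalize(pi: np.ndarray) -> np.ndarray:
    pi = np.maximum(pi, _FREQ_FLOOR)
    return pi / pi.sum()


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies.

    The product over the three codon positions, with stop codons removed
    and the remainder renormalized (the F3x4 model).
    """
    counts = np.zeros((3, 4))
    order = {nt: k for k, nt in enumerate("TCAG")}
    for seq in aln.sequences:
        for pos in range(3):
            for ch in seq[pos::3]:
                if ch in order:
                    counts[pos, order[ch]] += 1
    if counts.sum() == 0:
        raise ValueError("no countable nucleotides in alignment")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, order[c[0]]] * freqs[1, order[c[1]]] * freqs[2, order[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return _floor_and_normalize(pi)


def f3x4_from_nucleotide_freqs(freqs: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from a (3, 4) array of per-position
    nucleotide frequencies in TCAG order."""
    freqs = np.asarray(freqs, dtype=float)
    order = {nt: k for k, nt in enumerate("TCAG")}
    pi = np.array(
        [
            freqs[0, order[c[0]]] * freqs[1, order[c[1]]] * freqs[2, order[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return _floor_and_normalize(pi)


def empirical_codon_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Observed sense-codon frequencies across all sequences."""
    counts = np.zeros(N_CODONS)
    for i in range(aln.n_sequences):
        for codon in aln.codons(i):
            j = CODON_INDEX.get(codon)
            if j is not None:
                counts[j] += 1
    if counts.sum() == 0:
        raise ValueError("no countable codons in alignment")
    return _floor_and_normalize(counts / counts.sum())


# ---------------------------------------------------------------------------
# Pruning engine


class _Engine:
    """Flattened tree + compressed site patterns for fast pruning."""

    def __init__(self, aln: CodonAlignment, tree: LabeledTree,
                 code: GeneticCode = STANDARD_CODE):
        taxa = tree.taxa
        missing = [t for t in taxa if t not in aln.names]
        if missing:
            raise ValueError(f"taxa missing from alignment: {missing}")
        # site patterns
        ncol = aln.codon_columns
        mat = np.full((len(taxa), ncol), -1, dtype=np.int16)
        for r, taxon in enumerate(taxa):
            codons = aln.codons(aln.names.index(taxon))
            for c, codon in enumerate(codons):
                j = CODON_INDEX.get(codon)
                if j is None:
                    if all(ch in "ACGT" for ch in codon):
                        raise ValueError(
                            f"stop codon {codon} in {taxon!r} at codon {c + 1}"
                        )
                    mat[r, c] = -1
                else:
                    mat[r, c] = j
        patterns, inverse, weights = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns            # (ntaxa, npat)
        self.site_to_pattern = inverse      # (ncol,)
        self.weights = weights.astype(float)
        self.npat = patterns.shape[1]
        self.n_sites = ncol

        # flatten tree: postorder ids, branches in tree.branches() order
        nodes = list(tree.root.postorder())
        self.node_id = {id(n): i for i, n in enumerate(nodes)}
        self.nodes = nodes
        self.root_id = self.node_id[id(tree.root)]
        self.children: list[list[int]] = [
            [self.node_id[id(c)] for c in n.children] for n in nodes
        ]
        self.is_leaf = [n.is_leaf() for n in nodes]
        taxon_row = {t: r for r, t in enumerate(taxa)}
        self.leaf_states = [
            self.patterns[taxon_row[n.name]] if n.is_leaf() else None for n in nodes
        ]
        branch_nodes = tree.branches()
        self.branch_ids = [self.node_id[id(b)] for b in branch_nodes]
        self.branch_classes = [b.cls for b in branch_nodes]
        self.n_branches = len(branch_nodes)
        # postorder over internal nodes (root last)
        self.internal_order = [
            i for i, n in enumerate(nodes) if not n.is_leaf()
        ]

    def _leaf_message(self, P: np.ndarray, states: np.ndarray) -> np.ndarray:
        """P[:, state] per pattern; all-ones column for missing data."""
        M = np.empty((N_CODONS, self.npat))
        ok = states >= 0
        M[:, ok] = P[:, states[ok]]
        M[:, ~ok] = 1.0
        return M

    def site_loglik(self, P_by_node: dict[int, np.ndarray], pi: np.ndarray,
                    keep_cache: bool = False):
        """Per-pattern log-likelihoods; optionally keep the inside cache."""
        if self.is_leaf[self.root_id]:
            # degenerate single-taxon tree: product of stationary frequencies
            states = self.leaf_states[self.root_id]
            logf = np.where(states >= 0,
                            np.log(pi[np.maximum(states, 0)]), 0.0)
            return logf, None
        A_msg: dict[int, np.ndarray] = {}
        inside: dict[int, np.ndarray] = {}
        scale_at: dict[int, np.ndarray] = {}
        logscale = np.zeros(self.npat)
        for v in self.internal_order:
            I = np.ones((N_CODONS, self.npat))
            for c in self.children[v]:
                if self.is_leaf[c]:
                    msg = self._leaf_message(P_by_node[c], self.leaf_states[c])
                else:
                    msg = P_by_node[c] @ inside[c]
                A_msg[c] = msg
                I = I * msg
            s = I.max(axis=0)
            s = np.where(s > 0, s, 1.0)
            I = I / s
            logscale += np.log(s)
            inside[v] = I
            scale_at[v] = s
        f_scaled = pi @ inside[self.root_id]
        with np.errstate(divide="ignore"):
            logf = np.log(f_scaled) + logscale
        cache = (A_msg, inside, scale_at, f_scaled) if keep_cache else None
        return logf, cache

    def branch_gradient(
        self,
        P_by_node: dict[int, np.ndarray],
        QP_by_node: dict[int, np.ndarray],
        pi: np.ndarray,
        cache,
    ) -> np.ndarray:
        """d(log f_p)/d t_b for every branch: inside-outside pass.

        Returns an array (n_branches, npat) in the order of ``branch_ids``.
        """
        A_msg, inside, scale_at, f_scaled = cache
        G = np.zeros((self.n_branches, self.npat))
        branch_pos = {nid: k for k, nid in enumerate(self.branch_ids)}
        outside: dict[int, np.ndarray] = {
            self.root_id: np.broadcast_to(
                pi[:, np.newaxis], (N_CODONS, self.npat)
            ).copy()
        }
        # preorder = reverse postorder
        for v in reversed(self.internal_order):
            O_v = outside[v]
            kids = self.children[v]
            for c in kids:
                U = O_v / scale_at[v]
                for s_ in kids:
                    if s_ is not c:
                        U = U * A_msg[s_]
                if self.is_leaf[c]:
                    states = self.leaf_states[c]
                    M = np.zeros((N_CODONS, self.npat))
                    ok = states >= 0
                    M[:, ok] = QP_by_node[c][:, states[ok]]
                    G[branch_pos[c]] = np.einsum("ip,ip->p", U, M)
                else:
                    G[branch_pos[c]] = np.einsum(
                        "ip,ip->p", U, QP_by_node[c] @ inside[c]
                    )
                    outside[c] = P_by_node[c].T @ U
        safe_f = np.where(f_scaled > 0, f_scaled, 1.0)
        return G / safe_f


# ---------------------------------------------------------------------------
# Parameter layout


@dataclass
class _Param:
    name: str
    init: float
    lo: float
    hi: float
    kind: str  # "bl", "kappa", "omega", "prop", "shape"


def _stick_to_simplex(v: Sequence[float]) -> np.ndarray:
    """Stick-breaking map from K-1 box variables in (0,1) to a K-simplex."""
    p = []
    rest = 1.0
    for x in v:
        p.append(rest * x)
        rest *= 1.0 - x
    p.append(rest)
    return np.array(p)


def _beta_category_omegas(p: float, q: float, ncat: int) -> np.ndarray:
    """Quantile midpoints of Beta(p, q) for equal-probability categories."""
    probs = (2.0 * np.arange(ncat) + 1.0) / (2.0 * ncat)
    return np.clip(sps.beta.ppf(probs, p, q), 1e-9, 1.0)


# ---------------------------------------------------------------------------
# Results


@dataclass
class SitePosterior:
    """Per-site class posteriors from a fitted mixture model (naive
    empirical Bayes: parameters fixed at their maximum-likelihood
    estimates)."""

    method: str
    class_omegas: np.ndarray          # omega of each class (foreground where
                                      # branch-site)
    proportions: np.ndarray
    posteriors: np.ndarray            # (n_sites, n_classes)
    positive_classes: np.ndarray      # bool per class: omega > 1
    flagged_sites: list[tuple[int, str, float]]  # (site_1based, residue, prob)
    threshold: float = 0.95


@dataclass
class CodonModelResults:
    """Maximum-likelihood fit of a codon model.

    ``n_params`` counts the omega-structure parameters (omegas, mixture
    proportions, beta shapes) — the count LRT degrees of freedom are built
    from; ``n_free_total`` additionally counts branch lengths and kappa if
    they were optimized in this fit.  Omega estimates that hit the upper
    box are listed in ``unbounded_params`` and rendered as ``inf``.
    """

    model: "CodonModel"
    spec: BranchModelSpec | SiteModelSpec
    lnL: float
    kappa: float
    params: dict[str, float]
    branch_lengths: list[float]
    n_params: int
    n_free_total: int
    converged: bool
    unbounded_params: list[str] = field(default_factory=list)
    message: str = ""
    n_starts: int = 1
    n_evals: int = 0

    @property
    def tree(self) -> LabeledTree:
        t = self.model.tree.copy()
        t.set_lengths(self.branch_lengths)
        return t

    def render(self, name: str) -> str:
        v = self.params[name]
        if name in self.unbounded_params:
            return "inf"
        return f"{v:.4g}"

    def lrt(self, null: "CodonModelResults"):
        from .stats import lrt as _lrt

        return _lrt(null.lnL, self.lnL, null.n_params, self.n_params)

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "lnL": self.lnL,
            "kappa": self.kappa,
            "n_params": self.n_params,
            "n_free_total": self.n_free_total,
            "estimates": self.params,
            "unbounded": list(self.unbounded_params),
            "converged": self.converged,
            "branch_lengths": list(self.branch_lengths),
        }

    def summary(self) -> str:
        lines = [
            f"Codon model fit: {self.spec.name}",
            "=" * 40,
            f"log-likelihood      {self.lnL:.4f}",
            f"omega-structure p   {self.n_params}",
            f"total free params   {self.n_free_total}",
            f"kappa               {self.kappa:.4f}",
            f"tree length         {sum(self.branch_lengths):.4f}",
            f"converged           {self.converged}",
        ]
        lines.append("-" * 40)
        width = max(24, max((len(n) for n in self.params), default=0) + 2)
        for name in self.params:
            lines.append(f"{name:<{width}s}{self.render(name)}")
        return "\n".join(lines)

    def site_posteriors(self, threshold: float = 0.95) -> SitePosterior:
        return self.model._site_posteriors(self, threshold)


# ---------------------------------------------------------------------------
# The model object


class CodonModel:
    """A codon substitution model bound to data.

    Parameters
    ----------
    alignment
        In-frame codon alignment containing every taxon of ``tree``.
    tree
        :class:`~dupsel.trees.LabeledTree` whose branch classes the model
        specification refers to.  Branch lengths, when present, serve as
        starting values (or as fixed values when they are not optimized).
    spec
        A :class:`~dupsel.models.BranchModelSpec` or
        :class:`~dupsel.models.SiteModelSpec`; default is the one-ratio
        model M0 over all branch classes in the tree.
    freq_mode
        "F3x4" (default), "equal" or "empirical"; ignored when ``pi`` is
        given explicitly.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: LabeledTree,
        spec: BranchModelSpec | SiteModelSpec | None = None,
        freq_mode: str = "F3x4",
        pi: np.ndarray | None = None,
        code: GeneticCode = STANDARD_CODE,
    ):
        self.alignment = alignment
        self.tree = tree.copy()
        tree_classes = self.tree.classes
        if spec is None or (isinstance(spec, BranchModelSpec) and spec.name == "M0"):
            spec = BranchModelSpec("M0", (tuple(sorted(tree_classes)),))
        if isinstance(spec, BranchModelSpec):
            spec.validate(tree_classes)
        else:
            if spec.is_branch_site:
                fg = set(spec.foreground)
                if not fg <= tree_classes:
                    raise ValueError(
                        f"foreground classes {sorted(fg - tree_classes)} not in tree"
                    )
        self.spec = spec
        self.code = code
        if pi is not None:
            pi = np.asarray(pi, dtype=float)
            if pi.shape != (N_CODONS,) or abs(pi.sum() - 1.0) > 1e-8:
                raise ValueError("pi must be a 61-simplex")
            self.pi = _floor_and_normalize(pi)
        elif freq_mode == "F3x4":
            self.pi = f3x4_frequencies(alignment)
        elif freq_mode == "equal":
            self.pi = equal_frequencies()
        elif freq_mode == "empirical":
            self.pi = empirical_codon_frequencies(alignment)
        else:
            raise ValueError(f"unknown freq_mode {freq_mode!r}")
        self.engine = _Engine(alignment, self.tree, code)
        self._eig_cache: dict[float, _Eigen] = {}
        self._rate_cache: dict[float, float] = {}

    # -- low-level building blocks ------------------------------------------

    def _eig(self, kappa: float, omega: float) -> _Eigen:
        key = (round(kappa, 12), round(omega, 12))
        eig = self._eig_cache.get(key)
        if eig is None:
            eig = _eigen_decompose(kappa, omega, self.pi)
            if len(self._eig_cache) > 256:
                self._eig_cache.clear()
            self._eig_cache[key] = eig
        return eig

    def _rate(self, kappa: float, omega: float) -> float:
        key = (round(kappa, 12), round(omega, 12))
        r = self._rate_cache.get(key)
        if r is None:
            r = substitution_rate(kappa, omega, self.pi)
            self._rate_cache[key] = r
        return r

    def _branch_omegas(self, omegas: np.ndarray) -> list[float]:
        """Omega of each branch in engine branch order (branch models)."""
        spec = self.spec
        if spec.per_branch:
            return list(omegas)
        return [
            float(omegas[spec.group_of(cls)]) for cls in self.engine.branch_classes
        ]

    # -- likelihood evaluation ----------------------------------------------

    def _loglik_branch(self, bl, kappa, omegas, want_grad=False):
        eng = self.engine
        per_branch = self._branch_omegas(np.asarray(omegas, dtype=float))
        P_by_node, QP_by_node = {}, {}
        for k, nid in enumerate(eng.branch_ids):
            eig = self._eig(kappa, per_branch[k])
            P_by_node[nid] = eig.P(bl[k])
            if want_grad:
                QP_by_node[nid] = eig.QP(bl[k])
        logf, cache = eng.site_loglik(P_by_node, self.pi, keep_cache=want_grad)
        lnL = float(eng.weights @ logf)
        if not want_grad:
            return lnL, None
        G = eng.branch_gradient(P_by_node, QP_by_node, self.pi, cache)
        grad_bl = G @ eng.weights
        return lnL, grad_bl

    def _site_classes(self, kappa, params):
        """(proportions, bg omegas, fg omegas) for the current site spec."""
        spec = self.spec
        name = spec.name
        if name == "M1":
            props = np.array([params["p0"], 1.0 - params["p0"]])
            om = np.array([params["omega0"], 1.0])
            return props, om, om
        if name == "M2":
            props = _stick_to_simplex([params["v0"], params["v1"]])
            om = np.array([params["omega0"], 1.0, params["omega2"]])
            return props, om, om
        if name == "M3":
            K = spec.n_classes
            props = _stick_to_simplex([params[f"v{k}"] for k in range(K - 1)])
            om = np.array([params[f"omega{k}"] for k in range(K)])
            return props, om, om
        if name == "M7":
            K = spec.n_beta_categories
            om = _beta_category_omegas(params["beta_p"], params["beta_q"], K)
            return np.full(K, 1.0 / K), om, om
        if name == "M8":
            K = spec.n_beta_categories
            p0 = params["p0"]
            om = np.concatenate(
                [
                    _beta_category_omegas(params["beta_p"], params["beta_q"], K),
                    [params["omega_s"]],
                ]
            )
            props = np.concatenate([np.full(K, p0 / K), [1.0 - p0]])
            return props, om, om
        if name in ("bsA", "bsB"):
            p0, p1 = _stick_to_simplex([params["v0"], params["v1"]])[:2]
            rest = max(1.0 - p0 - p1, 0.0)
            denom = p0 + p1
            p2a = rest * p0 / denom
            p2b = rest * p1 / denom
            props = np.array([p0, p1, p2a, p2b])
            w0 = params["omega0"]
            w1 = 1.0 if name == "bsA" else params["omega1"]
            w2 = params["omega2"]
            bg = np.array([w0, w1, w0, w1])
            fg = np.array([w0, w1, w2, w2])
            return props, bg, fg
        raise AssertionError(name)

    def _loglik_site(self, bl, kappa, params, want_grad=False,
                     return_class_logf=False):
        eng = self.engine
        props, bg, fg = self._site_classes(kappa, params)
        K = len(props)
        fg_branch = [
            cls in set(getattr(self.spec, "foreground", ()))
            for cls in eng.branch_classes
        ]
        r_bg = np.array([self._rate(kappa, w) for w in bg])
        r_fg = np.array([self._rate(kappa, w) for w in fg])
        c_bg = float(props @ r_bg)
        c_fg = float(props @ r_fg)
        class_logf = np.empty((K, eng.npat))
        grads = []
        caches = []
        factors = np.empty((K, eng.n_branches))
        for k in range(K):
            P_by_node, QP_by_node = {}, {}
            for b, nid in enumerate(eng.branch_ids):
                if fg_branch[b]:
                    w, fac = fg[k], r_fg[k] / c_fg
                else:
                    w, fac = bg[k], r_bg[k] / c_bg
                eig = self._eig(kappa, w)
                t_eff = bl[b] * fac
                P_by_node[nid] = eig.P(t_eff)
                factors[k, b] = fac
                if want_grad:
                    QP_by_node[nid] = eig.QP(t_eff, rate_factor=fac)
            logf, cache = eng.site_loglik(P_by_node, self.pi,
                                          keep_cache=want_grad)
            class_logf[k] = logf
            if want_grad:
                G = eng.branch_gradient(P_by_node, QP_by_node, self.pi, cache)
                grads.append(G)
        # combine classes in log space
        logp = np.log(np.maximum(props, 1e-300))
        M = logp[:, np.newaxis] + class_logf
        mmax = M.max(axis=0)
        lik = np.exp(M - mmax)
        tot = lik.sum(axis=0)
        logf_total = mmax + np.log(tot)
        lnL = float(eng.weights @ logf_total)
        extras = {}
        if return_class_logf:
            extras["class_logf"] = class_logf
            extras["proportions"] = props
            extras["fg_omegas"] = fg
        if not want_grad:
            return lnL, None, extras
        resp = lik / tot  # (K, npat) posterior responsibilities
        Gtot = np.zeros((eng.n_branches, eng.npat))
        for k in range(K):
            Gtot += resp[k][np.newaxis, :] * grads[k]
        grad_bl = Gtot @ eng.weights
        return lnL, grad_bl, extras

    # -- public likelihood --------------------------------------------------

    def log_likelihood(
        self,
        kappa: float,
        branch_lengths: Sequence[float] | None = None,
        omega: float | Sequence[float] | None = None,
        **site_params,
    ) -> float:
        """Log-likelihood at explicitly given parameter values.

        For branch models pass ``omega`` (scalar for M0, one value per
        group otherwise); for site models pass the layout parameters by
        name (``p0``, ``omega0``, ``beta_p`` ... as used in fit results).
        """
        bl = (
            np.asarray(branch_lengths, dtype=float)
            if branch_lengths is not None
            else np.asarray(self.tree.get_lengths(), dtype=float)
        )
        if len(bl) != self.engine.n_branches:
            raise ValueError("wrong number of branch lengths")
        if isinstance(self.spec, BranchModelSpec):
            if omega is None:
                raise ValueError("branch models need omega")
            om = np.atleast_1d(np.asarray(omega, dtype=float))
            if not self.spec.per_branch and len(om) == 1:
                om = np.repeat(om, len(self.spec.groups))
            lnL, _ = self._loglik_branch(bl, kappa, om)
            return lnL
        lnL, _, _ = self._loglik_site(bl, kappa, site_params)
        return lnL

    # -- parameter layout ---------------------------------------------------

    def _layout(self, optimize_bl, kappa_fixed, start_omega, start_index):
        params: list[_Param] = []
        eng = self.engine
        if optimize_bl:
            init_bl = self._initial_branch_lengths()
            for k in range(eng.n_branches):
                params.append(_Param(f"t{k}", init_bl[k], 1e-8, 50.0, "bl"))
        if kappa_fixed is None:
            params.append(_Param("kappa", 2.0, 0.01, 100.0, "kappa"))
        spec = self.spec
        s = start_omega
        if isinstance(spec, BranchModelSpec):
            n = eng.n_branches if spec.per_branch else len(spec.groups)
            for g in range(n):
                nm = f"omega{g}" if spec.per_branch else self._group_name(g)
                params.append(_Param(nm, s, OMEGA_MIN, OMEGA_MAX, "omega"))
            return params
        w0 = min(max(s, 1e-4), 0.9)
        w_pos = [1.5, 4.0, 10.0][start_index % 3]
        name = spec.name
        if name == "M1":
            params += [
                _Param("p0", 0.8, 1e-9, 1 - 1e-9, "prop"),
                _Param("omega0", w0, OMEGA_MIN, 1 - 1e-6, "omega"),
            ]
        elif name == "M2":
            params += [
                _Param("v0", 0.7, 1e-9, 1 - 1e-9, "prop"),
                _Param("v1", 0.7, 1e-9, 1 - 1e-9, "prop"),
                _Param("omega0", w0, OMEGA_MIN, 1 - 1e-6, "omega"),
                _Param("omega2", w_pos, 1.0, OMEGA_MAX, "omega"),
            ]
        elif name == "M3":
            K = spec.n_classes
            for k in range(K - 1):
                params.append(_Param(f"v{k}", 0.6, 1e-9, 1 - 1e-9, "prop"))
            oms = np.geomspace(max(s / 5, 1e-4), max(s * 5, 1e-3), K)
            for k in range(K):
                params.append(
                    _Param(f"omega{k}", float(oms[k]), OMEGA_MIN, OMEGA_MAX,
                           "omega")
                )
        elif name == "M7":
            params += [
                _Param("beta_p", [0.3, 1.0, 2.0][start_index % 3], 0.005, 99.0,
                       "shape"),
                _Param("beta_q", [1.5, 1.0, 5.0][start_index % 3], 0.005, 99.0,
                       "shape"),
            ]
        elif name == "M8":
            params += [
                _Param("p0", 0.9, 1e-9, 1 - 1e-9, "prop"),
                _Param("beta_p", [0.3, 1.0, 2.0][start_index % 3], 0.005, 99.0,
                       "shape"),
                _Param("beta_q", [1.5, 1.0, 5.0][start_index % 3], 0.005, 99.0,
                       "shape"),
                _Param("omega_s", w_pos, 1.0, OMEGA_MAX, "omega"),
            ]
        elif name in ("bsA", "bsB"):
            params += [
                _Param("v0", 0.75, 1e-9, 1 - 1e-9, "prop"),
                _Param("v1", 0.75, 1e-9, 1 - 1e-9, "prop"),
                _Param("omega0", w0, OMEGA_MIN, 1 - 1e-6, "omega"),
            ]
            if name == "bsB":
                params.append(
                    _Param("omega1", max(s, 0.5), OMEGA_MIN, OMEGA_MAX, "omega")
                )
                params.append(
                    _Param("omega2", w_pos, OMEGA_MIN, OMEGA_MAX, "omega")
                )
            else:
                params.append(_Param("omega2", w_pos, 1.0, OMEGA_MAX, "omega"))
        return params

    def _group_name(self, g: int) -> str:
        labels = self.spec.groups[g]
        return "omega(" + ",".join(labels) + ")"

    def _initial_branch_lengths(self) -> np.ndarray:
        if self.tree.has_lengths() and self.tree.total_length() > 0:
            return np.maximum(np.asarray(self.tree.get_lengths()), 1e-6)
        from .divergence import jc_distance

        ds = []
        seqs = self.alignment.sequences
        for i in range(min(len(seqs), 8)):
            for j in range(i + 1, min(len(seqs), 8)):
                d = jc_distance(seqs[i], seqs[j])
                if not math.isnan(d):
                    ds.append(d)
        mean_k = float(np.mean(ds)) if ds else 0.2
        init = min(max(mean_k / 4.0, 0.01), 2.0)
        return np.full(self.engine.n_branches, init)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        optimize_branch_lengths: bool | None = None,
        kappa: float | None = None,
        starts: Sequence[float] = (0.05, 0.5, 2.0),
        maxiter: int = 500,
        tol: float = 1e-8,
    ) -> CodonModelResults:
        """Maximize the log-likelihood.

        Parameters
        ----------
        optimize_branch_lengths
            None (default) estimates branch lengths only for the one-ratio
            model M0 (or when the tree carries no lengths); other models
            reuse the lengths on the tree — the customary two-stage
            protocol where M0 supplies branch lengths and kappa for the
            whole model ladder.
        kappa
            None to estimate jointly, or a fixed value (typically the M0
            estimate).
        starts
            Initial omega values for the multi-start search; fixed list,
            no randomness.
        """
        is_m0_like = (
            isinstance(self.spec, BranchModelSpec)
            and not self.spec.per_branch
            and len(self.spec.groups) == 1
        )
        if optimize_branch_lengths is None:
            optimize_branch_lengths = is_m0_like or not self.tree.has_lengths()
        if not optimize_branch_lengths and not self.tree.has_lengths():
            raise ValueError(
                "tree has no branch lengths; fit M0 first or pass "
                "optimize_branch_lengths=True"
            )

        best = None
        n_evals_total = 0
        for si, s in enumerate(starts):
            layout = self._layout(optimize_branch_lengths, kappa, s, si)
            x0 = np.array([p.init for p in layout])
            bounds = [(p.lo, p.hi) for p in layout]
            res, n_evals = self._optimize(layout, x0, bounds,
                                          optimize_branch_lengths, kappa,
                                          maxiter, tol)
            n_evals_total += n_evals
            if best is None or res.fun < best[0].fun - 1e-12:
                best = (res, layout)
        res, layout = best
        return self._package(res, layout, optimize_branch_lengths, kappa,
                             len(starts), n_evals_total)

    def _unpack(self, x, layout, optimize_bl, kappa_fixed):
        vals = dict(zip((p.name for p in layout), x))
        if optimize_bl:
            bl = np.array([vals[f"t{k}"] for k in range(self.engine.n_branches)])
        else:
            bl = np.asarray(self.tree.get_lengths(), dtype=float)
        kap = vals.get("kappa", kappa_fixed)
        other = {
            p.name: vals[p.name]
            for p in layout
            if p.kind not in ("bl",)
        }
        return bl, float(kap), other

    def _objective(self, layout, optimize_bl, kappa_fixed):
        nbl = self.engine.n_branches if optimize_bl else 0
        other_idx = list(range(nbl, len(layout)))

        def eval_lnL(x, want_grad_bl):
            bl, kap, other = self._unpack(x, layout, optimize_bl, kappa_fixed)
            if isinstance(self.spec, BranchModelSpec):
                n = (
                    self.engine.n_branches
                    if self.spec.per_branch
                    else len(self.spec.groups)
                )
                names = (
                    [f"omega{g}" for g in range(n)]
                    if self.spec.per_branch
                    else [self._group_name(g) for g in range(n)]
                )
                om = np.array([other[nm] for nm in names])
                return self._loglik_branch(bl, kap, om, want_grad=want_grad_bl)
            site = {k: v for k, v in other.items() if k != "kappa"}
            lnL, g, _ = self._loglik_site(bl, kap, site,
                                          want_grad=want_grad_bl)
            return lnL, g

        counter = {"n": 0}

        def fun_and_grad(x):
            counter["n"] += 1
            lnL, grad_bl = eval_lnL(x, optimize_bl)
            grad = np.zeros_like(x)
            if optimize_bl:
                grad[:nbl] = grad_bl
            for i in other_idx:
                h = max(1e-7, 1e-7 * abs(x[i]))
                lo, hi = layout[i].lo, layout[i].hi
                xp = x.copy()
                xm = x.copy()
                xp[i] = min(x[i] + h, hi)
                xm[i] = max(x[i] - h, lo)
                fp, _ = eval_lnL(xp, False)
                fm, _ = eval_lnL(xm, False)
                denom = xp[i] - xm[i]
                grad[i] = (fp - fm) / denom if denom > 0 else 0.0
                counter["n"] += 2
            return -lnL, -grad

        return fun_and_grad, counter

    def _optimize(self, layout, x0, bounds, optimize_bl, kappa_fixed,
                  maxiter, tol):
        fun_and_grad, counter = self._objective(layout, optimize_bl,
                                                kappa_fixed)
        res = sopt.minimize(
            fun_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7,
                     "maxcor": 20},
        )
        # polish: a short tighter-tolerance pass so converged likelihoods
        # honor model-nesting inequalities to ~1e-7
        res2 = sopt.minimize(
            fun_and_grad,
            res.x,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-15, "gtol": 1e-9,
                     "maxcor": 20},
        )
        if res2.fun <= res.fun:
            res2.success = res.success or res2.success
            res = res2
        return res, counter["n"]

    def _package(self, res, layout, optimize_bl, kappa_fixed, n_starts,
                 n_evals):
        bl, kap, other = self._unpack(res.x, layout, optimize_bl, kappa_fixed)
        spec = self.spec
        params: dict[str, float] = {}
        unbounded = []
        if isinstance(spec, BranchModelSpec):
            n = self.engine.n_branches if spec.per_branch else len(spec.groups)
            names = (
                [f"omega{g}" for g in range(n)]
                if spec.per_branch
                else [self._group_name(g) for g in range(n)]
            )
            for nm in names:
                params[nm] = float(other[nm])
            n_params = n
        else:
            site = {k: v for k, v in other.items() if k != "kappa"}
            props, bg, fg = self._site_classes(kap, site)
            for k, v in site.items():
                params[k] = float(v)
            for k, p_ in enumerate(props):
                params[f"p{k}_hat"] = float(p_)
            if spec.is_branch_site or spec.name in ("M1", "M2", "M3", "M8"):
                for k, w in enumerate(fg):
                    params[f"omega{k}_hat"] = float(w)
            n_params = spec.n_omega
        for nm, v in list(params.items()):
            if nm.startswith("omega") and v >= OMEGA_UNBOUNDED:
                unbounded.append(nm)
        n_free_total = len(layout)
        converged = bool(res.success)
        if not converged:
            warnings.warn(
                f"{spec.name}: optimizer did not report convergence "
                f"({res.message}); best found lnL = {-res.fun:.6f}",
                stacklevel=3,
            )
        return CodonModelResults(
            model=self,
            spec=spec,
            lnL=-float(res.fun),
            kappa=float(kap),
            params=params,
            branch_lengths=[float(t) for t in bl],
            n_params=n_params,
            n_free_total=n_free_total,
            converged=converged,
            unbounded_params=unbounded,
            message=str(res.message),
            n_starts=n_starts,
            n_evals=n_evals,
        )

    # -- posteriors ---------------------------------------------------------

    def _site_posteriors(self, results: CodonModelResults,
                         threshold: float) -> SitePosterior:
        if isinstance(self.spec, BranchModelSpec):
            raise ValueError("site posteriors require a site-mixture model")
        site = {
            k: v
            for k, v in results.params.items()
            if not k.endswith("_hat")
        }
        bl = np.asarray(results.branch_lengths)
        _, _, extras = self._loglik_site(
            bl, results.kappa, site, return_class_logf=True
        )
        class_logf = extras["class_logf"]
        props = extras["proportions"]
        fg = extras["fg_omegas"]
        logp = np.log(np.maximum(props, 1e-300))
        M = logp[:, np.newaxis] + class_logf
        M -= M.max(axis=0)
        lik = np.exp(M)
        post_pat = (lik / lik.sum(axis=0)).T  # (npat, K)
        post = post_pat[self.engine.site_to_pattern]  # (nsites, K)
        positive = fg > 1.0
        flagged = []
        if positive.any():
            p_pos = post[:, positive].sum(axis=1)
            ref = self.alignment.codons(0)
            for h in np.nonzero(p_pos >= threshold)[0]:
                codon = ref[h]
                aa = (
                    self.code.translate(codon)
                    if all(c in "ACGT" for c in codon)
                    else "X"
                )
                flagged.append((int(h) + 1, aa, float(p_pos[h])))
        return SitePosterior(
            method="NEB",
            class_omegas=np.asarray(fg),
            proportions=np.asarray(props),
            posteriors=post,
            positive_classes=positive,
            flagged_sites=flagged,
            threshold=threshold,
        )
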