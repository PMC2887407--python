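"""Declarative specifications of codon substitution models.

Two families are supported, both built on the Goldman–Yang (1994) codon
rate matrix with transition/transversion ratio kappa and selection
parameter omega = dN/dS:

* **Branch models** partition the branches of a labeled tree into groups,
  each with its own omega.  The standard ladder for a gene duplication with
  branch classes {pre, stem_g1, stem_g5, g1, g5} runs from a single ratio
  (M0) through two (M2r: before vs after the duplication), three (M3r: the
  two paralog lineages differ), four (M4r) and five ratios (M5r), plus the
  free-ratio model (Mf, one omega per branch).

* **Site models** let omega vary among codon sites via a finite mixture
  (M1 nearly-neutral, M2 positive-selection, M3 discrete) or a discretized
  beta distribution (M7, and M8 with an extra omega class), and the
  branch-site models A and B in which an extra site class takes a separate
  omega only on designated foreground branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "BranchModelSpec",
    "SiteModelSpec",
    "DUPLICATION_CLASSES",
]

# canonical branch classes of a duplication-shaped tree
DUPLICATION_CLASSES = ("pre", "stem_g1", "stem_g5", "g1", "g5")

OMEGA_MIN = 1e-6
OMEGA_MAX = 999.0
# estimates at or above this are reported as unbounded ("inf")
OMEGA_UNBOUNDED = 990.0


@dataclass(frozen=True)
class BranchModelSpec:
    """A partition of branch classes into shared-omega groups.

    ``groups`` lists tuples of branch-class labels; classes in one tuple
    share a single omega.  ``per_branch`` marks the free-ratio model, which
    ignores ``groups`` and gives every branch its own omega.
    """

    name: str
    groups: tuple[tuple[str, ...], ...] = ()
    per_branch: bool = False

    @property
    def n_omega(self) -> int | None:
        return None if self.per_branch else len(self.groups)

    def group_of(self, cls: str) -> int:
        for g, labels in enumerate(self.groups):
            if cls in labels:
                return g
        raise KeyError(f"branch class {cls!r} not covered by model {self.name}")

    def validate(self, classes: set[str]) -> None:
        if self.per_branch:
            return
        covered = {c for g in self.groups for c in g}
        missing = classes - covered
        if missing:
            raise ValueError(
                f"model {self.name} does not cover branch classes {sorted(missing)}"
            )

    # -- canonical duplication-ladder constructors --------------------------

    @classmethod
    def M0(cls, classes=DUPLICATION_CLASSES) -> "BranchModelSpec":
        """One ratio for every branch."""
        return cls("M0", (tuple(classes),))

    @classmethod
    def M2r(cls) -> "BranchModelSpec":
        """Pre-duplication vs all post-duplication branches."""
        return cls("M2r", (("pre",), ("stem_g1", "stem_g5", "g1", "g5")))

    @classmethod
    def M3r(cls) -> "BranchModelSpec":
        """Pre-duplication vs the two paralog lineages (stem + crown each)."""
        return cls("M3r", (("pre",), ("stem_g1", "g1"), ("stem_g5", "g5")))

    @classmethod
    def M4r(cls) -> "BranchModelSpec":
        """Separate ratio for the stems, and for each paralog crown."""
        return cls("M4r", (("pre",), ("stem_g1", "stem_g5"), ("g1",), ("g5",)))

    @classmethod
    def M5r(cls) -> "BranchModelSpec":
        """All five duplication classes free."""
        return cls("M5r", tuple((c,) for c in DUPLICATION_CLASSES))

    @classmethod
    def Mf(cls) -> "BranchModelSpec":
        """Free-ratio model: one omega per branch."""
        return cls("Mf", per_branch=True)


@dataclass(frozen=True)
class SiteModelSpec:
    """A site-mixture (or branch-site) omega model.

    ``name`` is one of M1, M2, M3, M7, M8, bsA, bsB.  ``n_classes`` applies
    to M3 (discrete categories); ``n_beta_categories`` to M7/M8;
    ``foreground`` (branch-class labels) to the branch-site models.
    """

    name: str
    n_classes: int = 3
    n_beta_categories: int = 10
    foreground: tuple[str, ...] = ()

    def __post_init__(self):
        if self.name not in {"M1", "M2", "M3", "M7", "M8", "bsA", "bsB"}:
            raise ValueError(f"unknown site model {self.name!r}")
        if self.is_branch_site and not self.foreground:
            raise ValueError(f"{self.name} requires foreground branch classes")

    @property
    def is_branch_site(self) -> bool:
        return self.name in {"bsA", "bsB"}

    @property
    def n_omega(self) -> int:
        """Count of free omega-structure parameters (omegas, proportions,
        beta shapes), the quantity LRT degrees of freedom are built from."""
        return {
            "M1": 2,          # p0, w0
            "M2": 4,          # p0, p1, w0, w2
            "M3": 2 * self.n_classes - 1,
            "M7": 2,          # p, q
            "M8": 4,          # p0, p, q, ws
            "bsA": 4,         # p0, p1, w0, w2
            "bsB": 5,         # p0, p1, w0, w1, w2
        }[self.name]

    @classmethod
    def M1(cls) -> "SiteModelSpec":
        return cls("M1")

    @classmethod
    def M2(cls) -> "SiteModelSpec":
        return cls("M2")

    @classmethod
    def M3(cls, n_classes: int = 3) -> "SiteModelSpec":
        return cls("M3", n_classes=n_classes)

    @classmethod
    def M7(cls, n_beta_categories: int = 10) -> "SiteModelSpec":
        return cls("M7", n_beta_categories=n_beta_categories)

    @classmethod
    def M8(cls, n_beta_categories: int = 10) -> "SiteModelSpec":
        return cls("M8", n_beta_categories=n_beta_categories)

    @classmethod
    def bsA(cls, foreground) -> "SiteModelSpec":
        return cls("bsA", foreground=tuple(foreground))

    @classmethod
    def bsB(cls, foreground) -> "SiteModelSpec":
        return cls("bsB", foreground=tuple(foreground))
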