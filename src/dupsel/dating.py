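"""Molecular-clock dating of a gene duplication from synonymous distances.

Given the synonymous distance between orthologs of two species whose split
is dated at T_calibration million years, the per-lineage synonymous rate is
r = dS_ortholog / (2 T).  The paralog pair then dates the duplication at
t = dS_paralog / (2 r).  Inputs may come from NG86 mean divergences or be
supplied directly: dating is decoupled from distance estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ClockEstimate", "clock_date"]


@dataclass
class ClockEstimate:
    """A dS-clock duplication-age estimate.

    ``rate`` is in synonymous substitutions per synonymous site per million
    years (per lineage); ``t_duplication`` in million years ago.  Inputs are
    echoed for the report.  ``t_rounded`` gives the nearest-integer
    rendering used in prose.
    """

    rate: float
    t_duplication: float
    dS_ortholog: float
    dS_paralog: float
    T_calibration: float

    @property
    def t_rounded(self) -> int:
        return round(self.t_duplication)


def clock_date(
    dS_ortholog: float, dS_paralog: float, T_calibration: float
) -> ClockEstimate:
    """Date a duplication from ortholog/paralog dS and a calibration split.

    Algebraically t = dS_paralog * T_calibration / dS_ortholog; all three
    inputs must be positive.
    """
    if dS_ortholog <= 0 or dS_paralog <= 0 or T_calibration <= 0:
        raise ValueError("all clock inputs must be positive")
    rate = dS_ortholog / (2.0 * T_calibration)
    t = dS_paralog / (2.0 * rate)
    return ClockEstimate(
        rate=rate,
        t_duplication=t,
        dS_ortholog=dS_ortholog,
        dS_paralog=dS_paralog,
        T_calibration=T_calibration,
    )
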