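"""Two-state conformational-switching model of the 26S proteasome.

The substrate-free proteasome interconverts between an engagement-competent
state (s1, low apparent FRET) and an aggregate of processing-competent states
(non-s1, high apparent FRET).  Both directions are treated as single-
exponential processes; ubiquitin binding slows the forward (s1 -> non-s1)
transition with hyperbolic saturation in the free ligand concentration while
leaving the backward rate essentially unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class KineticParams:
    """Rates of the two-state switch and the ligand-binding constant.

    Parameters
    ----------
    k_f_apo : float
        s1 -> non-s1 rate at zero ligand, in s^-1.
    k_f_sat : float
        s1 -> non-s1 rate at saturating ligand, in s^-1.  Must not exceed
        ``k_f_apo``: ubiquitin only decelerates the forward transition.
    k_b : float
        non-s1 -> s1 rate, in s^-1 (ligand-independent by default).
    K_D_app : float
        Apparent dissociation constant of the ligand, in uM.
    """

    k_f_apo: float
    k_f_sat: float
    k_b: float
    K_D_app: float

    def __post_init__(self) -> None:
        if not (self.k_f_apo > 0 and self.k_f_sat > 0 and self.k_b > 0):
            raise ValueError("all rates must be > 0")
        if not self.K_D_app > 0:
            raise ValueError("K_D_app must be > 0")
        if self.k_f_sat > self.k_f_apo:
            raise ValueError("k_f_sat must not exceed k_f_apo")


@dataclass(frozen=True)
class ConditionSpec:
    """A named experimental condition: proteasome variant plus ligand level.

    ``k_f`` and ``k_b`` are the effective rates resolved for this condition
    (condition-level rates, not necessarily on the titration hyperbola).
    """

    label: str
    ligand_conc: float = 0.0
    k_f: float | None = None
    k_b: float | None = None
    params: KineticParams | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("condition label must be nonempty")
        if self.ligand_conc < 0:
            raise ValueError("ligand_conc must be >= 0")

    def forward_rate(self) -> float:
        if self.k_f is not None:
            return self.k_f
        if self.params is not None:
            return forward_rate_at_conc(self.params, self.ligand_conc)
        raise ValueError(f"condition {self.label!r} has no forward rate")

    def backward_rate(self) -> float:
        if self.k_b is not None:
            return self.k_b
        if self.params is not None:
            return self.params.k_b
        raise ValueError(f"condition {self.label!r} has no backward rate")


def forward_rate_at_conc(p: KineticParams, c: float) -> float:
    """s1 -> non-s1 rate at free ligand concentration ``c`` (uM).

    Single-site binding isotherm: the apo rate at c = 0 relaxes
    hyperbolically to the saturated rate,

        k_f(c) = k_f_sat + (k_f_apo - k_f_sat) * K_D / (K_D + c).

    Ligand depletion is ignored (immobilized proteasome at <= 1 nM against
    uM ligand).  Monotone non-increasing in ``c``.
    """
    if c < 0:
        raise ValueError("concentration must be >= 0")
    return p.k_f_sat + (p.k_f_apo - p.k_f_sat) * p.K_D_app / (p.K_D_app + c)


def mean_dwell(rate: float) -> float:
    """Mean dwell time tau = 1/k of an exponential process (seconds)."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return 1.0 / rate


def stationary_occupancy_s1(k_f: float, k_b: float) -> float:
    """Equilibrium fraction of time in s1: k_b / (k_f + k_b)."""
    if k_f <= 0 or k_b <= 0:
        raise ValueError("rates must be > 0")
    return k_b / (k_f + k_b)
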