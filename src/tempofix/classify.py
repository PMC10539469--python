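"""Amplifier/suppressor classification on the nine-point fitness grid.

A network (static or switching) is an amplifier of selection when its
fixation probability beats the Moran baseline at every advantageous fitness
on the grid and falls below it at every deleterious one; a suppressor when
all nine inequalities are reversed; isothermal when the fixation probability
matches the Moran value everywhere.  Remaining sign patterns are "neither".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

from .solvers import moran_probability

__all__ = [
    "R_BELOW",
    "R_ABOVE",
    "R_GRID",
    "R_LARGE_PROBES",
    "DEFAULT_TOL",
    "Classification",
    "classify",
    "classify_values",
]

R_BELOW: tuple[float, ...] = (0.7, 0.8, 0.9)
R_ABOVE: tuple[float, ...] = (1.1, 1.2, 1.3, 1.4, 1.6, 1.8)
R_GRID: tuple[float, ...] = R_BELOW + R_ABOVE

# large-r probes for the global (all-r) amplifier/suppressor notion: a
# network whose fixation probability re-crosses the Moran curve above
# r = 1.8 is not a suppressor in the classical sense even though it looks
# like one on the nine-point grid
R_LARGE_PROBES: tuple[float, ...] = (2.0, 3.0, 6.0, 10.0)

# direct transient solves are accurate to ~1e-13; 1e-9 separates genuine
# equality (isothermal families) from tiny but real amplification
DEFAULT_TOL = 1e-9

VERDICTS = ("amplifier", "suppressor", "isothermal", "neither")


@dataclass(frozen=True)
class Classification:
    verdict: str
    rho_by_r: dict[float, float]
    moran_by_r: dict[float, float]

    @property
    def differences(self) -> dict[float, float]:
        return {r: self.rho_by_r[r] - self.moran_by_r[r] for r in self.rho_by_r}


def classify_values(
    rho_by_r: Mapping[float, float], n: int, tol: float = DEFAULT_TOL
) -> Classification:
    """Classify from precomputed fixation probabilities on the grid.

    The nine-point grid must be covered; any additional r values supplied
    (e.g. the ``R_LARGE_PROBES`` used for static censuses) join the strict
    inequalities on their side of r = 1.  Comparisons within ``tol`` of the
    Moran value count as ties: all ties is isothermal, and a tie anywhere
    else demotes the verdict to neither (the amplifier/suppressor
    inequalities are strict at every evaluated point).
    """
    missing = [r for r in R_GRID if r not in rho_by_r]
    if missing:
        raise ValueError(f"rho values missing for grid points {missing}")
    rho = {r: float(rho_by_r[r]) for r in sorted(rho_by_r)}
    for r, v in rho.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"fixation probability {v} at r={r} is outside [0, 1]")
    moran = {r: moran_probability(r, n) for r in rho}
    diff = {r: rho[r] - moran[r] for r in rho}
    above = [r for r in rho if r > 1.0]
    below = [r for r in rho if r < 1.0]

    if all(abs(d) <= tol for d in diff.values()):
        verdict = "isothermal"
    elif all(diff[r] > tol for r in above) and all(diff[r] < -tol for r in below):
        verdict = "amplifier"
    elif all(diff[r] < -tol for r in above) and all(diff[r] > tol for r in below):
        verdict = "suppressor"
    else:
        verdict = "neither"
    return Classification(verdict=verdict, rho_by_r=rho, moran_by_r=moran)


def classify(
    rho_fn: Callable[[float], float], n: int, tol: float = DEFAULT_TOL
) -> Classification:
    """Classify a network given a callable r -> fixation probability."""
    return classify_values({r: rho_fn(r) for r in R_GRID}, n, tol)
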