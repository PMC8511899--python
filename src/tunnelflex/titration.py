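"""Constant-pH Metropolis Monte Carlo titration at fixed geometry.

Protonation states of titratable sites are sampled by Metropolis Monte
Carlo.  The free energy of moving one site from protonated to
deprotonated at a given pH is

    dG = kB * T * (pH - pKa_ref) * ln(10) + dG_elec - dG_elec_ref

where pKa_ref is the reference-compound pKa of the site and the two
electrostatic terms describe the site in its environment versus the
reference compound (a model dipeptide).  The sign convention is fixed by
requiring that the reference compound titrate correctly: dG is the free
energy of the *protonated* microstate relative to the deprotonated one,
so above the pKa the protonated state is penalized and a single site
with dG_elec == dG_elec_ref ("null model") titrates exactly along the
Henderson-Hasselbalch curve f_prot(pH) = 1 / (1 + 10**(pH - pKa_ref)),
which is the module's primary closed-form oracle.

Implementation is energy-based: a system free energy over the binary
protonation microstate is defined whose single-flip differences
reproduce the equation above, so site-site electrostatic coupling can be
plugged in while Metropolis detailed balance continues to hold.  No
conformational propagation happens between MC steps — geometry is fixed,
which is what makes this a desk-scale engine rather than a molecular
dynamics one.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "KB_KCAL",
    "LN10",
    "TitrationSite",
    "TitrationSystem",
    "TitrationRun",
    "transition_free_energy",
    "mc_step",
    "run_titration",
    "henderson_hasselbalch",
    "estimate_pka",
]

#: Boltzmann constant, kcal/(mol*K)
KB_KCAL = 1.9872e-3
LN10 = math.log(10.0)


def transition_free_energy(
    pH: float,
    pKa_ref: float,
    dG_elec: float = 0.0,
    dG_elec_ref: float = 0.0,
    T: float = 300.0,
) -> float:
    """pH-dependent transition free energy (kcal/mol).

    Assigned to the protonated microstate relative to the deprotonated
    one; the reverse move carries the negation.  A constant electrostatic
    offset delta = dG_elec - dG_elec_ref shifts the zero-crossing pH (the
    apparent pKa) by -delta / (kB*T*ln10).
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    return KB_KCAL * T * (pH - pKa_ref) * LN10 + dG_elec - dG_elec_ref


@dataclasses.dataclass
class TitrationSite:
    id: str
    pKa_ref: float
    elec_offset: float = 0.0       # dG_elec - dG_elec_ref, kcal/mol
    protonated: bool = True

    def __post_init__(self) -> None:
        if not math.isfinite(self.pKa_ref):
            raise ValueError(f"site {self.id}: pKa_ref must be finite")


@dataclasses.dataclass
class TitrationSystem:
    sites: list[TitrationSite]
    temperature: float = 300.0
    #: optional state-dependent electrostatic coupling, kcal/mol, taking the
    #: protonation vector; added to the per-site terms in the total energy
    coupling: Callable[[np.ndarray], float] | None = None

    @property
    def states(self) -> np.ndarray:
        return np.array([s.protonated for s in self.sites], dtype=bool)

    def free_energy(self, states: np.ndarray, pH: float) -> float:
        """Total free energy of a protonation microstate (kcal/mol).

        Each protonated site contributes its transition free energy, so
        single-site flips reproduce the per-site equation exactly and the
        null model titrates along Henderson-Hasselbalch.
        """
        g = 0.0
        for site, protonated in zip(self.sites, states):
            if protonated:
                g += transition_free_energy(
                    pH, site.pKa_ref, site.elec_offset, 0.0, self.temperature
                )
        if self.coupling is not None:
            g += self.coupling(np.asarray(states, dtype=bool))
        return g

    def flip_dg(self, index: int, pH: float) -> float:
        states = self.states
        new = states.copy()
        new[index] = not new[index]
        return self.free_energy(new, pH) - self.free_energy(states, pH)


def mc_step(system: TitrationSystem, pH: float, rng: np.random.Generator) -> bool:
    """One Metropolis attempt: flip a uniformly chosen site.

    Accepts with probability min(1, exp(-dG / kB*T)); dG == 0 is always
    accepted.  Returns whether the proposal was accepted.
    """
    if not system.sites:
        raise ValueError("system has no titratable sites")
    index = int(rng.integers(len(system.sites)))
    dg = system.flip_dg(index, pH)
    kt = KB_KCAL * system.temperature
    if dg <= 0 or rng.random() < math.exp(-dg / kt):
        system.sites[index].protonated = not system.sites[index].protonated
        return True
    return False


@dataclasses.dataclass
class TitrationRun:
    temperature: float
    pH_grid: list[float]
    n_steps: int
    burn_in: int
    seed: int
    #: site id -> {pH -> protonated fraction}
    fractions: dict[str, dict[float, float]]
    n_samples: int

    def curve(self, site_id: str) -> tuple[np.ndarray, np.ndarray]:
        f = self.fractions[site_id]
        ph = np.array(sorted(f))
        return ph, np.array([f[p] for p in ph])


def run_titration(
    system: TitrationSystem,
    pH_grid: Sequence[float],
    n_steps: int,
    burn_in: int | None = None,
    seed: int = 0,
) -> TitrationRun:
    """Sample protonated fractions on a pH grid; bit-reproducible per seed.

    ``n_steps`` counts MC attempts per pH point.  ``burn_in`` defaults to
    10% of the steps; after it, the state is recorded once per sweep
    (one sweep = one attempt per site).  Each pH point restarts from the
    all-protonated state with an independently derived RNG stream, so
    grid points are independent.
    """
    if len(pH_grid) == 0:
        raise ValueError("pH grid is empty")
    if burn_in is None:
        burn_in = n_steps // 10
    if not n_steps > burn_in >= 0:
        raise ValueError("need n_steps > burn_in >= 0")
    n_sites = len(system.sites)
    if n_sites == 0:
        raise ValueError("system has no titratable sites")
    sweep = n_sites
    fractions: dict[str, dict[float, float]] = {s.id: {} for s in system.sites}
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(pH_grid))
    n_samples = 0
    for ph, stream in zip(pH_grid, streams):
        rng = np.random.default_rng(stream)
        for site in system.sites:
            site.protonated = True
        tally = np.zeros(n_sites)
        n_samples = 0
        for step in range(1, n_steps + 1):
            mc_step(system, ph, rng)
            if step > burn_in and step % sweep == 0:
                tally += system.states
                n_samples += 1
        if n_samples == 0:
            raise ValueError("no post-burn-in samples; increase n_steps")
        for site, frac in zip(system.sites, tally / n_samples):
            fractions[site.id][float(ph)] = float(frac)
    return TitrationRun(
        temperature=system.temperature,
        pH_grid=[float(p) for p in pH_grid],
        n_steps=n_steps,
        burn_in=burn_in,
        seed=seed,
        fractions=fractions,
        n_samples=n_samples,
    )


def henderson_hasselbalch(ph, pka: float, hill: float = 1.0):
    """Protonated fraction 1 / (1 + 10**(hill*(pH - pKa)))."""
    return 1.0 / (1.0 + 10.0 ** (hill * (np.asarray(ph, dtype=float) - pka)))


def estimate_pka(
    ph: Sequence[float], fraction: Sequence[float]
) -> tuple[float, float]:
    """(pKa, Hill coefficient) from a titration curve by Hill-form fit.

    The curve must bracket 0.5; otherwise the midpoint is unconstrained
    and an error is raised.
    """
    ph = np.asarray(ph, dtype=float)
    frac = np.asarray(fraction, dtype=float)
    if frac.min() >= 0.5 or frac.max() <= 0.5:
        raise ValueError("titration curve does not cross fraction 0.5")
    p0 = (float(ph[np.argmin(np.abs(frac - 0.5))]), 1.0)
    popt, _ = curve_fit(henderson_hasselbalch, ph, frac, p0=p0, maxfev=10000)
    return float(popt[0]), float(popt[1])
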