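"""Matched-background contact-strength probes.

On full-stack trajectories the first-peak PMF height of a contact class
mixes its well depth with the conformational background of its pairs: a
backbone-tethered turn pair has far less open-state volume than an
inter-molecular pair, which inflates its apparent strength irrespective
of the well.  To read the well-depth hierarchy itself back out of the
model, this module samples each contact class in an identical radial
background: a single pair interacting through the class's 12-10 well,
confined by one common weak harmonic tether, with the 3D radial Jacobian
(p(r) proportional to r^2) folded into the effective 1D potential.  The
first-peak strengths of the resulting PMFs then order exactly as the
class depths.

The quadrature profile is the analytic oracle; the Langevin route
exercises the same sampler and PMF machinery used on stack runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .amd import langevin_1d
from .analysis import PMFProfile, bond_strength, unweighted_pmf
from .dynamics import KB


def contact_potential(r, eps: float, r0: float):
    """12-10 native-contact well, kcal/mol."""
    u = r0 / np.asarray(r, dtype=float)
    return eps * (5.0 * u**12 - 6.0 * u**10)


def contact_gradient(r, eps: float, r0: float):
    r = np.asarray(r, dtype=float)
    u = r0 / r
    return 60.0 * eps * (u**10 - u**12) / r


@dataclass(frozen=True)
class ProbeResult:
    pmf: PMFProfile
    strength: float          # kcal/mol, first-peak height
    minimum: float           # A, location of the PMF minimum


def _effective(eps: float, r0: float, k_tether: float,
               temperature: float):
    kt = KB * temperature

    def u_eff(r):
        return (contact_potential(r, eps, r0) + k_tether * r * r
                - 2.0 * kt * np.log(r))

    def g_eff(r):
        return (contact_gradient(r, eps, r0) + 2.0 * k_tether * r
                - 2.0 * kt / r)

    return u_eff, g_eff


def quadrature_strength(eps: float, r0: float,
                        k_tether: float = 0.003,
                        temperature: float = 300.0,
                        bin_size: float = 0.2) -> ProbeResult:
    """Analytic (quadrature) radial PMF and first-peak strength."""
    u_eff, _ = _effective(eps, r0, k_tether, temperature)
    r_max = max(4.0 * r0, 30.0)
    edges = np.arange(0.5 * r0, r_max + bin_size, bin_size)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kt = KB * temperature
    # bin-integrated Boltzmann weights on a fine sub-grid
    fine = np.linspace(edges[0], edges[-1], len(centers) * 20 + 1)
    w = np.exp(-(u_eff(fine) - u_eff(r0)) / kt)
    idx = np.clip(((fine - edges[0]) / bin_size).astype(int), 0,
                  len(centers) - 1)
    counts = np.bincount(idx, weights=w, minlength=len(centers))
    f = -kt * np.log(np.maximum(counts, 1e-300))
    f -= f.min()
    pmf = PMFProfile(bin_edges=edges, f=f, counts=counts,
                     bin_size=bin_size, temperature=temperature)
    return ProbeResult(pmf=pmf, strength=bond_strength(pmf),
                       minimum=float(centers[np.argmin(f)]))


def sampled_strength(eps: float, r0: float,
                     k_tether: float = 0.003,
                     temperature: float = 300.0,
                     bin_size: float = 0.2,
                     n_steps: int = 400_000,
                     seed: int | None = None) -> ProbeResult:
    """Langevin-sampled radial PMF and first-peak strength."""
    u_eff, g_eff = _effective(eps, r0, k_tether, temperature)
    xs, _ = langevin_1d(u_eff, g_eff, x0=r0, n_steps=n_steps, dt=0.02,
                        friction=2.0, temperature=temperature, mass=50.0,
                        seed=seed, save_interval=5)
    pmf = unweighted_pmf(xs, bin_size, temperature)
    return ProbeResult(
        pmf=pmf, strength=bond_strength(pmf),
        minimum=float(pmf.bin_centers[np.nanargmin(pmf.f)]))
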