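#!/usr/bin/env python
"""Boost algebra and reweighting demonstrated on a 1D double well.

Shows, with numbers, the three claims the accelerated-MD scheme rests
on: (1) boosting preserves minima and never raises energies above the
threshold; (2) it multiplies barrier-crossing rates; (3) exponential
reweighting by exp(dV / kB T) recovers exact Boltzmann populations that
the raw boosted ensemble distorts.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad

import betaroll as br
from betaroll.amd import langevin_1d
from betaroll.dynamics import KB

OUT = Path("results/06_boost")
OUT.mkdir(parents=True, exist_ok=True)

H = 3.0          # kcal/mol barrier of the double well
TILT = 0.5       # kcal/mol asymmetry


def u(x):
    return H * (x * x - 1.0) ** 2 + TILT * x


def g(x):
    return 4.0 * H * x * (x * x - 1.0) + TILT


# (1) boost algebra on a grid
vs = np.linspace(-2.0, 8.0, 101)
dv = br.boost_delta(vs, 3.0, 1.0)
fac = br.boost_force_factor(vs, 3.0, 1.0)
algebra = pd.DataFrame({"v": vs, "dv": dv, "v_star": vs + dv,
                        "force_factor": fac})
algebra.to_csv(OUT / "boost_algebra.csv", index=False)
assert (dv >= 0).all() and ((vs + dv)[vs < 3.0] <= 3.0 + 1e-12).all()

# (2) + (3) sampling
common = dict(x0=-1.0, n_steps=400_000, dt=0.02, friction=1.0,
              temperature=300.0, mass=50.0, seed=5)
xs_u, _ = langevin_1d(u, g, **common)
xs_b, dv_b = langevin_1d(u, g, e_threshold=H, alpha=1.0, **common)


def crossings(x):
    s = np.sign(x)
    s = s[s != 0]
    return int((np.diff(s) != 0).sum())


kt = KB * 300.0
w = np.exp((dv_b - dv_b.max()) / kt)
z = quad(lambda x: np.exp(-u(x) / kt), -3, 3)[0]
p_exact = quad(lambda x: np.exp(-u(x) / kt), 0, 3)[0] / z
table = pd.DataFrame([{
    "crossings_unboosted": crossings(xs_u),
    "crossings_boosted": crossings(xs_b),
    "p_right_exact": p_exact,
    "p_right_unboosted": (xs_u > 0).mean(),
    "p_right_boosted_raw": (xs_b > 0).mean(),
    "p_right_boosted_reweighted": float(w[xs_b > 0].sum() / w.sum()),
}])
table.to_csv(OUT / "double_well.csv", index=False)
print(table.round(4).to_string(index=False))
print("\nthe boost multiplies barrier crossings; the raw boosted "
      "population is biased toward the shallow basin and the "
      "exp(dV/kBT) reweighting pulls it back onto the exact value")
print(f"wrote {OUT}/boost_algebra.csv, double_well.csv")
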