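"""Shared fixtures and the independent trajectory oracle.

The oracle evaluates the integrating-factor solution

    Dep(t) = e^{-rt} dep0 + r * integral_0^t e^{-r(t-s)} (1 - I(s)) ds

by adaptive quadrature (scipy.integrate.quad), with the inhibition signal
I(s) built directly from the event list.  It shares no code with the
package's trajectory integrators.
"""

import numpy as np
import pytest
from scipy.integrate import quad

from sessiondose.model import ServiceType, SessionEvent, StructuralParameters


@pytest.fixture
def params():
    return StructuralParameters(k_out_coaching=0.05, k_out_therapy=0.1,
                                k_out_psychiatry=0.2, s50=1.0, r=0.05)


def oracle_trajectory(events, params, times, dep0=1.0):
    """Quadrature oracle for the severity trajectory (independent route)."""
    kv = {ServiceType.COACHING: params.k_out_coaching,
          ServiceType.THERAPY: params.k_out_therapy,
          ServiceType.PSYCHIATRY: params.k_out_psychiatry}

    def inhibition_at(s):
        trt = sum(np.exp(-kv[e.service] * (s - e.time))
                  for e in events if e.time <= s)
        return trt / (trt + params.s50)

    breakpoints = sorted({e.time for e in events})
    out = []
    for t in np.atleast_1d(np.asarray(times, dtype=float)):
        if t == 0:
            out.append(dep0)
            continue
        pts = [b for b in breakpoints if 0 < b < t] or None
        integral, _ = quad(lambda s: np.exp(-params.r * (t - s))
                           * (1.0 - inhibition_at(s)),
                           0.0, t, points=pts, limit=500,
                           epsabs=1e-12, epsrel=1e-12)
        out.append(np.exp(-params.r * t) * dep0 + params.r * integral)
    return np.asarray(out)


def random_structural(rng, spread=0.5):
    """A random positive parameter set around the package defaults."""
    base = np.log([0.05, 0.1, 0.2, 1.0, 0.05])
    return StructuralParameters.from_array(
        np.exp(base + spread * rng.standard_normal(5)))


def random_events(rng, n_max=15, t_max=300.0):
    services = list(ServiceType)
    n = int(rng.integers(0, n_max + 1))
    times = np.sort(rng.uniform(0.0, t_max, n))
    return [SessionEvent(float(t), services[int(rng.integers(0, 3))])
            for t in times]
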