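"""Hierarchical nonlinear mixed-effects estimation.

The population layer places independent log-normal distributions on the five
structural parameters: for individual i and parameter p,

    log theta_ip = log theta_pop,p + eta_ip,   eta_ip ~ N(0, omega_p^2),

with a single additive Gaussian residual on the severity scale,
y_ij = Dep(t_ij; theta_i) + eps, eps ~ N(0, sigma^2).  Population fitting
uses stochastic-approximation EM: a Metropolis-Hastings E-step samples each
patient's log-parameters given the current population, and the M-step has
closed-form updates of the population mean, the diagonal between-subject
variances and the residual variance from stochastic-approximation-smoothed
sufficient statistics.  Empirical-Bayes (MAP) individual estimates come from
multi-start local optimisation of the per-patient posterior.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import _kernels
from ._kernels import dep_profile, gl_nodes, saem_estep
from .model import (PatientRecord, StructuralParameters, ValidationError,
                    SolverError)

__all__ = [
    "PopulationParameters",
    "IndividualParameters",
    "PatientFit",
    "FitResult",
    "SaemConfig",
    "SessionDoseModel",
    "individual_objective",
    "empirical_bayes",
    "fit_population",
    "DEFAULT_TYPICAL",
]

#: Default initial typical values: elimination rates ordered with the
#: clinical triaging hierarchy (coaching < therapy < psychiatry).  These are
#: engineering starting points, not estimates from any dataset.
DEFAULT_TYPICAL = StructuralParameters(
    k_out_coaching=0.05, k_out_therapy=0.1, k_out_psychiatry=0.2,
    s50=1.0, r=0.05)

_N_PAR = 5
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PopulationParameters:
    """Typical values, between-subject SDs (log scale) and residual SD."""

    typical: StructuralParameters
    omega: np.ndarray  # 5 non-negative log-scale SDs, diagonal model
    sigma: float       # additive residual SD on the severity scale

    def __post_init__(self):
        om = np.asarray(self.omega, dtype=np.float64)
        if om.shape != (_N_PAR,) or np.any(om < 0) or np.any(~np.isfinite(om)):
            raise ValidationError("omega must be 5 finite non-negative reals")
        object.__setattr__(self, "omega", om)
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValidationError(f"sigma must be finite and > 0, got {self.sigma}")

    def to_dict(self) -> dict:
        return {"typical": self.typical.to_dict(),
                "omega": {n: float(o) for n, o in
                          zip(StructuralParameters.PARAM_NAMES, self.omega)},
                "sigma": float(self.sigma)}

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParameters":
        return cls(typical=StructuralParameters.from_dict(d["typical"]),
                   omega=np.array([d["omega"][n] for n in
                                   StructuralParameters.PARAM_NAMES]),
                   sigma=float(d["sigma"]))


@dataclass(frozen=True)
class IndividualParameters:
    """Log-scale deviations eta and the realized structural constants.

    realized_p = typical_p * exp(eta_p); eta = 0 reproduces the typical
    individual.
    """

    eta: np.ndarray
    realized: StructuralParameters

    def __post_init__(self):
        e = np.asarray(self.eta, dtype=np.float64)
        if e.shape != (_N_PAR,) or np.any(~np.isfinite(e)):
            raise ValidationError("eta must be 5 finite reals")
        object.__setattr__(self, "eta", e)

    @classmethod
    def from_eta(cls, eta, typical: StructuralParameters) -> "IndividualParameters":
        eta = np.asarray(eta, dtype=np.float64)
        realized = StructuralParameters.from_array(typical.as_array() * np.exp(eta))
        return cls(eta=eta, realized=realized)


@dataclass(frozen=True)
class PatientFit:
    """Per-patient empirical-Bayes output aligned 1:1 with observations."""

    patient_id: str
    individual: IndividualParameters
    obs_times: np.ndarray
    observed: np.ndarray
    ipred: np.ndarray   # predictions at the individual's parameters
    ppred: np.ndarray   # predictions at the population typical parameters
    residuals: np.ndarray  # observed - ipred
    eligible: bool


@dataclass
class FitResult:
    """Population estimates, per-patient fits and the SAEM iteration trace."""

    population: PopulationParameters
    patients: list[PatientFit]
    trace: dict[str, np.ndarray]
    config: dict
    seed: int

    def patient(self, patient_id: str) -> PatientFit:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(f"no patient {patient_id!r} in fit result")


@dataclass
class SaemConfig:
    """SAEM schedule: exploration (step size 1) then polynomial-decay
    smoothing (step size m^-a)."""

    n_burnin: int = 100
    n_smooth: int = 300
    n_chains: int = 3
    n_transitions: int = 5
    smooth_exponent: float = 0.6  # step size m^(-a) in the smoothing phase
    initial_typical: StructuralParameters = field(default_factory=lambda: DEFAULT_TYPICAL)
    initial_omega: float = 0.5
    initial_sigma: float = 0.2
    omega_floor: float = 0.01
    sigma_floor: float = 1e-3
    annealing: float = 0.97  # exploration-phase lower bound on variance shrinkage

    def to_dict(self) -> dict:
        return {"n_burnin": self.n_burnin, "n_smooth": self.n_smooth,
                "n_chains": self.n_chains, "n_transitions": self.n_transitions,
                "smooth_exponent": self.smooth_exponent,
                "initial_typical": self.initial_typical.to_dict(),
                "initial_omega": self.initial_omega,
                "initial_sigma": self.initial_sigma,
                "omega_floor": self.omega_floor,
                "sigma_floor": self.sigma_floor,
                "annealing": self.annealing}

    @classmethod
    def from_dict(cls, d: dict) -> "SaemConfig":
        d = dict(d)
        if "initial_typical" in d:
            d["initial_typical"] = StructuralParameters.from_dict(d["initial_typical"])
        return cls(**d)


def _record_arrays(record: PatientRecord):
    obs_t = np.array([o.time for o in record.observations], dtype=np.float64)
    obs_y = np.array([o.severity for o in record.observations], dtype=np.float64)
    ev_t, ev_s = record.event_arrays()
    order = np.argsort(ev_t, kind="stable")
    return obs_t, obs_y, ev_t[order], ev_s[order]


def _predict(obs_t, ev_t, ev_s, theta: np.ndarray) -> np.ndarray:
    return dep_profile(obs_t, ev_t, ev_s, theta[:3], theta[3], theta[4])


def patient_key(patient_id: str) -> int:
    """Stable 32-bit key for per-patient RNG streams (order-independent)."""
    return zlib.crc32(str(patient_id).encode("utf-8")) & 0x7FFFFFFF


def individual_objective(record: PatientRecord, indiv: IndividualParameters,
                         pop: PopulationParameters) -> float:
    """-2 * [data log-likelihood + random-effect log-prior] (MAP objective).

    Prior terms are dropped for parameters with omega_p = 0, where eta_p is
    required to be 0 (the parameter is fixed at its typical value).
    """
    if not (np.isfinite(pop.sigma) and pop.sigma > 0):
        raise ValidationError(f"sigma must be > 0, got {pop.sigma}")
    for p, (om, et) in enumerate(zip(pop.omega, indiv.eta)):
        if om == 0 and et != 0:
            raise ValidationError(
                f"eta[{p}] must be 0 when omega[{p}] = 0 (parameter fixed)")
    obs_t, obs_y, ev_t, ev_s = _record_arrays(record)
    pred = _predict(obs_t, ev_t, ev_s, indiv.realized.as_array())
    res = obs_y - pred
    ll = float(np.sum(-0.5 * (res / pop.sigma) ** 2
                      - math.log(pop.sigma) - 0.5 * _LOG_2PI))
    for om, et in zip(pop.omega, indiv.eta):
        if om > 0:
            ll += -0.5 * (et / om) ** 2 - math.log(om) - 0.5 * _LOG_2PI
    return -2.0 * ll


def empirical_bayes(record: PatientRecord, pop: PopulationParameters,
                    seed: int = 0, n_starts: int = 3) -> IndividualParameters:
    """MAP estimate of the individual deviations eta (multi-start L-BFGS-B).

    Parameters with omega_p = 0 are held at eta_p = 0.  Starts: the prior
    mode eta = 0 plus ``n_starts - 1`` seeded prior draws; deterministic for
    a fixed seed.
    """
    obs_t, obs_y, ev_t, ev_s = _record_arrays(record)
    free = np.flatnonzero(pop.omega > 0)
    mu = np.log(pop.typical.as_array())
    if free.size == 0:
        return IndividualParameters.from_eta(np.zeros(_N_PAR), pop.typical)

    def objective(eta_free):
        eta = np.zeros(_N_PAR)
        eta[free] = eta_free
        theta = np.exp(mu + eta)
        pred = _predict(obs_t, ev_t, ev_s, theta)
        nll = 0.5 * float(np.sum(((obs_y - pred) / pop.sigma) ** 2))
        nll += 0.5 * float(np.sum((eta[free] / pop.omega[free]) ** 2))
        return nll

    rng = np.random.default_rng([seed, patient_key(record.id)])
    starts = [np.zeros(free.size)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.standard_normal(free.size) * pop.omega[free])

    best = None
    failures = []
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B",
                       bounds=[(-6 * max(om, 0.5), 6 * max(om, 0.5))
                               for om in pop.omega[free]])
        if res.success or np.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
        else:
            failures.append(res.message)
    if best is None:
        raise SolverError(
            f"empirical Bayes optimisation failed for patient {record.id!r}: "
            f"{failures}")
    eta = np.zeros(_N_PAR)
    eta[free] = best.x
    # never return a start worse than the prior mode
    if objective(eta[free]) > objective(np.zeros(free.size)) + 1e-12:
        eta = np.zeros(_N_PAR)
    return IndividualParameters.from_eta(eta, pop.typical)


class SessionDoseModel(BaseEstimator):
    """Population session-dosing model with SAEM fitting.

    A scikit-learn-style estimator: ``fit`` takes a cohort (sequence of
    :class:`PatientRecord`) and produces the fitted population layer plus
    per-patient empirical-Bayes estimates and predictions.

    Parameters
    ----------
    n_burnin, n_smooth
        SAEM exploration iterations (step size 1) and smoothing iterations
        (step size 1/m).
    n_chains, n_transitions
        Metropolis-Hastings chains per patient and transitions per E-step.
    initial_typical, initial_omega, initial_sigma
        Starting values of the population layer.
    seed
        Root seed; fans out to per-patient streams keyed by patient id, so
        estimates do not depend on cohort ordering.

    Attributes
    ----------
    population_ : PopulationParameters
    individuals_ : dict mapping patient id to IndividualParameters
    result_ : FitResult
    trace_ : dict of per-iteration population parameter arrays
    """

    def __init__(self, n_burnin: int = 100, n_smooth: int = 300,
                 n_chains: int = 3, n_transitions: int = 5,
                 smooth_exponent: float = 0.6,
                 initial_typical: StructuralParameters | None = None,
                 initial_omega: float = 0.5, initial_sigma: float = 0.2,
                 omega_floor: float = 0.01, sigma_floor: float = 1e-3,
                 annealing: float = 0.97, seed: int = 0):
        self.n_burnin = n_burnin
        self.n_smooth = n_smooth
        self.n_chains = n_chains
        self.n_transitions = n_transitions
        self.smooth_exponent = smooth_exponent
        self.initial_typical = initial_typical
        self.initial_omega = initial_omega
        self.initial_sigma = initial_sigma
        self.omega_floor = omega_floor
        self.sigma_floor = sigma_floor
        self.annealing = annealing
        self.seed = seed

    def _config(self) -> SaemConfig:
        return SaemConfig(
            n_burnin=self.n_burnin, n_smooth=self.n_smooth,
            n_chains=self.n_chains, n_transitions=self.n_transitions,
            smooth_exponent=self.smooth_exponent,
            initial_typical=self.initial_typical or DEFAULT_TYPICAL,
            initial_omega=self.initial_omega, initial_sigma=self.initial_sigma,
            omega_floor=self.omega_floor, sigma_floor=self.sigma_floor,
            annealing=self.annealing)

    def fit(self, X, y=None):
        """Fit the population model to a cohort of patient records."""
        cohort = list(X)
        eligible = [r for r in cohort if isinstance(r, PatientRecord)
                    and r.is_inclusion_eligible]
        if len(eligible) < 2:
            raise ValidationError(
                f"need at least 2 inclusion-eligible patients, got {len(eligible)}")
        # id-sorted processing makes results independent of input order
        eligible = sorted(eligible, key=lambda r: r.id)
        cfg = self._config()
        seed = int(self.seed) % (2 ** 31)

        obs_t, obs_y, obs_off, ev_t, ev_s, ev_off, keys = _pack(eligible)
        glx, glw = gl_nodes()

        mu = np.log(cfg.initial_typical.as_array())
        omega = np.full(_N_PAR, float(cfg.initial_omega))
        sigma = float(cfg.initial_sigma)

        n = len(eligible)
        n_obs_total = obs_t.size
        rng = np.random.default_rng([seed, 9173])
        phi = mu[None, None, :] + omega[None, None, :] * rng.standard_normal(
            (n, cfg.n_chains, _N_PAR))
        rss = np.empty((n, cfg.n_chains))
        for i in range(n):
            for c in range(cfg.n_chains):
                _, rss[i, c] = _kernels._data_loglik(
                    np.ascontiguousarray(phi[i, c]),
                    obs_t[obs_off[i]:obs_off[i + 1]],
                    obs_y[obs_off[i]:obs_off[i + 1]],
                    ev_t[ev_off[i]:ev_off[i + 1]],
                    ev_s[ev_off[i]:ev_off[i + 1]], sigma, glx, glw)

        s_phi = np.zeros((n, _N_PAR))
        s_phi2 = np.zeros((n, _N_PAR))
        s_rss = 0.0
        mean_phi = np.empty((n, _N_PAR))
        mean_phi2 = np.empty((n, _N_PAR))
        mean_rss = np.empty(n)
        # scale 0: joint random walk; scales 1..5: per-component walks
        rw_scale = np.array([0.4, 1.0, 1.0, 1.0, 1.0, 1.0])

        n_iter = cfg.n_burnin + cfg.n_smooth
        trace = {"typical": np.empty((n_iter, _N_PAR)),
                 "omega": np.empty((n_iter, _N_PAR)),
                 "sigma": np.empty(n_iter)}

        for it in range(n_iter):
            acc = np.zeros(1 + _N_PAR, dtype=np.int64)
            prop = np.zeros(1 + _N_PAR, dtype=np.int64)
            saem_estep(phi, rss, obs_t, obs_y, obs_off, ev_t, ev_s, ev_off,
                       mu, omega, sigma, cfg.n_transitions, rw_scale,
                       it % _N_PAR, keys, it, seed, glx, glw,
                       mean_phi, mean_phi2, mean_rss, acc, prop)
            # adapt random-walk scales toward ~35% acceptance (burn-in only)
            if it < cfg.n_burnin:
                for k in range(1 + _N_PAR):
                    rate = acc[k] / max(prop[k], 1)
                    rw_scale[k] *= math.exp(0.3 * (rate - 0.35))
                rw_scale = np.clip(rw_scale, 0.01, 10.0)

            gamma = (1.0 if it < cfg.n_burnin
                     else (it - cfg.n_burnin + 1) ** (-cfg.smooth_exponent))
            s_phi += gamma * (mean_phi - s_phi)
            s_phi2 += gamma * (mean_phi2 - s_phi2)
            s_rss += gamma * (float(np.sum(mean_rss)) - s_rss)

            mu = s_phi.mean(axis=0)
            var = np.maximum(s_phi2.mean(axis=0) - 2 * mu * s_phi.mean(axis=0)
                             + mu ** 2, 0.0)
            # equivalently mean(s_phi2) - mu^2; written out for clarity
            sigma2 = s_rss / n_obs_total
            if it < cfg.n_burnin:
                # simulated-annealing guard against premature variance collapse
                var = np.maximum(var, cfg.annealing * omega ** 2)
                sigma2 = max(sigma2, cfg.annealing * sigma ** 2)
            omega = np.sqrt(np.maximum(var, cfg.omega_floor ** 2))
            sigma = max(math.sqrt(sigma2), cfg.sigma_floor)

            if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(omega))
                    and np.isfinite(sigma)):
                raise SolverError(
                    f"SAEM diverged at iteration {it}: mu={mu}, omega={omega}, "
                    f"sigma={sigma}")
            trace["typical"][it] = np.exp(mu)
            trace["omega"][it] = omega
            trace["sigma"][it] = sigma

        typical = StructuralParameters.from_array(np.exp(mu))
        self.population_ = PopulationParameters(typical=typical, omega=omega,
                                                sigma=sigma)
        self.trace_ = trace

        patients = []
        self.individuals_ = {}
        ppred_theta = typical.as_array()
        for rec in eligible:
            indiv = empirical_bayes(rec, self.population_, seed=seed)
            ot, oy, et, es = _record_arrays(rec)
            ipred = _predict(ot, et, es, indiv.realized.as_array())
            ppred = _predict(ot, et, es, ppred_theta)
            patients.append(PatientFit(
                patient_id=rec.id, individual=indiv, obs_times=ot, observed=oy,
                ipred=ipred, ppred=ppred, residuals=oy - ipred, eligible=True))
            self.individuals_[rec.id] = indiv
        self.result_ = FitResult(population=self.population_, patients=patients,
                                 trace=trace, config=cfg.to_dict(), seed=seed)
        return self

    def predict(self, record: PatientRecord, times=None) -> np.ndarray:
        """Individual-level predicted severities for a fitted patient."""
        if not hasattr(self, "population_"):
            raise ValidationError("model is not fitted")
        indiv = self.individuals_.get(record.id)
        theta = (indiv.realized if indiv is not None
                 else self.population_.typical).as_array()
        if times is None:
            times = [o.time for o in record.observations]
        ot = np.asarray(times, dtype=np.float64)
        _, _, et, es = _record_arrays(record)
        return _predict(ot, et, es, theta)


def _pack(cohort: list[PatientRecord]):
    """Flatten a cohort into offset-indexed arrays for the compiled E-step."""
    obs_t, obs_y, ev_t, ev_s = [], [], [], []
    obs_off = [0]
    ev_off = [0]
    keys = []
    for rec in cohort:
        ot, oy, et, es = _record_arrays(rec)
        obs_t.append(ot)
        obs_y.append(oy)
        ev_t.append(et)
        ev_s.append(es)
        obs_off.append(obs_off[-1] + ot.size)
        ev_off.append(ev_off[-1] + et.size)
        keys.append(patient_key(rec.id))
    return (np.concatenate(obs_t), np.concatenate(obs_y),
            np.array(obs_off, dtype=np.int64),
            np.concatenate(ev_t) if ev_t else np.empty(0),
            np.concatenate(ev_s).astype(np.int64) if ev_s else np.empty(0, np.int64),
            np.array(ev_off, dtype=np.int64),
            np.array(keys, dtype=np.int64))


def fit_population(cohort, config: SaemConfig | None = None,
                   seed: int = 0) -> FitResult:
    """Fit the hierarchical model to a cohort; thin wrapper over the estimator."""
    cfg = config or SaemConfig()
    est = SessionDoseModel(
        n_burnin=cfg.n_burnin, n_smooth=cfg.n_smooth, n_chains=cfg.n_chains,
        n_transitions=cfg.n_transitions, smooth_exponent=cfg.smooth_exponent,
        initial_typical=cfg.initial_typical,
        initial_omega=cfg.initial_omega, initial_sigma=cfg.initial_sigma,
        omega_floor=cfg.omega_floor, sigma_floor=cfg.sigma_floor,
        annealing=cfg.annealing, seed=seed)
    est.fit(cohort)
    return est.result_
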