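"""Importance-sampling Bayesian estimation of fold parameters from width waveforms.

Posterior ~ likelihood x prior (Bayes' rule with the evidence dropped).  With
the prior as proposal, importance weights are proportional to the likelihood,
so w_i = exp(log L_i) normalized over the ensemble; the weighted set is
multinomially resampled and per-parameter mean, standard deviation and
relative uncertainty (std as % of the estimate) summarize the posterior.

The estimated parameters are the three deep-layer moduli (body, SLP,
ligament), subglottal pressure, density, Kelvin-Voigt viscosity and medial
compression; the Bernoulli separation ratio r_sep is added when the flow
model treats it as unknown.  Epithelium stiffness, Poisson ratio and
supraglottal pressure stay fixed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields, replace
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .coupled_sim import ObservationSeries, SimulationConfig, run_forward
from .errors import (AlignmentError, ConfigurationError, DegeneratePosteriorError,
                     SimulationBlowupError, ShootingError)
from .geometry import LayeredMesh
from .solid_fem import MaterialParams

_POSITIVE = ("E_body", "E_slp", "E_lig", "p_sub", "rho_b", "m")


@dataclass
class ParameterVector:
    """One point in the estimated-parameter space (kPa, kg/m³, Pa·s, mm)."""

    E_body: float = 11.8
    E_slp: float = 0.6
    E_lig: float = 2.0
    p_sub: float = 1.092
    rho_b: float = 1070.0
    eta: float = 0.01
    m: float = 0.4
    r_sep: float | None = None

    def __post_init__(self):
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.eta < 0:
            raise ConfigurationError("eta must be non-negative")
        if self.r_sep is not None and self.r_sep < 1.0:
            raise ConfigurationError("r_sep must be >= 1 when present")

    @classmethod
    def names(cls, with_r_sep: bool = False) -> list[str]:
        base = [f.name for f in dc_fields(cls) if f.name != "r_sep"]
        return base + (["r_sep"] if with_r_sep else [])

    def to_dict(self) -> dict:
        d = {n: getattr(self, n) for n in self.names()}
        if self.r_sep is not None:
            d["r_sep"] = self.r_sep
        return d

    @classmethod
    def from_mapping(cls, d: Mapping) -> "ParameterVector":
        return cls(**{k: d[k] for k in list(cls.names(True)) if k in d})


@dataclass
class PriorSpec:
    """Independent per-parameter prior descriptors.

    Each entry maps a parameter name to ``("uniform", lo, hi)``,
    ``("normal", mu, sd)`` or ``("delta", value)``.
    """

    dists: dict

    def __post_init__(self):
        for name, desc in self.dists.items():
            fam = desc[0]
            if fam == "uniform":
                _, lo, hi = desc
                if not lo < hi:
                    raise ConfigurationError(f"empty uniform support for {name}")
            elif fam == "normal":
                _, _, sd = desc
                if sd <= 0:
                    raise ConfigurationError(f"non-positive normal sd for {name}")
            elif fam == "delta":
                pass
            else:
                raise ConfigurationError(f"unknown prior family {fam!r} for {name}")

    @property
    def names(self) -> list[str]:
        return list(self.dists)

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        cols = {}
        for name, desc in self.dists.items():
            fam = desc[0]
            if fam == "uniform":
                cols[name] = rng.uniform(desc[1], desc[2], size=n)
            elif fam == "normal":
                cols[name] = rng.normal(desc[1], desc[2], size=n)
            else:
                cols[name] = np.full(n, float(desc[1]))
        return pd.DataFrame(cols)


def default_priors(truth: ParameterVector | Mapping | None = None,
                   with_r_sep: bool = False, width: float = 0.5) -> PriorSpec:
    """Independent uniform priors around nominal values.

    Moduli within ±``width`` (fractional) of nominal, subglottal pressure
    within ±20%, density in [900, 1200] kg/m³, viscosity in [0, 10] Pa·s,
    medial compression in [0.2, 0.6] mm and, if requested, r_sep in
    [1.0, 1.6] (the swept range).
    """
    t = truth if isinstance(truth, ParameterVector) else ParameterVector(
        **dict(truth or {}))
    d = {
        "E_body": ("uniform", t.E_body * (1 - width), t.E_body * (1 + width)),
        "E_slp": ("uniform", t.E_slp * (1 - width), t.E_slp * (1 + width)),
        "E_lig": ("uniform", t.E_lig * (1 - width), t.E_lig * (1 + width)),
        "p_sub": ("uniform", t.p_sub * 0.8, t.p_sub * 1.2),
        "rho_b": ("uniform", 900.0, 1200.0),
        "eta": ("uniform", 0.0, 10.0),
        "m": ("uniform", 0.2, 0.6),
    }
    if with_r_sep:
        d["r_sep"] = ("uniform", 1.0, 1.6)
    return PriorSpec(d)


def sample_prior(prior: PriorSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` independent prior samples, reproducibly."""
    if n < 1:
        raise ConfigurationError("need n >= 1 samples")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return prior.sample(n, rng)


def register_lag(sim_w: np.ndarray, obs_w: np.ndarray) -> int:
    """Best circular lag (samples) aligning ``sim_w`` to ``obs_w``.

    Maximizes the circular cross-correlation of the mean-removed series;
    both waveforms are near-periodic so a cyclic shift registers the phase.
    """
    a = obs_w - obs_w.mean()
    b = sim_w - sim_w.mean()
    if not (np.any(a) and np.any(b)):
        return 0
    corr = np.fft.irfft(np.fft.rfft(a) * np.conj(np.fft.rfft(b)), n=a.size)
    return int(np.argmax(corr))


def log_likelihood(sim: ObservationSeries, obs: ObservationSeries,
                   sigma_area: float = 1.0, register: bool = True) -> float:
    """Gaussian log-likelihood of ``obs`` given the simulated waveform.

    The area-noise standard deviation ``sigma_area`` (mm²) converts to width
    units through the anterior-posterior depth; residuals are evaluated on
    the observation grid after circular cross-correlation registration
    (additive constants are dropped - they cancel in normalized weights).
    """
    if obs.t.size < 1:
        raise AlignmentError("empty observation")
    if sim.t.size < obs.t.size:
        raise AlignmentError("simulated series shorter than the observation")
    if obs.t.size > 1 and not math.isclose(sim.dt, obs.dt, rel_tol=1e-8):
        raise AlignmentError(f"grid mismatch: sim dt {sim.dt} vs obs dt {obs.dt}")
    w_sim = sim.width[-obs.t.size:]
    w_obs = obs.width
    if register and obs.t.size > 1:
        lag = register_lag(w_sim, w_obs)
        w_sim = np.roll(w_sim, lag)
    depth = obs.depth if obs.depth > 0 else 1.0
    sigma_w = sigma_area / depth
    r = (w_obs - w_sim) / sigma_w
    return float(-0.5 * np.dot(r, r))


@dataclass
class PosteriorEnsemble:
    """Prior samples, importance weights, resampled set and summaries."""

    samples: pd.DataFrame
    log_weights: np.ndarray
    weights: np.ndarray
    resample_idx: np.ndarray
    mean: pd.Series
    std: pd.Series
    rel_uncertainty_pct: pd.Series
    n_eff: float
    n_failures: int
    meta: dict = field(default_factory=dict)

    @property
    def resampled(self) -> pd.DataFrame:
        return self.samples.iloc[self.resample_idx].reset_index(drop=True)


def importance_estimate(prior: PriorSpec, obs: ObservationSeries,
                        forward: Callable[[dict], ObservationSeries],
                        n: int, seed: int, sigma_area: float = 1.0,
                        register: bool = True,
                        progress: Callable[[int, int], None] | None = None,
                        ) -> PosteriorEnsemble:
    """Prior-as-proposal importance sampling of the posterior.

    ``forward`` maps a parameter dict to a simulated ObservationSeries;
    samples whose forward run fails (blow-up, shooting failure) get zero
    weight and are counted in ``n_failures``.  Weights are invariant to any
    constant shift of the log-likelihoods; resampling uses a seed stream
    decoupled from the prior draws.
    """
    ss = np.random.SeedSequence(seed)
    rng_sample, rng_resample = [np.random.default_rng(c) for c in ss.spawn(2)]
    samples = prior.sample(n, rng_sample)
    loglik = np.full(n, -np.inf)
    failures = 0
    for i in range(n):
        params = samples.iloc[i].to_dict()
        try:
            sim = forward(params)
            loglik[i] = log_likelihood(sim, obs, sigma_area, register=register)
        except (SimulationBlowupError, ShootingError, AlignmentError):
            failures += 1
        if progress is not None:
            progress(i + 1, n)
    finite = np.isfinite(loglik)
    if not np.any(finite):
        raise DegeneratePosteriorError(
            "all importance weights are zero; widen the priors or increase sigma")
    shifted = loglik - loglik[finite].max()
    w = np.where(finite, np.exp(shifted), 0.0)
    total = w.sum()
    if total <= 0:
        raise DegeneratePosteriorError("importance weights underflowed to zero")
    w = w / total
    n_eff = float(1.0 / np.sum(w ** 2))
    idx = rng_resample.choice(n, size=n, replace=True, p=w)

    mean = pd.Series({c: float(np.sum(w * samples[c].to_numpy()))
                      for c in samples.columns})
    std = pd.Series({c: float(np.sqrt(np.sum(
        w * (samples[c].to_numpy() - mean[c]) ** 2))) for c in samples.columns})
    rel = 100.0 * std / mean.abs().replace(0.0, np.nan)
    return PosteriorEnsemble(
        samples=samples, log_weights=loglik, weights=w, resample_idx=idx,
        mean=mean, std=std, rel_uncertainty_pct=rel, n_eff=n_eff,
        n_failures=failures,
        meta={"n": n, "seed": seed, "sigma_area": sigma_area})


@dataclass
class FlowPermutation:
    """One fluid-model setting of the study: Bernoulli with fixed r_sep,
    Bernoulli with estimated r_sep, or the 1D viscous model."""

    kind: str                       # bernoulli_fixed | bernoulli_estimated | viscous
    r_sep: float | None = None

    def __post_init__(self):
        if self.kind == "bernoulli_fixed" and self.r_sep is None:
            raise ConfigurationError("bernoulli_fixed needs a prescribed r_sep")

    @property
    def label(self) -> str:
        if self.kind == "bernoulli_fixed":
            return f"bernoulli r_sep={self.r_sep:g}"
        return {"bernoulli_estimated": "bernoulli r_sep estimated",
                "viscous": "viscous"}[self.kind]


def bernoulli_sweep(start: float = 1.0, stop: float = 1.6, step: float = 0.1
                    ) -> list[FlowPermutation]:
    """Fixed-separation permutations r_sep = start, start+step, ..., stop."""
    n = int(round((stop - start) / step)) + 1
    return [FlowPermutation("bernoulli_fixed", round(start + i * step, 10))
            for i in range(n)]


def make_forward(mesh: LayeredMesh, config: SimulationConfig,
                 fixed: MaterialParams | None = None
                 ) -> Callable[[dict], ObservationSeries]:
    """Forward operator mapping a parameter dict to a width waveform.

    Estimated entries override the corresponding material/configuration
    values; anything absent falls back to ``fixed`` / ``config`` (notably the
    epithelium stiffness and Poisson ratio, which stay fixed).
    """
    fixed = fixed or MaterialParams()

    def forward(params: Mapping) -> ObservationSeries:
        mat = MaterialParams(
            E_body=params.get("E_body", fixed.E_body),
            E_slp=params.get("E_slp", fixed.E_slp),
            E_lig=params.get("E_lig", fixed.E_lig),
            E_epi=fixed.E_epi, nu=fixed.nu,
            rho_b=params.get("rho_b", fixed.rho_b),
            eta=params.get("eta", fixed.eta))
        cfg = replace(config,
                      p_sub=params.get("p_sub", config.p_sub),
                      m=params.get("m", config.m),
                      r_sep=params.get("r_sep", config.r_sep))
        return run_forward(cfg, mesh, mat)

    return forward


def run_study(observations: Mapping[str, ObservationSeries],
              permutations: Iterable[FlowPermutation],
              mesh: LayeredMesh, config: SimulationConfig,
              prior: PriorSpec | None = None, n: int = 500, seed: int = 0,
              sigma_area: float = 1.0,
              fixed: MaterialParams | None = None) -> pd.DataFrame:
    """Estimate every observation under every flow-model permutation.

    Returns a tidy table with one row per (observation, permutation,
    parameter): estimate, posterior std, relative uncertainty, the estimate
    normalized by the truth recorded in the observation metadata (synthetic
    twins), effective sample size and forward-failure count.  Failures of a
    whole cell are recorded as rows with NaN estimates and the study
    continues.
    """
    permutations = list(permutations)
    if not permutations:
        raise ConfigurationError("permutation list is empty")
    rows = []
    base_seed = np.random.SeedSequence(seed)
    cell_seeds = base_seed.spawn(len(permutations) * len(observations))
    k = 0
    for obs_name, obs in observations.items():
        truth = (obs.metadata or {}).get("truth", {})
        for perm in permutations:
            with_r = perm.kind == "bernoulli_estimated"
            cell_prior = prior
            if cell_prior is None:
                cell_prior = default_priors(
                    ParameterVector.from_mapping(truth) if truth else None,
                    with_r_sep=with_r)
            elif with_r and "r_sep" not in cell_prior.dists:
                cell_prior = PriorSpec({**cell_prior.dists,
                                        "r_sep": ("uniform", 1.0, 1.6)})
            elif not with_r and "r_sep" in cell_prior.dists:
                cell_prior = PriorSpec({k2: v for k2, v in cell_prior.dists.items()
                                        if k2 != "r_sep"})
            cfg = replace(config,
                          flow_model=("viscous" if perm.kind == "viscous"
                                      else perm.kind),
                          r_sep=perm.r_sep if perm.r_sep is not None else config.r_sep)
            fwd = make_forward(mesh, cfg, fixed)
            cell_seed = int(cell_seeds[k].generate_state(1)[0] % (2 ** 31))
            k += 1
            try:
                post = importance_estimate(cell_prior, obs, fwd, n=n,
                                           seed=cell_seed, sigma_area=sigma_area)
            except DegeneratePosteriorError as exc:
                rows.append({"observation": obs_name, "permutation": perm.label,
                             "parameter": "-", "estimate": np.nan, "std": np.nan,
                             "relative_uncertainty_pct": np.nan,
                             "normalized_estimate": np.nan, "n_eff": 0.0,
                             "failures": n, "error": str(exc)})
                continue
            for par in post.mean.index:
                tv = truth.get(par)
                rows.append({
                    "observation": obs_name, "permutation": perm.label,
                    "parameter": par, "estimate": post.mean[par],
                    "std": post.std[par],
                    "relative_uncertainty_pct": post.rel_uncertainty_pct[par],
                    "normalized_estimate": (post.mean[par] / tv
                                            if tv else np.nan),
                    "n_eff": post.n_eff, "failures": post.n_failures,
                    "error": "",
                })
    return pd.DataFrame(rows)
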