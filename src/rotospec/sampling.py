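"""Affine-invariant ensemble MCMC with parallel tempering.

The affine-invariant stretch move (as implemented by ``emcee``) explores a
single posterior; multimodal or strongly ridged posteriors additionally
benefit from replica exchange.  Here one ``emcee.EnsembleSampler`` runs per
temperature rung with the tempered log-density

    log pi_l(x) = beta_l * logL(x) + log prior(x),   beta_l = ratio**(-l),

and after every joint ensemble step adjacent rungs attempt per-walker
configuration swaps with the standard acceptance probability

    A = min(1, exp((beta_i - beta_j) * (logL_j - logL_i))).

Only the cold (beta = 1) chain is recorded.  The prior is uniform on a box
in the sampling-scale coordinates, so the cold-chain posterior density is
the likelihood itself and the stored per-sample ``log_like`` doubles as the
log posterior up to a constant.

Everything is deterministic given ``seed``: each rung's sampler is seeded
with ``seed + rung`` and swap decisions draw from a separate generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import emcee
import numpy as np
from emcee.state import State

__all__ = ["SamplerConfig", "PTSampleResult", "ParallelTemperedEnsembleSampler"]


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-sampler budget; defaults follow the full analysis setting."""

    n_walkers: int = 20
    n_temps: int = 5
    n_steps: int = 10000
    temp_ratio: float = 2.0
    burn_in: int = 0

    def __post_init__(self) -> None:
        if self.n_walkers < 4 or self.n_walkers % 2:
            raise ValueError("n_walkers must be even and >= 4")
        if self.n_temps < 1 or self.n_steps < 1:
            raise ValueError("n_temps and n_steps must be >= 1")
        if self.temp_ratio <= 1:
            raise ValueError("temp_ratio must be > 1")
        if not 0 <= self.burn_in < self.n_steps:
            raise ValueError("burn_in must be in [0, n_steps)")


@dataclass
class PTSampleResult:
    """Cold-chain output of a parallel-tempered run."""

    chain: np.ndarray       # (n_kept, n_walkers, ndim), sampling-scale coords
    log_like: np.ndarray    # (n_kept, n_walkers)
    betas: np.ndarray
    swap_acceptance: np.ndarray  # per adjacent pair
    move_acceptance: float       # cold-chain fraction of accepted moves
    diagnostics: dict = field(default_factory=dict)

    @property
    def flat_chain(self) -> np.ndarray:
        return self.chain.reshape(-1, self.chain.shape[-1])

    @property
    def flat_log_like(self) -> np.ndarray:
        return self.log_like.ravel()

    def map_sample(self) -> tuple[np.ndarray, float]:
        """Sample with maximum posterior density (first occurrence on ties)."""
        i = int(np.argmax(self.flat_log_like))
        return self.flat_chain[i].copy(), float(self.flat_log_like[i])


class ParallelTemperedEnsembleSampler:
    """Replica-exchange wrapper around per-temperature emcee ensembles.

    Parameters
    ----------
    log_likelihood : callable
        Vectorized: maps ``(k, ndim)`` coordinate arrays (sampling scale)
        to ``(k,)`` log-likelihoods.  Must be finite inside the box.
    lower, upper : ndarray
        Uniform-prior box in sampling-scale coordinates.
    config : SamplerConfig
    seed : int
    """

    def __init__(self, log_likelihood, lower, upper,
                 config: SamplerConfig = SamplerConfig(), seed: int = 0):
        self.log_likelihood = log_likelihood
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("lower/upper must be 1-D of equal length")
        if np.any(self.lower >= self.upper):
            raise ValueError("need lower < upper elementwise")
        self.ndim = self.lower.size
        self.config = config
        self.seed = int(seed)
        self.betas = config.temp_ratio ** (-np.arange(config.n_temps, dtype=float))
        # the stretch move needs at least 2*ndim walkers
        n_min = 2 * self.ndim + (2 * self.ndim) % 2
        self.n_walkers = max(config.n_walkers, n_min)

    # ------------------------------------------------------------------
    def _make_log_prob(self, beta: float):
        lo, hi, ll = self.lower, self.upper, self.log_likelihood

        def log_prob(coords):
            coords = np.atleast_2d(coords)
            inside = np.all((coords >= lo) & (coords <= hi), axis=1)
            out = np.full(coords.shape[0], -np.inf)
            if np.any(inside):
                out[inside] = beta * ll(coords[inside])
            return out

        return log_prob

    def _initial_coords(self, rng: np.random.Generator) -> np.ndarray:
        shape = (self.config.n_temps, self.n_walkers, self.ndim)
        return self.lower + (self.upper - self.lower) * rng.random(shape)

    # ------------------------------------------------------------------
    def run(self, n_steps: int | None = None,
            initial_coords: np.ndarray | None = None) -> PTSampleResult:
        cfg = self.config
        n_steps = cfg.n_steps if n_steps is None else int(n_steps)
        n_temps, n_walkers, ndim = cfg.n_temps, self.n_walkers, self.ndim

        rng = np.random.default_rng(self.seed)
        swap_rng = np.random.default_rng(self.seed + 10_000)
        coords = (self._initial_coords(rng) if initial_coords is None
                  else np.array(initial_coords, dtype=float))

        samplers, states = [], []
        for l in range(n_temps):
            s = emcee.EnsembleSampler(n_walkers, ndim,
                                      self._make_log_prob(self.betas[l]),
                                      vectorize=True)
            s.random_state = np.random.RandomState(self.seed + l).get_state()
            samplers.append(s)
            lp = s.log_prob_fn(coords[l])
            states.append(State(coords[l], log_prob=lp))

        kept = n_steps - cfg.burn_in
        chain = np.empty((kept, n_walkers, ndim))
        loglike = np.empty((kept, n_walkers))
        swap_tries = np.zeros(max(n_temps - 1, 1))
        swap_accepts = np.zeros(max(n_temps - 1, 1))
        prev_cold = states[0].coords.copy()
        moved = 0

        for step in range(n_steps):
            for l in range(n_temps):
                states[l] = samplers[l].run_mcmc(
                    states[l], 1, store=False, skip_initial_state_check=True)

            if n_temps > 1:
                # per-walker logL from the tempered log-density (flat prior)
                ll = [st.log_prob / b for st, b in zip(states, self.betas)]
                for l in range(n_temps - 1, 0, -1):  # hottest pair first
                    cold_b, hot_b = self.betas[l - 1], self.betas[l]
                    perm = swap_rng.permutation(n_walkers)
                    d_ll = ll[l][perm] - ll[l - 1]
                    accept = np.log(swap_rng.random(n_walkers)) < (
                        cold_b - hot_b) * d_ll
                    swap_tries[l - 1] += n_walkers
                    swap_accepts[l - 1] += accept.sum()
                    if np.any(accept):
                        idx = perm[accept]
                        c_cold = states[l - 1].coords[accept].copy()
                        c_hot = states[l].coords[idx].copy()
                        states[l - 1].coords[accept] = c_hot
                        states[l].coords[idx] = c_cold
                        ll_cold = ll[l - 1][accept].copy()
                        ll[l - 1][accept] = ll[l][idx]
                        ll[l][idx] = ll_cold
                        states[l - 1].log_prob = cold_b * ll[l - 1]
                        states[l].log_prob = hot_b * ll[l]

            if step >= cfg.burn_in:
                k = step - cfg.burn_in
                chain[k] = states[0].coords
                loglike[k] = states[0].log_prob / self.betas[0]
            moved += int(np.any(states[0].coords != prev_cold))
            prev_cold = states[0].coords.copy()

        with np.errstate(invalid="ignore"):
            swap_rate = np.where(swap_tries > 0, swap_accepts / swap_tries, 0.0)
        return PTSampleResult(
            chain=chain, log_like=loglike, betas=self.betas,
            swap_acceptance=swap_rate,
            move_acceptance=moved / n_steps,
            diagnostics={"n_walkers": n_walkers, "seed": self.seed,
                         "n_steps": n_steps},
        )
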