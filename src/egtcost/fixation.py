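"""Wright-Fisher simulation of the fixation of a transfer allele.

A new nuclear copy of an organellar gene starts as a single allele in a
population of N haploid individuals and either fixes or is lost under
selection (relative fitness 1 + s) and binomial drift.  Each generation the
allele frequency p is first moved deterministically by selection,

    p* = p (1 + s) / (1 + p s),

then resampled as Binomial(N, p*) / N.  A diploid flag switches the number
of sampled gene copies to 2N (and the default initial frequency to 1/2N);
the haploid form is the default, matching a unicellular host population.

For comparison, the diffusion approximation gives a fixation probability of
(1 - exp(-2 s N p0)) / (1 - exp(-2 N s)) — the simulator agrees with this
within Monte Carlo error, which is exercised by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class WFParams:
    """Wright-Fisher run parameters.

    ``pop_size`` of 1e7 matches a unicellular-eukaryote effective
    population size; desk-scale runs use smaller N with N*s held at
    comparable magnitudes.  ``p0`` defaults to a single new allele
    (1 / gene copies).  ``max_generations`` defaults to 20N, several times
    the neutral conditional fixation time.
    """

    pop_size: int
    s: float
    p0: Optional[float] = None
    max_generations: Optional[int] = None
    replicates: int = 1000
    seed: int = 0
    diploid: bool = False

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.p0 is not None and not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie in (0, 1)")
        if self.s <= -1.0:
            raise ValueError("s must exceed -1")

    @property
    def n_copies(self) -> int:
        """Gene copies sampled per generation (N haploid, 2N diploid)."""
        return self.pop_size * (2 if self.diploid else 1)

    @property
    def initial_frequency(self) -> float:
        return self.p0 if self.p0 is not None else 1.0 / self.n_copies

    @property
    def generation_cap(self) -> int:
        return (
            self.max_generations
            if self.max_generations is not None
            else 20 * self.pop_size
        )


@dataclass(frozen=True)
class WFResult:
    """Outcome of a replicate set of Wright-Fisher runs.

    ``p_fix`` counts only replicates that actually fixed; censored runs
    (still segregating at the generation cap) are reported separately, and
    ``capped`` flags runs where more than half the replicates were censored
    — a sign the cap is too tight for the parameter regime.
    """

    p_fix: float
    mean_t_fix: float
    n_fixed: int
    n_lost: int
    n_censored: int
    capped: bool

    @property
    def replicates(self) -> int:
        return self.n_fixed + self.n_lost + self.n_censored


def wf_generation(
    p, s: float, n_copies: int, rng: np.random.Generator
):
    """Advance allele frequency by one generation (selection then drift).

    Accepts a scalar or array of frequencies; 0 and 1 are absorbing.
    """
    p_arr = np.asarray(p, dtype=float)
    p_star = p_arr * (1.0 + s) / (1.0 + p_arr * s)
    out = np.asarray(rng.binomial(n_copies, p_star) / n_copies)
    return float(out) if out.ndim == 0 else out


def selection_step(p: float, s: float) -> float:
    """Deterministic expected frequency after one round of selection."""
    return p * (1.0 + s) / (1.0 + p * s)


def diffusion_fixation_probability(n: int, s: float, p0: float) -> float:
    """Kimura's diffusion approximation to the fixation probability."""
    if s == 0.0:
        return p0
    return float(-np.expm1(-2.0 * n * s * p0) / -np.expm1(-2.0 * n * s))


def simulate_fixation(params: WFParams) -> WFResult:
    """Run replicate Wright-Fisher trajectories to absorption or cap.

    Vectorised across replicates; exact binomial sampling per generation
    (no Gaussian or Poisson approximation).  Reproducible under a fixed
    seed.
    """
    rng = np.random.default_rng(params.seed)
    n_copies = params.n_copies
    p = np.full(params.replicates, params.initial_frequency)
    active = np.ones(params.replicates, dtype=bool)
    fix_times = np.zeros(params.replicates, dtype=np.int64)
    fixed = np.zeros(params.replicates, dtype=bool)

    gen = 0
    cap = params.generation_cap
    while active.any() and gen < cap:
        gen += 1
        idx = np.flatnonzero(active)
        p_star = p[idx] * (1.0 + params.s) / (1.0 + p[idx] * params.s)
        p[idx] = rng.binomial(n_copies, p_star) / n_copies
        newly_fixed = idx[p[idx] >= 1.0]
        newly_lost = idx[p[idx] <= 0.0]
        fixed[newly_fixed] = True
        fix_times[newly_fixed] = gen
        active[newly_fixed] = False
        active[newly_lost] = False

    n_fixed = int(fixed.sum())
    n_censored = int(active.sum())
    n_lost = params.replicates - n_fixed - n_censored
    return WFResult(
        p_fix=n_fixed / params.replicates,
        mean_t_fix=float(fix_times[fixed].mean()) if n_fixed else float("nan"),
        n_fixed=n_fixed,
        n_lost=n_lost,
        n_censored=n_censored,
        capped=n_censored > params.replicates / 2,
    )
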