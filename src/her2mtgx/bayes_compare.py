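"""Beta-binomial comparison of pCR rates between two arms.

With a Beta(alpha, beta) prior (uniform Beta(1,1) by default) and s
successes / f failures, each arm's pCR rate theta has a conjugate
Beta(alpha+s, beta+f) posterior. The quantity of interest is the lift
probability

    P(theta_B > (1 + delta) * theta_A)

estimated by Monte Carlo draws from both posteriors (seed-reproducible)
and, independently, by one-dimensional numeric quadrature — the latter
serves as a deterministic oracle for the sampler. A negative delta
expresses a tolerated reduction (delta = -0.2 asks for "at least 20%
below A" to be *excluded* with the complementary probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats


@dataclass(frozen=True)
class BetaPosterior:
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass
class PosteriorComparison:
    arm_a: tuple[int, int]  # (successes, failures)
    arm_b: tuple[int, int]
    prior: tuple[float, float]
    posterior_a: BetaPosterior
    posterior_b: BetaPosterior
    n_draws: int
    seed: int
    lift_probabilities: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "arm_a": list(self.arm_a), "arm_b": list(self.arm_b),
            "prior": list(self.prior),
            "posterior_a": [self.posterior_a.a, self.posterior_a.b],
            "posterior_b": [self.posterior_b.a, self.posterior_b.b],
            "n_draws": self.n_draws, "seed": self.seed,
            "lift_probabilities": {str(d): p for d, p
                                   in self.lift_probabilities.items()},
        }


def posterior(successes: int, failures: int,
              prior: tuple[float, float] = (1.0, 1.0)) -> BetaPosterior:
    """Conjugate update: Beta(alpha + s, beta + f)."""
    if successes < 0 or failures < 0:
        raise ValueError("counts must be non-negative")
    if prior[0] <= 0 or prior[1] <= 0:
        raise ValueError("prior parameters must be positive")
    return BetaPosterior(prior[0] + successes, prior[1] + failures)


def prob_lift(post_a: BetaPosterior, post_b: BetaPosterior, delta: float = 0.0,
              n_draws: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of P(theta_B > (1 + delta) * theta_A)."""
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    rng = np.random.default_rng(seed)
    a = rng.beta(post_a.a, post_a.b, size=n_draws)
    b = rng.beta(post_b.a, post_b.b, size=n_draws)
    return float(np.mean(b > (1.0 + delta) * a))


def prob_lift_exact(post_a: BetaPosterior, post_b: BetaPosterior,
                    delta: float = 0.0) -> float:
    """Deterministic quadrature oracle for :func:`prob_lift`.

    P(theta_B > c*theta_A) = int_0^1 f_A(a) * S_B(c*a) da with c = 1+delta;
    S_B is the Beta survival function (zero past 1).
    """
    c = 1.0 + delta
    if c <= 0:
        return 1.0  # theta_B > non-positive bound almost surely

    def integrand(a: float) -> float:
        return stats.beta.pdf(a, post_a.a, post_a.b) * \
            stats.beta.sf(min(c * a, 1.0), post_b.a, post_b.b)

    val, _ = integrate.quad(integrand, 0.0, 1.0, limit=200,
                            epsabs=1e-10, epsrel=1e-8)
    return float(min(1.0, max(0.0, val)))


def compare_arms(s_a: int, f_a: int, s_b: int, f_b: int,
                 prior: tuple[float, float] = (1.0, 1.0),
                 deltas: tuple[float, ...] = (0.0,),
                 n_draws: int = 100_000, seed: int = 0) -> PosteriorComparison:
    """Full A/B comparison: posteriors plus lift probabilities per delta."""
    pa = posterior(s_a, f_a, prior)
    pb = posterior(s_b, f_b, prior)
    lifts = {float(d): prob_lift(pa, pb, d, n_draws=n_draws, seed=seed)
             for d in deltas}
    return PosteriorComparison(
        arm_a=(s_a, f_a), arm_b=(s_b, f_b), prior=tuple(prior),
        posterior_a=pa, posterior_b=pb, n_draws=n_draws, seed=seed,
        lift_probabilities=lifts)


def counts_from_rate(rate_percent: float, n: int) -> tuple[int, int]:
    """Reconstruct (successes, failures) from a printed percentage rate."""
    s = int(round(rate_percent / 100.0 * n))
    return s, n - s
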