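"""Bayes-factor and posterior-odds arithmetic for essentiality calling.

Pooled CRISPR fitness screens analysed with a BAGEL-style classifier report,
per gene and screen, a log2 Bayes factor (BF): the log likelihood ratio of the
gene's guide fold changes under an "essential" versus a "nonessential" model.
Combining a BF with log2 prior odds of essentiality gives posterior log odds:

    posterior log2 odds = BF + log2( Pr(Ess) / Pr(Noness) )

With the background expectation that ~10% of human genes are essential the
uninformative log2 prior odds are ~-3, so a BF of 10 corresponds to posterior
odds of 7, i.e. a posterior probability of essentiality of ~99%, and a BF of 5
to posterior odds of 2, i.e. 80%.

Everything in this module is base 2 and pure-functional; the sequential
prior-updating machinery that consumes it lives in :mod:`jloe.joint_odds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "BayesParams",
    "PriorTable",
    "bf_to_posterior_log_odds",
    "posterior_log_odds_to_prob",
    "fdr_to_log_prior_ratio",
    "uninformative_log_prior",
]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class BayesParams:
    """Thresholds and prior bounds shared by the whole pipeline.

    Attributes
    ----------
    p_ess : float
        Prior probability that a random gene is essential (background rate).
    uninformative_log_prior : float
        Flat log2 prior odds used before any cross-screen evidence exists.
        The pipeline uses the rounded constant -3 (from p_ess = 0.1), which
        reproduces the standard BF-10 ~ 99% / BF-5 ~ 80% correspondences
        exactly; the unrounded value is available via
        :func:`uninformative_log_prior`.
    call_threshold : float
        Posterior log2 odds above which (strict >) a binary essential call is
        made. 7 corresponds to ~99% posterior probability.
    hit_threshold : float
        Log2 BF at or above which a gene is a plain "hit" in one screen.
    prior_cap : float
        Maximum log2 prior odds ratio; caps the boost from very small
        bin-wise FDR estimates to prevent instability.
    prior_floor : float
        Minimum log2 prior odds ratio. Equal to the uninformative prior by
        default so that accumulated evidence never penalises a gene below
        the flat-prior baseline.
    """

    p_ess: float = 0.1
    uninformative_log_prior: float = -3.0
    call_threshold: float = 7.0
    hit_threshold: float = 10.0
    prior_cap: float = 9.0
    prior_floor: float = -3.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_ess < 1.0):
            raise ValueError(f"p_ess must be in (0, 1), got {self.p_ess}")
        if not (self.prior_floor <= self.uninformative_log_prior <= self.prior_cap):
            raise ValueError(
                "uninformative_log_prior must lie in "
                f"[{self.prior_floor}, {self.prior_cap}], "
                f"got {self.uninformative_log_prior}"
            )


DEFAULT_PARAMS = BayesParams()


@dataclass
class PriorTable:
    """Map from prior-evidence bin to FDR and updated log2 prior odds.

    Bin ``b`` is the number of essential calls already made for a gene among
    higher-ranked screens in a k-screen set (b = 1 .. k-1). ``fdr[b]`` is the
    bin-wise false discovery rate estimated by saturation resampling and
    ``log_prior[b] = log2((1-fdr)/fdr)`` clipped to the params' bounds.
    """

    fdr: dict[int, float]
    log_prior: dict[int, float]
    source: str = "estimated"
    params: BayesParams = field(default_factory=BayesParams)

    def __post_init__(self) -> None:
        if set(self.fdr) != set(self.log_prior):
            raise ValueError("fdr and log_prior must cover the same bins")
        for b, f in self.fdr.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fdr for bin {b} must be in [0, 1], got {f}")
        for b, lp in self.log_prior.items():
            if not (self.params.prior_floor - 1e-12 <= lp <= self.params.prior_cap + 1e-12):
                raise ValueError(
                    f"log_prior for bin {b} outside "
                    f"[{self.params.prior_floor}, {self.params.prior_cap}]: {lp}"
                )

    @classmethod
    def from_fdr(
        cls,
        fdr: dict[int, float],
        params: BayesParams = DEFAULT_PARAMS,
        source: str = "estimated",
    ) -> "PriorTable":
        """Build a table from bin-wise FDR values, deriving the log priors."""
        log_prior = {b: fdr_to_log_prior_ratio(f, params) for b, f in fdr.items()}
        return cls(fdr=dict(fdr), log_prior=log_prior, source=source, params=params)

    @property
    def bins(self) -> list[int]:
        return sorted(self.fdr)

    def log_prior_for(self, n_calls: int) -> float:
        """Log2 prior odds given ``n_calls`` prior essential calls.

        Zero prior calls fall back to the uninformative prior; a count above
        the largest tabulated bin uses the largest bin (FDR is monotone
        negligible for very frequent hits).
        """
        if n_calls <= 0:
            return self.params.uninformative_log_prior
        if n_calls in self.log_prior:
            return self.log_prior[n_calls]
        top = max(self.log_prior)
        if n_calls > top:
            return self.log_prior[top]
        raise KeyError(f"no prior tabulated for bin {n_calls} (bins: {self.bins})")


def bf_to_posterior_log_odds(bf: float, log_prior: float) -> float:
    """Posterior log2 odds of essentiality: ``bf + log_prior``.

    ``bf`` is a log2 Bayes factor (BAGEL output is already a log quantity)
    and ``log_prior`` the log2 prior odds ratio; their sum is the posterior
    log2 odds.
    """
    return _require_finite("bf", bf) + _require_finite("log_prior", log_prior)


def posterior_log_odds_to_prob(plo: float) -> float:
    """Convert posterior log2 odds to a posterior probability in (0, 1)."""
    plo = _require_finite("plo", plo)
    # 2^x / (1 + 2^x), computed stably for large |x|
    if plo >= 0:
        return 1.0 / (1.0 + 2.0 ** (-plo))
    z = 2.0**plo
    return z / (1.0 + z)


def fdr_to_log_prior_ratio(fdr: float, params: BayesParams = DEFAULT_PARAMS) -> float:
    """Updated log2 prior odds from a bin-wise FDR: ``log2((1-fdr)/fdr)``.

    Clipped to ``[params.prior_floor, params.prior_cap]``; an FDR of 0 maps
    to the cap, an FDR of 1 to the floor. E.g. an FDR of 0.3% (genes
    essential in five of eight screens) gives ~8.4; 50% gives 0.
    """
    fdr = float(fdr)
    if math.isnan(fdr) or not (0.0 <= fdr <= 1.0):
        raise ValueError(f"fdr must be in [0, 1], got {fdr!r}")
    if fdr == 0.0:
        return params.prior_cap
    if fdr == 1.0:
        return params.prior_floor
    lp = math.log2((1.0 - fdr) / fdr)
    return min(max(lp, params.prior_floor), params.prior_cap)


def uninformative_log_prior(p_ess: float) -> float:
    """Exact uninformative log2 prior odds: ``log2(p_ess / (1 - p_ess))``.

    For p_ess = 0.1 this is -3.17; the pipeline default uses the rounded
    constant -3 (see :class:`BayesParams`). Exposed for documentation and
    sensitivity analyses.
    """
    p_ess = float(p_ess)
    if not (0.0 < p_ess < 1.0):
        raise ValueError(f"p_ess must be strictly inside (0, 1), got {p_ess!r}")
    return math.log2(p_ess / (1.0 - p_ess))
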