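"""Synthetic chain generators: length sampling and acetylation patterns.

Three pattern families cover the spectrum reported for chitosans:

* Bernoullian random placement (``generate_bernoulli``),
* a two-state first-order Markov chain parameterised by the target
  fraction of acetylation F_A and the dyad statistic P_sigma
  (``generate_markov``; P_sigma < 1 gives block-wise patterns,
  P_sigma > 1 more alternating ones),
* a deterministic maximally even placement (``generate_regular``).

Chain lengths come from :func:`sample_lengths`, which supports fixed
lengths, empirical length lists, and the Schulz-Zimm (gamma) family
matched to a number-average DP and a dispersity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .polymer_core import A_CODE, ChainEnsemble, ChitosanChain

__all__ = [
    "DPDistributionSpec",
    "MarkovPASpec",
    "sample_lengths",
    "generate_bernoulli",
    "generate_markov",
    "generate_regular",
]


@dataclass(frozen=True)
class DPDistributionSpec:
    """Chain-length distribution specification.

    families:
      ``fixed``       every chain has DP = ``dpn``;
      ``schulz_zimm`` gamma distribution with shape ``z = 1/(Đ-1)`` and
                      mean ``dpn`` (so that Đ = (z+1)/z), rounded to
                      integers and clamped at ``min_dp``;
      ``empirical``   lengths drawn uniformly from ``lengths``.
    """

    family: str = "schulz_zimm"
    dpn: float = 800.0
    dispersity: float = 1.9
    min_dp: int = 2
    lengths: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.family not in {"fixed", "schulz_zimm", "empirical"}:
            raise ValueError(f"unknown length family {self.family!r}")
        if self.family == "empirical":
            if not self.lengths:
                raise ValueError("empirical family requires a non-empty lengths list")
            return
        if self.dpn < self.min_dp:
            raise ValueError("DPn target must be >= the minimum DP")
        if self.family == "schulz_zimm" and self.dispersity < 1.0:
            raise ValueError("dispersity must be >= 1")

    @property
    def shape(self) -> float:
        """Schulz-Zimm shape parameter z = 1/(Đ - 1)."""
        if self.dispersity <= 1.0:
            return float("inf")
        return 1.0 / (self.dispersity - 1.0)


def sample_lengths(spec: DPDistributionSpec, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` integer chain lengths according to ``spec``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if spec.family == "fixed":
        return np.full(n, int(round(spec.dpn)), dtype=np.int64)
    if spec.family == "empirical":
        return rng.choice(np.asarray(spec.lengths, dtype=np.int64), size=n)
    z = spec.shape
    if np.isinf(z):  # monodisperse limit
        draws = np.full(n, float(spec.dpn))
    else:
        draws = rng.gamma(shape=z, scale=spec.dpn / z, size=n)
    lengths = np.rint(draws).astype(np.int64)
    return np.maximum(lengths, spec.min_dp)


@dataclass(frozen=True)
class MarkovPASpec:
    """First-order Markov pattern specification.

    The two-state chain is parameterised so that the stationary fraction of
    A equals ``fa`` and the pooled-dyad statistic converges to ``p_sigma``:

    * ``Pr(A -> D) = (1 - fa) * p_sigma``
    * ``Pr(D -> A) = fa * p_sigma``

    Feasibility requires ``0 < p_sigma <= min(1/fa, 1/(1-fa))``.
    """

    fa: float
    p_sigma: float

    def __post_init__(self):
        if not 0.0 < self.fa < 1.0:
            raise ValueError("fa must lie strictly between 0 and 1")
        bound = min(1.0 / self.fa, 1.0 / (1.0 - self.fa))
        if not 0.0 < self.p_sigma <= bound:
            raise ValueError(
                f"p_sigma must lie in (0, {bound:.4g}] for fa={self.fa} "
                "(bound = min(1/fa, 1/(1-fa)))"
            )

    @property
    def p_ad(self) -> float:
        return (1.0 - self.fa) * self.p_sigma

    @property
    def p_da(self) -> float:
        return self.fa * self.p_sigma

    @classmethod
    def from_transitions(cls, p_ad: float, p_da: float) -> "MarkovPASpec":
        """Build a spec from explicit transition probabilities."""
        if not (0.0 < p_ad <= 1.0 and 0.0 < p_da <= 1.0):
            raise ValueError("transition probabilities must lie in (0, 1]")
        sigma = p_ad + p_da
        return cls(fa=p_da / sigma, p_sigma=sigma)


def _make_ensemble(arrays, prefix: str, meta: dict) -> ChainEnsemble:
    chains = [
        ChitosanChain(arr, id=f"{prefix}_{i:05d}", meta=dict(meta)) for i, arr in enumerate(arrays)
    ]
    return ChainEnsemble(chains)


def generate_bernoulli(fa: float, lengths: Sequence[int], seed=None) -> ChainEnsemble:
    """Chains with i.i.d. residues, Pr(A) = ``fa`` (random pattern)."""
    if not 0.0 <= fa <= 1.0:
        raise ValueError("fa must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    arrays = [(rng.random(int(L)) < fa).astype(np.uint8) for L in lengths]
    return _make_ensemble(arrays, "bern", {"pa": "bernoulli", "fa": f"{fa:g}"})


def generate_markov(spec: MarkovPASpec, lengths: Sequence[int], seed=None) -> ChainEnsemble:
    """Stationary first-order Markov chains targeting (F_A, P_sigma).

    The first residue is drawn from the stationary distribution
    (Pr(A) = fa); at ``p_sigma = 1`` the construction reduces exactly to
    the Bernoulli generator in distribution.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("need at least one chain length")
    rng = np.random.default_rng(seed)
    n, lmax = lengths.size, int(lengths.max())
    u = rng.random((n, lmax))
    states = np.zeros((n, lmax), dtype=np.uint8)
    states[:, 0] = u[:, 0] < spec.fa
    p_stay_a = 1.0 - spec.p_ad
    for t in range(1, lmax):
        prev_a = states[:, t - 1] == A_CODE
        thresh = np.where(prev_a, p_stay_a, spec.p_da)
        states[:, t] = u[:, t] < thresh
    arrays = [states[i, : lengths[i]].copy() for i in range(n)]
    meta = {"pa": "markov", "fa": f"{spec.fa:g}", "psigma": f"{spec.p_sigma:g}"}
    return _make_ensemble(arrays, "markov", meta)


def regular_sequence(fa: float, dp: int) -> np.ndarray:
    """Deterministic maximally even placement of the minority residue.

    For ``fa <= 0.5`` the ``round(fa * dp)`` A residues are spread with
    near-constant spacing (Bresenham/euclidean-rhythm rule); for
    ``fa > 0.5`` the symmetric rule is applied to the D residues.
    """
    if not 0.0 < fa < 1.0:
        raise ValueError("fa must lie strictly between 0 and 1")
    if dp < 1:
        raise ValueError("dp must be >= 1")
    minority_fa = fa if fa <= 0.5 else 1.0 - fa
    k = int(round(minority_fa * dp))
    i = np.arange(dp, dtype=np.int64)
    minority = (i * k) % dp < k
    if fa <= 0.5:
        return minority.astype(np.uint8)
    return (~minority).astype(np.uint8)


def generate_regular(fa: float, lengths: Sequence[int]) -> ChainEnsemble:
    """Regular (evenly spaced) acetylation pattern; deterministic, no seed.

    Achieved F_A is within 1/DP of the target and the resulting pooled
    P_sigma exceeds 1 (no AA dyads while A is the minority residue).
    """
    arrays = [regular_sequence(fa, int(L)) for L in lengths]
    return _make_ensemble(arrays, "reg", {"pa": "regular", "fa": f"{fa:g}"})
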