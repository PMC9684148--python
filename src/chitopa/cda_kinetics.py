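"""Kinetic Monte Carlo of reverse-mode chitin-deacetylase N-acetylation.

A deacetylase acting in reverse (excess acetate) converts D (GlcN) units
to A (GlcNAc).  The catalytic subsite {0} holds the residue being
modified; the flanking subsites {-2}, {-1}, {+1} (non-reducing side
negative, reducing side positive) contribute multiplicative preference
weights to the per-site rate:

    rate(i) = k * prod_s w_s(residue at i + s)

Sites are picked by a Gillespie loop (event rates -> exponential waiting
times); each event acetylates exactly one D.  Preference weights are
editable model defaults (the underlying enzymology is qualitative), so
only orderings between presets are meaningful, never absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .polymer_core import A_CODE, D_CODE, ChainEnsemble, ChitosanChain, compute_fa

__all__ = [
    "DeacetylaseSpec",
    "AcetylationTrajectory",
    "site_rates",
    "run_acetylation",
    "preset_deacetylases",
]

_SUBSITES = (-2, -1, 1)


@dataclass(frozen=True)
class DeacetylaseSpec:
    """Subsite-preference model for a (de)acetylase.

    ``weights`` maps subsite offsets (-2, -1, +1) to ``{"A": wA, "D": wD}``
    with all weights finite and >= 0.  ``end_weight`` is used whenever a
    subsite falls beyond a chain end (neutral default 1).  ``mode`` is
    ``"acetylation"`` (reverse mode, D -> A; the default) or
    ``"deacetylation"`` (forward mode, A -> D).
    """

    name: str
    weights: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: {s: {"A": 1.0, "D": 1.0} for s in _SUBSITES}
    )
    end_weight: float = 1.0
    rate_constant: float = 1.0
    mode: str = "acetylation"

    def __post_init__(self):
        if self.mode not in {"acetylation", "deacetylation"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.rate_constant <= 0:
            raise ValueError("rate constant must be > 0")
        if self.end_weight < 0 or not np.isfinite(self.end_weight):
            raise ValueError("end weight must be finite and >= 0")
        for s, w in self.weights.items():
            if s == 0:
                raise ValueError("subsite {0} holds the modified residue; no weight allowed")
            for res in ("A", "D"):
                v = w.get(res, 1.0)
                if v < 0 or not np.isfinite(v):
                    raise ValueError(f"weight w_[{s}]({res}) must be finite and >= 0")

    @property
    def target_code(self) -> int:
        return D_CODE if self.mode == "acetylation" else A_CODE

    def weight(self, s: int, code: int) -> float:
        w = self.weights.get(s)
        if w is None:
            return 1.0
        return float(w.get("A" if code == A_CODE else "D", 1.0))

    @classmethod
    def from_dict(cls, name: str, data: Mapping) -> "DeacetylaseSpec":
        weights = {int(s): {k: float(v) for k, v in w.items()} for s, w in data.get("weights", {}).items()}
        return cls(
            name=name,
            weights=weights,
            end_weight=float(data.get("end_weight", 1.0)),
            rate_constant=float(data.get("rate_constant", 1.0)),
            mode=str(data.get("mode", "acetylation")),
        )

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "end_weight": self.end_weight,
            "rate_constant": self.rate_constant,
            "weights": {s: dict(w) for s, w in self.weights.items()},
        }


def site_rates(chain: ChitosanChain, spec: DeacetylaseSpec) -> np.ndarray:
    """Per-position event rate for every residue of a chain.

    Positions already in the product state (A for acetylation mode) have
    rate 0.  Subsites beyond the chain ends take ``end_weight``.
    """
    x = chain.residues
    L = x.size
    rates = np.full(L, spec.rate_constant, dtype=float)
    idx = np.arange(L)
    for s in spec.weights:
        j = idx + s
        valid = (j >= 0) & (j < L)
        wvec = np.full(L, spec.end_weight, dtype=float)
        wa = spec.weight(s, A_CODE)
        wd = spec.weight(s, D_CODE)
        wvec[valid] = np.where(x[j[valid]] == A_CODE, wa, wd)
        rates *= wvec
    rates[x != spec.target_code] = 0.0
    return rates


def _single_rate(x: np.ndarray, i: int, spec: DeacetylaseSpec) -> float:
    if x[i] != spec.target_code:
        return 0.0
    r = spec.rate_constant
    for s in spec.weights:
        j = i + s
        if 0 <= j < x.size:
            r *= spec.weight(s, int(x[j]))
        else:
            r *= spec.end_weight
    return r


@dataclass
class AcetylationTrajectory:
    """F_A versus pseudo-time along a kinetic Monte Carlo run."""

    times: np.ndarray
    fas: np.ndarray
    steps: int
    final_ensemble: ChainEnsemble | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("pseudo-time must be strictly increasing")


def run_acetylation(
    ensemble: ChainEnsemble,
    spec: DeacetylaseSpec,
    target_fa: float,
    seed=None,
    max_steps: int | None = None,
) -> tuple[ChainEnsemble, AcetylationTrajectory]:
    """Acetylate an ensemble up to ``target_fa`` with a Gillespie loop.

    Each event converts one D to A, chosen with probability proportional
    to its subsite-weighted rate; pseudo-time advances by an Exp(1/R)
    increment where R is the total rate.  Stops at the first event where
    F_A >= ``target_fa`` (honoured within one event), or at ``max_steps``.

    Abundances must be uniform (the simulator modifies individual
    molecules).  Raises if the target is below the initial F_A or if no
    eligible site remains before the target is reached.
    """
    if spec.mode != "acetylation":
        raise ValueError("run_acetylation requires an acetylation-mode spec")
    if not 0.0 < target_fa <= 1.0:
        raise ValueError("target_fa must lie in (0, 1]")
    if not np.all(ensemble.abundances == ensemble.abundances[0]):
        raise ValueError("run_acetylation requires uniform abundances")
    rng = np.random.default_rng(seed)

    arrays = [chain.residues.copy() for chain in ensemble.chains]
    for arr in arrays:
        arr.setflags(write=True)
    dps = np.array([a.size for a in arrays], dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(dps)))
    total = int(offsets[-1])
    n_a = int(sum(int(a.sum()) for a in arrays))
    fa0 = n_a / total
    if target_fa < fa0:
        raise ValueError(f"target_fa {target_fa} below initial F_A {fa0:.4f}")

    rates = np.concatenate([site_rates(ChitosanChain(a), spec) for a in arrays])
    if max_steps is None:
        max_steps = total

    times = [0.0]
    fas = [fa0]
    t = 0.0
    steps = 0
    while fas[-1] < target_fa and steps < max_steps:
        total_rate = float(rates.sum())
        if total_rate <= 0.0:
            raise ValueError("no eligible sites")
        t += rng.exponential(1.0 / total_rate)
        u = rng.random() * total_rate
        flat = int(np.searchsorted(np.cumsum(rates), u, side="right"))
        flat = min(flat, total - 1)
        c = int(np.searchsorted(offsets, flat, side="right")) - 1
        i = flat - int(offsets[c])
        arr = arrays[c]
        arr[i] = A_CODE
        n_a += 1
        rates[flat] = 0.0
        for q in (i - 1, i + 1, i + 2):
            if 0 <= q < arr.size:
                rates[offsets[c] + q] = _single_rate(arr, q, spec)
        steps += 1
        times.append(t)
        fas.append(n_a / total)

    new_chains = []
    for chain, arr in zip(ensemble.chains, arrays):
        meta = dict(chain.meta)
        meta.update({"enzyme": spec.name, "target_fa": f"{target_fa:g}"})
        new_chains.append(ChitosanChain(arr, id=chain.id, meta=meta))
    out = ChainEnsemble(new_chains, ensemble.abundances.copy())
    traj = AcetylationTrajectory(
        times=np.asarray(times), fas=np.asarray(fas), steps=steps, final_ensemble=out
    )
    return out, traj


def preset_deacetylases() -> dict[str, DeacetylaseSpec]:
    """Named default subsite models: uniform, AnCDA, PesCDA, CnCDA4, PgtCDA.

    AnCDA and PesCDA strongly prefer A at {-1} (block-forming), CnCDA4
    strongly prefers D at {-1} (regularising), PgtCDA slightly prefers D
    at {-1} (near random).  Loaded from the packaged config so the numeric
    defaults stay user-editable.
    """
    from .cli_io.config import load_packaged_deacetylases

    return load_packaged_deacetylases()
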