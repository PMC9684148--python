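"""In-silico endo-hydrolysis of chitosan under subsite-specificity rules.

Bond/subsite convention (sequences written non-reducing -> reducing):
residues are 1-based; bond ``j`` joins residues ``j`` and ``j+1`` and is
indexed by the position of its {-1} residue.  Subsite ``s`` maps to
residue index ``j + s + 1`` for ``s < 0`` and ``j + s`` for ``s > 0``::

        residues:   ...  j-1   j   |   j+1   j+2  ...
        subsites:        {-2} {-1} | {+1}  {+2}

The scissile bond sits between subsites {-1} and {+1}.

A bond is cleavable within a fragment iff every *required* subsite
(the union of residue-constrained subsites and the explicit occupancy
set) holds a residue of that same fragment, and every residue-constrained
subsite holds an allowed residue.  Cleaving separates the fragments, so
residues beyond a cut no longer occupy subsites — occupancy constraints
therefore deactivate bonds near new ends, which is why digestion is run
as an iterative random-order process until no cleavable bond remains
(complete digestion; the wet-lab 24-h incubations are modelled as the
limit digest).
"""

from __future__ import annotations

from bisect import insort
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .polymer_core import A_CODE, ChainEnsemble, ChitosanChain, decode_sequence

__all__ = [
    "HydrolaseSpec",
    "ProductRecord",
    "ProductTable",
    "cleavable_bonds",
    "digest",
    "preset_hydrolases",
]

END_FLAGS = ("interior", "non_reducing_terminal", "reducing_terminal", "intact")


def _subsite_residue_index(bond: int, s: int) -> int:
    """1-based residue index occupying subsite ``s`` of bond ``bond``."""
    return bond + s + 1 if s < 0 else bond + s


@dataclass(frozen=True)
class HydrolaseSpec:
    """Subsite rule set for an endo-hydrolase.

    ``constraints`` maps subsite offsets to the set of allowed residues
    (subset of ``{"A", "D"}``); ``occupancy`` lists subsites that must be
    occupied by a residue of the current fragment even if their identity
    is unconstrained.  Residue-constrained subsites are implicitly
    occupancy-required (an empty subsite cannot present an allowed
    residue).  ``mode`` is ``"absolute"`` (uniform choice among cleavable
    bonds) or ``"weighted"`` (choice proportional to the product of
    ``subsite_weights``; zero-weight bonds are never cleaved).
    """

    name: str
    constraints: Mapping[int, frozenset] = field(default_factory=dict)
    occupancy: frozenset = frozenset()
    mode: str = "absolute"
    subsite_weights: Mapping[int, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in {"absolute", "weighted"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.constraints and not self.subsite_weights:
            raise ValueError("at least one subsite must be constrained")
        norm = {}
        for s, allowed in self.constraints.items():
            allowed = frozenset(str(r).upper() for r in allowed)
            if not allowed or not allowed <= {"A", "D"}:
                raise ValueError(f"allowed set for subsite {s} must be a non-empty subset of {{A, D}}")
            if s == 0:
                raise ValueError("subsite 0 does not exist for a hydrolase (bond between -1 and +1)")
            norm[int(s)] = allowed
        object.__setattr__(self, "constraints", norm)
        object.__setattr__(self, "occupancy", frozenset(int(s) for s in self.occupancy))

    @property
    def required_subsites(self) -> frozenset:
        return frozenset(self.constraints) | self.occupancy

    @property
    def min_left_product_dp(self) -> int:
        """Smallest fragment a cut can leave on the non-reducing side."""
        offs = [_subsite_residue_index(0, s) for s in self.required_subsites if s < 0] + [0]
        return 1 - min(offs)

    @property
    def min_right_product_dp(self) -> int:
        offs = [_subsite_residue_index(0, s) for s in self.required_subsites if s > 0] + [1]
        return max(offs)

    @classmethod
    def from_dict(cls, name: str, data: Mapping) -> "HydrolaseSpec":
        constraints = {
            int(s): frozenset(str(allowed).upper())
            if isinstance(allowed, str)
            else frozenset(allowed)
            for s, allowed in data.get("constraints", {}).items()
        }
        weights = {
            int(s): {k: float(v) for k, v in w.items()}
            for s, w in data.get("subsite_weights", {}).items()
        }
        return cls(
            name=name,
            constraints=constraints,
            occupancy=frozenset(int(s) for s in data.get("occupancy", [])),
            mode=str(data.get("mode", "absolute")),
            subsite_weights=weights,
        )

    def to_dict(self) -> dict:
        return {
            "constraints": {s: "".join(sorted(a)) for s, a in self.constraints.items()},
            "occupancy": sorted(self.occupancy),
            "mode": self.mode,
            "subsite_weights": {s: dict(w) for s, w in self.subsite_weights.items()},
        }


def _eligible_mask(
    x: np.ndarray, spec: HydrolaseSpec, bonds: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Vectorised cleavability test for 1-based ``bonds`` within fragments
    ``[starts, ends]`` (1-based, inclusive)."""
    ok = np.ones(bonds.size, dtype=bool)
    for s in spec.required_subsites:
        r = bonds + (s + 1 if s < 0 else s)
        ok &= (r >= starts) & (r <= ends)
        allowed = spec.constraints.get(s)
        if allowed is not None and allowed != {"A", "D"}:
            inside = (r >= 1) & (r <= x.size)
            res_a = np.zeros(bonds.size, dtype=bool)
            res_a[inside] = x[r[inside] - 1] == A_CODE
            want_a = "A" in allowed
            want_d = "D" in allowed
            ok &= np.where(res_a, want_a, want_d)
    return ok


def cleavable_bonds(chain: ChitosanChain, spec: HydrolaseSpec) -> list[int]:
    """1-based indices of bonds cleavable on the intact chain."""
    L = chain.dp
    if L < 2:
        return []
    bonds = np.arange(1, L, dtype=np.int64)
    ok = _eligible_mask(chain.residues, spec, bonds, np.int64(1), np.int64(L))
    return [int(j) for j in bonds[ok]]


def _bond_weights(x: np.ndarray, spec: HydrolaseSpec, bonds: np.ndarray) -> np.ndarray:
    w = np.ones(bonds.size, dtype=float)
    for s, table in spec.subsite_weights.items():
        r = bonds + (s + 1 if s < 0 else s)
        inside = (r >= 1) & (r <= x.size)
        wa = float(table.get("A", 1.0))
        wd = float(table.get("D", 1.0))
        vec = np.ones(bonds.size, dtype=float)
        res_a = np.zeros(bonds.size, dtype=bool)
        res_a[inside] = x[r[inside] - 1] == A_CODE
        vec[inside] = np.where(res_a[inside], wa, wd)
        w *= vec
    return w


@dataclass
class ProductRecord:
    """One oligomer species of a digestion product pool."""

    dp: int
    na: int
    nd: int
    end_flag: str
    abundance: float
    sequence: str | None = None
    fraction: float | None = None  # set by fingerprint.normalize_window

    def __post_init__(self):
        if self.dp != self.na + self.nd or self.dp < 1:
            raise ValueError(f"require dp = na + nd >= 1, got dp={self.dp}, na={self.na}, nd={self.nd}")
        if self.abundance <= 0:
            raise ValueError("abundance must be > 0")
        if self.end_flag not in END_FLAGS:
            raise ValueError(f"end_flag must be one of {END_FLAGS}")
        if self.sequence is not None:
            up = self.sequence.upper()
            if len(up) != self.dp or up.count("A") != self.na:
                raise ValueError("explicit sequence inconsistent with (dp, na, nd)")
            self.sequence = up


class ProductTable:
    """Aggregated oligomer products of a digestion (the in-silico fingerprint)."""

    def __init__(self, records: Iterable[ProductRecord], provenance: Mapping | None = None):
        self.records = list(records)
        self.provenance = dict(provenance or {})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def total_monomers(self) -> float:
        return float(sum(r.abundance * r.dp for r in self.records))

    @property
    def total_acetyl(self) -> float:
        return float(sum(r.abundance * r.na for r in self.records))

    def validate_conservation(self, total_monomers: float, total_acetyl: float, tol: float = 1e-6) -> None:
        if abs(self.total_monomers - total_monomers) > tol:
            raise ValueError(
                f"monomer conservation violated: products carry {self.total_monomers}, "
                f"substrate had {total_monomers}"
            )
        if abs(self.total_acetyl - total_acetyl) > tol:
            raise ValueError(
                f"acetyl conservation violated: products carry {self.total_acetyl}, "
                f"substrate had {total_acetyl}"
            )

    def by_composition(self) -> dict[tuple[int, int, int], float]:
        """Total abundance keyed by (dp, na, nd), pooled over end flags."""
        out: dict[tuple[int, int, int], float] = {}
        for r in self.records:
            key = (r.dp, r.na, r.nd)
            out[key] = out.get(key, 0.0) + r.abundance
        return out


def _digest_chain(x: np.ndarray, spec: HydrolaseSpec, rng: np.random.Generator) -> list[int]:
    """Cut one chain to completion; returns the sorted cut-bond list."""
    L = x.size
    if L < 2:
        return []
    bonds = np.arange(1, L, dtype=np.int64)
    # residue-identity constraints never change, so prefilter once
    cand = bonds[_eligible_mask(x, spec, bonds, np.int64(1), np.int64(L))]
    # also keep bonds that fail only through occupancy on the intact chain:
    # they can never become eligible later (fragments only shrink), so the
    # intact-chain eligibility set is the full candidate set.
    if cand.size == 0:
        return []
    if spec.mode == "weighted":
        base_w = _bond_weights(x, spec, cand)
        cand = cand[base_w > 0]
        base_w = base_w[base_w > 0]
    alive = np.ones(cand.size, dtype=bool)
    cuts: list[int] = []
    while True:
        if cuts:
            cuts_arr = np.asarray(cuts, dtype=np.int64)
            k = np.searchsorted(cuts_arr, cand)
            starts = np.where(k > 0, cuts_arr[np.maximum(k - 1, 0)] + 1, 1)
            ends = np.where(k < cuts_arr.size, cuts_arr[np.minimum(k, cuts_arr.size - 1)], L)
        else:
            starts = np.full(cand.size, 1, dtype=np.int64)
            ends = np.full(cand.size, L, dtype=np.int64)
        ok = alive & _eligible_mask(x, spec, cand, starts, ends)
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            break
        if spec.mode == "weighted":
            w = base_w[idx]
            pick = idx[rng.choice(idx.size, p=w / w.sum())]
        else:
            pick = idx[rng.integers(idx.size)]
        alive[pick] = False
        insort(cuts, int(cand[pick]))
    return cuts


def digest(
    ensemble: ChainEnsemble,
    spec: HydrolaseSpec,
    seed=None,
    store_sequences: bool = False,
) -> ProductTable:
    """Exhaustively digest an ensemble; deterministic under ``seed``.

    Bonds are cleaved one at a time, chosen uniformly at random among the
    currently cleavable bonds (or weight-proportionally in weighted mode),
    re-evaluating occupancy after every cut, until none remains.  Chains
    with no cleavable bond are returned intact.  Products are aggregated
    by (dp, na, nd, end flag, sequence); sequences are always retained for
    terminal and intact products (needed for exact block inference) and
    for all products when ``store_sequences`` is set.
    """
    rng = np.random.default_rng(seed)
    agg: dict[tuple, float] = {}
    n_cleavages = 0.0
    for chain, ab in zip(ensemble.chains, ensemble.abundances):
        x = chain.residues
        cuts = _digest_chain(x, spec, rng)
        n_cleavages += ab * len(cuts)
        starts = [1] + [c + 1 for c in cuts]
        ends = cuts + [x.size]
        for a, b in zip(starts, ends):
            seg = x[a - 1 : b]
            na = int(seg.sum())
            dp = b - a + 1
            if a == 1 and b == x.size:
                flag = "intact"
            elif a == 1:
                flag = "non_reducing_terminal"
            elif b == x.size:
                flag = "reducing_terminal"
            else:
                flag = "interior"
            keep_seq = store_sequences or flag != "interior"
            seq = decode_sequence(seg) if keep_seq else None
            key = (dp, na, flag, seq)
            agg[key] = agg.get(key, 0.0) + ab
    records = [
        ProductRecord(dp=dp, na=na, nd=dp - na, end_flag=flag, abundance=abund, sequence=seq)
        for (dp, na, flag, seq), abund in sorted(
            agg.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3] or "")
        )
    ]
    table = ProductTable(
        records,
        provenance={
            "enzyme": spec.name,
            "seed": seed,
            "n_chains": len(ensemble),
            "n_cleavages": n_cleavages,
            "substrate_total_monomers": ensemble.total_monomers,
            "substrate_total_acetyl": ensemble.total_acetyl,
        },
    )
    table.validate_conservation(ensemble.total_monomers, ensemble.total_acetyl)
    return table


def preset_hydrolases() -> dict[str, HydrolaseSpec]:
    """Named default rule sets.

    * ``chitinosanase`` — D at {-2}, A at {-1}, no downstream constraint
      (the DA/XX rule); occupancy {-2, -1, +1}.
    * ``ChiB`` / ``ChT`` — A at {-1}; occupancy {-2, -1, +1}.
    * ``Csn174`` — D at {-1} and {+1}; occupancy {-2 .. +2}.
    * ``lysozyme`` — A at {-2}, {-1}, {+1}; occupancy {-3 .. +2} (the
      enzyme's long cleft needs an additional occupied subsite beyond
      {-2}, which is what limits its smallest products).
    """
    from .cli_io.config import load_packaged_hydrolases

    return load_packaged_hydrolases()
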