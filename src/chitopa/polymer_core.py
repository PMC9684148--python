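"""Domain types and statistics for chitosan chains.

Chitosan is modelled as a binary copolymer over the alphabet ``{A, D}``
(A = GlcNAc, the acetylated unit; D = GlcN, the deacetylated unit).
Sequences are written from the non-reducing end to the reducing end,
left to right.  This module provides the core containers
(:class:`ChitosanChain`, :class:`ChainEnsemble`) plus the empirical and
closed-form statistics built on them: the fraction of acetylation F_A,
dyad fractions and the deviation-from-randomness statistic P_sigma,
run-length ("block") profiles, chain-length moments, and the Bernoulli
(random-pattern) reference theory.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: residue codes used in the internal uint8 representation
D_CODE = 0
A_CODE = 1

_CHAR_FOR_CODE = {A_CODE: "A", D_CODE: "D"}
_CODE_FOR_CHAR = {"A": A_CODE, "D": D_CODE}


def encode_sequence(text: str) -> np.ndarray:
    """Encode an ``A``/``D`` string (case-insensitive) as a uint8 array."""
    up = text.upper()
    bad = set(up) - {"A", "D"}
    if bad:
        pos = next(i for i, c in enumerate(up) if c in bad)
        raise ValueError(
            f"invalid residue {text[pos]!r} at position {pos + 1}; alphabet is {{A, D}}"
        )
    return (np.frombuffer(up.encode("ascii"), dtype=np.uint8) == ord("A")).astype(np.uint8)


def decode_sequence(arr: np.ndarray) -> str:
    """Decode a uint8 residue array back to an ``A``/``D`` string."""
    out = np.where(np.asarray(arr, dtype=np.uint8) == A_CODE, ord("A"), ord("D"))
    return out.astype(np.uint8).tobytes().decode("ascii")


class ChitosanChain:
    """A single chitosan chain.

    Parameters
    ----------
    sequence:
        ``A``/``D`` string (case-insensitive) or an array of residue codes
        (``1`` = A = GlcNAc, ``0`` = D = GlcN).  Orientation is
        non-reducing end -> reducing end, left to right.
    id:
        Text label.
    meta:
        Optional key/value annotations (carried through FASTA headers).
    """

    __slots__ = ("residues", "id", "meta")

    def __init__(self, sequence, id: str = "chain", meta: Mapping[str, str] | None = None):
        if isinstance(sequence, str):
            arr = encode_sequence(sequence)
        else:
            arr = np.array(sequence, dtype=np.uint8, copy=True)
            if arr.ndim != 1:
                raise ValueError("sequence must be one-dimensional")
            if arr.size and not np.all((arr == A_CODE) | (arr == D_CODE)):
                raise ValueError("residue codes must be 0 (D) or 1 (A)")
        if arr.size < 1:
            raise ValueError("chain must contain at least one residue (DP >= 1)")
        arr.setflags(write=False)
        self.residues = arr
        self.id = str(id)
        self.meta = dict(meta) if meta else {}

    @property
    def dp(self) -> int:
        """Degree of polymerisation (number of monomers)."""
        return int(self.residues.size)

    @property
    def n_acetyl(self) -> int:
        """Number of A (GlcNAc) residues."""
        return int(self.residues.sum())

    @property
    def text(self) -> str:
        return decode_sequence(self.residues)

    def __len__(self) -> int:
        return self.dp

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChitosanChain):
            return NotImplemented
        return self.id == other.id and np.array_equal(self.residues, other.residues)

    def __repr__(self) -> str:
        shown = self.text if self.dp <= 40 else self.text[:37] + "..."
        return f"ChitosanChain(id={self.id!r}, dp={self.dp}, sequence={shown!r})"


class ChainEnsemble:
    """A weighted collection of chains: the in-silico chitosan sample.

    ``abundances`` are molar multiplicities (default 1 per chain, all > 0).
    """

    __slots__ = ("chains", "abundances")

    def __init__(self, chains: Sequence[ChitosanChain], abundances: Sequence[float] | None = None):
        chains = list(chains)
        if not chains:
            raise ValueError("empty ensemble")
        if abundances is None:
            ab = np.ones(len(chains), dtype=float)
        else:
            ab = np.asarray(abundances, dtype=float)
            if ab.shape != (len(chains),):
                raise ValueError("abundances must match the number of chains")
            if not np.all(ab > 0):
                raise ValueError("all abundances must be > 0")
        self.chains = chains
        self.abundances = ab

    def __len__(self) -> int:
        return len(self.chains)

    def __iter__(self):
        return iter(self.chains)

    @property
    def total_monomers(self) -> float:
        return float(sum(a * c.dp for c, a in zip(self.chains, self.abundances)))

    @property
    def total_acetyl(self) -> float:
        return float(sum(a * c.n_acetyl for c, a in zip(self.chains, self.abundances)))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChainEnsemble):
            return NotImplemented
        return (
            len(self) == len(other)
            and np.array_equal(self.abundances, other.abundances)
            and all(c == d for c, d in zip(self.chains, other.chains))
        )


# ---------------------------------------------------------------------------
# dyads


@dataclass(frozen=True)
class DyadStats:
    """Dyad fractions and the derived transition statistics.

    A dyad ``XY`` is an ordered nearest-neighbour pair read along the
    non-reducing -> reducing direction.  Derived quantities:

    * ``p_ad = F_AD / (F_AA + F_AD)``
    * ``p_da = F_DA / (F_DD + F_DA)``
    * ``p_sigma = p_ad + p_da`` (1 for a Bernoullian random pattern,
      < 1 block-wise, -> 2 alternating)

    A zero denominator (homopolymer limit) makes the corresponding term 0;
    a warning is logged.
    """

    f_aa: float
    f_ad: float
    f_da: float
    f_dd: float

    def __post_init__(self):
        vals = (self.f_aa, self.f_ad, self.f_da, self.f_dd)
        if any(v < 0 for v in vals):
            raise ValueError("dyad fractions must be >= 0")
        total = sum(vals)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"dyad fractions must sum to 1, got {total}")

    @classmethod
    def from_counts(cls, c_aa: float, c_ad: float, c_da: float, c_dd: float) -> "DyadStats":
        total = c_aa + c_ad + c_da + c_dd
        if total <= 0:
            raise ValueError("no dyads")
        return cls(c_aa / total, c_ad / total, c_da / total, c_dd / total)

    @property
    def p_ad(self) -> float:
        denom = self.f_aa + self.f_ad
        if denom == 0:
            logger.warning("P_AD denominator zero (no A-initial dyads); defining P_AD = 0")
            return 0.0
        return self.f_ad / denom

    @property
    def p_da(self) -> float:
        denom = self.f_dd + self.f_da
        if denom == 0:
            logger.warning("P_DA denominator zero (no D-initial dyads); defining P_DA = 0")
            return 0.0
        return self.f_da / denom

    @property
    def p_sigma(self) -> float:
        return self.p_ad + self.p_da

    @property
    def fa(self) -> float:
        """Dyad-based fraction of acetylation, ``F_AA + F_AD``."""
        return self.f_aa + self.f_ad

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.f_aa, self.f_ad, self.f_da, self.f_dd)


def compute_fa(ensemble: ChainEnsemble) -> float:
    """Abundance-weighted molar fraction of acetylation of an ensemble."""
    total = ensemble.total_monomers
    if total <= 0:  # unreachable given ensemble invariants; keep the guard
        raise ValueError("empty ensemble")
    return ensemble.total_acetyl / total


def dyad_fractions(ensemble: ChainEnsemble) -> DyadStats:
    """Pool dyad counts over all chains (never across chain boundaries).

    Each chain of DP >= 2 contributes DP - 1 dyads, weighted by its
    abundance.  Raises ``ValueError("no dyads")`` if every chain has DP 1.
    """
    counts = np.zeros(4, dtype=float)  # index = 2*first + second
    for chain, ab in zip(ensemble.chains, ensemble.abundances):
        x = chain.residues
        if x.size < 2:
            continue
        codes = 2 * x[:-1].astype(np.intp) + x[1:]
        counts += ab * np.bincount(codes, minlength=4)
    if counts.sum() == 0:
        raise ValueError("no dyads")
    # codes: 0 = DD, 1 = DA, 2 = AD, 3 = AA
    return DyadStats.from_counts(counts[3], counts[2], counts[1], counts[0])


def p_sigma(dyads: DyadStats) -> float:
    """P_sigma = F_AD/(F_AA+F_AD) + F_DA/(F_DD+F_DA).

    Raises if both denominators vanish (degenerate composition).
    """
    if (dyads.f_aa + dyads.f_ad) == 0 and (dyads.f_dd + dyads.f_da) == 0:
        raise ValueError("degenerate composition")
    return dyads.p_sigma


# ---------------------------------------------------------------------------
# blocks


@dataclass
class BlockProfile:
    """Molar counts of maximal A- and D-runs ("blocks") by size.

    ``a_blocks``/``d_blocks`` hold every counted block.  The subsets
    ``a_terminal``/``d_terminal`` record blocks truncated by the reducing
    chain end (right-censored); they are excluded from averages by default.
    """

    a_blocks: Counter = field(default_factory=Counter)
    d_blocks: Counter = field(default_factory=Counter)
    a_terminal: Counter = field(default_factory=Counter)
    d_terminal: Counter = field(default_factory=Counter)

    def add(self, block: str, size: int, count: float = 1.0, terminal: bool = False) -> None:
        if size < 1:
            raise ValueError("block size must be >= 1")
        if count < 0:
            raise ValueError("block count must be >= 0")
        target = self.a_blocks if block == "A" else self.d_blocks
        target[size] += count
        if terminal:
            term = self.a_terminal if block == "A" else self.d_terminal
            term[size] += count

    def counts(self, block: str, include_terminal: bool = False) -> dict[int, float]:
        full = self.a_blocks if block == "A" else self.d_blocks
        if include_terminal:
            return {s: c for s, c in sorted(full.items()) if c > 0}
        term = self.a_terminal if block == "A" else self.d_terminal
        out = {}
        for s, c in sorted(full.items()):
            kept = c - term.get(s, 0.0)
            if kept > 0:
                out[s] = kept
        return out

    @property
    def total_monomers(self) -> float:
        return float(
            sum(s * c for s, c in self.a_blocks.items())
            + sum(s * c for s, c in self.d_blocks.items())
        )

    def number_average(self, block: str, include_terminal: bool = False) -> float:
        c = self.counts(block, include_terminal)
        n = sum(c.values())
        if n == 0:
            raise ValueError(f"empty {block}-block profile")
        return sum(s * v for s, v in c.items()) / n

    def weight_average(self, block: str, include_terminal: bool = False) -> float:
        c = self.counts(block, include_terminal)
        w = sum(s * v for s, v in c.items())
        if w == 0:
            raise ValueError(f"empty {block}-block profile")
        return sum(s * s * v for s, v in c.items()) / w

    def frequencies(self, block: str, include_terminal: bool = False) -> dict[int, float]:
        c = self.counts(block, include_terminal)
        n = sum(c.values())
        if n == 0:
            return {}
        return {s: v / n for s, v in c.items()}


def _runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Run-length decomposition: list of (residue_code, run_length)."""
    if x.size == 0:
        return []
    change = np.flatnonzero(np.diff(x)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [x.size]))
    return [(int(x[s]), int(e - s)) for s, e in zip(starts, ends)]


def block_profile_from_sequences(ensemble: ChainEnsemble) -> BlockProfile:
    """Direct run-length decomposition of an ensemble.

    Every maximal run of identical residues is counted once (abundance
    weighted).  The last run of each chain touches the reducing end and is
    flagged terminal (right-censored).  Serves as the brute-force oracle
    for fingerprint-based block inference.
    """
    profile = BlockProfile()
    for chain, ab in zip(ensemble.chains, ensemble.abundances):
        runs = _runs(chain.residues)
        for i, (code, length) in enumerate(runs):
            terminal = i == len(runs) - 1
            profile.add(_CHAR_FOR_CODE[code], length, ab, terminal=terminal)
    return profile


# ---------------------------------------------------------------------------
# chain-length moments


@dataclass(frozen=True)
class DPMoments:
    """Number-/weight-average DP and the dispersity ``Đ = DPw / DPn``.

    Monomer mass is treated as 1, so the dispersity is that of the DP
    distribution (documented approximation; A and D differ by 42 Da).
    """

    dpn: float
    dpw: float

    def __post_init__(self):
        if self.dpn < 1 or self.dpw < self.dpn - 1e-12:
            raise ValueError("require DPw >= DPn >= 1")

    @property
    def dispersity(self) -> float:
        return self.dpw / self.dpn


def dp_moments(ensemble: ChainEnsemble) -> DPMoments:
    """Abundance-weighted DP moments of an ensemble."""
    dps = np.array([c.dp for c in ensemble.chains], dtype=float)
    ab = ensemble.abundances
    dpn = float(np.sum(ab * dps) / np.sum(ab))
    dpw = float(np.sum(ab * dps**2) / np.sum(ab * dps))
    return DPMoments(dpn=dpn, dpw=dpw)


# ---------------------------------------------------------------------------
# Bernoulli (random-pattern) theory


@dataclass(frozen=True)
class BernoulliTheory:
    """Closed-form statistics of a Bernoullian random acetylation pattern.

    Run lengths are geometric: an A-run continues with probability ``fa``
    (mean ``1/(1-fa)``), a D-run with probability ``1-fa`` (mean ``1/fa``).
    """

    fa: float

    @property
    def dyads(self) -> DyadStats:
        fa, fd = self.fa, 1.0 - self.fa
        return DyadStats(fa * fa, fa * fd, fd * fa, fd * fd)

    @property
    def mean_a_block(self) -> float:
        return 1.0 / (1.0 - self.fa)

    @property
    def mean_d_block(self) -> float:
        return 1.0 / self.fa

    def a_run_pmf(self, k: int | np.ndarray):
        """P(A-run length = k) = fa^(k-1) (1-fa)."""
        k = np.asarray(k)
        return np.where(k >= 1, self.fa ** (k - 1) * (1 - self.fa), 0.0)

    def d_run_pmf(self, k: int | np.ndarray):
        """P(D-run length = k) = (1-fa)^(k-1) fa."""
        k = np.asarray(k)
        return np.where(k >= 1, (1 - self.fa) ** (k - 1) * self.fa, 0.0)

    def block_frequency(self, k: int, block: str = "A", exact: bool = False) -> float:
        """Per-monomer frequency of a block of ``k`` identical residues.

        The default is the simple estimate ``p^k`` (``p = fa`` for A-blocks,
        ``1 - fa`` for D-blocks): the probability that a given monomer
        starts a run of at least ``k`` such residues.  With ``exact=True``
        the interior exact-block-start probability ``(1-p)^2 p^k`` is
        returned instead (both boundaries required to differ).
        """
        p = self.fa if block == "A" else 1.0 - self.fa
        if exact:
            return (1.0 - p) ** 2 * p**k
        return p**k

    def expected_blocks_per_polymer(self, k: int, dp: int, block: str = "A", exact: bool = False) -> float:
        """Expected number of ``k``-blocks in a polymer of length ``dp``."""
        return dp * self.block_frequency(k, block=block, exact=exact)


def bernoulli_theory(fa: float) -> BernoulliTheory:
    """Reference statistics for a random pattern at fraction ``fa`` in (0, 1)."""
    if not 0.0 < fa < 1.0:
        raise ValueError("fa must lie strictly between 0 and 1")
    return BernoulliTheory(fa=fa)
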