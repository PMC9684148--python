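"""FASTA I/O over the two-letter chitosan alphabet {A, D}.

Headers carry the chain id plus optional ``key=value`` metadata tokens
(e.g. ``fa=0.33 pa=markov seed=7``).  Reading is case-insensitive;
writing is canonical (upper-case residues, 60-column wrapping), so
``write . read`` is the identity on canonicalised records.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO

from ..polymer_core import ChainEnsemble, ChitosanChain, encode_sequence

__all__ = ["read_sequences", "write_sequences"]

_WRAP = 60


def read_sequences(path: str | os.PathLike) -> ChainEnsemble:
    """Read an {A, D} FASTA file into a :class:`ChainEnsemble`.

    Invalid characters raise with the offending record and position.
    A chain abundance may be given as an ``abundance=`` header token.
    """
    chains: list[ChitosanChain] = []
    abundances: list[float] = []
    for record in SeqIO.parse(os.fspath(path), "fasta"):
        meta = {}
        for token in record.description.split()[1:]:
            if "=" in token:
                key, _, value = token.partition("=")
                meta[key] = value
        try:
            arr = encode_sequence(str(record.seq))
        except ValueError as exc:
            raise ValueError(f"record {record.id!r}: {exc}") from None
        abundance = float(meta.pop("abundance", 1.0))
        chains.append(ChitosanChain(arr, id=record.id, meta=meta))
        abundances.append(abundance)
    if not chains:
        raise ValueError(f"no FASTA records found in {os.fspath(path)!r}")
    return ChainEnsemble(chains, abundances)


def _header(chain: ChitosanChain, abundance: float) -> str:
    tokens = [chain.id]
    for key, value in chain.meta.items():
        tokens.append(f"{key}={value}")
    if abundance != 1.0:
        tokens.append(f"abundance={abundance:g}")
    return " ".join(tokens)


def write_sequences(ensemble: ChainEnsemble, path: str | os.PathLike) -> None:
    """Write an ensemble to canonical FASTA."""
    with open(path, "w") as fh:
        for chain, abundance in zip(ensemble.chains, ensemble.abundances):
            fh.write(f">{_header(chain, abundance)}\n")
            text = chain.text
            for i in range(0, len(text), _WRAP):
                fh.write(text[i : i + _WRAP] + "\n")
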