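"""Product-table CSV I/O.

Schema: columns ``dp, n_acetyl, n_deacetyl, end_flag, abundance`` plus an
optional ``sequence`` column; provenance is carried as ``# key: value``
comment lines ahead of the header and re-validated on read when the
substrate totals are present.
"""

from __future__ import annotations

import ast
import os

import pandas as pd

from ..digestion import ProductRecord, ProductTable

__all__ = ["read_products", "write_products"]

_COLUMNS = ["dp", "n_acetyl", "n_deacetyl", "end_flag", "abundance", "sequence"]


def write_products(table: ProductTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for key, value in table.provenance.items():
            fh.write(f"# {key}: {value!r}\n")
        has_seq = any(r.sequence is not None for r in table.records)
        cols = _COLUMNS if has_seq else _COLUMNS[:-1]
        fh.write(",".join(cols) + "\n")
        for r in table.records:
            row = [str(r.dp), str(r.na), str(r.nd), r.end_flag, f"{r.abundance:.10g}"]
            if has_seq:
                row.append(r.sequence or "")
            fh.write(",".join(row) + "\n")


def read_products(path: str | os.PathLike) -> ProductTable:
    """Read a product CSV, validating each row and the conservation totals."""
    provenance = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            value = value.strip()
            try:
                provenance[key.strip()] = ast.literal_eval(value)
            except (ValueError, SyntaxError):
                provenance[key.strip()] = value
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"product CSV missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        dp, na, nd = int(row.dp), int(row.n_acetyl), int(row.n_deacetyl)
        if dp != na + nd:
            raise ValueError(f"row {i}: dp ({dp}) != n_acetyl + n_deacetyl ({na} + {nd})")
        abundance = float(row.abundance)
        if abundance <= 0:
            raise ValueError(f"row {i}: abundance must be > 0, got {abundance}")
        seq = getattr(row, "sequence", None)
        if seq is not None and (not isinstance(seq, str) or seq == ""):
            seq = None
        try:
            records.append(
                ProductRecord(dp=dp, na=na, nd=nd, end_flag=str(row.end_flag),
                              abundance=abundance, sequence=seq)
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
    table = ProductTable(records, provenance=provenance)
    if "substrate_total_monomers" in provenance and "substrate_total_acetyl" in provenance:
        table.validate_conservation(
            float(provenance["substrate_total_monomers"]),
            float(provenance["substrate_total_acetyl"]),
        )
    return table
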