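"""Readers, writers and minimal normalization for the pipeline formats.

Expression data travel as long-format TSV/CSV with the mandatory header
``sample  gene  spot  replicate  value``; pathway gene sets as GMT
(name TAB description TAB gene...). Output tables are TSV with a ``#``
header comment naming the units of every quantity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, require_valid

__all__ = [
    "read_expression",
    "write_expression",
    "normalize_to_median",
    "read_gmt",
    "write_gmt",
    "write_table",
]


def read_expression(path: str | Path, replicas_per_group: int | None = None) -> ExpressionDataset:
    """Read a long-format expression table and validate it.

    Delimiter is inferred from the extension (.csv -> comma, else tab).
    Fails fast on missing columns, duplicate (sample, gene, spot, replicate)
    keys, non-numeric values, or any dataset-invariant violation.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, comment="#")
    missing = {"sample", "gene", "spot", "replicate", "value"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    bad = pd.to_numeric(frame["value"], errors="coerce").isna() & frame["value"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header line + 1-based
        raise ValueError(f"{path}: non-numeric value at line {line}")
    frame["value"] = frame["value"].astype(float)
    try:
        dataset = ExpressionDataset.from_long(frame, replicas_per_group=replicas_per_group)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
    require_valid(dataset)
    return dataset


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset as long-format TSV (round-trips with read_expression)."""
    dataset.to_long().to_csv(path, sep="\t", index=False)


def normalize_to_median(dataset: ExpressionDataset) -> ExpressionDataset:
    """Scale every array so its median spot value is 1.

    Each (group, replicate) column — one physical array — is divided by the
    median of its spot values, expressing everything in multiples of the
    median gene. Idempotent up to floating-point tolerance.
    """
    values = {}
    for grp, vals in dataset.values.items():
        med = np.median(vals, axis=0)
        if np.any(med <= 0):
            raise ValueError(f"group {grp!r}: array with non-positive median")
        values[grp] = vals / med
    return ExpressionDataset(
        groups=list(dataset.groups),
        genes=list(dataset.genes),
        spot_ids=[list(s) for s in dataset.spot_ids],
        values=values,
        replicas_per_group=dataset.replicas_per_group,
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: ordered mapping name -> de-duplicated gene list."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {ln}: GMT needs name, description, >=1 gene")
            name = fields[0]
            sets[name] = list(dict.fromkeys(g for g in fields[2:] if g))
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_table(frame: pd.DataFrame, path: str | Path, header_comment: str | None = None,
                index: bool = True) -> None:
    """Write a TSV with an optional '#' units/caveat header comment."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index)
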