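"""Core expression-data container shared by every analysis stage.

The unit of data is a normalized expression value ``a(group, gene, spot,
replicate)``: one microarray gene may be probed redundantly by several spots
(``Ri`` per gene, identical across sample groups because the platform is
fixed), and every sample group is profiled on a fixed number of biological
replicas (four in the motivating studies).

Internally values are stored per group as a dense ``(total_spots, J)`` float
array in CSR-like layout: the spots of gene ``i`` occupy rows
``spot_offsets[i]:spot_offsets[i+1]``. This keeps the per-spot and per-gene
reductions used by the fabric statistics fully vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SpotSummary",
    "validate_dataset",
    "ValidationError",
]

#: values at or below this floor are rejected by validation (log2 is taken
#: downstream, so clamping would silently distort the statistics)
VALUE_FLOOR = 1e-6


class ValidationError(ValueError):
    """Raised when a dataset failing validation is passed downstream."""


@dataclass
class ExpressionDataset:
    """Replicated, spot-redundant expression values for several sample groups.

    Parameters
    ----------
    groups : list of str
        Sample-group labels, e.g. ``["Z", "P", "Q", "M"]`` (one normal tissue
        plus cancer nodules).
    genes : list of str
        Gene symbols. Probes mapping to the same symbol are treated as
        redundant *spots* of that gene.
    spot_ids : list of list of str
        Per-gene spot identifiers; ``len(spot_ids[i]) == Ri``.
    values : dict of str -> ndarray
        Per group, a ``(total_spots, J)`` array of strictly positive
        normalized intensities; row layout follows ``spot_offsets``.
    replicas_per_group : int
        Number of biological replicas ``J`` (the same for every group).
    """

    groups: list[str]
    genes: list[str]
    spot_ids: list[list[str]]
    values: dict[str, np.ndarray]
    replicas_per_group: int = 4
    spot_offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        counts = np.array([len(s) for s in self.spot_ids], dtype=np.int64)
        self.spot_offsets = np.concatenate([[0], np.cumsum(counts)])
        self.values = {g: np.asarray(v, dtype=float) for g, v in self.values.items()}
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    # -- basic geometry ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def total_spots(self) -> int:
        return int(self.spot_offsets[-1])

    def spot_counts(self) -> np.ndarray:
        """Per-gene redundant spot count ``Ri``."""
        return np.diff(self.spot_offsets)

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def gene_rows(self, gene: str) -> slice:
        i = self.gene_index(gene)
        return slice(int(self.spot_offsets[i]), int(self.spot_offsets[i + 1]))

    def group_values(self, group: str) -> np.ndarray:
        try:
            return self.values[group]
        except KeyError:
            raise KeyError(f"unknown sample group {group!r}") from None

    def gene_values(self, group: str, gene: str) -> np.ndarray:
        """``(Ri, J)`` block of gene values in one group."""
        return self.group_values(group)[self.gene_rows(gene)]

    # -- conversion --------------------------------------------------------
    @classmethod
    def from_long(cls, frame: pd.DataFrame, replicas_per_group: int | None = None) -> "ExpressionDataset":
        """Build a dataset from a long-format table.

        Required columns: ``sample, gene, spot, replicate, value``. Each
        (sample, gene, spot) must carry exactly ``replicas_per_group`` rows;
        violations surface in :func:`validate_dataset`, which is the caller's
        responsibility to run (the I/O layer does it automatically).
        """
        required = {"sample", "gene", "spot", "replicate", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        dup = frame.duplicated(["sample", "gene", "spot", "replicate"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise ValueError(
                "duplicate (sample, gene, spot, replicate) row: "
                f"({row['sample']}, {row['gene']}, {row['spot']}, {row['replicate']})"
            )
        groups = frame["sample"].astype(str).unique().tolist()  # first-appearance order
        if replicas_per_group is None:
            replicas_per_group = int(frame["replicate"].nunique())

        # Gene/spot universe from the union over groups; order deterministic.
        spot_table = (
            frame[["gene", "spot"]].astype(str).drop_duplicates().sort_values(["gene", "spot"])
        )
        genes = spot_table["gene"].unique().tolist()
        spot_ids = [spot_table.loc[spot_table["gene"] == g, "spot"].tolist() for g in genes]

        spot_key = pd.MultiIndex.from_arrays(
            [spot_table["gene"], spot_table["spot"]]
        )
        row_of = pd.Series(np.arange(len(spot_key)), index=spot_key)
        total = len(spot_key)

        rep_labels = sorted(frame["replicate"].unique())
        col_of = {r: j for j, r in enumerate(rep_labels)}

        values: dict[str, np.ndarray] = {}
        for grp in groups:
            sub = frame[frame["sample"].astype(str) == grp]
            arr = np.full((total, max(replicas_per_group, len(rep_labels))), np.nan)
            rows = row_of[
                pd.MultiIndex.from_arrays([sub["gene"].astype(str), sub["spot"].astype(str)])
            ].to_numpy()
            cols = sub["replicate"].map(col_of).to_numpy()
            arr[rows, cols] = sub["value"].to_numpy(dtype=float)
            values[grp] = arr[:, :replicas_per_group] if len(rep_labels) <= replicas_per_group else arr
        return cls(
            groups=groups,
            genes=genes,
            spot_ids=spot_ids,
            values=values,
            replicas_per_group=replicas_per_group,
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format table with columns sample, gene, spot, replicate, value."""
        counts = self.spot_counts()
        gene_col = np.repeat(self.genes, counts)
        spot_col = [s for spots in self.spot_ids for s in spots]
        records = []
        for grp in self.groups:
            vals = self.values[grp]
            for j in range(self.replicas_per_group):
                records.append(
                    pd.DataFrame(
                        {
                            "sample": grp,
                            "gene": gene_col,
                            "spot": spot_col,
                            "replicate": j + 1,
                            "value": vals[:, j],
                        }
                    )
                )
        return pd.concat(records, ignore_index=True)


@dataclass
class SpotSummary:
    """Per-spot replicate mean and standard deviation for one group.

    ``mu`` and ``s`` are ``(total_spots,)`` arrays aligned with the dataset's
    spot layout; ``s`` uses the n-1 (sample) denominator.
    """

    mu: np.ndarray
    s: np.ndarray

    @classmethod
    def from_dataset(cls, dataset: ExpressionDataset, group: str) -> "SpotSummary":
        vals = dataset.group_values(group)
        return cls(mu=vals.mean(axis=1), s=vals.std(axis=1, ddof=1))


def validate_dataset(dataset: ExpressionDataset, value_floor: float = VALUE_FLOOR) -> list[str]:
    """Check dataset invariants; return a list of human-readable violations.

    An empty list means the dataset is accepted by every downstream stage.
    The check is side-effect free and idempotent.
    """
    report: list[str] = []
    if dataset.replicas_per_group < 1:
        report.append(f"replicas_per_group must be >= 1, got {dataset.replicas_per_group}")
    if len(set(dataset.genes)) != len(dataset.genes):
        report.append("duplicate gene symbols")
    counts = dataset.spot_counts()
    if (counts < 1).any():
        bad = [dataset.genes[i] for i in np.flatnonzero(counts < 1)]
        report.append(f"genes with zero spots: {bad[:5]}")
    for grp in dataset.groups:
        if grp not in dataset.values:
            report.append(f"group {grp!r} has no value block")
            continue
        vals = dataset.values[grp]
        if vals.shape != (dataset.total_spots, dataset.replicas_per_group):
            report.append(
                f"group {grp!r}: value block shape {vals.shape} != "
                f"({dataset.total_spots}, {dataset.replicas_per_group}) — spot-count "
                "mismatch or wrong replica count"
            )
            continue
        nan_rows = np.flatnonzero(np.isnan(vals).any(axis=1))
        for r in nan_rows[:10]:
            g = dataset.genes[int(np.searchsorted(dataset.spot_offsets, r, side="right")) - 1]
            report.append(f"group {grp!r}, gene {g!r}: missing replica value (spot row {r})")
        ok = ~np.isnan(vals)
        if (vals[ok] <= value_floor).any():
            n_bad = int((vals[ok] <= value_floor).sum())
            report.append(
                f"group {grp!r}: {n_bad} non-positive value(s) at or below floor {value_floor}"
            )
    extra = set(dataset.values) - set(dataset.groups)
    if extra:
        report.append(f"value blocks for unlisted groups: {sorted(extra)}")
    return report


def require_valid(dataset: ExpressionDataset) -> None:
    """Raise :class:`ValidationError` if the dataset fails validation."""
    report = validate_dataset(dataset)
    if report:
        raise ValidationError("; ".join(report[:5]))
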