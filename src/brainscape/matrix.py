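"""Core containers: expression matrices with declared units and gene universes.

An :class:`ExpressionMatrix` is a thin wrapper around a genes x samples
:class:`pandas.DataFrame` that carries the unit of its values through the
pipeline (FPKM -> TPM -> log2TPM -> log2TPM_corrected).  Stages check the
unit of their input so that, e.g., batch correction cannot silently run on
raw FPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Units an expression matrix may carry, in pipeline order.
UNITS = ("FPKM", "TPM", "log2TPM", "log2TPM_corrected")

#: Column sum every TPM sample must hit.
TPM_TOTAL = 1e6


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared unit.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as the columns.  Identifiers are opaque strings matched exactly.
    unit
        One of :data:`UNITS`.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_unit(self, *units: str) -> None:
        if self.unit not in units:
            raise ValueError(
                f"matrix has unit {self.unit!r}; this operation requires {units}"
            )

    def copy_with(self, values: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, unit=unit)

    def validate_tpm(self, rtol: float = 1e-6) -> None:
        """Check the TPM invariant: every sample column sums to 1e6."""
        self.require_unit("TPM")
        sums = self.values.sum(axis=0).to_numpy()
        if not np.allclose(sums, TPM_TOTAL, rtol=rtol):
            bad = np.flatnonzero(~np.isclose(sums, TPM_TOTAL, rtol=rtol))
            names = [self.sample_ids[i] for i in bad[:5]]
            raise ValueError(f"TPM columns do not sum to 1e6: {names}")


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered, duplicate-free gene identifiers defining the common analysis set."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene universe is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene universe contains duplicates")

    @classmethod
    def from_iterable(cls, genes) -> "GeneUniverse":
        return cls(tuple(genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class SampleMetadata:
    """Per-sample annotations: cohort, disease, subtype, sample type, survival.

    Wraps a DataFrame indexed by ``sample_id`` with (at least) the columns
    ``patient_id``, ``dataset``, ``disease``, ``subtype``, ``sample_type``,
    ``age``, ``sex``, ``time``, ``event``.  ``sample_type`` is restricted to
    the vocabulary {primary, recurrent, secondary, normal}.
    """

    table: pd.DataFrame

    SAMPLE_TYPES = ("primary", "recurrent", "secondary", "normal")
    REQUIRED = ("patient_id", "dataset", "subtype", "sample_type")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        bad = ~self.table["sample_type"].isin(self.SAMPLE_TYPES)
        if bad.any():
            rows = self.table.index[bad].tolist()
            raise ValueError(
                f"sample_type outside vocabulary {self.SAMPLE_TYPES} for: {rows[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())
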