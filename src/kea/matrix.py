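"""Phosphosite-by-sample expression matrix with design and stage tracking."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

STAGES = ("raw", "filtered", "normalized", "imputed")


class StageError(ValueError):
    """Raised when a processing step is applied at the wrong stage."""


@dataclass
class ExpressionMatrix:
    """Unique phosphosites x samples intensity matrix.

    Attributes
    ----------
    data
        DataFrame indexed by site key (``GENE_Y207_m1``) with one column per
        sample.  Values are linear intensities at stage ``raw`` and log2
        intensities afterwards; missing values are NaN.
    design
        DataFrame indexed by sample id with at least a ``condition`` column.
    row_meta
        Per-site annotations (gene, residue, position, multiplicity,
        localization probability, contaminant/reverse provenance).
    stage
        One of ``raw``, ``filtered``, ``normalized``, ``imputed``; stages
        only move forward.
    scale
        ``linear`` or ``log2``.
    observed
        Boolean mask of cells that were measured (set at assembly, carried
        unchanged through every stage so imputation provenance is never
        lost).
    """

    data: pd.DataFrame
    design: pd.DataFrame
    row_meta: pd.DataFrame
    stage: str = "raw"
    scale: str = "linear"
    observed: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        if not self.data.index.is_unique:
            raise ValueError("site keys must be unique")
        missing_design = set(self.data.columns) - set(self.design.index)
        if missing_design:
            raise ValueError(f"samples missing from design: {sorted(missing_design)}")
        if self.observed is None:
            self.observed = self.data.notna()

    # -- stage bookkeeping -------------------------------------------------

    def advance(self, new_stage: str, **changes) -> "ExpressionMatrix":
        """Return a copy at ``new_stage``; transitions only move forward."""
        if STAGES.index(new_stage) < STAGES.index(self.stage):
            raise StageError(f"cannot move from {self.stage!r} back to {new_stage!r}")
        return replace(self, stage=new_stage, **changes)

    def with_data(self, data: pd.DataFrame, **changes) -> "ExpressionMatrix":
        out = replace(self, data=data, **changes)
        out.observed = self.observed.loc[data.index, data.columns]
        return out

    # -- convenience -------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.design.loc[self.samples, "condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        mask = self.design.loc[self.samples, "condition"] == condition
        return [s for s, keep in zip(self.samples, mask) if keep]

    def imputed_fraction(self) -> pd.Series:
        """Per-site fraction of cells that were filled in rather than measured."""
        filled = self.data.notna() & ~self.observed.loc[self.data.index, self.data.columns]
        return filled.sum(axis=1) / self.data.shape[1]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="site")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({self.data.shape[0]} sites x {self.data.shape[1]} samples, "
            f"stage={self.stage}, scale={self.scale})"
        )
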