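"""Reading MaxQuant Phospho (STY)Sites tables into the site/sample matrix.

The parser targets the tab-separated ``Phospho (STY)Sites.txt`` layout:
site rows carry a localization probability, contaminant/reverse flags
(``+`` = flagged) and, per sample, up to three ``Intensity <sample>___k``
columns, one per phospho-multiplicity.  Intensities of 0 mean the site was
not quantified and are read as missing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

VALID_RESIDUES = frozenset("STY")

REQUIRED_COLUMNS = (
    "Proteins",
    "Gene names",
    "Amino acid",
    "Position",
    "Localization prob",
    "Reverse",
    "Potential contaminant",
)

_INTENSITY_RE = re.compile(r"^Intensity (?P<sample>.+)___(?P<mult>[123])$")


class FormatError(ValueError):
    """Input file does not match the expected MaxQuant dialect."""


@dataclass
class PhosphoSiteRecord:
    """One localized phosphosite at one multiplicity, with its intensities."""

    protein_id: str
    gene_symbol: str
    residue: str
    position: int
    localization_prob: float
    multiplicity: int
    is_reverse: bool
    is_contaminant: bool
    intensities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residue not in VALID_RESIDUES:
            raise ValueError(f"residue must be S, T or Y, got {self.residue!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if not 0.0 <= self.localization_prob <= 1.0:
            raise ValueError("localization probability must lie in [0, 1]")
        if self.multiplicity not in (1, 2, 3):
            raise ValueError("multiplicity must be 1, 2 or 3")

    @property
    def site_key(self) -> str:
        return make_site_key(
            self.gene_symbol, self.residue, self.position, self.multiplicity,
            protein_id=self.protein_id,
        )


def make_site_key(
    gene: str,
    residue: str,
    position: int,
    multiplicity: int | None = None,
    protein_id: str = "",
) -> str:
    """Canonical site key ``GENE_<residue><position>[_m<k>]``.

    The gene symbol is uppercased; when it is empty the protein accession is
    used instead.  The multiplicity suffix is appended when given, keeping
    singly/doubly/triply phosphorylated forms of one residue distinct.
    """
    if residue not in VALID_RESIDUES:
        raise ValueError(f"residue must be S, T or Y, got {residue!r}")
    name = (gene or "").strip() or (protein_id or "").strip()
    if not name:
        raise ValueError("both gene symbol and protein id are empty")
    key = f"{name.upper()}_{residue}{int(position)}"
    if multiplicity is not None:
        key += f"_m{int(multiplicity)}"
    return key


def base_site_key(key: str) -> str:
    """Strip the multiplicity suffix: ``CRKL_Y207_m1`` -> ``CRKL_Y207``."""
    return re.sub(r"_m[123]$", "", key)


def _leading(value: str) -> str:
    """First entry of a ';'-separated MaxQuant group column."""
    return str(value).split(";")[0].strip() if pd.notna(value) else ""


def parse_phosphosty(
    path: str | Path | list[str | Path],
    design: dict[str, str] | pd.DataFrame,
) -> list[PhosphoSiteRecord]:
    """Parse one or more MaxQuant phosphosite tables into site records.

    ``path`` may be a list of fraction files for the same samples; they are
    parsed separately and their records concatenated (matrix assembly then
    sums intensities of identical site keys, which merges fractions).

    One record is emitted per (site row, multiplicity) pair that has at
    least one positive intensity.  Zeros are read as missing.  Samples
    named in the design but absent from the header raise :class:`FormatError`.
    """
    paths = path if isinstance(path, (list, tuple)) else [path]
    sample_ids = _design_samples(design)
    records: list[PhosphoSiteRecord] = []
    for p in paths:
        records.extend(_parse_one(Path(p), sample_ids))
    return records


def _design_samples(design) -> list[str]:
    if isinstance(design, pd.DataFrame):
        return list(design.index)
    return list(design)


def _parse_one(path: Path, sample_ids: list[str]) -> list[PhosphoSiteRecord]:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if table.empty:
        raise FormatError(f"{path}: no data rows")
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")

    intensity_cols: dict[tuple[str, int], str] = {}
    for col in table.columns:
        m = _INTENSITY_RE.match(col)
        if m:
            intensity_cols[(m.group("sample"), int(m.group("mult")))] = col
    header_samples = {s for s, _ in intensity_cols}
    absent = [s for s in sample_ids if s not in header_samples]
    if absent:
        raise FormatError(f"{path}: design samples not found in header: {absent}")
    multiplicities = sorted({k for _, k in intensity_cols})

    records: list[PhosphoSiteRecord] = []
    for row in table.itertuples(index=False):
        rowd = dict(zip(table.columns, row))
        residue = str(rowd["Amino acid"]).strip()
        try:
            position = int(float(rowd["Position"]))
            loc_prob = float(rowd["Localization prob"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: malformed Position/Localization prob in row {rowd!r}"
            ) from None
        gene = _leading(rowd["Gene names"])
        protein = _leading(rowd["Proteins"])
        is_rev = str(rowd["Reverse"]).strip() == "+"
        is_con = str(rowd["Potential contaminant"]).strip() == "+"
        for mult in multiplicities:
            intens: dict[str, float] = {}
            any_positive = False
            for s in sample_ids:
                col = intensity_cols.get((s, mult))
                raw = rowd.get(col, "") if col else ""
                try:
                    value = float(raw) if str(raw).strip() != "" else 0.0
                except ValueError:
                    value = 0.0
                if value > 0:
                    intens[s] = value
                    any_positive = True
                else:
                    intens[s] = np.nan
            if any_positive:
                records.append(
                    PhosphoSiteRecord(
                        protein_id=protein,
                        gene_symbol=gene,
                        residue=residue,
                        position=position,
                        localization_prob=loc_prob,
                        multiplicity=mult,
                        is_reverse=is_rev,
                        is_contaminant=is_con,
                        intensities=intens,
                    )
                )
    return records


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample->condition design CSV with columns sample,condition[,replicate]."""
    design = pd.read_csv(path)
    for col in ("sample", "condition"):
        if col not in design.columns:
            raise FormatError(f"{path}: design table missing column {col!r}")
    return design.set_index("sample")


def assemble_matrix(
    records: list[PhosphoSiteRecord],
    design: dict[str, str] | pd.DataFrame,
    merge_multiplicity: bool = False,
) -> ExpressionMatrix:
    """Collapse records to unique site keys and build the raw intensity matrix.

    Records mapping to the same key (e.g. fraction files of one sample) have
    their intensities summed on the linear scale, preserving total ion
    signal.  Flags are OR-combined and the best localization probability is
    kept.  Values stay linear; the stage is ``raw``.
    """
    if not records:
        raise ValueError("no records to assemble")
    if isinstance(design, pd.DataFrame):
        design_df = design.copy()
    else:
        design_df = pd.DataFrame(
            {"condition": pd.Series(design, dtype=object)}
        ).rename_axis("sample")
    samples = list(design_df.index)

    by_key: dict[str, dict] = {}
    for rec in records:
        key = make_site_key(
            rec.gene_symbol, rec.residue, rec.position,
            None if merge_multiplicity else rec.multiplicity,
            protein_id=rec.protein_id,
        )
        slot = by_key.setdefault(
            key,
            {
                "gene": rec.gene_symbol or rec.protein_id,
                "protein": rec.protein_id,
                "residue": rec.residue,
                "position": rec.position,
                "multiplicity": 0 if merge_multiplicity else rec.multiplicity,
                "localization_prob": rec.localization_prob,
                "is_reverse": rec.is_reverse,
                "is_contaminant": rec.is_contaminant,
                "intensities": {s: np.nan for s in samples},
            },
        )
        slot["localization_prob"] = max(slot["localization_prob"], rec.localization_prob)
        slot["is_reverse"] = slot["is_reverse"] or rec.is_reverse
        slot["is_contaminant"] = slot["is_contaminant"] or rec.is_contaminant
        for s in samples:
            v = rec.intensities.get(s, np.nan)
            if not np.isnan(v):
                prev = slot["intensities"][s]
                slot["intensities"][s] = v if np.isnan(prev) else prev + v

    keys = list(by_key)
    data = pd.DataFrame(
        [[by_key[k]["intensities"][s] for s in samples] for k in keys],
        index=pd.Index(keys, name="site"),
        columns=samples,
        dtype=float,
    )
    row_meta = pd.DataFrame(
        {
            "gene": [by_key[k]["gene"] for k in keys],
            "protein": [by_key[k]["protein"] for k in keys],
            "residue": [by_key[k]["residue"] for k in keys],
            "position": [by_key[k]["position"] for k in keys],
            "multiplicity": [by_key[k]["multiplicity"] for k in keys],
            "localization_prob": [by_key[k]["localization_prob"] for k in keys],
            "is_reverse": [by_key[k]["is_reverse"] for k in keys],
            "is_contaminant": [by_key[k]["is_contaminant"] for k in keys],
        },
        index=data.index,
    )
    return ExpressionMatrix(data=data, design=design_df, row_meta=row_meta, stage="raw")
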