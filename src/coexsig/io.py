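"""Readers, writers and packaged fixtures for the pipeline's file formats.

The canonical in-memory containers are thin dataclasses around pandas
objects: :class:`ExpressionMatrix` (genes as rows, samples as columns, with
a scale tag tracking what transforms have been applied) and
:class:`ClinicalTable` (one row per sample: pathologic stage, overall
survival, demographics, TNM codes).

Two fixtures ship with the package: the stage-wise differentially expressed
transcripts of the five staging-and-survival (SAS) modules of the TCGA-LUAD
co-expression network (with hub flags), and the 8-gene prognostic sum-ratio
signature discovered from that network.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

Scale = Literal["raw", "log2", "normalized"]

#: Required clinical columns (death is coded 1, alive 0; time in days).
CLINICAL_REQUIRED = ("os_time_days", "os_event")
CLINICAL_COLUMNS = (
    "stage",
    "substage",
    "os_time_days",
    "os_event",
    "age",
    "sex",
    "t_stage",
    "n_stage",
    "m_stage",
)

_ROMAN_STAGE = {"I": 1, "II": 2, "III": 3, "IV": 4}


class DataFormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix with a scale tag.

    ``scale='raw'`` means non-negative FPKM-like abundances; ``'log2'``
    means log2(x + pseudocount); ``'normalized'`` means median-centred
    values from the three-step normalization.
    """

    data: pd.DataFrame
    scale: Scale = "raw"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate gene IDs: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate sample IDs: {dups[:5]}")
        if self.scale == "raw" and (self.data.to_numpy() < 0).any():
            raise DataFormatError("raw-scale expression must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], scale=self.scale)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], scale=self.scale)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations indexed by sample ID."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise DataFormatError("duplicate sample IDs in clinical table")
        for col in CLINICAL_REQUIRED:
            if col not in self.data.columns:
                raise DataFormatError(f"clinical table missing required column {col!r}")
        ev = self.data["os_event"].dropna()
        if not ev.isin((0, 1)).all():
            raise DataFormatError("os_event must be coded 0 (alive) / 1 (deceased)")
        t = self.data["os_time_days"].dropna()
        if (t < 0).any():
            raise DataFormatError("os_time_days must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)])


@dataclass
class SignatureDef:
    """A sum-ratio signature: numerator genes are the high-expression /
    high-survival side, denominator genes the low-expression /
    high-survival side. ``invert`` negates the score (used for comparator
    signatures published with the opposite orientation)."""

    name: str
    numerator_genes: list[str]
    denominator_genes: list[str]
    invert: bool = False

    def __post_init__(self) -> None:
        overlap = set(self.numerator_genes) & set(self.denominator_genes)
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: genes on both sides: {sorted(overlap)}"
            )
        if not self.numerator_genes or not self.denominator_genes:
            raise ValueError(f"signature {self.name!r}: both sides must be non-empty")

    @property
    def genes(self) -> list[str]:
        return list(self.numerator_genes) + list(self.denominator_genes)

    def label(self) -> str:
        return "+".join(self.numerator_genes) + "/" + "+".join(self.denominator_genes)


@dataclass
class Table3Fixture:
    """Stage-wise DEG lists for the five SAS modules, with hub flags."""

    modules: dict = field(repr=False)

    def genes(self, module: str, comparison: str) -> list[str]:
        key = {"stage1-vs-2": "stage1_vs_2", "stage1-vs-rest": "stage1_vs_rest"}[comparison]
        return list(self.modules[module][key])

    def hubs(self, module: str, comparison: str) -> list[str]:
        key = {"stage1-vs-2": "hubs_stage1_vs_2", "stage1-vs-rest": "hubs_stage1_vs_rest"}[
            comparison
        ]
        return list(self.modules[module][key])

    def direction(self, module: str) -> str | None:
        return self.modules[module]["direction"]

    @property
    def module_names(self) -> list[str]:
        return list(self.modules)

    def distinct_genes(self, comparison: str) -> set[str]:
        out: set[str] = set()
        for m in self.modules:
            out.update(self.genes(m, comparison))
        return out


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, comment="#", dtype=str)


def read_expression(
    path: str | Path,
    scale: Scale = "raw",
    samples_as_rows: bool = False,
) -> ExpressionMatrix:
    """Read a TSV/CSV expression matrix (first column gene IDs, header
    sample IDs). Duplicate gene rows are collapsed by their mean with a
    warning; any non-numeric or missing cell is an error naming its
    coordinates."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    # pandas mangles duplicate column names; check the raw header first
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split(sep)[1:]
                break
        else:
            raise DataFormatError(f"{path}: empty file")
    if not samples_as_rows and len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise DataFormatError(f"{path}: duplicate sample IDs: {dups[:5]}")
    df = _read_table(path)
    if samples_as_rows:
        df = df.T
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataFormatError(f"{path}: duplicate sample IDs: {dups[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"{path}: non-numeric or missing value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    if numeric.index.duplicated().any():
        dups = numeric.index[numeric.index.duplicated()].unique().tolist()
        warnings.warn(
            f"{path}: {len(dups)} duplicated gene ID(s) collapsed by mean "
            f"(e.g. {dups[:3]})",
            stacklevel=2,
        )
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(numeric.astype(float), scale=scale)


def write_expression(
    path: str | Path, expr: ExpressionMatrix, header_comment: str | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# scale={expr.scale}\n")
        expr.data.to_csv(fh, sep="\t", index_label="gene_id")


def parse_stage(value: object) -> float:
    """Map a pathologic-stage string to a numeric stage 1-4.

    Accepts Roman numerals with optional a/b/c substage suffix ('IA',
    'IIIB'), an optional 'Stage ' prefix, or plain digits. Substages
    collapse to their whole stage; anything unparseable maps to NaN.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip().upper()
    if s in ("", "NA", "NAN", "NONE", "NULL"):
        return np.nan
    s = re.sub(r"^STAGE\s*", "", s)
    m = re.fullmatch(r"(IV|III|II|I)\s*([ABC]?)", s)
    if m:
        return float(_ROMAN_STAGE[m.group(1)])
    m = re.fullmatch(r"([1-4])(\.0)?\s*[ABC]?", s)
    if m:
        return float(m.group(1))
    return np.nan


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read the per-sample clinical TSV.

    Stage may be given as Roman substage strings; empty strings and "NA"
    are both treated as missing. ``os_time_days`` and ``os_event`` are
    mandatory."""
    df = _read_table(path)
    for col in CLINICAL_REQUIRED:
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing required column {col!r}")
    out = pd.DataFrame(index=df.index)
    raw_stage = df["stage"] if "stage" in df.columns else pd.Series(np.nan, index=df.index)
    out["stage"] = raw_stage.map(parse_stage)
    out["substage"] = raw_stage.where(raw_stage.notna(), None)
    for col in ("os_time_days", "os_event", "age", "t_stage", "n_stage", "m_stage"):
        if col in df.columns:
            out[col] = pd.to_numeric(df[col].replace({"": np.nan, "NA": np.nan}), errors="coerce")
        else:
            out[col] = np.nan
    out["sex"] = (
        df["sex"].replace({"": None, "NA": None}) if "sex" in df.columns else None
    )
    return ClinicalTable(out)


def write_clinical(path: str | Path, clinical: ClinicalTable) -> None:
    clinical.data.to_csv(path, sep="\t", index_label="sample_id")


def read_signatures(path: str | Path, invert: Sequence[str] = ()) -> list[SignatureDef]:
    """Read signature definitions from a 3-column TSV: name, side
    ('num'/'den'), gene. Names listed in ``invert`` get the invert flag."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 3:
        raise DataFormatError(f"{path}: expected 3 columns (name, side, gene)")
    df.columns = ["name", "side", "gene"] + [f"x{i}" for i in range(df.shape[1] - 3)]
    # drop an optional header row
    if df.iloc[0].tolist()[:3] == ["name", "side", "gene"]:
        df = df.iloc[1:]
    sigs = []
    for name, grp in df.groupby("name", sort=False):
        sides = grp["side"].str.lower()
        bad = ~sides.isin(("num", "den"))
        if bad.any():
            raise DataFormatError(f"{path}: invalid side value(s) {grp['side'][bad].tolist()}")
        sigs.append(
            SignatureDef(
                name=str(name),
                numerator_genes=grp.loc[sides == "num", "gene"].tolist(),
                denominator_genes=grp.loc[sides == "den", "gene"].tolist(),
                invert=str(name) in set(invert),
            )
        )
    return sigs


def write_signatures(path: str | Path, signatures: Sequence[SignatureDef]) -> None:
    with open(path, "w") as fh:
        fh.write("name\tside\tgene\n")
        for sig in signatures:
            for g in sig.numerator_genes:
                fh.write(f"{sig.name}\tnum\t{g}\n")
            for g in sig.denominator_genes:
                fh.write(f"{sig.name}\tden\t{g}\n")


def _load_packaged_json(name: str) -> dict:
    with resources.files("coexsig.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_table3_fixture() -> Table3Fixture:
    """The packaged stage-wise DEG lists of the five SAS modules."""
    return Table3Fixture(modules=_load_packaged_json("table3.json")["modules"])


def load_signature_fixtures() -> list[SignatureDef]:
    """Packaged signatures; the first is the 8-gene LUAD sum-ratio
    signature (numerator ATP6V0E1+SVBP+HSDL1+UBTD1, denominator
    GNPNAT1+XRCC2+TFAP2A+PPP1R13L)."""
    raw = _load_packaged_json("signatures.json")["signatures"]
    return [
        SignatureDef(
            name=s["name"],
            numerator_genes=list(s["numerator_genes"]),
            denominator_genes=list(s["denominator_genes"]),
            invert=bool(s.get("invert", False)),
        )
        for s in raw
    ]
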