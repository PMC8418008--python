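"""Readers and writers for every on-disk format the pipeline touches.

All readers validate strictly and raise :class:`FormatError` carrying file,
line and field context; nothing is silently coerced.  Formats:

* expression matrix — TSV, genes as rows, header of sample IDs encoding
  ``<context>_d<dose>_r<replicate>``
* sample sheet — TSV companion of the matrix
* peaks — BED6+3 (extra columns: M_value, P_value, location_class)
* enhancer signal — BED4+1 (extra column: signal)
* pathway catalog — GMT
* viability plate readings — CSV
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

PROMOTER = "promoter"
NON_PROMOTER = "non_promoter"
LOCATION_CLASSES = (PROMOTER, NON_PROMOTER)

_SAMPLE_ID_RE = re.compile(r"^(?P<context>[^_]+)_d(?P<dose>[0-9.eE+-]+)_r(?P<rep>\d+)$")

#: serialization precision — lossless for float64 round trips
_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """A file failed validation; message carries file/line/field context."""


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample design metadata.

    ``values`` is a DataFrame indexed by gene_id with sample_id columns;
    ``sample_meta`` is indexed by sample_id with columns context, dose,
    replicate.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values.index.name = "gene_id"
        self.values.columns.name = None
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene ID: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample ID: {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError("expression values must all be finite")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)}")
        # identical dose ladder in every context
        ladders = {
            ctx: tuple(sorted(set(grp["dose"])))
            for ctx, grp in self.sample_meta.groupby("context", sort=False)
        }
        if len(set(ladders.values())) > 1:
            raise FormatError(f"dose levels differ across contexts: {ladders}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def contexts(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.sample_meta.loc[self.sample_ids, "context"]:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def doses(self) -> list[float]:
        return sorted(set(self.sample_meta["dose"]))

    def __eq__(self, other: object) -> bool:  # round-trip identity
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.sample_meta.equals(
            other.sample_meta
        )


def make_sample_id(context: str, dose: float, replicate: int) -> str:
    return f"{context}_d{dose:g}_r{replicate}"


def parse_sample_id(sample_id: str) -> tuple[str, float, int]:
    m = _SAMPLE_ID_RE.match(sample_id)
    if m is None:
        raise FormatError(
            f"sample ID {sample_id!r} does not encode '<context>_d<dose>_r<rep>'"
        )
    return m["context"], float(m["dose"]), int(m["rep"])


def sample_meta_from_ids(sample_ids: Iterable[str]) -> pd.DataFrame:
    rows = []
    for sid in sample_ids:
        ctx, dose, rep = parse_sample_id(sid)
        rows.append((sid, ctx, dose, rep))
    return pd.DataFrame(
        rows, columns=["sample_id", "context", "dose", "replicate"]
    ).set_index("sample_id")


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_expression(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype=None,
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: malformed expression TSV: {exc}") from exc
    if df.index.name != "gene_id":
        raise FormatError(f"{path}: line 1: header must start with 'gene_id'")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicated gene row {dup!r}")
    for col in df.columns:
        bad = df[col].map(lambda v: not isinstance(v, (int, float)) or not math.isfinite(v))
        if bad.any():
            gene = df.index[bad][0]
            raise FormatError(
                f"{path}: sample {col!r}, gene {gene!r}: value is not a finite number"
            )
    meta = sample_meta_from_ids(df.columns)
    return ExpressionMatrix(values=df.astype(float), sample_meta=meta)


def write_sample_sheet(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.sample_meta.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# peaks (BED6+3) and gene annotation
# ---------------------------------------------------------------------------

PEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "peak_id",
    "score",
    "strand",
    "m_value",
    "p_value",
    "location_class",
]


def validate_peaks(peaks: pd.DataFrame, source: str = "peak table") -> pd.DataFrame:
    for col in PEAK_COLUMNS:
        if col not in peaks.columns:
            raise FormatError(f"{source}: missing column {col!r}")
    for i, row in enumerate(peaks.itertuples(index=False), start=1):
        if row.start >= row.end:
            raise FormatError(
                f"{source}: line {i}: start >= end ({row.start} >= {row.end})"
            )
        if not (0 <= row.p_value <= 1):
            raise FormatError(
                f"{source}: line {i}: field p_value outside [0, 1]: {row.p_value}"
            )
        if row.location_class not in LOCATION_CLASSES:
            raise FormatError(
                f"{source}: line {i}: field location_class must be one of "
                f"{LOCATION_CLASSES}, got {row.location_class!r}"
            )
    return peaks


def write_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    cols = PEAK_COLUMNS + (["assigned_gene"] if "assigned_gene" in peaks.columns else [])
    peaks[cols].to_csv(path, sep="\t", header=False, index=False,
                       float_format=_FLOAT_FMT)


def read_peaks(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 9 tab fields (BED6+3), "
                    f"got {len(fields)}"
                )
            chrom, start, end, peak_id, score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: field start/end not integer"
                ) from exc
            try:
                m_value = float(fields[6])
                p_value = float(fields[7])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: field M_value/P_value not numeric"
                ) from exc
            loc = fields[8]
            assigned = fields[9] if len(fields) > 9 and fields[9] not in (".", "") else None
            rows.append(
                (chrom, start_i, end_i, peak_id, score, strand, m_value, p_value, loc, assigned)
            )
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS + ["assigned_gene"])
    if df["assigned_gene"].isna().all():
        df = df.drop(columns=["assigned_gene"])
    return validate_peaks(df, source=str(path))


GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand"]


def validate_genes(genes: pd.DataFrame, source: str = "gene annotation") -> pd.DataFrame:
    for col in GENE_COLUMNS:
        if col not in genes.columns:
            raise FormatError(f"{source}: missing column {col!r}")
    if (genes["tss"] < 0).any():
        bad = genes.loc[genes["tss"] < 0, "gene_id"].iloc[0]
        raise FormatError(f"{source}: gene {bad!r}: field tss must be >= 0")
    bad_strand = ~genes["strand"].isin(["+", "-"])
    if bad_strand.any():
        bad = genes.loc[bad_strand, "gene_id"].iloc[0]
        raise FormatError(f"{source}: gene {bad!r}: field strand must be + or -")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{source}: duplicate gene ID {dup!r}")
    return genes


def write_genes(genes: pd.DataFrame, path: str | Path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    return validate_genes(df, source=str(path))


# ---------------------------------------------------------------------------
# enhancer signal (BED4+1)
# ---------------------------------------------------------------------------

ENHANCER_COLUMNS = ["chrom", "start", "end", "region_id", "signal"]


def validate_enhancers(regions: pd.DataFrame, source: str = "enhancer table") -> pd.DataFrame:
    for col in ENHANCER_COLUMNS:
        if col not in regions.columns:
            raise FormatError(f"{source}: missing column {col!r}")
    for i, row in enumerate(regions.itertuples(index=False), start=1):
        if row.start >= row.end:
            raise FormatError(f"{source}: line {i}: start >= end")
        if row.signal < 0:
            raise FormatError(f"{source}: line {i}: field signal must be >= 0")
    return regions


def write_enhancers(regions: pd.DataFrame, path: str | Path) -> None:
    cols = ENHANCER_COLUMNS + [c for c in regions.columns if c not in ENHANCER_COLUMNS]
    regions[cols].to_csv(path, sep="\t", header=False, index=False,
                         float_format=_FLOAT_FMT)


def read_enhancers(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 5 tab fields (BED4+1)"
                )
            try:
                rows.append(
                    (fields[0], int(fields[1]), int(fields[2]), fields[3], float(fields[4]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: numeric field malformed") from exc
    return validate_enhancers(pd.DataFrame(rows, columns=ENHANCER_COLUMNS), source=str(path))


# ---------------------------------------------------------------------------
# pathway catalog (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pathway:
    name: str
    genes: tuple[str, ...]
    oncogenic: bool = False


@dataclass
class PathwayCatalog:
    """Gene-set catalog keyed by pathway_id with oncogenic flags.

    Flags mark the tumorigenesis-associated families (RAS signaling, cell
    cycle, stem-cell pluripotency, ubiquitin-mediated proteolysis) that the
    ranking's pathway criterion weights above raw pathway count.
    """

    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, pw in self.pathways.items():
            if len(pw.genes) == 0:
                raise FormatError(f"pathway {pid!r} is empty")

    def __len__(self) -> int:
        return len(self.pathways)

    def membership(self, gene_id: str) -> list[str]:
        return [pid for pid, pw in self.pathways.items() if gene_id in pw.genes]


_DEFAULT_ONCOGENIC_RE = re.compile(
    r"RAS_SIGNALING|CELL_CYCLE|PLURIPOTENCY|UBIQUITIN", re.IGNORECASE
)


def read_gmt(path: str | Path, oncogenic_ids: Iterable[str] | None = None) -> PathwayCatalog:
    """Read a GMT catalog.

    ``oncogenic_ids`` is an optional sidecar list of pathway IDs to flag;
    when absent, flags default to name-matching the four oncogenic families.
    """
    path = Path(path)
    onco = set(oncogenic_ids) if oncogenic_ids is not None else None
    pathways: dict[str, Pathway] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab fields, "
                    f"got {len(fields)}"
                )
            pid, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: pathway {pid!r} is empty")
            if pid in pathways:
                raise FormatError(f"{path}: line {lineno}: duplicate pathway {pid!r}")
            flagged = (pid in onco) if onco is not None else bool(
                _DEFAULT_ONCOGENIC_RE.search(pid)
            )
            pathways[pid] = Pathway(name=desc, genes=tuple(genes), oncogenic=flagged)
    return PathwayCatalog(pathways=pathways)


def write_gmt(catalog: PathwayCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, pw in catalog.pathways.items():
            fh.write("\t".join([pid, pw.name, *pw.genes]) + "\n")


# ---------------------------------------------------------------------------
# viability plates (CSV)
# ---------------------------------------------------------------------------

VIABILITY_ROLES = ("treated", "control", "blank")
VIABILITY_COLUMNS = ["dose", "od", "role", "replicate"]


def validate_viability(table: pd.DataFrame, source: str = "viability table") -> pd.DataFrame:
    for col in VIABILITY_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"{source}: missing column {col!r}")
    bad_role = ~table["role"].isin(VIABILITY_ROLES)
    if bad_role.any():
        raise FormatError(
            f"{source}: field role must be one of {VIABILITY_ROLES}, "
            f"got {table.loc[bad_role, 'role'].iloc[0]!r}"
        )
    if not np.isfinite(table["od"].to_numpy(dtype=float)).all():
        raise FormatError(f"{source}: field od must be finite")
    if (table["role"] == "control").sum() == 0:
        raise FormatError(f"{source}: needs at least one control row")
    if (table["role"] == "blank").sum() == 0:
        raise FormatError(f"{source}: needs at least one blank row")
    return table


def write_viability(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_viability(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("dose", "od", "dose_a", "dose_b"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    return validate_viability(df, source=str(path))
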