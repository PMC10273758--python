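"""Readers and writers for every file format the pipeline touches.

Dialects
--------
* **l2r matrix**: headerless, delimiter-separated text, one row per SNP
  position, one column per sample; ``NA`` or an empty token marks a missing
  value. Sample IDs live in a sidecar file, one per line (the UK Biobank
  release stores them separately). Delimiter is auto-detected among tab,
  comma and whitespace.
* **SEG**: tab-separated with a header; required columns Sample,
  Chromosome, Start, End, Segment_Mean (case-insensitive, GDC aliases
  accepted). Coordinates are 1-based inclusive on disk.
* **chrom.sizes**: headerless two-column TSV (UCSC convention).
* **phenotypes / feature tables**: TSV with header, ``sample_id`` first.

Coordinates are converted to 0-based half-open intervals internally; the
SEG convention (1-based inclusive) applies only on disk.
"""

from __future__ import annotations

import io as _stdio
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CnvFormatError",
    "L2RMatrix",
    "SegmentRecord",
    "normalize_chromosome",
    "read_l2r",
    "write_l2r",
    "read_seg",
    "write_seg",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_phenotypes",
    "write_phenotypes",
    "read_feature_table",
    "write_feature_table",
]


class CnvFormatError(ValueError):
    """Malformed input file; message names the file and offending line."""


def normalize_chromosome(name: str) -> str:
    """Normalize a chromosome name: strip a leading ``chr``, uppercase X.

    The Y chromosome is rejected: masked germline CNV releases exclude it
    and no operation in this package is defined for it.
    """
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.lower() == "x":
        return "X"
    if name.lower() == "y":
        raise CnvFormatError("chromosome Y is not supported (masked CNV data excludes it)")
    return name


@dataclass
class L2RMatrix:
    """Per-SNP log2 intensity ratios for one chromosome.

    ``values`` has one row per genomic position (ascending) and one column
    per sample; ``NaN`` marks a missing measurement. An l2r of 0 is the
    diploid expectation.
    """

    chromosome: str
    positions: np.ndarray  # 1-based bp, strictly increasing
    sample_ids: list[str]
    values: np.ndarray  # shape (n_positions, n_samples)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape != (len(self.positions), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.positions)} positions x {len(self.sample_ids)} samples"
            )
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class SegmentRecord:
    """One reported copy-number segment (SEG row).

    ``start``/``end`` are 1-based inclusive bp, matching the on-disk SEG
    convention. ``segment_mean`` is log2(copies / 2): 0 for a normal
    diploid region, negative for deletions, positive for gains.
    """

    sample_id: str
    chromosome: str
    start: int
    end: int
    num_probes: int | None
    segment_mean: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"segment end {self.end} < start {self.start}")
        if not math.isfinite(self.segment_mean):
            raise ValueError("segment_mean must be finite")

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open (start, end)."""
        return self.start - 1, self.end


# ---------------------------------------------------------------------------
# l2r matrices


def _sniff_delimiter(line: str) -> str | None:
    """Return the split argument for str.split: tab, comma, or None (any ws)."""
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None


_MISSING_TOKENS = {"", "NA", "na", "NaN", "nan", "."}


def read_l2r(
    matrix_path: str | Path,
    samples_path: str | Path,
    chromosome: str,
    positions_path: str | Path | None = None,
) -> L2RMatrix:
    """Read a headerless l2r matrix plus its sidecar sample-ID list.

    Positions come from *positions_path* (one integer per line) when given,
    otherwise synthetic indices 1..n_rows are used. Ragged rows and
    non-numeric tokens raise :class:`CnvFormatError` naming the line.
    """
    matrix_path = Path(matrix_path)
    sample_ids = [ln.strip() for ln in Path(samples_path).read_text().splitlines() if ln.strip()]
    if len(set(sample_ids)) != len(sample_ids):
        raise CnvFormatError(f"{samples_path}: duplicate sample ids")
    n_samples = len(sample_ids)

    rows: list[np.ndarray] = []
    delim: str | None = None
    with open(matrix_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if delim is None and not rows:
                delim = _sniff_delimiter(line)
            tokens = line.split(delim) if delim else line.split()
            if len(tokens) != n_samples:
                raise CnvFormatError(
                    f"{matrix_path}: line {lineno}: expected {n_samples} values, got {len(tokens)}"
                )
            row = np.empty(n_samples, dtype=np.float64)
            for j, tok in enumerate(tokens):
                tok = tok.strip()
                if tok in _MISSING_TOKENS:
                    row[j] = np.nan
                else:
                    try:
                        row[j] = float(tok)
                    except ValueError:
                        raise CnvFormatError(
                            f"{matrix_path}: line {lineno}: cannot parse value {tok!r}"
                        ) from None
            rows.append(row)

    values = np.vstack(rows) if rows else np.empty((0, n_samples))
    if positions_path is not None:
        positions = np.asarray(
            [int(ln) for ln in Path(positions_path).read_text().split()], dtype=np.int64
        )
        if len(positions) != len(values):
            raise CnvFormatError(
                f"{positions_path}: {len(positions)} positions for {len(values)} matrix rows"
            )
    else:
        positions = np.arange(1, len(values) + 1, dtype=np.int64)
    return L2RMatrix(normalize_chromosome(chromosome), positions, sample_ids, values)


def write_l2r(
    matrix: L2RMatrix,
    matrix_path: str | Path,
    samples_path: str | Path,
    positions_path: str | Path | None = None,
    delimiter: str = "\t",
) -> None:
    """Write an l2r matrix losslessly (``%.17g``; NaN becomes ``NA``)."""
    buf = _stdio.StringIO()
    for row in matrix.values:
        buf.write(delimiter.join("NA" if np.isnan(v) else format(v, ".17g") for v in row))
        buf.write("\n")
    Path(matrix_path).write_text(buf.getvalue())
    Path(samples_path).write_text("".join(f"{s}\n" for s in matrix.sample_ids))
    if positions_path is not None:
        Path(positions_path).write_text("".join(f"{p}\n" for p in matrix.positions))


# ---------------------------------------------------------------------------
# SEG files

_SEG_ALIASES = {
    "sample_id": ("sample", "sample_id", "id", "gdc_aliquot", "aliquot"),
    "chromosome": ("chromosome", "chrom", "chr"),
    "start": ("start", "loc_start", "start_position"),
    "end": ("end", "loc_end", "end_position"),
    "num_probes": ("num_probes", "num_mark", "probes", "markers"),
    "segment_mean": ("segment_mean", "seg_mean", "segmented_mean"),
}

_REQUIRED_SEG = ("sample_id", "chromosome", "start", "end", "segment_mean")


def _canon(col: str) -> str:
    return re.sub(r"[.\s-]+", "_", col.strip().lower())


def read_seg(path: str | Path) -> list[SegmentRecord]:
    """Read a SEG-like TSV into :class:`SegmentRecord` objects, in file order."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    colmap: dict[str, str] = {}
    canon_cols = {_canon(c): c for c in frame.columns}
    for field, aliases in _SEG_ALIASES.items():
        for alias in aliases:
            if alias in canon_cols:
                colmap[field] = canon_cols[alias]
                break
    for field in _REQUIRED_SEG:
        if field not in colmap:
            raise CnvFormatError(f"{path}: missing required column {field!r}")

    records: list[SegmentRecord] = []
    has_probes = "num_probes" in colmap
    for i in range(len(frame)):
        lineno = i + 2  # header is line 1
        vals = {f: frame.iloc[i][colmap[f]] for f in colmap}
        try:
            start = int(vals["start"])
            end = int(vals["end"])
            mean = float(vals["segment_mean"])
        except (TypeError, ValueError) as exc:
            raise CnvFormatError(f"{path}: line {lineno}: {exc}") from None
        num_probes: int | None = None
        if has_probes and not pd.isna(vals.get("num_probes")):
            num_probes = int(float(vals["num_probes"]))
        if end < start:
            raise CnvFormatError(f"{path}: line {lineno}: end {end} < start {start}")
        records.append(
            SegmentRecord(
                sample_id=str(vals["sample_id"]),
                chromosome=normalize_chromosome(vals["chromosome"]),
                start=start,
                end=end,
                num_probes=num_probes,
                segment_mean=mean,
            )
        )
    return records


def write_seg(records: Iterable[SegmentRecord], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n")
        for rec in records:
            probes = "" if rec.num_probes is None else str(rec.num_probes)
            fh.write(
                f"{rec.sample_id}\t{rec.chromosome}\t{rec.start}\t{rec.end}\t"
                f"{probes}\t{format(rec.segment_mean, '.17g')}\n"
            )


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a UCSC-style two-column chrom.sizes file (no header)."""
    path = Path(path)
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 2:
            raise CnvFormatError(f"{path}: line {lineno}: expected two columns")
        name = normalize_chromosome(fields[0])
        try:
            length = int(fields[1])
        except ValueError:
            raise CnvFormatError(f"{path}: line {lineno}: bad length {fields[1]!r}") from None
        if length <= 0:
            raise CnvFormatError(f"{path}: line {lineno}: non-positive length {length}")
        if name in sizes:
            raise CnvFormatError(f"{path}: line {lineno}: duplicate chromosome {name}")
        sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{name}\t{length}\n" for name, length in sizes.items()))


# ---------------------------------------------------------------------------
# phenotypes

_PHENO_COLUMNS = ["sample_id", "sex", "self_report_cancer", "registry_cancer", "cancer_type"]

_FLAG_MAP = {
    "0": False, "1": True, "false": False, "true": True,
    "no": False, "yes": True,
}


def _parse_flag(value: object, path: Path, lineno: int) -> bool:
    token = str(value).strip().lower()
    if token in _FLAG_MAP:
        return _FLAG_MAP[token]
    raise CnvFormatError(f"{path}: line {lineno}: cannot parse flag {value!r}")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV; returns a DataFrame with canonical columns.

    Columns: sample_id (str), sex ('F'/'M'), self_report_cancer (bool),
    registry_cancer (bool), cancer_type (str, '' when absent).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _PHENO_COLUMNS[:-1] if c not in frame.columns]
    if missing:
        raise CnvFormatError(f"{path}: missing required column(s) {missing}")
    if "cancer_type" not in frame.columns:
        frame["cancer_type"] = ""
    if frame["sample_id"].duplicated().any():
        dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise CnvFormatError(f"{path}: duplicate sample ids {dupes}")
    out = pd.DataFrame({
        "sample_id": frame["sample_id"].astype(str),
        "sex": frame["sex"].astype(str).str.strip().str.upper().str[:1],
        "self_report_cancer": [
            _parse_flag(v, path, i + 2) for i, v in enumerate(frame["self_report_cancer"])
        ],
        "registry_cancer": [
            _parse_flag(v, path, i + 2) for i, v in enumerate(frame["registry_cancer"])
        ],
        "cancer_type": frame["cancer_type"].fillna("").astype(str).str.strip().str.lower(),
    })
    bad_sex = ~out["sex"].isin(["F", "M"])
    if bad_sex.any():
        lineno = int(np.flatnonzero(bad_sex)[0]) + 2
        raise CnvFormatError(f"{path}: line {lineno}: sex must be F or M")
    return out


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    out = phenotypes.copy()
    for col in ("self_report_cancer", "registry_cancer"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature tables


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a CSLV feature table (TSV, sample_id index, float features)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in frame.columns:
        raise CnvFormatError(f"{path}: missing required column 'sample_id'")
    if frame["sample_id"].duplicated().any():
        raise CnvFormatError(f"{path}: duplicate sample ids")
    frame = frame.set_index("sample_id")
    return frame.astype(np.float64)


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table at 12 significant digits (round-trip < 1e-10)."""
    features.to_csv(path, sep="\t", index_label="sample_id", float_format="%.12g")
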