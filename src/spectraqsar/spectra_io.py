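"""Spectral library IO and record assembly.

Reads and writes NIST-dialect MSP libraries and merges tabular property /
chemical-class annotations into the unified :class:`Dataset` that the rest of
the pipeline consumes.  The MSP dialect accepted here covers both
semicolon-separated (``77 500; 152 999;``) and whitespace-separated peak
lines; files are always written whitespace-separated, one peak per line.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: property names a record may carry (all on the scales used for modeling)
PROPERTY_NAMES = (
    "log_mw",
    "bp",
    "mp",
    "log_kow",
    "log_ws",
    "log_ld50_rat_oral",
    "log_ld50_mouse_oral",
)

#: recognized chemical-taxonomy levels (ClassyFire-style)
CLASS_LEVELS = ("kingdom", "superclass", "class", "subclass")


class ColumnPolarity(str, Enum):
    semi_polar = "semi_polar"
    non_polar = "non_polar"
    unknown = "unknown"


class MSPFormatError(ValueError):
    """Raised when an MSP entry violates the format contract."""


@dataclass
class SpectrumRecord:
    """One compound: EI peak list plus retention index and annotations.

    ``peaks`` are (m/z, intensity) pairs sorted by ascending m/z; exact
    duplicate m/z values are consolidated (intensities summed) at parse or
    construction time.
    """

    compound_id: str
    name: str
    peaks: list[tuple[float, float]]
    smiles: str | None = None
    ri: float | None = None
    column_polarity: ColumnPolarity = ColumnPolarity.unknown
    class_labels: dict[str, str] = field(default_factory=dict)
    properties: dict[str, float] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = _consolidate(self.peaks)
        self.validate()

    def validate(self) -> None:
        if not self.peaks:
            raise ValueError(f"record {self.compound_id!r}: empty peak list")
        if not any(i > 0 for _, i in self.peaks):
            raise ValueError(f"record {self.compound_id!r}: all intensities zero")
        for mz, inten in self.peaks:
            if mz <= 0:
                raise ValueError(f"record {self.compound_id!r}: non-positive m/z {mz}")
            if inten < 0:
                raise ValueError(
                    f"record {self.compound_id!r}: negative intensity at m/z {mz}"
                )
        if self.ri is not None and (self.ri < 0 or not math.isfinite(self.ri)):
            raise ValueError(f"record {self.compound_id!r}: invalid RI {self.ri}")
        for prop in self.properties:
            if prop not in PROPERTY_NAMES:
                raise ValueError(
                    f"record {self.compound_id!r}: unknown property {prop!r}"
                )


def _consolidate(peaks: Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    acc: dict[float, float] = {}
    for mz, inten in peaks:
        acc[float(mz)] = acc.get(float(mz), 0.0) + float(inten)
    return sorted(acc.items())


@dataclass
class Dataset:
    """A spectral library with a common rectangular m/z frame."""

    records: list[SpectrumRecord]
    provenance: str = ""
    global_mz_range: tuple[int, int] = (35, 600)

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound_id(s): {dupes}")
        lo, hi = self.global_mz_range
        for rec in self.records:
            mzs = [round(mz) for mz, _ in rec.peaks]
            if mzs and (min(mzs) < lo or max(mzs) > hi):
                raise ValueError(
                    f"global_mz_range {self.global_mz_range} does not cover "
                    f"record {rec.compound_id!r} (peaks span {min(mzs)}-{max(mzs)})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def by_id(self, compound_id: str) -> SpectrumRecord:
        for rec in self.records:
            if rec.compound_id == compound_id:
                return rec
        raise KeyError(compound_id)

    @staticmethod
    def infer_range(
        records: Sequence[SpectrumRecord], frame: tuple[int, int] = (35, 600)
    ) -> tuple[int, int]:
        """Union of the default frame and every record's nominal-mass span."""
        lo, hi = frame
        for rec in records:
            for mz, _ in rec.peaks:
                nominal = math.floor(mz + 0.5)
                lo = min(lo, nominal)
                hi = max(hi, nominal)
        return lo, hi

    # -- lightweight JSON persistence used by the CLI -----------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "provenance": self.provenance,
            "global_mz_range": list(self.global_mz_range),
            "records": [
                {
                    "compound_id": r.compound_id,
                    "name": r.name,
                    "smiles": r.smiles,
                    "ri": r.ri,
                    "column_polarity": r.column_polarity.value,
                    "peaks": [[mz, inten] for mz, inten in r.peaks],
                    "class_labels": r.class_labels,
                    "properties": r.properties,
                    "metadata": r.metadata,
                }
                for r in self.records
            ],
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "Dataset":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        records = [
            SpectrumRecord(
                compound_id=r["compound_id"],
                name=r["name"],
                smiles=r.get("smiles"),
                ri=r.get("ri"),
                column_polarity=ColumnPolarity(r.get("column_polarity", "unknown")),
                peaks=[(mz, inten) for mz, inten in r["peaks"]],
                class_labels=r.get("class_labels", {}),
                properties=r.get("properties", {}),
                metadata=r.get("metadata", {}),
            )
            for r in payload["records"]
        ]
        return cls(
            records=records,
            provenance=payload.get("provenance", ""),
            global_mz_range=tuple(payload.get("global_mz_range", (35, 600))),
        )


# ---------------------------------------------------------------------------
# MSP read / write
# ---------------------------------------------------------------------------

_KNOWN_HEADERS = {
    "name",
    "compound_id",
    "smiles",
    "retention_index",
    "retention_index_non_polar",
    "column_polarity",
    "comments",
    "num peaks",
}


def read_msp(path: str | Path, ri_field: str = "Retention_index") -> list[SpectrumRecord]:
    """Parse a NIST-dialect MSP library into records.

    RI is resolved from the ``ri_field`` header line first, then from an
    ``RI=`` token inside a Comments line.  When both a semi-polar and a
    non-polar RI are present the semi-polar value is kept and the conflict
    is logged.  Unknown header lines are preserved verbatim in ``metadata``.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    records: list[SpectrumRecord] = []
    entry_lines: list[tuple[int, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            entry_lines.append((lineno, line))
        elif entry_lines:
            records.append(_parse_entry(entry_lines, ri_field))
            entry_lines = []
    if entry_lines:
        records.append(_parse_entry(entry_lines, ri_field))
    return records


def _parse_entry(
    lines: list[tuple[int, str]], ri_field: str
) -> SpectrumRecord:
    headers: dict[str, str] = {}
    metadata: dict[str, str] = {}
    peak_lines: list[tuple[int, str]] = []
    num_peaks: int | None = None
    in_peaks = False
    for lineno, line in lines:
        if in_peaks:
            peak_lines.append((lineno, line))
            continue
        if ":" in line:
            key, _, value = line.partition(":")
            key_norm = key.strip().lower()
            if key_norm == "num peaks":
                try:
                    num_peaks = int(value.strip())
                except ValueError as exc:
                    raise MSPFormatError(
                        f"line {lineno}: non-integer Num Peaks {value.strip()!r}"
                    ) from exc
                in_peaks = True
                continue
            headers[key_norm] = value.strip()
            if key_norm not in _KNOWN_HEADERS and key_norm != ri_field.lower():
                metadata[key.strip()] = value.strip()
        else:
            raise MSPFormatError(f"line {lineno}: header line without ':': {line!r}")

    name = headers.get("name")
    if name is None:
        first_line = lines[0][0]
        raise MSPFormatError(f"entry starting at line {first_line}: missing Name field")
    if num_peaks is None:
        raise MSPFormatError(f"entry {name!r}: missing 'Num Peaks' field")

    peaks: list[tuple[float, float]] = []
    for lineno, line in peak_lines:
        tokens = line.replace(";", " ").replace(",", " ").split()
        if len(tokens) % 2 != 0:
            raise MSPFormatError(
                f"line {lineno}: odd number of peak tokens in entry {name!r}"
            )
        for mz_tok, int_tok in zip(tokens[::2], tokens[1::2]):
            try:
                peaks.append((float(mz_tok), float(int_tok)))
            except ValueError as exc:
                raise MSPFormatError(
                    f"line {lineno}: non-numeric peak token in entry {name!r}"
                ) from exc
    if len(peaks) != num_peaks:
        raise MSPFormatError(
            f"entry {name!r}: declared Num Peaks {num_peaks} but parsed {len(peaks)}"
        )

    ri, ri_source = _resolve_ri(headers, ri_field, name)
    polarity = ColumnPolarity.unknown
    if "column_polarity" in headers:
        try:
            polarity = ColumnPolarity(headers["column_polarity"])
        except ValueError:
            metadata["Column_polarity"] = headers["column_polarity"]
    elif ri_source is not ColumnPolarity.unknown:
        # which header supplied the RI implies the column type
        polarity = ri_source

    class_labels = {
        level: metadata.pop(f"Class_{level}")
        for level in CLASS_LEVELS
        if f"Class_{level}" in metadata
    }
    properties = {}
    for prop in PROPERTY_NAMES:
        key = f"Prop_{prop}"
        if key in metadata:
            properties[prop] = float(metadata.pop(key))

    return SpectrumRecord(
        compound_id=headers.get("compound_id", name),
        name=name,
        smiles=headers.get("smiles") or None,
        ri=ri,
        column_polarity=polarity,
        peaks=peaks,
        class_labels=class_labels,
        properties=properties,
        metadata=metadata,
    )


def _resolve_ri(
    headers: Mapping[str, str], ri_field: str, name: str
) -> tuple[float | None, ColumnPolarity]:
    semi = headers.get(ri_field.lower())
    nonpolar = headers.get("retention_index_non_polar")
    source = ColumnPolarity.semi_polar if semi is not None else ColumnPolarity.unknown
    if semi is None and "comments" in headers:
        for token in headers["comments"].replace('"', " ").split():
            if token.upper().startswith("RI="):
                semi = token[3:]
                break
    if semi is not None and nonpolar is not None:
        logger.info(
            "entry %r: both semi-polar and non-polar RI present; keeping semi-polar",
            name,
        )
    chosen = semi if semi is not None else nonpolar
    if chosen is nonpolar and nonpolar is not None:
        source = ColumnPolarity.non_polar
    if chosen is None:
        return None, ColumnPolarity.unknown
    try:
        return float(chosen), source
    except ValueError as exc:
        raise MSPFormatError(f"entry {name!r}: non-numeric RI {chosen!r}") from exc


def write_msp(records: Sequence[SpectrumRecord], path: str | Path) -> None:
    """Write records as a re-readable NIST-dialect MSP file (UTF-8)."""
    lines: list[str] = []
    for rec in records:
        lines.append(f"Name: {rec.name}")
        lines.append(f"Compound_id: {rec.compound_id}")
        if rec.smiles:
            lines.append(f"SMILES: {rec.smiles}")
        if rec.ri is not None:
            lines.append(f"Retention_index: {rec.ri!r}")
        if rec.column_polarity is not ColumnPolarity.unknown:
            lines.append(f"Column_polarity: {rec.column_polarity.value}")
        for level in CLASS_LEVELS:
            if level in rec.class_labels:
                lines.append(f"Class_{level}: {rec.class_labels[level]}")
        for prop in PROPERTY_NAMES:
            if prop in rec.properties:
                lines.append(f"Prop_{prop}: {rec.properties[prop]!r}")
        for key, value in rec.metadata.items():
            lines.append(f"{key}: {value}")
        lines.append(f"Num Peaks: {len(rec.peaks)}")
        for mz, inten in rec.peaks:
            lines.append(f"{mz!r} {inten!r}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# annotation merge
# ---------------------------------------------------------------------------


def attach_annotations(
    records: Sequence[SpectrumRecord],
    property_table: str | Path | pd.DataFrame | None = None,
    class_table: str | Path | pd.DataFrame | None = None,
    provenance: str = "",
) -> Dataset:
    """Merge property and class CSV tables into a :class:`Dataset`.

    Tables are keyed by ``compound_id``; rows with ids absent from the
    records are logged as unmatched, never an error.  Duplicate ids inside
    a table are an error.  Peaks and RI are never altered.
    """
    prop_df = _load_table(property_table, "property")
    class_df = _load_table(class_table, "class")

    by_id = {r.compound_id: r for r in records}
    n_prop = n_class = 0
    if prop_df is not None:
        for _, row in prop_df.iterrows():
            rec = by_id.get(row["compound_id"])
            if rec is None:
                logger.info("property row %r unmatched", row["compound_id"])
                continue
            for prop in PROPERTY_NAMES:
                if prop in row.index and pd.notna(row[prop]):
                    rec.properties[prop] = float(row[prop])
            n_prop += 1
    if class_df is not None:
        for _, row in class_df.iterrows():
            rec = by_id.get(row["compound_id"])
            if rec is None:
                logger.info("class row %r unmatched", row["compound_id"])
                continue
            for level in CLASS_LEVELS:
                if level in row.index and pd.notna(row[level]):
                    rec.class_labels[level] = str(row[level])
            n_class += 1
    logger.info(
        "attach_annotations: %d property rows and %d class rows joined onto %d records",
        n_prop,
        n_class,
        len(records),
    )
    return Dataset(
        records=list(records),
        provenance=provenance,
        global_mz_range=Dataset.infer_range(records),
    )


def _load_table(
    table: str | Path | pd.DataFrame | None, what: str
) -> pd.DataFrame | None:
    if table is None:
        return None
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    if "compound_id" not in df.columns:
        raise ValueError(f"{what} table lacks a compound_id column")
    if df["compound_id"].duplicated().any():
        dupes = sorted(df.loc[df["compound_id"].duplicated(), "compound_id"].unique())
        raise ValueError(f"duplicate compound_id(s) in {what} table: {dupes}")
    return df
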