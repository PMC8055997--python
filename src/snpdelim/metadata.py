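"""Sample metadata: specimen table reading and coordinate/depth parsing.

The package ships a transcription of the Antarctophilinidae specimen table
(voucher, COI barcode accession, coordinates, gear, depth, locality, and
whether the specimen entered the ddRADseq matrices) under
``data/antarctophilinidae_samples.csv``; :func:`load_reference_samples`
returns it parsed. Arbitrary user tables with the same columns are read by
:func:`read_sample_table`.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["SampleRecord", "read_sample_table", "load_reference_samples"]

_DEPTH = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(?:[–\-—]\s*(\d+(?:\.\d+)?))?\s*$")


def parse_coordinate(text: str) -> float | None:
    """Degree[-minute[-second]] + hemisphere -> signed decimal degrees.

    Accepts the loose punctuation of collection tables, e.g.
    ``"71° 7.3′ S"``, ``"61° 13′ 3.7″ S"`` or ``"62° 58.18S"``.
    South and West are negative. Returns None for empty/absent cells.
    """
    text = (text or "").strip()
    if not text or text in {"–", "-"}:
        return None
    m = re.match(r"^(.*?)\s*([NSEW])\s*$", text)
    if m is None:
        raise ValueError(f"unparseable coordinate {text!r} (no hemisphere)")
    nums = re.findall(r"\d+(?:\.\d+)?", m.group(1))
    if not 1 <= len(nums) <= 3:
        raise ValueError(f"unparseable coordinate {text!r}")
    val = sum(float(x) / 60**i for i, x in enumerate(nums))
    return -val if m.group(2) in "SW" else val


def parse_depth_range(text: str) -> tuple[float, float] | None:
    """``"150–247"`` -> (150, 247); a single depth maps to a zero-width range."""
    text = (text or "").strip()
    if not text or text in {"–", "-"}:
        return None
    m = _DEPTH.match(text)
    if m is None:
        raise ValueError(f"unparseable depth {text!r}")
    lo = float(m.group(1))
    hi = float(m.group(2)) if m.group(2) else lo
    if lo > hi:
        raise ValueError(f"depth range min > max in {text!r}")
    return lo, hi


@dataclass
class SampleRecord:
    """One specimen row: identifiers, provenance and analysis membership."""

    code: str
    species_label: str
    voucher: str | None = None
    barcode_accession: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    depth_range: tuple[float, float] | None = None
    location: str | None = None
    ddrad_included: bool = False


def _clean(cell: str | None) -> str | None:
    cell = (cell or "").strip()
    return cell if cell and cell not in {"–", "-"} else None


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read a delimited specimen table into :class:`SampleRecord` rows.

    Required columns: ``code`` and ``species``; recognised optional
    columns: ``voucher``, ``barcode``, ``latitude``, ``longitude``,
    ``depth_m``, ``location``, ``ddrad_included`` (truthy values:
    1/true/yes, case-insensitive). Empty or en-dash cells are treated as
    absent. Duplicate codes are an error.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.DictReader(_strip_comments(fh))]
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for r in rows:
        code = (r.get("code") or "").strip()
        if not code:
            raise ValueError("row without a sample code")
        if code in seen:
            raise ValueError(f"duplicate sample code {code!r}")
        seen.add(code)
        records.append(
            SampleRecord(
                code=code,
                species_label=(r.get("species") or "").strip(),
                voucher=_clean(r.get("voucher")),
                barcode_accession=_clean(r.get("barcode")),
                latitude=parse_coordinate(r.get("latitude") or ""),
                longitude=parse_coordinate(r.get("longitude") or ""),
                depth_range=parse_depth_range(r.get("depth_m") or ""),
                location=_clean(r.get("location")),
                ddrad_included=(r.get("ddrad_included") or "").strip().lower()
                in {"1", "true", "yes", "y"},
            )
        )
    return records


def _strip_comments(fh):
    for line in fh:
        if not line.lstrip().startswith("#"):
            yield line


def load_reference_samples() -> list[SampleRecord]:
    """The packaged Antarctophilinidae specimen table."""
    ref = resources.files("snpdelim.data").joinpath("antarctophilinidae_samples.csv")
    with resources.as_file(ref) as p:
        return read_sample_table(p)
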