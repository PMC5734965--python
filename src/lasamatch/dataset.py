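"""Name canonicalization, pair-table I/O, and the packaged reference set.

The reference set is a transcription of a published audit table of 100
locally approved proprietary drug names, each paired with an overseas name
it resembles, together with the printed match value (99 rows; one row
prints no value) and the printed confusion-risk rating (92 high, 8 medium).
It ships inside the package as an uncompressed TSV so the transcription is
auditable, and is checksum-pinned.
"""

from __future__ import annotations

import csv
import hashlib
import io
import itertools
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .coding import CanonicalName, MatchParams, ValidationError, grid_scores
from .risk import Thresholds, classify

__all__ = [
    "PairRecord",
    "ReproductionReport",
    "canonicalize",
    "load_pairs",
    "write_pairs",
    "load_formulary",
    "reference_pairs",
    "REFERENCE_SHA256",
    "default_convention_grid",
    "reproduce_reference",
    "convention_id",
]

COLUMNS = (
    "row_id",
    "generic_name",
    "local_proprietary",
    "overseas_similar",
    "overseas_generic",
    "match_percent",
    "risk",
)

_REFERENCE_RESOURCE = "reference_pairs.tsv"
REFERENCE_SHA256 = "0964833534a3a1a4fd5edf1a530ab0657ac28fa71ec2bb3ce913c5df0260c16c"

_NON_LETTER = re.compile(r"[^A-Z]")


@dataclass(frozen=True)
class PairRecord:
    """One pair-table row: names as printed plus printed score and band."""

    row_id: int
    generic_name: str
    local_proprietary: str
    overseas_similar: str
    overseas_generic: str = ""
    printed_match_percent: int | None = None
    printed_risk: str | None = None

    def __post_init__(self) -> None:
        if not self.local_proprietary or not self.overseas_similar:
            raise ValidationError(f"row {self.row_id}: both pair names are required")
        if self.printed_match_percent is not None and not (
            0 <= self.printed_match_percent <= 100
        ):
            raise ValidationError(
                f"row {self.row_id}: match value {self.printed_match_percent} "
                "outside [0, 100]"
            )

    @property
    def names(self) -> tuple[CanonicalName, CanonicalName]:
        """Canonical (local, overseas) name pair."""
        return canonicalize(self.local_proprietary), canonicalize(self.overseas_similar)


def canonicalize(raw_label: str) -> CanonicalName:
    """Reduce a label to its ordered A-Z letter sequence.

    Uppercases, then strips trademark signs, whitespace, hyphens, digits
    and every other non-letter.  Errors if nothing remains.
    """
    if not raw_label:
        raise ValidationError("empty label")
    letters = _NON_LETTER.sub("", raw_label.upper())
    if not letters:
        raise ValidationError(f"label {raw_label!r} contains no letters")
    return CanonicalName.from_text(letters, raw_label=raw_label)


def _sniff_delimiter(path: Path, forced: str | None) -> str:
    if forced:
        return forced
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def _parse_rows(reader: csv.DictReader, source: str) -> list[PairRecord]:
    fields = set(reader.fieldnames or ())
    required = {"local_proprietary", "overseas_similar"}
    if not required <= fields:
        raise ValidationError(
            f"{source}: missing required columns {sorted(required - fields)}"
        )
    records: list[PairRecord] = []
    seen_ids: set[int] = set()
    for lineno, row in enumerate(reader, start=2):
        raw_id = (row.get("row_id") or "").strip()
        try:
            row_id = int(raw_id) if raw_id else len(records) + 1
        except ValueError:
            raise ValidationError(f"{source}, row {lineno}: bad row_id {raw_id!r}") from None
        if row_id in seen_ids:
            raise ValidationError(f"{source}, row {lineno}: duplicate row_id {row_id}")
        seen_ids.add(row_id)
        raw_match = (row.get("match_percent") or "").strip()
        if raw_match:
            try:
                match = int(raw_match)
            except ValueError:
                raise ValidationError(
                    f"{source}, row {lineno}: unparseable match value {raw_match!r}"
                ) from None
        else:
            match = None
        risk = (row.get("risk") or "").strip() or None
        try:
            records.append(
                PairRecord(
                    row_id=row_id,
                    generic_name=(row.get("generic_name") or "").strip(),
                    local_proprietary=(row.get("local_proprietary") or "").strip(),
                    overseas_similar=(row.get("overseas_similar") or "").strip(),
                    overseas_generic=(row.get("overseas_generic") or "").strip(),
                    printed_match_percent=match,
                    printed_risk=risk.lower() if risk else None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{source}, row {lineno}: {exc}") from None
    return records


def load_pairs(path: str | Path, delimiter: str | None = None) -> list[PairRecord]:
    """Read a CSV/TSV pair table (UTF-8; '#' comment lines are skipped).

    The delimiter is taken from the file extension or sniffed from the
    header unless forced.  Blank match-value cells become missing values;
    duplicate row ids and unparseable values are rejected with the row
    number.
    """
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ValidationError(f"{path}: empty table")
    return _parse_rows(csv.DictReader(io.StringIO("".join(lines)), delimiter=delim), str(path))


def write_pairs(
    path: str | Path,
    records: Iterable[PairRecord],
    delimiter: str = ",",
    header_comments: Sequence[str] = (),
    extra_columns: dict[int, dict[str, object]] | None = None,
) -> None:
    """Write records in the standard column order, losslessly round-trippable.

    ``header_comments`` lines are prefixed with '# '; ``extra_columns``
    maps row_id to additional cells (e.g. computed percent and band).
    """
    records = list(records)
    extra_names: list[str] = []
    if extra_columns:
        for cells in extra_columns.values():
            for name in cells:
                if name not in extra_names:
                    extra_names.append(name)

    def _emit(fh) -> None:
        for line in header_comments:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(list(COLUMNS) + extra_names)
        for r in records:
            row = [
                r.row_id,
                r.generic_name,
                r.local_proprietary,
                r.overseas_similar,
                r.overseas_generic,
                "" if r.printed_match_percent is None else r.printed_match_percent,
                r.printed_risk or "",
            ]
            cells = (extra_columns or {}).get(r.row_id, {})
            row.extend(cells.get(name, "") for name in extra_names)
            writer.writerow(row)

    if hasattr(path, "write"):
        _emit(path)
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            _emit(fh)


def load_formulary(path: str | Path) -> list[str]:
    """Read a plain-text formulary: one name per line, '#' comments."""
    names = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                names.append(entry)
    if not names:
        raise ValidationError(f"{path}: formulary contains no names")
    return names


def reference_pairs(verify_checksum: bool = True) -> list[PairRecord]:
    """The packaged 100-row reference pair table.

    99 rows carry a printed match value; row 1 prints a band but no value.
    """
    data = (
        resources.files("lasamatch").joinpath("data", _REFERENCE_RESOURCE).read_bytes()
    )
    if verify_checksum:
        digest = hashlib.sha256(data).hexdigest()
        if digest != REFERENCE_SHA256:
            raise ValidationError(
                f"reference table checksum mismatch: {digest} != {REFERENCE_SHA256}"
            )
    reader = csv.DictReader(io.StringIO(data.decode("utf-8")), delimiter="\t")
    records = _parse_rows(reader, _REFERENCE_RESOURCE)
    if len(records) != 100:
        raise ValidationError(f"reference table must have 100 rows, got {len(records)}")
    return records


# --- reproduction sweep -----------------------------------------------------

CALIBRATED = MatchParams()


def convention_id(p: MatchParams) -> str:
    """Compact fingerprint of one convention, used in reports and logs."""
    return (
        f"role={p.word_role};den={p.denominator_mode};"
        f"markers={'on' if p.end_markers else 'off'};bind={p.binding_mode};"
        f"series={p.code_series};sigma={p.sigma:g}"
        + (";exp=sigma2" if p.sigma_squared_exponent else "")
    )


def default_convention_grid(sigma: float = 3.0) -> list[MatchParams]:
    """word_role x denominator_mode x end_markers x binding_mode at one sigma."""
    return [
        MatchParams(
            sigma=sigma,
            end_markers=markers,
            denominator_mode=den,
            word_role=role,
            binding_mode=bind,
        )
        for role, den, markers, bind in itertools.product(
            ("first_name", "second_name"),
            ("word", "input", "longer", "shorter", "mean"),
            (True, False),
            ("in_order", "optimal"),
        )
    ]


@dataclass(frozen=True)
class ReproductionReport:
    """Computed-vs-printed scores for every convention in a sweep.

    ``scores`` is long-format: one row per (table row with a printed
    value) x convention, with the computed percent and the absolute
    deviation from the printed value at printed (integer) precision.
    ``convention_summary`` ranks conventions by median absolute deviation.
    """

    scores: pd.DataFrame
    convention_summary: pd.DataFrame

    @property
    def best_convention(self) -> str:
        return str(self.convention_summary.iloc[0]["convention"])


def reproduce_reference(
    grid: Sequence[MatchParams] | None = None,
    records: Sequence[PairRecord] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> ReproductionReport:
    """Rescore the reference table under every convention in ``grid``.

    Deviations are taken at the table's printed precision: the computed
    percent is rounded to the nearest integer before subtracting the
    printed value.  Rows without a printed value are skipped.  Ranking is
    by median absolute deviation, then mean absolute deviation; the
    calibrated default convention wins remaining ties.
    """
    grid = list(grid) if grid is not None else default_convention_grid()
    if not grid:
        raise ValidationError("empty convention grid")
    records = list(records) if records is not None else reference_pairs()
    rows = []
    for rec in records:
        if rec.printed_match_percent is None:
            continue
        a, b = rec.names
        for params, value in grid_scores(a, b, grid).items():
            percent = 100.0 * value
            rows.append(
                {
                    "row_id": rec.row_id,
                    "local_proprietary": rec.local_proprietary,
                    "overseas_similar": rec.overseas_similar,
                    "printed": rec.printed_match_percent,
                    "convention": convention_id(params),
                    "computed_percent": percent,
                    "computed_band": classify(percent, thresholds),
                    "abs_deviation": abs(round(percent) - rec.printed_match_percent),
                }
            )
    scores = pd.DataFrame(rows)
    summary = (
        scores.groupby("convention")["abs_deviation"]
        .agg(
            median_abs_deviation="median",
            mean_abs_deviation="mean",
            n_exact=lambda s: int((s == 0).sum()),
        )
        .reset_index()
    )
    calibrated = convention_id(CALIBRATED)
    summary["is_calibrated"] = summary["convention"] == calibrated
    summary = summary.sort_values(
        ["median_abs_deviation", "mean_abs_deviation", "is_calibrated", "convention"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return ReproductionReport(scores=scores, convention_summary=summary)
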