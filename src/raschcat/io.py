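"""File formats: item banks, response matrices, session reports.

Everything is plain comma-separated UTF-8 text with dot decimals.
Comment lines starting ``#`` carry metadata: tool version, seed, a
config hash, the shared thresholds (banks) and the category coding
(matrices).  Survey-facing matrices store the 1-4 Likert codes; the
in-memory representation is always 0-based.  Malformed numeric fields
are rejected, never silently coerced.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import json
import math
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationResult, ResponseMatrix
from .cat import AbilityEstimate, CatConfig, CatSession, CatStep
from .model import Item, ItemBank, RatingScale

__all__ = [
    "SchemaError",
    "read_item_bank",
    "write_item_bank",
    "read_response_matrix",
    "write_response_matrix",
    "write_session_report",
    "read_session_log",
    "write_calibration_report",
    "packaged_bank",
]

BANK_COLUMNS = ["item_id", "label", "difficulty", "se", "infit", "outfit", "status"]


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def _header_lines(kind: str, seed: Optional[int] = None,
                  config: Optional[object] = None) -> list[str]:
    lines = [f"# raschcat {kind} v1 (tool version {__version__})"]
    lines.append(f"# seed: {seed if seed is not None else 'none'}")
    if config is not None:
        blob = json.dumps(asdict(config) if hasattr(config, "__dataclass_fields__")
                          else config, sort_keys=True, default=str)
        lines.append(f"# config-sha1: {hashlib.sha1(blob.encode()).hexdigest()[:12]}")
    return lines


def _parse_float(text: str, where: str) -> Optional[float]:
    text = text.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise SchemaError(f"non-numeric field {text!r} at {where}") from None


# ---------------------------------------------------------------------------
# item banks
# ---------------------------------------------------------------------------

def read_item_bank(path: str | Path) -> ItemBank:
    """Read a bank file: ``#`` metadata (incl. thresholds) + CSV rows.

    Misfit rows are preserved in the bank but excluded from
    calibrated-item operations.  Schema violations (duplicate ids,
    non-numeric difficulty on a calibrated row, missing thresholds)
    raise :class:`SchemaError` naming the offending line.
    """
    text = Path(path).read_text(encoding="utf-8")
    return _parse_bank(text, str(path))


def _parse_bank(text: str, name: str) -> ItemBank:
    thresholds: Optional[list[float]] = None
    body: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("thresholds:"):
                raw = stripped.split(":", 1)[1]
                try:
                    thresholds = [float(v) for v in raw.split(",")]
                except ValueError:
                    raise SchemaError(
                        f"{name}:{lineno}: unparsable thresholds {raw!r}"
                    ) from None
        elif line.strip():
            body.append((lineno, line))
    if thresholds is None:
        raise SchemaError(f"{name}: no '# thresholds:' metadata line")
    if not body:
        raise SchemaError(f"{name}: no table rows")
    header = next(csv.reader([body[0][1]]))
    if [h.strip() for h in header] != BANK_COLUMNS:
        raise SchemaError(
            f"{name}:{body[0][0]}: header must be {','.join(BANK_COLUMNS)}"
        )
    items: list[Item] = []
    seen: set[int] = set()
    for lineno, line in body[1:]:
        row = next(csv.reader([line]))
        if len(row) != len(BANK_COLUMNS):
            raise SchemaError(f"{name}:{lineno}: expected {len(BANK_COLUMNS)} fields")
        where = f"{name}:{lineno}"
        try:
            item_id = int(row[0])
        except ValueError:
            raise SchemaError(f"{where}: bad item_id {row[0]!r}") from None
        if item_id in seen:
            raise SchemaError(f"{where}: duplicate item_id {item_id}")
        seen.add(item_id)
        status = row[6].strip()
        if status not in ("calibrated", "misfit"):
            raise SchemaError(f"{where}: unknown status {row[6]!r}")
        difficulty = _parse_float(row[2], where)
        if status == "calibrated" and (difficulty is None or not math.isfinite(difficulty)):
            raise SchemaError(f"{where}: calibrated row needs a numeric difficulty")
        items.append(
            Item(
                item_id=item_id,
                label=row[1],
                difficulty=difficulty,
                se=_parse_float(row[3], where),
                infit=_parse_float(row[4], where),
                outfit=_parse_float(row[5], where),
                status=status,
            )
        )
    return ItemBank(items=items, scale=RatingScale(tuple(thresholds)))


def write_item_bank(bank: ItemBank, path: str | Path,
                    seed: Optional[int] = None) -> None:
    buf = _io.StringIO()
    for line in _header_lines("item bank", seed=seed):
        buf.write(line + "\n")
    buf.write("# thresholds: " + ",".join(repr(t) for t in bank.scale.thresholds) + "\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(BANK_COLUMNS)
    for it in bank.items:
        writer.writerow(
            [
                it.item_id,
                it.label,
                _fmt(it.difficulty),
                _fmt(it.se),
                _fmt(it.infit),
                _fmt(it.outfit),
                it.status,
            ]
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _fmt(value: Optional[float]) -> str:
    return "" if value is None else repr(value)


def packaged_bank() -> ItemBank:
    """The packaged 37-item job-satisfaction bank (24 calibrated items)."""
    text = resources.files("raschcat.data").joinpath("jcq37_bank.csv").read_text(
        encoding="utf-8"
    )
    return _parse_bank(text, "jcq37_bank.csv")


# ---------------------------------------------------------------------------
# response matrices
# ---------------------------------------------------------------------------

def write_response_matrix(
    matrix: ResponseMatrix,
    path: str | Path,
    coding: str = "likert",
    seed: Optional[int] = None,
) -> None:
    """Persons as rows, item ids as columns, empty field = missing.

    ``coding='likert'`` stores categories as 1..M+1 (survey convention);
    ``coding='zero'`` stores the internal 0..M codes.  The convention is
    recorded in the header and honored on re-read.
    """
    if coding not in ("likert", "zero"):
        raise ValueError("coding must be 'likert' or 'zero'")
    offset = 1 if coding == "likert" else 0
    buf = _io.StringIO()
    for line in _header_lines("response matrix", seed=seed):
        buf.write(line + "\n")
    buf.write(f"# coding: {coding} (stored = internal + {offset})\n")
    buf.write(f"# categories: {matrix.n_categories}\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["person_id"] + [str(i) for i in matrix.item_ids])
    for pid, row in zip(matrix.person_ids, matrix.data):
        writer.writerow(
            [pid] + ["" if np.isnan(v) else str(int(v) + offset) for v in row]
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_response_matrix(path: str | Path) -> ResponseMatrix:
    coding = "likert"
    n_categories: Optional[int] = None
    body: list[tuple[int, str]] = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("coding:"):
                coding = stripped.split(":", 1)[1].strip().split()[0]
            elif stripped.startswith("categories:"):
                n_categories = int(stripped.split(":", 1)[1])
        elif line.strip():
            body.append((lineno, line))
    if not body:
        raise SchemaError(f"{path}: empty matrix file")
    if coding not in ("likert", "zero"):
        raise SchemaError(f"{path}: unknown coding {coding!r}")
    offset = 1 if coding == "likert" else 0
    header = next(csv.reader([body[0][1]]))
    if header[0] != "person_id":
        raise SchemaError(f"{path}:{body[0][0]}: first column must be person_id")
    try:
        item_ids = [int(h) for h in header[1:]]
    except ValueError:
        raise SchemaError(f"{path}:{body[0][0]}: item columns must be integer ids") from None
    person_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in body[1:]:
        row = next(csv.reader([line]))
        if len(row) != len(header):
            raise SchemaError(f"{path}:{lineno}: expected {len(header)} fields")
        person_ids.append(row[0])
        vals: list[float] = []
        for col, cell in zip(item_ids, row[1:]):
            cell = cell.strip()
            if cell == "":
                vals.append(np.nan)
                continue
            try:
                v = int(cell)
            except ValueError:
                raise SchemaError(
                    f"{path}:{lineno}: non-integer category {cell!r} in column {col}"
                ) from None
            v -= offset
            if v < 0 or (n_categories is not None and v > n_categories - 1):
                raise SchemaError(
                    f"{path}:{lineno}: category {cell} out of range in column {col}"
                )
            vals.append(float(v))
        rows.append(vals)
    return ResponseMatrix(
        person_ids=person_ids,
        item_ids=item_ids,
        data=np.array(rows, dtype=float),
        n_categories=n_categories,
    )


# ---------------------------------------------------------------------------
# session reports
# ---------------------------------------------------------------------------

_REPORT_COLS = (
    "Step",
    "Item difficulty",
    "Prob.",
    "Your response",
    "Expected score",
    "Estimated ability",
    "Standard error",
    "Outfit MNSQ",
)


def write_session_report(
    session: CatSession, path: str | Path, seed: Optional[int] = None
) -> Path:
    """Write the human seven-column table plus a machine JSON log.

    The human table goes to ``path``; the structured log (which
    round-trips through :func:`read_session_log`) goes to
    ``path + '.json'``.  Responses flagged unexpected carry ``*``.
    """
    path = Path(path)
    lines = _header_lines("session report", seed=seed, config=session.config)
    lines.append(f"# global rating: {session.global_rating}")
    lines.append(
        f"# final measure: {session.final.theta:.2f} logits "
        f"(SE {session.final.se:.2f}); stop: {session.stop_reason}; "
        f"outfit MNSQ {session.outfit:.2f}"
        + ("; ABERRANT" if session.aberrant else "")
    )
    widths = [4, 15, 6, 13, 14, 17, 14, 11]
    lines.append("  ".join(c.ljust(w) for c, w in zip(_REPORT_COLS, widths)))
    for s in session.steps:
        resp = f"{s.observed}*" if s.unexpected else str(s.observed)
        cells = [
            str(s.step),
            f"{s.difficulty:.2f}",
            f"{s.prob_observed:.2f}",
            resp,
            f"{s.expected:.2f}",
            f"{s.theta:.2f}",
            "-" if s.se is None else f"{s.se:.2f}",
            "-" if s.outfit is None else f"{s.outfit:.2f}",
        ]
        lines.append("  ".join(c.ljust(w) for c, w in zip(cells, widths)))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    log = {
        "version": __version__,
        "seed": seed,
        "global_rating": session.global_rating,
        "stop_reason": session.stop_reason,
        "aberrant": session.aberrant,
        "outfit": session.outfit,
        "final": asdict(session.final),
        "config": {
            k: (v if not isinstance(v, dict) else {str(a): b for a, b in v.items()})
            for k, v in asdict(session.config).items()
        },
        "steps": [asdict(s) for s in session.steps],
    }
    json_path = path.with_name(path.name + ".json")
    json_path.write_text(json.dumps(log, indent=1), encoding="utf-8")
    return json_path


def read_session_log(path: str | Path) -> CatSession:
    """Reload a machine session log into an equivalent :class:`CatSession`."""
    log = json.loads(Path(path).read_text(encoding="utf-8"))
    cfg_raw = dict(log["config"])
    cfg_raw["initial_rating_map"] = {
        int(k): float(v) for k, v in cfg_raw["initial_rating_map"].items()
    }
    config = CatConfig(**cfg_raw)
    steps = [CatStep(**s) for s in log["steps"]]
    return CatSession(
        steps=steps,
        final=AbilityEstimate(**log["final"]),
        stop_reason=log["stop_reason"],
        aberrant=log["aberrant"],
        global_rating=log["global_rating"],
        config=config,
        outfit=log["outfit"],
    )


# ---------------------------------------------------------------------------
# calibration report
# ---------------------------------------------------------------------------

def write_calibration_report(
    result: CalibrationResult, path: str | Path, seed: Optional[int] = None
) -> None:
    """Item table (difficulty, SE, infit, outfit) plus a diagnostics block."""
    buf = _io.StringIO()
    for line in _header_lines("calibration report", seed=seed):
        buf.write(line + "\n")
    d = result.dimensionality
    g = result.category_report.guideline_flags
    buf.write(f"# converged: {result.converged} after {result.n_iter} iterations\n")
    buf.write(f"# person-separation reliability: {result.reliability:.3f}\n")
    buf.write(
        "# variance explained by measures: "
        f"{d.variance_explained_by_measures:.1f}%; first contrast eigenvalue "
        f"{d.first_contrast_eigenvalue:.2f} ({d.first_contrast_variance:.1f}%)\n"
    )
    buf.write(
        "# thresholds: "
        + ",".join(f"{t:.4f}" for t in result.bank.scale.thresholds)
        + "\n"
    )
    buf.write("# category guidelines: " + json.dumps(g) + "\n")
    if result.misfit_item_ids:
        buf.write(f"# misfit items (infit outside 0.5-1.5): {result.misfit_item_ids}\n")
    table = pd.DataFrame(
        {
            "item_id": [it.item_id for it in result.bank.items],
            "label": [it.label for it in result.bank.items],
            "difficulty": [it.difficulty for it in result.bank.items],
            "se": [it.se for it in result.bank.items],
            "infit": [it.infit for it in result.bank.items],
            "outfit": [it.outfit for it in result.bank.items],
        }
    )
    table.to_csv(buf, index=False, float_format="%.4f")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
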