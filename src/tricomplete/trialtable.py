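"""Trial-table CSV reading, writing and validation.

The trial table is the package's interchange format: UTF-8, comma-separated,
one row per trial with columns

    subject_id, trial_index, design_id, template_label, handedness,
    xA_x, xA_y, xB_x, xB_y, xD_x, xD_y

All coordinates are meters with a decimal point; missing responses are empty
cells. Floats are written with 12 significant digits, so writing is
bit-exact for a fixed session. On reading, each trial's template (sides,
interior angles, handedness) is reconstructed from the guided vectors
themselves, which keeps the format self-contained.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .exceptions import TriangleError
from .geometry import PlanarVector, Session, TriangleTemplate, Trial, wrap_angle

__all__ = ["COLUMNS", "write_trial_table", "read_trial_table", "validate_trial_table"]

COLUMNS = (
    "subject_id",
    "trial_index",
    "design_id",
    "template_label",
    "handedness",
    "xA_x",
    "xA_y",
    "xB_x",
    "xB_y",
    "xD_x",
    "xD_y",
)

_FLOAT_FMT = "{:.12g}"


def _fmt(v: float) -> str:
    return _FLOAT_FMT.format(v)


def write_trial_table(sessions, path: str | Path) -> None:
    """Write one or more sessions to a trial-table CSV."""
    if isinstance(sessions, Session):
        sessions = [sessions]
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for session in sessions:
            for t in session.trials:
                row = [
                    session.subject_id,
                    t.index,
                    session.design_id,
                    t.template.label,
                    t.template.handedness,
                    _fmt(t.xA.x),
                    _fmt(t.xA.y),
                    _fmt(t.xB.x),
                    _fmt(t.xB.y),
                    _fmt(t.xD.x) if t.xD is not None else "",
                    _fmt(t.xD.y) if t.xD is not None else "",
                ]
                writer.writerow(row)


def _template_from_vectors(
    label: str, handedness: str, xA: PlanarVector, xB: PlanarVector
) -> TriangleTemplate:
    """Reconstruct the triangle template implied by the guided vectors."""
    xC = -(xA + xB)
    a, b, c = xA.magnitude, xB.magnitude, xC.magnitude
    if min(a, b, c) <= 0:
        raise TriangleError(f"degenerate guided path for template {label!r}")

    def _angle(opposite: float, s1: float, s2: float) -> float:
        cos = (s1 * s1 + s2 * s2 - opposite * opposite) / (2 * s1 * s2)
        return math.degrees(math.acos(min(1.0, max(-1.0, cos))))

    ang_origin = _angle(b, a, c)
    ang_g1 = _angle(c, a, b)
    ang_g2 = 180.0 - ang_origin - ang_g1
    return TriangleTemplate(
        label=label,
        angles=(ang_origin, ang_g1, ang_g2),
        side_a=a,
        side_b=b,
        side_c=c,
        handedness=handedness,
    )


def read_trial_table(path: str | Path) -> list[Session]:
    """Read a trial-table CSV back into sessions (one per subject)."""
    path = Path(path)
    by_subject: dict[str, list[Trial]] = {}
    design_ids: dict[str, str] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != COLUMNS:
            raise ValueError(
                f"unexpected header {reader.fieldnames}; expected {list(COLUMNS)}"
            )
        for row in reader:
            xA = PlanarVector(float(row["xA_x"]), float(row["xA_y"]))
            xB = PlanarVector(float(row["xB_x"]), float(row["xB_y"]))
            xD = None
            if row["xD_x"] != "" and row["xD_y"] != "":
                xD = PlanarVector(float(row["xD_x"]), float(row["xD_y"]))
            template = _template_from_vectors(
                row["template_label"], row["handedness"], xA, xB
            )
            trial = Trial(
                index=int(row["trial_index"]),
                template=template,
                xA=xA,
                xB=xB,
                xC=-(xA + xB),
                xD=xD,
            )
            by_subject.setdefault(row["subject_id"], []).append(trial)
            design_ids[row["subject_id"]] = row["design_id"]
    sessions = []
    for subject_id, trials in by_subject.items():
        trials.sort(key=lambda t: t.index)
        sessions.append(
            Session(
                subject_id=subject_id,
                design_id=design_ids[subject_id],
                trials=tuple(trials),
            )
        )
    return sessions


@dataclass
class ValidationReport:
    """Machine-readable validation outcome for one trial table."""

    path: str
    n_rows: int = 0
    violations: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, line: int, kind: str, message: str) -> None:
        self.violations.append({"line": line, "kind": kind, "message": message})

    def to_dict(self) -> dict:
        return {
            "path": self.path,
            "n_rows": self.n_rows,
            "ok": self.ok,
            "violations": self.violations,
        }


def validate_trial_table(
    path: str | Path,
    reference_templates: Mapping[str, TriangleTemplate] | None = None,
    tol: float = 1e-6,
) -> ValidationReport:
    """Check a trial-table CSV for structural and geometric violations.

    Checks: exact header, parseable numeric fields, handedness values,
    consecutive 1..n trial indices per subject, guided vectors forming a
    valid (non-degenerate) triangle, the handedness column matching the turn
    direction of the vectors, and — when ``reference_templates`` maps labels
    to known templates (e.g. the built-in designs) — side lengths matching
    the labeled template within ``tol``.
    """
    path = Path(path)
    report = ValidationReport(path=str(path))
    indices: dict[str, list[int]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != COLUMNS:
            report.add(1, "header", f"expected {list(COLUMNS)}, got {reader.fieldnames}")
            return report
        for line, row in enumerate(reader, start=2):
            report.n_rows += 1
            try:
                idx = int(row["trial_index"])
            except (TypeError, ValueError):
                report.add(line, "parse", f"bad trial_index {row['trial_index']!r}")
                continue
            if row["handedness"] not in ("left", "right"):
                report.add(line, "handedness", f"bad handedness {row['handedness']!r}")
                continue
            try:
                xA = PlanarVector(float(row["xA_x"]), float(row["xA_y"]))
                xB = PlanarVector(float(row["xB_x"]), float(row["xB_y"]))
            except (TypeError, ValueError) as exc:
                report.add(line, "parse", f"bad guided vector: {exc}")
                continue
            indices.setdefault(row["subject_id"], []).append(idx)
            try:
                _template_from_vectors(row["template_label"], row["handedness"], xA, xB)
            except TriangleError as exc:
                report.add(line, "geometry", str(exc))
                continue
            turn = wrap_angle(xB.heading_deg - xA.heading_deg)
            vec_hand = "left" if turn > 0 else "right"
            if vec_hand != row["handedness"]:
                report.add(
                    line,
                    "handedness",
                    f"vectors imply {vec_hand}-handed turns but row says {row['handedness']}",
                )
            if reference_templates and row["template_label"] in reference_templates:
                ref = reference_templates[row["template_label"]]
                for name, got, want in (
                    ("A", xA.magnitude, ref.side_a),
                    ("B", xB.magnitude, ref.side_b),
                    ("C", (-(xA + xB)).magnitude, ref.side_c),
                ):
                    if abs(got - want) > tol * max(1.0, want):
                        report.add(
                            line,
                            "geometry",
                            f"|x{name}| = {got:.6f} differs from template side {want:.6f}",
                        )
    for subject, idxs in indices.items():
        if sorted(idxs) != list(range(1, len(idxs) + 1)):
            report.add(
                0,
                "ordering",
                f"subject {subject}: trial indices {sorted(idxs)} are not 1..n consecutive",
            )
    return report
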