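"""Data model, parsing and validation for annotated cleavage-division events.

The raw observable of a time-lapse experiment is, per embryo, a binary
lineage tree of blastomeres: the zygote (lineage label ``"1"``) divides into
``"1.1"`` and ``"1.2"``, and so on.  Each cell carries its birth and end time
in hours post activation (hpa; activation of the reconstructed NT oocyte or
sperm injection defines t = 0), a fate (``divided``, ``arrested``, ``fused``
or ``censored`` at the observation horizon), and any M-phase aberrancies
observed at its division (multipolar/unipolar spindle, chromatid
nondisjunction, cell fusion, cytokinesis failure).

A division is a single time stamp: the mother's ``end_time`` equals both
daughters' ``birth_time``.  Aberrancies at a division are attributed to the
mother (M phase belongs to the dividing cell).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, StructureError, ValidationError

logger = logging.getLogger(__name__)

FATES = ("divided", "arrested", "fused", "censored")
ABERRANCIES = (
    "multipolar_spindle",
    "unipolar_spindle",
    "nondisjunction",
    "cell_fusion",
    "cytokinesis_failure",
)

#: default observation horizon of the time-lapse experiment, hpa
DEFAULT_HORIZON = 96.0

#: tolerance for comparing annotated times (inputs carry decimal hours)
TIME_ATOL = 1e-6

REQUIRED_COLUMNS = (
    "embryo_id",
    "group",
    "cell_id",
    "parent_id",
    "birth_hpa",
    "end_hpa",
    "fate",
)
OPTIONAL_COLUMNS = (
    "treatment",
    "aberrancy",
    "cytokinesis_onset_hpa",
    "blastocyst",
    "esc",
    "fetus",
)


@dataclass
class DivisionRecord:
    """One blastomere: a row of the annotated division-event table."""

    embryo_id: str
    cell_id: str
    parent_id: str | None
    birth_time: float
    end_time: float | None
    fate: str
    aberrancy: frozenset[str] = frozenset()
    cytokinesis_onset: float | None = None

    @property
    def round(self) -> int:
        """Cleavage round = depth in the lineage tree (root is round 1)."""
        return self.cell_id.count(".") + 1

    @property
    def cycle_length(self) -> float | None:
        """end - birth for cells that completed their cycle, else None."""
        if self.fate == "divided" and self.end_time is not None:
            return self.end_time - self.birth_time
        return None

    def validate(self) -> None:
        if self.fate not in FATES:
            raise ValidationError(
                f"embryo {self.embryo_id}, cell {self.cell_id}: unknown fate "
                f"{self.fate!r}"
            )
        unknown = self.aberrancy - set(ABERRANCIES)
        if unknown:
            raise ValidationError(
                f"embryo {self.embryo_id}, cell {self.cell_id}: unknown "
                f"aberrancy {sorted(unknown)}"
            )
        if self.birth_time < 0:
            raise ValidationError(
                f"embryo {self.embryo_id}, cell {self.cell_id}: negative "
                f"birth_time {self.birth_time}"
            )
        if self.fate == "divided":
            if self.end_time is None or not self.end_time > self.birth_time:
                raise ValidationError(
                    f"embryo {self.embryo_id}, cell {self.cell_id}: divided "
                    f"cell needs end_time > birth_time "
                    f"(birth={self.birth_time}, end={self.end_time})"
                )
        is_root = self.parent_id in (None, "")
        if is_root and abs(self.birth_time) > TIME_ATOL:
            raise ValidationError(
                f"embryo {self.embryo_id}: root cell {self.cell_id} must have "
                f"birth_time 0 (activation), got {self.birth_time}"
            )


@dataclass
class EmbryoRecord:
    """All cells of one embryo plus its grouping and outcome annotations."""

    embryo_id: str
    group: str
    treatment: str = "none"
    outcome_blastocyst: bool | None = None
    outcome_esc: bool | None = None
    outcome_fetus: bool | None = None
    cells: dict[str, DivisionRecord] = field(default_factory=dict)

    @property
    def root(self) -> DivisionRecord:
        roots = [c for c in self.cells.values() if not c.parent_id]
        if len(roots) != 1:
            raise ValidationError(
                f"embryo {self.embryo_id}: expected exactly one root cell, "
                f"found {len(roots)}"
            )
        return roots[0]

    def children_of(self, cell_id: str) -> list[DivisionRecord]:
        kids = [c for c in self.cells.values() if c.parent_id == cell_id]
        return sorted(kids, key=lambda c: c.cell_id)

    def validate(self) -> None:
        _ = self.root  # exactly-one-root invariant
        for cell in self.cells.values():
            cell.validate()
            if not cell.parent_id:
                continue
            parent = self.cells.get(cell.parent_id)
            if parent is None:
                raise ValidationError(
                    f"embryo {self.embryo_id}: cell {cell.cell_id} names "
                    f"missing parent {cell.parent_id!r}"
                )
            if not cell.cell_id.startswith(cell.parent_id + "."):
                raise ValidationError(
                    f"embryo {self.embryo_id}: cell {cell.cell_id} label does "
                    f"not extend parent label {cell.parent_id!r}"
                )
            if parent.fate != "divided":
                raise ValidationError(
                    f"embryo {self.embryo_id}: cell {cell.cell_id} has parent "
                    f"{parent.cell_id} with fate {parent.fate!r} (must be "
                    f"'divided')"
                )
            if parent.end_time is None or not math.isclose(
                parent.end_time, cell.birth_time, abs_tol=TIME_ATOL
            ):
                raise ValidationError(
                    f"embryo {self.embryo_id}: cell {cell.cell_id} birth_time "
                    f"{cell.birth_time} does not match parent "
                    f"{parent.cell_id} end_time {parent.end_time}"
                )


@dataclass
class LineageTree:
    """Validated binary division tree of one embryo.

    Thin view over an :class:`EmbryoRecord` with the binary-division
    invariant enforced: every divided cell has exactly two children; cells
    alive at the observation horizon are censored there.
    """

    embryo: EmbryoRecord
    observation_horizon: float = DEFAULT_HORIZON

    @property
    def embryo_id(self) -> str:
        return self.embryo.embryo_id

    @property
    def nodes(self) -> dict[str, DivisionRecord]:
        return self.embryo.cells

    @property
    def root(self) -> DivisionRecord:
        return self.embryo.root

    def cells_of_round(self, k: int) -> list[DivisionRecord]:
        return sorted(
            (c for c in self.nodes.values() if c.round == k),
            key=lambda c: c.cell_id,
        )

    def sister_pairs(self, k: int) -> list[tuple[DivisionRecord, DivisionRecord]]:
        """Sister pairs of round k, each ordered (".1" cell, ".2" cell)."""
        pairs = []
        by_parent: dict[str, list[DivisionRecord]] = {}
        for cell in self.cells_of_round(k):
            if cell.parent_id:
                by_parent.setdefault(cell.parent_id, []).append(cell)
        for kids in by_parent.values():
            if len(kids) == 2:
                pairs.append(tuple(sorted(kids, key=lambda c: c.cell_id)))
        return pairs


def build_lineage(
    embryo: EmbryoRecord, horizon: float = DEFAULT_HORIZON
) -> LineageTree:
    """Build a validated :class:`LineageTree` from a parsed embryo.

    Divided cells must have exactly two children (a :class:`StructureError`
    otherwise); arrested/fused cells are legal leaves; censored cells carry
    ``end_time = horizon``.
    """
    embryo.validate()
    for cell in embryo.cells.values():
        n_children = len(embryo.children_of(cell.cell_id))
        # a divided cell has exactly two annotated daughters, or none at all
        # (division observed at the edge of the annotation)
        if cell.fate == "divided" and n_children not in (0, 2):
            raise StructureError(
                f"embryo {embryo.embryo_id}: divided cell {cell.cell_id} has "
                f"{n_children} children (expected 2)"
            )
        if cell.fate != "divided" and n_children:
            raise StructureError(
                f"embryo {embryo.embryo_id}: non-divided cell {cell.cell_id} "
                f"has children"
            )
        if cell.fate == "censored":
            cell.end_time = horizon
    return LineageTree(embryo, observation_horizon=horizon)


# ---------------------------------------------------------------------------
# parsing


def _parse_float(value, column: str, context: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "NA", "nan", "NaN"):
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise FormatError(f"{context}: cannot parse {column}={s!r}") from exc


def _parse_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "NA", "nan", "NaN"):
        return None
    if s in ("1", "1.0", "True", "true"):
        return True
    if s in ("0", "0.0", "False", "false"):
        return False
    raise FormatError(f"cannot parse boolean outcome value {s!r}")


def _parse_aberrancy(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return frozenset()
    s = str(value).strip()
    if s in ("", "none", "NA"):
        return frozenset()
    return frozenset(part.strip() for part in s.split(";") if part.strip())


def embryos_from_frame(table: pd.DataFrame) -> list[EmbryoRecord]:
    """Convert a division-event table (long format) into validated embryos."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if table.empty:
        logger.warning("division-event table contains no rows")
        return []

    embryos: dict[str, EmbryoRecord] = {}
    for row in table.to_dict("records"):
        eid = str(row["embryo_id"])
        ctx = f"embryo {eid}, cell {row['cell_id']}"
        if eid not in embryos:
            embryos[eid] = EmbryoRecord(
                embryo_id=eid,
                group=str(row["group"]),
                treatment=str(row.get("treatment", "none") or "none"),
                outcome_blastocyst=_parse_bool(row.get("blastocyst")),
                outcome_esc=_parse_bool(row.get("esc")),
                outcome_fetus=_parse_bool(row.get("fetus")),
            )
        parent_raw = row["parent_id"]
        parent = None if pd.isna(parent_raw) or str(parent_raw) == "" else str(parent_raw)
        record = DivisionRecord(
            embryo_id=eid,
            cell_id=str(row["cell_id"]),
            parent_id=parent,
            birth_time=_parse_float(row["birth_hpa"], "birth_hpa", ctx),
            end_time=_parse_float(row["end_hpa"], "end_hpa", ctx),
            fate=str(row["fate"]).strip(),
            aberrancy=_parse_aberrancy(row.get("aberrancy")),
            cytokinesis_onset=_parse_float(
                row.get("cytokinesis_onset_hpa"), "cytokinesis_onset_hpa", ctx
            ),
        )
        if record.cell_id in embryos[eid].cells:
            raise ValidationError(
                f"embryo {eid}: duplicate cell_id {record.cell_id!r}"
            )
        embryos[eid].cells[record.cell_id] = record

    out = list(embryos.values())
    for embryo in out:
        embryo.validate()
    return out


def parse_division_table(path, **read_csv_kwargs) -> list[EmbryoRecord]:
    """Read a division-event CSV and return validated :class:`EmbryoRecord`s.

    The CSV is UTF-8 with "." as decimal separator and NA for missing; see
    the package README for the column schema.
    """
    table = pd.read_csv(path, dtype=str, **read_csv_kwargs)
    return embryos_from_frame(table)


def embryos_to_frame(embryos: list[EmbryoRecord]) -> pd.DataFrame:
    """Serialize embryos back to the long division-event table schema."""
    rows = []
    for embryo in embryos:
        for cell in sorted(embryo.cells.values(), key=lambda c: (c.round, c.cell_id)):
            rows.append(
                {
                    "embryo_id": embryo.embryo_id,
                    "group": embryo.group,
                    "treatment": embryo.treatment,
                    "cell_id": cell.cell_id,
                    "parent_id": cell.parent_id or "",
                    "birth_hpa": cell.birth_time,
                    "end_hpa": cell.end_time,
                    "fate": cell.fate,
                    "aberrancy": ";".join(sorted(cell.aberrancy)) or "none",
                    "cytokinesis_onset_hpa": cell.cytokinesis_onset,
                    "blastocyst": _bool_out(embryo.outcome_blastocyst),
                    "esc": _bool_out(embryo.outcome_esc),
                    "fetus": _bool_out(embryo.outcome_fetus),
                }
            )
    return pd.DataFrame(rows)


def _bool_out(value: bool | None):
    return "NA" if value is None else int(value)
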