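"""Component algebra for hydration free energies.

A hydration free energy ΔA_hyd splits into the solute's internal
reorganization energy E_reorg plus the free-energy change of the water,
and the water part further splits into electrostatic, dispersion and
cavitation components:

    ΔA_hyd   = E_reorg + ΔA_wat
    ΔA_wat   = ΔA_ES + ΔA_disp + ΔA_cav
    ΔA_nonES = ΔA_disp + ΔA_cav

Signs follow the component tables verbatim: ΔA_ES and ΔA_disp are
stabilizing (negative), ΔA_cav is a cost (positive), E_reorg small and
positive.  Nothing here recomputes components from simulation — the
module validates and recombines tabulated values, and provides the
Weeks–Chandler–Andersen (WCA) split of a Lennard-Jones potential that
defines the cavitation/dispersion separation.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "SoluteRecord",
    "ComponentSums",
    "LJParams",
    "ConsistencyEntry",
    "compose",
    "load_component_table",
    "write_component_table",
    "aromatics_records",
    "check_consistency",
    "wca_split",
    "lj_potential",
    "CONSISTENCY_TOL",
]

logger = logging.getLogger(__name__)

#: Default tolerance (kcal/mol) for comparing a recomposed ΔA_hyd against a
#: printed total.  Tables round each column to 0.01 independently, so the
#: sum of four columns may drift from the printed total by up to ~0.02.
CONSISTENCY_TOL = 0.015

_SCHEMA = ["name", "dA_hyd", "e_reorg", "dA_es", "dA_disp", "dA_cav", "exp", "asa"]
_REQUIRED = _SCHEMA[:6]


class TableFormatError(ValueError):
    """Raised when a component table violates the documented CSV schema."""


@dataclass(frozen=True)
class SoluteRecord:
    """One solute's named free-energy components (kcal/mol).

    ``dA_hyd_printed`` is the total as printed in a source table (kept
    separately so rounding consistency can be audited); ``exp_dA_hyd`` an
    optional experimental reference; ``asa`` an optional solvent-accessible
    surface area in Å².
    """

    name: str
    e_reorg: float
    dA_es: float
    dA_disp: float
    dA_cav: float
    dA_hyd_printed: float | None = None
    exp_dA_hyd: float | None = None
    asa: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("solute name must be non-empty")
        for fld in ("e_reorg", "dA_es", "dA_disp", "dA_cav"):
            v = getattr(self, fld)
            if v is None or not math.isfinite(v):
                raise ValueError(f"{self.name}: component {fld} missing or non-finite ({v!r})")


@dataclass(frozen=True)
class ComponentSums:
    """The three composed sums for one solute (kcal/mol)."""

    dA_wat: float
    dA_non_es: float
    dA_hyd: float


@dataclass(frozen=True)
class LJParams:
    """Lennard-Jones well depth ε (kcal/mol) and size σ (Å)."""

    epsilon: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class ConsistencyEntry:
    name: str
    recomposed: float
    printed: float
    deviation: float
    flagged: bool


def compose(rec: SoluteRecord) -> ComponentSums:
    """Recombine a record's components into ΔA_wat, ΔA_nonES and ΔA_hyd."""
    dA_non_es = rec.dA_disp + rec.dA_cav
    dA_wat = rec.dA_es + dA_non_es
    return ComponentSums(dA_wat=dA_wat, dA_non_es=dA_non_es, dA_hyd=rec.e_reorg + dA_wat)


def _parse_float(cell: str, row_idx: int, col: str) -> float:
    # tables pasted from PDFs use U+2212 for the minus sign
    txt = cell.strip().replace("−", "-")
    try:
        return float(txt)
    except ValueError:
        raise TableFormatError(
            f"row {row_idx}: non-numeric value {cell!r} in column {col!r}"
        ) from None


def _records_from_reader(reader: csv.reader) -> list[SoluteRecord]:
    rows = [r for r in reader if r and any(c.strip() for c in r)]
    if not rows:
        raise TableFormatError("empty file: no header row")
    header = [h.strip() for h in rows[0]]
    if header[: len(_REQUIRED)] != _REQUIRED:
        raise TableFormatError(
            f"header must start with {_REQUIRED}, got {header}"
        )
    col = {name: i for i, name in enumerate(header)}
    records: list[SoluteRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(rows[1:], start=1):
        if len(row) < len(_REQUIRED):
            raise TableFormatError(f"row {idx}: expected ≥{len(_REQUIRED)} cells, got {len(row)}")
        name = row[col["name"]].strip()
        if name in seen:
            raise TableFormatError(f"row {idx}: duplicate solute name {name!r}")
        seen.add(name)

        def cell(c: str) -> str | None:
            i = col.get(c)
            if i is None or i >= len(row):
                return None
            v = row[i].strip()
            return v or None

        for c in _REQUIRED[2:]:
            if cell(c) is None:
                raise TableFormatError(f"row {idx}: missing required column {c!r}")
        records.append(
            SoluteRecord(
                name=name,
                dA_hyd_printed=(
                    _parse_float(cell("dA_hyd"), idx, "dA_hyd") if cell("dA_hyd") else None
                ),
                e_reorg=_parse_float(cell("e_reorg"), idx, "e_reorg"),
                dA_es=_parse_float(cell("dA_es"), idx, "dA_es"),
                dA_disp=_parse_float(cell("dA_disp"), idx, "dA_disp"),
                dA_cav=_parse_float(cell("dA_cav"), idx, "dA_cav"),
                exp_dA_hyd=_parse_float(cell("exp"), idx, "exp") if cell("exp") else None,
                asa=_parse_float(cell("asa"), idx, "asa") if cell("asa") else None,
            )
        )
    if not records:
        logger.warning("component table has a header but no data rows")
    return records


def load_component_table(path) -> list[SoluteRecord]:
    """Load a component table from CSV (schema: name, dA_hyd, e_reorg,
    dA_es, dA_disp, dA_cav[, exp[, asa]]; UTF-8, '.' decimal)."""
    with open(path, newline="", encoding="utf-8") as fh:
        return _records_from_reader(csv.reader(fh))


def write_component_table(records: list[SoluteRecord], path) -> None:
    """Write records back out in the same CSV schema (blank optionals)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_SCHEMA)
        for r in records:
            w.writerow(
                [
                    r.name,
                    "" if r.dA_hyd_printed is None else repr(r.dA_hyd_printed),
                    repr(r.e_reorg),
                    repr(r.dA_es),
                    repr(r.dA_disp),
                    repr(r.dA_cav),
                    "" if r.exp_dA_hyd is None else repr(r.exp_dA_hyd),
                    "" if r.asa is None else repr(r.asa),
                ]
            )


def aromatics_records() -> list[SoluteRecord]:
    """The packaged eight-solute aromatic-hydrocarbon component table."""
    text = resources.files("hydrodecomp.data").joinpath("aromatics_components.csv").read_text(
        encoding="utf-8"
    )
    return _records_from_reader(csv.reader(io.StringIO(text)))


def check_consistency(
    records: list[SoluteRecord], tol: float = CONSISTENCY_TOL
) -> list[ConsistencyEntry]:
    """Audit each record's printed total against the recomposed sum.

    Records without a printed total are skipped with a warning.  A record
    is flagged when ``|recomposed − printed| > tol``.
    """
    report: list[ConsistencyEntry] = []
    for rec in records:
        if rec.dA_hyd_printed is None:
            logger.warning("%s: no printed total; skipped in consistency check", rec.name)
            continue
        total = compose(rec).dA_hyd
        dev = abs(total - rec.dA_hyd_printed)
        report.append(
            ConsistencyEntry(
                name=rec.name,
                recomposed=total,
                printed=rec.dA_hyd_printed,
                deviation=dev,
                flagged=dev > tol,
            )
        )
    return report


def lj_potential(r: float, lj: LJParams) -> float:
    """Lennard-Jones 12-6 potential u(r) = 4ε[(σ/r)¹² − (σ/r)⁶]."""
    if r <= 0:
        raise ValueError(f"r must be positive, got {r}")
    sr6 = (lj.sigma / r) ** 6
    return 4.0 * lj.epsilon * (sr6 * sr6 - sr6)


def wca_split(r: float, lj: LJParams) -> tuple[float, float]:
    """Split a Lennard-Jones potential at its minimum (WCA construction).

    Returns ``(u_repulsive, u_attractive)``.  For r below the minimum
    r_min = 2^(1/6)·σ the repulsive branch is u_LJ(r)+ε and the attractive
    branch is the constant −ε; beyond r_min the repulsive branch is zero
    and the attractive branch is u_LJ(r).  The two branches sum to u_LJ(r)
    everywhere.  The repulsive branch is the cavity-forming (hard-core)
    part; the attractive branch carries the dispersion well.
    """
    u = lj_potential(r, lj)  # validates r > 0
    r_min = 2.0 ** (1.0 / 6.0) * lj.sigma
    if r < r_min:
        return u + lj.epsilon, -lj.epsilon
    return 0.0, u
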