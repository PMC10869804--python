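"""Chemical-shift-perturbation (CSP) mapping.

Amide 1H/15N shifts of the free and ligand-bound protein are combined into a
weighted per-residue perturbation

    d = sqrt(0.5 * (dH^2 + (w * dN)^2)),    w = 0.14 by default,

where dH and dN are the bound-minus-free shift changes in ppm.  The nitrogen
weight compensates for the larger 15N shift range.  A second variant
("as_printed") applies the weight outside the square, d = sqrt(0.5 * (dH^2 +
w * dN^2)); it is dimensionally inconsistent but ships so that either reading
of a published methods equation can be reproduced.  Residues with d above a
threshold (default 0.05 ppm) are flagged significant.

Exchange-regime labels (fast/slow) are input annotations carried through from
the shift tables, not inferred from spectra.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import pandas as pd

from .errors import ShiftTableError
from .structure import NumberingMap, Structure, write_annotated_structure

__all__ = [
    "ShiftRecord",
    "CSPRecord",
    "CSPConfig",
    "CSPResult",
    "read_shift_table",
    "compute_csp",
    "saturation_check",
    "map_csp",
]

REQUIRED_COLUMNS = ("residue", "aa", "H_ppm", "N_ppm")


@dataclasses.dataclass(frozen=True)
class ShiftRecord:
    native_num: int
    res_type: str  # 1-letter code
    dH: float  # amide 1H shift, ppm
    dN: float  # amide 15N shift, ppm
    exchange: str = "unassigned"  # {fast, slow, unassigned}

    def __post_init__(self) -> None:
        if self.native_num < 1:
            raise ValueError("residue numbers are 1-based")
        if not (math.isfinite(self.dH) and math.isfinite(self.dN)):
            raise ValueError(f"residue {self.native_num}: shifts must be finite")


@dataclasses.dataclass
class CSPRecord:
    native_num: int
    d: float  # weighted CSP, ppm
    significant: bool
    exchange: str = "unassigned"


@dataclasses.dataclass(frozen=True)
class CSPConfig:
    nitrogen_weight: float = 0.14
    threshold: float = 0.05  # ppm
    formula_variant: str = "weight_squared_with_shift"  # or "as_printed"

    def __post_init__(self) -> None:
        if self.nitrogen_weight <= 0:
            raise ValueError("nitrogen_weight must be positive")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.formula_variant not in ("weight_squared_with_shift", "as_printed"):
            raise ValueError(f"unknown formula variant {self.formula_variant!r}")


@dataclasses.dataclass
class CSPResult:
    records: list[CSPRecord]
    only_in_free: list[int]  # residues without a bound-state counterpart
    only_in_bound: list[int]

    @property
    def significant(self) -> list[CSPRecord]:
        return [r for r in self.records if r.significant]


def weighted_csp(delta_h: float, delta_n: float, config: CSPConfig | None = None) -> float:
    """The weighted perturbation for one residue's shift changes."""
    config = config or CSPConfig()
    w = config.nitrogen_weight
    if config.formula_variant == "as_printed":
        return math.sqrt(0.5 * (delta_h**2 + w * delta_n**2))
    return math.sqrt(0.5 * (delta_h**2 + (w * delta_n) ** 2))


def read_shift_table(path: str | Path) -> list[ShiftRecord]:
    """Read a TSV shift table with columns residue, aa, H_ppm, N_ppm [, exchange].

    Duplicate residue numbers and non-numeric shifts are rejected; rows absent
    from the table (e.g. prolines, which have no amide) simply yield no record.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise ShiftTableError(f"{path.name}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ShiftTableError(f"{path.name}: missing column(s) {missing}")
    if df.empty:
        raise ShiftTableError(f"{path.name}: table has no rows")
    if df["residue"].duplicated().any():
        dup = int(df["residue"][df["residue"].duplicated()].iloc[0])
        raise ShiftTableError(f"{path.name}: duplicate residue number {dup}")
    records = []
    for _, row in df.iterrows():
        try:
            h = float(row["H_ppm"])
            n = float(row["N_ppm"])
            num = int(row["residue"])
        except (TypeError, ValueError) as exc:
            raise ShiftTableError(
                f"{path.name}: non-numeric value in row for residue {row['residue']!r}"
            ) from exc
        exchange = str(row["exchange"]) if "exchange" in df.columns else "unassigned"
        if exchange not in ("fast", "slow"):
            exchange = "unassigned"
        records.append(ShiftRecord(num, str(row["aa"]), h, n, exchange))
    return records


def write_shift_table(records: list[ShiftRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "residue": [r.native_num for r in records],
            "aa": [r.res_type for r in records],
            "H_ppm": [r.dH for r in records],
            "N_ppm": [r.dN for r in records],
            "exchange": [r.exchange for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def compute_csp(
    free: list[ShiftRecord],
    bound: list[ShiftRecord],
    config: CSPConfig | None = None,
) -> CSPResult:
    """Per-residue weighted CSP between free and bound shift tables.

    Residues present in only one table are reported in the result, never
    silently dropped: a peak missing from the bound state is typically a
    line-broadened slow-exchange resonance and is biologically meaningful.
    """
    config = config or CSPConfig()
    free_by_num = {r.native_num: r for r in free}
    bound_by_num = {r.native_num: r for r in bound}
    common = sorted(set(free_by_num) & set(bound_by_num))
    if not common:
        raise ShiftTableError("free and bound tables share no residues")
    records = []
    for num in common:
        f, b = free_by_num[num], bound_by_num[num]
        d = weighted_csp(b.dH - f.dH, b.dN - f.dN, config)
        exchange = b.exchange if b.exchange != "unassigned" else f.exchange
        records.append(CSPRecord(num, d, d > config.threshold, exchange))
    return CSPResult(
        records=records,
        only_in_free=sorted(set(free_by_num) - set(bound_by_num)),
        only_in_bound=sorted(set(bound_by_num) - set(free_by_num)),
    )


def saturation_check(
    titration_tables: list[list[ShiftRecord]],
    config: CSPConfig | None = None,
    saturation_threshold: float = 0.01,
) -> tuple[list[float], bool]:
    """Maximum per-residue CSP change between consecutive titration points.

    Returns ``(per_step_max, saturated)``; the titration is saturated when the
    final step's maximum change is below `saturation_threshold` (ppm).
    Residue sets are intersected between steps (with no error) since peaks
    appear/disappear during a titration.
    """
    if len(titration_tables) < 2:
        raise ValueError("saturation check needs at least 2 titration points")
    config = config or CSPConfig()
    per_step = []
    for prev, curr in zip(titration_tables, titration_tables[1:]):
        prev_by = {r.native_num: r for r in prev}
        curr_by = {r.native_num: r for r in curr}
        common = set(prev_by) & set(curr_by)
        if not common:
            per_step.append(float("inf"))
            continue
        per_step.append(
            max(
                weighted_csp(curr_by[n].dH - prev_by[n].dH, curr_by[n].dN - prev_by[n].dN, config)
                for n in common
            )
        )
    return per_step, per_step[-1] < saturation_threshold


@dataclasses.dataclass
class CSPMapSummary:
    significant: list[int]
    in_region: list[int]
    fraction_in_region: float | None  # None when nothing is significant
    unmapped: list[int]  # CSP residues with no residue in the structure


def map_csp(
    result: CSPResult,
    structure: Structure,
    numbering: NumberingMap,
    out_path: str | Path,
    region: tuple[int, int] | None = None,
) -> CSPMapSummary:
    """Write CSP values into the B-factor column and summarize the map.

    CSP residues are translated to coordinate-file numbering and annotated on
    every chain that has them; residues absent from the coordinates are listed
    as unmapped.  When a native-numbered `region` (start, end) is given, the
    summary reports the fraction of significant residues falling inside it.
    """
    values: dict[tuple[str, int], float] = {}
    present: set[int] = set()
    chain_ids = [c.chain_id for c in structure.models[0]]
    for rec in result.records:
        file_num = numbering.to_file(rec.native_num)
        for chain_id in chain_ids:
            chain = structure.chain(chain_id)
            if chain is not None and chain.residue(file_num) is not None:
                values[(chain_id, file_num)] = rec.d
                present.add(rec.native_num)
    write_annotated_structure(structure, values, out_path)

    significant = sorted(r.native_num for r in result.records if r.significant)
    unmapped = sorted(set(r.native_num for r in result.records) - present)
    in_region: list[int] = []
    fraction = None
    if region is not None and significant:
        lo, hi = region
        in_region = [n for n in significant if lo <= n <= hi]
        fraction = len(in_region) / len(significant)
    return CSPMapSummary(
        significant=significant,
        in_region=in_region,
        fraction_in_region=fraction,
        unmapped=unmapped,
    )
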