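"""The flat per-cell table: AIRR-style rearrangement TSV with metadata.

One row per cell, paired heavy+light chains flattened onto the row
(``*_light`` extension columns).  The same schema is produced by the
simulator and expected from mapped real data, so the whole analysis
pipeline is agnostic to the origin of the table.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .cells import Cell, translate
from .config import HOTSPOT_MUTATIONS, HOTSPOT_POSITIONS, SimConfig

REQUIRED_COLUMNS = (
    "sequence_id",
    "cell_id",
    "clone_id",
    "mouse_id",
    "compartment",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "v_call_light",
    "j_call_light",
    "junction_light",
    "junction_aa_light",
    "zsg_s1pr2",
    "zsg_blimp1",
    "label_dilution",
    "division_count",
    "affinity",
    "mutations_heavy",
    "mutations_light",
    "hotspot_mutations",
)

_INT_COLUMNS = ("zsg_s1pr2", "zsg_blimp1", "division_count")
_FLOAT_COLUMNS = ("label_dilution", "affinity")
_VALID_COMPARTMENTS = {"LZ", "DZ", "prePC", "PC"}


class SchemaError(ValueError):
    """A cell table is missing required columns or contains bad values."""


def _join(mutations: Iterable[str]) -> str:
    return ";".join(sorted(mutations))


def split_mutations(value: str) -> frozenset[str]:
    """Inverse of the semicolon serialization of a mutation set."""
    if not value or pd.isna(value):
        return frozenset()
    return frozenset(value.split(";"))


def cells_to_table(cells: Iterable[Cell], config: SimConfig, mouse_id: str = "m0") -> pd.DataFrame:
    """Export simulated cells in the cell-table schema."""
    rows = []
    for c in cells:
        g = c.genotype
        rows.append(
            {
                "sequence_id": f"{mouse_id}_{c.id}",
                "cell_id": c.id,
                "clone_id": f"clone{c.founder_id}",
                "mouse_id": mouse_id,
                "compartment": c.compartment,
                "v_call": g.germline_v_heavy,
                "j_call": "IGHJ2",
                "junction": g.junction_heavy,
                "junction_aa": translate(g.junction_heavy),
                "v_call_light": g.germline_v_light,
                "j_call_light": "IGLJ1",
                "junction_light": g.junction_light,
                "junction_aa_light": translate(g.junction_light),
                "zsg_s1pr2": int(c.label_s1pr2),
                "zsg_blimp1": int(c.label_blimp1),
                "label_dilution": c.label_dilution(config.label_l0),
                "division_count": c.division_count,
                "affinity": c.affinity,
                "mutations_heavy": _join(g.mutations_heavy),
                "mutations_light": _join(g.mutations_light),
                "hotspot_mutations": _join(g.hotspot_mutations),
            }
        )
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    if rows:
        return df
    return _empty_table()


def _empty_table() -> pd.DataFrame:
    df = pd.DataFrame({col: pd.Series(dtype=object) for col in REQUIRED_COLUMNS})
    for col in _INT_COLUMNS:
        df[col] = df[col].astype("int64")
    for col in _FLOAT_COLUMNS:
        df[col] = df[col].astype(float)
    return df


def validate_cell_table(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` naming every problem found."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table is missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        return
    bad = ~df["compartment"].isin(_VALID_COMPARTMENTS)
    if bad.any():
        i = int(bad.idxmax())
        raise SchemaError(
            f"row {i + 2}: unknown compartment {df.loc[i, 'compartment']!r}"
        )  # +2: 1-based with header line
    nonpos = ~(df["label_dilution"] > 0)
    if nonpos.any():
        i = int(nonpos.idxmax())
        raise SchemaError(f"row {i + 2}: label_dilution must be > 0")


def write_cell_table(df: pd.DataFrame, path: str) -> None:
    validate_cell_table(df)
    df.to_csv(path, sep="\t", index=False)


def read_cell_table(path: str) -> pd.DataFrame:
    """Read and validate a cell-table TSV; unknown extra columns survive."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=object, keep_default_na=False, na_values=[])
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed cell table {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table is missing required column(s): {', '.join(missing)}")
    for col in _INT_COLUMNS + _FLOAT_COLUMNS + ("cell_id",):
        kind = float if col in _FLOAT_COLUMNS else int
        try:
            df[col] = df[col].astype(kind)
        except ValueError as exc:
            bad = None
            for i, v in enumerate(df[col]):
                try:
                    kind(v)
                except ValueError:
                    bad = i
                    break
            raise SchemaError(
                f"row {bad + 2 if bad is not None else '?'}: cannot parse column "
                f"{col!r} as {kind.__name__} ({exc})"
            ) from exc
    validate_cell_table(df)
    return df


def detect_hotspots_aa(sequence_aa: str, germline_aa: str) -> frozenset[str]:
    """Detect the canonical affinity-enhancing substitutions in a real
    IMGT-gapped heavy-chain amino-acid alignment (1-based codon positions).

    Provided for mapping deposited rearrangement data; simulated tables
    carry their hotspot mutations explicitly.
    """
    found = set()
    for name, pos in HOTSPOT_POSITIONS.items():
        i = pos - 1
        if i < len(sequence_aa) and i < len(germline_aa):
            if germline_aa[i] == name[0] and sequence_aa[i] == name[-1]:
                found.add(name)
    return frozenset(found & set(HOTSPOT_MUTATIONS))
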