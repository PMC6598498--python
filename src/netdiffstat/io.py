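"""Reading sample tables and GMT variable-set collections; writing results.

The sample table is CSV/TSV with a header of variable names and one
designated label column giving each row's condition.  Variable sets follow
the MSigDB GMT dialect: tab-separated lines of set name, description/URL,
then member names.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .data import GroupedData


@dataclass
class VariableSetCollection:
    """Ordered collection of (set_name, description, members) entries."""

    entries: list[tuple[str, str, list[str]]]

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicated set names: {dupes}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return [e[0] for e in self.entries]


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_sample_table(path, label_column: str) -> GroupedData:
    """Read a CSV/TSV samples-by-variables table into :class:`GroupedData`.

    Numeric columns become variables; ``label_column`` supplies the condition
    of each row.  Non-numeric columns other than the label column are
    rejected with an error naming them, as are duplicated variable names and
    unparseable numeric values.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n")
    sep = _sniff_delimiter(header)
    columns = [c.strip().strip('"') for c in header.split(sep)]
    dupes = sorted({c for c in columns if columns.count(c) > 1})
    if dupes:
        raise ValueError(f"duplicated column names in {path}: {dupes}")
    df = pd.read_csv(path, sep=sep)
    return GroupedData.from_dataframe(df, label_column)


def read_gmt(path) -> VariableSetCollection:
    """Read an MSigDB-dialect GMT file.

    Tab-separated: field 1 is the set name, field 2 a description or URL,
    fields 3+ the members (de-duplicated, order preserved).  Blank lines are
    skipped; a line with fewer than 3 fields is an error naming the line.
    """
    path = Path(path)
    entries: list[tuple[str, str, list[str]]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, members...)"
                )
            name, description = fields[0], fields[1]
            members: list[str] = []
            seen = set()
            for m in fields[2:]:
                m = m.strip()
                if m and m not in seen:
                    seen.add(m)
                    members.append(m)
            entries.append((name, description, members))
    return VariableSetCollection(entries)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as CSV (header always written, full precision)."""
    table.to_csv(path, index=False)


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick + ("\n" if not newick.endswith("\n") else ""))


def load_config(path) -> dict:
    """Load a YAML or JSON analysis config (YAML is a JSON superset)."""
    with Path(path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping of option names")
    return cfg
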