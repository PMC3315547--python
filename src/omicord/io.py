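"""Readers and writers for the flat-text formats the pipeline exchanges.

Everything is plain TSV/GMT/SIF/JSON so that runs are diffable and
archivable.  Expression matrices encode time and replicate in the column
header as ``t<hours>_r<rep>`` (e.g. ``t0.25_r2``); per-time result columns
use ``<prefix>_<hours>`` (e.g. ``ratio_13``).
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .design import fmt_time

_SAMPLE_RE = re.compile(r"^t(?P<time>[0-9.]+)_r(?P<rep>\d+)$")


def sample_column(time: float, rep: int) -> str:
    return f"t{fmt_time(time)}_r{rep}"


def parse_sample_column(name: str) -> tuple[float, int]:
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise ValueError(f"column {name!r} does not look like t<hours>_r<rep>")
    return float(m.group("time")), int(m.group("rep"))


def time_column(prefix: str, time: float) -> str:
    return f"{prefix}_{fmt_time(time)}"


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "symbol") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gmt(categories: Mapping[str, Iterable[str]], path: str | Path) -> None:
    """Write gene-set membership as GMT (name, description, members...)."""
    with open(path, "w") as fh:
        for name in categories:
            members = "\t".join(categories[name])
            fh.write(f"{name}\t{name}\t{members}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out[parts[0]] = set(p for p in parts[2:] if p)
    return out


def write_sif(edges: pd.DataFrame, path: str | Path) -> None:
    """Write typed edges as SIF: ``source<TAB>type<TAB>target``."""
    edges[["source", "type", "target"]].to_csv(
        path, sep="\t", index=False, header=False, lineterminator="\n"
    )


def read_sif(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["source", "type", "target"])
    return df


def read_symbol_list(path: str | Path) -> set[str]:
    """One symbol per line; blank lines and ``#`` comments ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.add(sym)
    return out


def write_symbol_list(symbols: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sym in sorted(symbols):
            fh.write(f"{sym}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
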