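"""File schemas, readers/writers and run configuration.

Canonical dialect: comma-separated UTF-8 with "." decimals and a mandatory
header row; missing values are empty fields.  Writers append a footer comment
``# nrows=N`` which readers verify when present, so silently truncated files
are rejected.  Rates are stored in linear units; logs are taken only at model
fit time.

Experiment tables are tidy, one row per parallel culture; the Nt replicate
measurements (shared by all cultures of an experiment) sit in wide columns
``nt_cfu_per_ml_{1..k}`` (densities, cells/ml), ``nt_atp_{1..k}`` and
``nt_cc_{1..k}`` (whole-culture sizes, cells).
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from dampkit.fluctuation import FluctuationExperiment, RateEstimate
from dampkit.luria_delbruck import MutantCounts

__all__ = [
    "RunConfig",
    "read_experiments",
    "write_experiments",
    "experiments_to_table",
    "read_literature",
    "write_table",
    "read_table",
    "rates_to_table",
    "write_report",
    "read_report",
]

EXPERIMENT_BASE_COLUMNS = [
    "experiment_id", "strain", "marker", "medium", "block",
    "volume_ml", "time_h", "N0", "evaporation", "r",
]
_NT_PREFIX = {"CFU": "nt_cfu_per_ml_", "ATP": "nt_atp_", "CC": "nt_cc_"}


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips losslessly via JSON."""

    seed: int = 0
    nt_method: str = "CFU"
    include_excluded: bool = True
    w: float = 1.0
    w_grid: tuple[float, ...] = (0.5, 0.75, 1.0, 1.5, 2.0)
    r_max: int = 10_000
    organism_remap: dict = dataclasses.field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["w_grid"] = list(d["w_grid"])
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["w_grid"] = tuple(d["w_grid"])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


class SchemaError(ValueError):
    pass


def write_table(df: pd.DataFrame, path) -> None:
    """Write a canonical CSV with a row-count footer."""
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    buf.write(f"# nrows={len(df)}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    """Read a canonical CSV, verifying the row-count footer when present."""
    text = Path(path).read_text(encoding="utf-8")
    expected = None
    lines = text.splitlines()
    body = []
    for line in lines:
        if line.startswith("# nrows="):
            expected = int(line.split("=", 1)[1])
        elif line.strip():
            body.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(body)))
    if expected is not None and len(df) != expected:
        raise SchemaError(
            f"{path}: row-count footer says {expected} rows but found {len(df)} "
            "(file truncated or edited?)"
        )
    return df


def experiments_to_table(experiments: Iterable[FluctuationExperiment]) -> pd.DataFrame:
    """Tidy per-culture table for a list of experiments."""
    rows = []
    for exp in experiments:
        base = {
            "experiment_id": exp.experiment_id,
            "strain": exp.strain,
            "marker": exp.marker,
            "medium": exp.medium,
            "block": exp.block,
            "volume_ml": exp.volume_ml,
            "time_h": exp.time_h,
            "N0": exp.N0,
            "evaporation": exp.evaporation,
        }
        for method, prefix in _NT_PREFIX.items():
            for i, v in enumerate(exp.nt_replicates.get(method, ()), start=1):
                base[f"{prefix}{i}"] = v
        for r in exp.counts:
            rows.append({**base, "r": r})
    return pd.DataFrame(rows)


def write_experiments(experiments: Iterable[FluctuationExperiment], path) -> None:
    write_table(experiments_to_table(experiments), path)


def _experiment_from_group(eid: str, g: pd.DataFrame, line_of) -> FluctuationExperiment:
    first = g.iloc[0]
    reps = {}
    for method, prefix in _NT_PREFIX.items():
        vals = []
        for col in sorted(c for c in g.columns if c.startswith(prefix)):
            v = first[col]
            if pd.notna(v):
                vals.append(float(v))
        if vals:
            reps[method] = tuple(vals)
    return FluctuationExperiment(
        counts=MutantCounts(tuple(int(r) for r in g["r"])),
        N0=float(first["N0"]),
        nt_replicates=reps,
        volume_ml=float(first["volume_ml"]),
        time_h=float(first["time_h"]),
        evaporation=float(first.get("evaporation", 0.0) or 0.0),
        strain=str(first.get("strain", "")),
        marker=str(first.get("marker", "")),
        medium=str(first.get("medium", "")),
        block=str(first.get("block", "")),
        experiment_id=str(eid),
    )


def read_experiments(
    path, column_map: Mapping[str, str] | None = None
) -> list[FluctuationExperiment]:
    """Read a tidy experiment table into FluctuationExperiment objects.

    ``column_map`` renames file columns to the canonical schema (to absorb
    naming drift in external files).  Missing required columns raise a
    SchemaError naming them; malformed rows are reported with their line
    number in the file (header = line 1).
    """
    df = read_table(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in EXPERIMENT_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    bad = df.index[pd.to_numeric(df["r"], errors="coerce").isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +1 header, +1 1-based
        raise SchemaError(f"{path}: non-numeric mutant counts at lines {lines}")
    out = []
    for eid, g in df.groupby("experiment_id", sort=False):
        try:
            out.append(_experiment_from_group(eid, g, None))
        except (ValueError, KeyError) as exc:
            line = int(g.index[0]) + 2
            raise SchemaError(
                f"{path}: invalid experiment {eid!r} starting at line {line}: {exc}"
            ) from exc
    return out


LITERATURE_COLUMNS = ["mutation_rate", "D", "organism", "marker", "medium", "study"]


def read_literature(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = read_table(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in LITERATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    return df


def rates_to_table(rates: Iterable[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rates])


def write_report(report: Mapping, path) -> None:
    """Plain-text key -> value report (tab-separated, one pair per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in report.items():
            fh.write(f"{key}\t{value}\n")


def read_report(path) -> dict:
    out = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition("\t")
        try:
            out[key] = float(value)
        except ValueError:
            out[key] = value
    return out
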