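"""Plain-text readers and writers (TSV/CSV/GMT/JSON) with round-trip fidelity."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .assay_quant import ActivityTrace
from .biophys import MeltingCurve, TwoStateFit
from .coexpr import ExpressionMatrix
from .errors import InvalidConfigError

__all__ = [
    "read_gmt", "write_gmt",
    "read_expression", "write_expression",
    "read_quant_table", "write_quant_table",
    "read_melting_curve", "write_melting_curve",
    "read_activity_trace", "write_activity_trace",
    "write_fit", "write_json", "read_json",
]


class GmtParseError(InvalidConfigError):
    """A GMT line does not carry name, description and at least one member."""


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into {set_name: member set}.

    Duplicate members within a set are deduplicated with a warning; a
    malformed line raises with its line number.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected name, description and >=1 member"
                )
            name, _desc, *members = parts
            members = [m for m in members if m]
            if len(members) != len(set(members)):
                warnings.warn(f"GMT set {name!r}: duplicate members deduplicated")
            if name in sets:
                raise GmtParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_expression(path_values: str | Path, path_meta: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (genes in rows) and its sample-metadata TSV."""
    values = pd.read_csv(path_values, sep="\t", index_col=0)
    meta = pd.read_csv(path_meta, sep="\t", index_col=0)
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise InvalidConfigError(f"duplicate gene ids in {path_values}: {dups}")
    orphans = [s for s in values.columns if s not in meta.index]
    if orphans:
        raise InvalidConfigError(f"samples missing from metadata: {orphans}")
    meta["tumor"] = meta["tumor"].astype(bool)
    return ExpressionMatrix(values=values, sample_meta=meta)


def write_expression(expr: ExpressionMatrix, path_values: str | Path,
                     path_meta: str | Path) -> None:
    expr.values.to_csv(path_values, sep="\t")
    meta = expr.sample_meta.copy()
    meta["tumor"] = meta["tumor"].astype(bool)
    meta.to_csv(path_meta, sep="\t")


def read_quant_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    table["site_residue"] = table["site_residue"].astype("Int64")
    return table


def write_quant_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_melting_curve(path: str | Path, label: str = "") -> MeltingCurve:
    df = pd.read_csv(path)
    return MeltingCurve(
        temp_c=df["temp_c"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        label=label or Path(path).stem,
    )


def write_melting_curve(curve: MeltingCurve, path: str | Path) -> None:
    pd.DataFrame({"temp_c": curve.temp_c, "signal": curve.signal}).to_csv(
        path, index=False
    )


def read_activity_trace(
    path: str | Path,
    eps_mM_cm: float = 21.0,
    path_cm: float = 1.0,
    volume_ml: float = 1.0,
    protein_mg: float | None = None,
) -> ActivityTrace:
    df = pd.read_csv(path)
    return ActivityTrace(
        time_s=df["time_s"].to_numpy(float),
        a600=df["a600"].to_numpy(float),
        eps_mM_cm=eps_mM_cm,
        path_cm=path_cm,
        volume_ml=volume_ml,
        protein_mg=protein_mg,
        label=Path(path).stem,
    )


def write_activity_trace(trace: ActivityTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "a600": trace.a600}).to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_fit(fit: TwoStateFit, path: str | Path) -> None:
    write_json(
        {
            "tm_c": fit.tm_c, "dh_vh": fit.dh_vh,
            "yN": fit.yN, "mN": fit.mN, "yU": fit.yU, "mU": fit.mU,
            "rss": fit.rss, "converged": fit.converged, "message": fit.message,
        },
        path,
    )
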