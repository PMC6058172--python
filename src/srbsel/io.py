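"""Delimited-text observation tables and flat key-value configuration.

Tables are CSV or TSV with a header and the input columns ``label, period,
tfr, srb``.  Metadata rides in leading comment lines::

    # srb_unit: b100g
    # p: 0.486
    # source: synthetic fixture
    label,period,tfr,srb
    ...

The SRB unit is never inferred: it must be declared in the file, in a
config, or as an argument (a 1.06-vs-106 confusion would silently corrupt
every downstream estimate).  Proportion-male inputs are converted to the
canonical boys-per-100-girls representation on load.  Rows failing
validation are reported with their file line numbers and the whole read
fails; nothing is silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .inversion import Observation
from .params import DEFAULT_PARAMS, NaturalBirthParams

__all__ = [
    "SRB_UNITS",
    "ObservationTable",
    "TableValidationError",
    "convert_srb_to_b100g",
    "read_observations",
    "write_observations",
    "write_estimates",
    "load_config",
]

SRB_UNITS = ("b100g", "prop")
REQUIRED_COLUMNS = ("label", "period", "tfr", "srb")


class TableValidationError(ValueError):
    """Structured table-read failure carrying (line number, message) pairs."""

    def __init__(self, path, errors: Sequence[tuple[int | None, str]]):
        self.path = str(path)
        self.errors = list(errors)
        detail = "; ".join(
            (f"line {ln}: {msg}" if ln is not None else msg) for ln, msg in self.errors
        )
        super().__init__(f"{self.path}: {detail}")


def convert_srb_to_b100g(value: float, unit: str) -> float:
    """Convert a declared-unit SRB value to boys per 100 girls."""
    if unit == "b100g":
        return value
    if unit == "prop":
        if not 0.0 < value < 1.0:
            raise ValueError(
                f"proportion-male SRB must lie in (0, 1), got {value}"
            )
        return 100.0 * value / (1.0 - value)
    raise ValueError(f"unknown srb unit {unit!r}; expected one of {SRB_UNITS}")


@dataclass
class ObservationTable:
    """Validated observations plus the metadata needed to interpret them."""

    observations: list[Observation]
    srb_unit: str = "b100g"  # unit of the *source* file; values stored as b100g
    params: NaturalBirthParams = DEFAULT_PARAMS
    source: str = ""
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "label": [o.label for o in self.observations],
                "period": [o.period for o in self.observations],
                "tfr": [o.tfr for o in self.observations],
                "srb": [o.srb for o in self.observations],
            }
        )
        if self.extra is not None:
            for col in self.extra.columns:
                if col not in df.columns:
                    df[col] = self.extra[col].to_numpy()
        return df


def _parse_metadata(path: Path) -> tuple[dict[str, str], int]:
    """Leading '# key: value' lines -> dict, plus how many lines they span."""
    meta: dict[str, str] = {}
    n = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta, n


def read_observations(
    path,
    srb_unit: str | None = None,
    config: dict | None = None,
) -> ObservationTable:
    """Read and validate a delimited observation table.

    SRB-unit resolution order: explicit argument, then ``config['srb_unit']``,
    then the file's ``# srb_unit:`` metadata line; absence is an error.
    Delimiter is taken from the extension (``.tsv`` -> tab, else comma).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, n_meta = _parse_metadata(path)
    unit = srb_unit or (config or {}).get("srb_unit") or meta.get("srb_unit")
    if unit is None:
        raise TableValidationError(
            path, [(None, "srb unit not declared (argument, config or '# srb_unit:' line)")]
        )
    if unit not in SRB_UNITS:
        raise TableValidationError(
            path, [(None, f"unknown srb unit {unit!r}; expected one of {SRB_UNITS}")]
        )
    params = NaturalBirthParams(float(meta["p"])) if "p" in meta else DEFAULT_PARAMS

    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True, dtype=str)
    df.columns = [c.strip() for c in df.columns]

    errors: list[tuple[int | None, str]] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(
            path, [(n_meta + 1, f"missing required column(s) {missing}; found {list(df.columns)}")]
        )

    header_line = n_meta + 1
    observations: list[Observation] = []
    for i, row in df.iterrows():
        line_no = header_line + 1 + int(i)
        try:
            tfr = float(row["tfr"])
            srb_raw = float(row["srb"])
        except (TypeError, ValueError):
            errors.append(
                (line_no, f"non-numeric tfr/srb: tfr={row['tfr']!r}, srb={row['srb']!r}")
            )
            continue
        try:
            srb = convert_srb_to_b100g(srb_raw, unit)
            observations.append(
                Observation(
                    label=str(row["label"]).strip(),
                    period=str(row["period"]).strip(),
                    tfr=tfr,
                    srb=srb,
                )
            )
        except ValueError as exc:
            errors.append((line_no, str(exc)))
    if errors:
        raise TableValidationError(path, errors)

    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    extra = df[extra_cols].apply(pd.to_numeric, errors="coerce") if extra_cols else None
    return ObservationTable(
        observations, srb_unit=unit, params=params,
        source=meta.get("source", ""), extra=extra,
    )


def _write_table(path, df: pd.DataFrame, meta: dict[str, object]) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        # repr-style float formatting keeps write->read lossless
        df.to_csv(fh, sep=sep, index=False, float_format=None)


def write_observations(path, table: ObservationTable) -> None:
    """Write an ObservationTable with its metadata header (always b100g units)."""
    meta: dict[str, object] = {"srb_unit": "b100g", "p": table.params.p}
    if table.source:
        meta["source"] = table.source
    _write_table(path, table.to_dataframe(), meta)


def write_estimates(path, estimates: pd.DataFrame, params: NaturalBirthParams) -> None:
    """Write a batch-estimation output table, recording the benchmark p used."""
    df = estimates.copy()
    for col in ("below_benchmark", "implausible"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    _write_table(path, df, {"srb_unit": "b100g", "p": params.p})


def load_config(path) -> dict:
    """Load a flat key-value YAML config; empty file -> empty dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return cfg
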