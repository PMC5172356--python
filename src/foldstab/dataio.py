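"""Typed containers and tabular I/O for the fold-stability pipeline.

All tabular input is delimited text (CSV/TSV) in long format — one row per
observation — with a header row.  Column names are remapped through
``schema_options['column_map']`` when an instrument export uses different
headers.  Temperatures are Kelvin internally; pass ``celsius=True`` to convert
on read.  Relaxation delays are seconds internally; pass ``delay_unit='ms'``
to convert on read.

Readers validate every stated invariant and raise :class:`SchemaError`
(missing/unmappable column) or :class:`ValidationError` (rule violated, with
the rule named) rather than returning malformed records.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("foldstab")

__all__ = [
    "SchemaError",
    "ValidationError",
    "EmissionSpectrum",
    "DecayCurve",
    "NoePair",
    "DSCTrace",
    "PeakList",
    "read_dataset",
    "write_results",
    "read_results",
    "write_residue_attributes",
]


class SchemaError(ValueError):
    """A required column is missing or cannot be resolved from the header."""


class ValidationError(ValueError):
    """An input violates a stated invariant; the message names the rule."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EmissionSpectrum:
    """Fluorescence emission spectrum F(λ) at one condition.

    ``condition_value`` is a temperature in K (``condition_kind='thermal'``)
    or a denaturant concentration in mol/L (``condition_kind='chemical'``).
    """

    condition_value: float
    wavelengths: np.ndarray
    intensities: np.ndarray
    condition_kind: str = "thermal"
    replicate_id: str = "rep1"

    def __post_init__(self):
        self.wavelengths = _as_float_array(self.wavelengths, "wavelengths")
        self.intensities = _as_float_array(self.intensities, "intensities")
        if self.condition_kind not in ("thermal", "chemical"):
            raise ValidationError(
                "condition_kind must be 'thermal' or 'chemical', "
                f"got {self.condition_kind!r}"
            )
        if self.wavelengths.size < 3:
            raise ValidationError("wavelength grid must have at least 3 points")
        if self.wavelengths.size != self.intensities.size:
            raise ValidationError("wavelengths and intensities differ in length")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("all intensities must be finite")


@dataclass
class DecayCurve:
    """Peak intensities I(t) across relaxation delays for one residue."""

    residue_id: str
    delays: np.ndarray           # seconds
    intensities: np.ndarray      # arbitrary units
    experiment: str = "T1"       # 'T1' or 'T2'

    def __post_init__(self):
        self.delays = _as_float_array(self.delays, "delays")
        self.intensities = _as_float_array(self.intensities, "intensities")
        if self.experiment not in ("T1", "T2"):
            raise ValidationError(f"experiment must be 'T1' or 'T2', got {self.experiment!r}")
        if self.delays.size != self.intensities.size:
            raise ValidationError("delays and intensities differ in length")
        if np.any(self.delays < 0):
            raise ValidationError("delays must be non-negative")
        if not np.all(np.diff(self.delays) > 0):
            raise ValidationError("delays must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("all intensities must be finite")


@dataclass
class NoePair:
    """Saturated / equilibrium intensity pair for one residue, one replicate."""

    residue_id: str
    i_sat: float
    i_eq: float
    replicate_id: str = "rep1"

    def __post_init__(self):
        if not (np.isfinite(self.i_sat) and np.isfinite(self.i_eq)):
            raise ValidationError("NOE intensities must be finite")
        if self.i_eq == 0:
            raise ValidationError("i_eq must be nonzero")


@dataclass
class DSCTrace:
    """Heat capacity Cp(T) scan; ``scan_label`` distinguishes reheats."""

    temperatures: np.ndarray     # K, strictly increasing
    heat_capacity: np.ndarray    # kJ K^-1 mol^-1
    scan_label: str = "first_heat"
    scan_rate: float = 1.0       # K min^-1

    def __post_init__(self):
        self.temperatures = _as_float_array(self.temperatures, "temperatures")
        self.heat_capacity = _as_float_array(self.heat_capacity, "heat_capacity")
        if self.scan_label not in ("first_heat", "reheat"):
            raise ValidationError(
                f"scan_label must be 'first_heat' or 'reheat', got {self.scan_label!r}"
            )
        if self.temperatures.size < 20:
            raise ValidationError("DSC trace must have at least 20 points")
        if self.temperatures.size != self.heat_capacity.size:
            raise ValidationError("temperatures and heat_capacity differ in length")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValidationError("temperature axis must be strictly increasing (monotone)")
        if self.scan_rate <= 0:
            raise ValidationError("scan_rate must be positive")


@dataclass
class PeakRecord:
    residue_id: str
    h_ppm: float
    n_ppm: float
    intensity: float = np.nan


@dataclass
class PeakList:
    """Assigned 2D peak positions (¹H, ¹⁵N) with intensities."""

    records: list = field(default_factory=list)

    def __post_init__(self):
        ids = [r.residue_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError("residue_id must be unique within a peak list")
        for r in self.records:
            if not (np.isfinite(r.h_ppm) and np.isfinite(r.n_ppm)):
                raise ValidationError(f"residue {r.residue_id}: shifts must be finite")

    def shifts(self) -> dict:
        return {r.residue_id: (r.h_ppm, r.n_ppm) for r in self.records}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "melt": {
        "wavelength": ("wavelength", "wavelength_nm", "lambda"),
        "intensity": ("intensity", "fluorescence", "F"),
        "condition": ("condition", "temperature", "temperature_K", "denaturant", "denaturant_M"),
        "replicate": ("replicate", "replicate_id", "rep"),
    },
    "decay": {
        "residue": ("residue", "residue_id", "res"),
        "delay": ("delay", "delay_s", "t"),
        "intensity": ("intensity", "height", "I"),
        "experiment": ("experiment", "exp"),
    },
    "noe": {
        "residue": ("residue", "residue_id", "res"),
        "i_sat": ("i_sat", "sat", "I_sat"),
        "i_eq": ("i_eq", "eq", "I_eq"),
        "replicate": ("replicate", "replicate_id", "rep"),
    },
    "dsc": {
        "temperature": ("temperature", "temperature_K", "T"),
        "heat_capacity": ("heat_capacity", "cp", "Cp", "heat_capacity_kJ_K_mol"),
    },
    "peaklist": {
        "residue": ("residue", "residue_id", "assignment"),
        "h_ppm": ("h_ppm", "w2", "1H"),
        "n_ppm": ("n_ppm", "w1", "15N"),
        "intensity": ("intensity", "height", "Height"),
    },
}


def _resolve_columns(df: pd.DataFrame, kind: str, column_map: Mapping[str, str],
                     required: Sequence[str], optional: Sequence[str] = ()) -> dict:
    out = {}
    lower = {c.lower(): c for c in df.columns}
    for role in tuple(required) + tuple(optional):
        if role in column_map:
            col = column_map[role]
            if col not in df.columns:
                raise SchemaError(f"mapped column {col!r} for {role!r} not found in header")
            out[role] = col
            continue
        for cand in _DEFAULT_COLUMNS[kind][role]:
            if cand.lower() in lower:
                out[role] = lower[cand.lower()]
                break
        else:
            if role in required:
                raise SchemaError(
                    f"required column for {role!r} missing (tried "
                    f"{_DEFAULT_COLUMNS[kind][role]}); supply schema_options['column_map']"
                )
    return out


def _read_table(path, schema_options: Mapping) -> pd.DataFrame:
    sep = schema_options.get("sep")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, comment="#")


def read_dataset(path, kind: str, schema_options: Mapping | None = None):
    """Read and validate a dataset of the given ``kind``.

    kind: one of ``melt``, ``decay``, ``noe``, ``dsc``, ``peaklist``.
    Returns a list of the corresponding typed records (a single
    :class:`PeakList` for ``peaklist``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opts = dict(schema_options or {})
    column_map = opts.get("column_map", {})

    if kind == "peaklist" and opts.get("sparky", _looks_like_sparky(path)):
        return _read_sparky(path)

    df = _read_table(path, opts)

    if kind == "melt":
        cols = _resolve_columns(df, kind, column_map,
                                ["wavelength", "intensity", "condition"], ["replicate"])
        ckind = opts.get("condition_kind", "thermal")
        cond = df[cols["condition"]].astype(float)
        if opts.get("celsius", False):
            cond = cond + 273.15
        rep = df[cols["replicate"]].astype(str) if "replicate" in cols else "rep1"
        work = pd.DataFrame({
            "wavelength": df[cols["wavelength"]].astype(float),
            "intensity": df[cols["intensity"]].astype(float),
            "condition": cond,
            "replicate": rep,
        })
        out = []
        for (repid, cval), grp in work.groupby(["replicate", "condition"], sort=True):
            grp = grp.sort_values("wavelength")
            try:
                out.append(EmissionSpectrum(
                    condition_value=float(cval),
                    wavelengths=grp["wavelength"].to_numpy(),
                    intensities=grp["intensity"].to_numpy(),
                    condition_kind=ckind,
                    replicate_id=str(repid),
                ))
            except ValidationError as e:
                raise ValidationError(
                    f"spectrum (replicate={repid}, condition={cval}): {e}") from e
        return out

    if kind == "decay":
        cols = _resolve_columns(df, kind, column_map,
                                ["residue", "delay", "intensity"], ["experiment"])
        scale = {"s": 1.0, "ms": 1e-3}[opts.get("delay_unit", "s")]
        experiment = opts.get("experiment")
        out = []
        for key, grp in df.groupby(cols["residue"], sort=True):
            grp = grp.sort_values(cols["delay"])
            exp = experiment or (str(grp[cols["experiment"]].iloc[0])
                                 if "experiment" in cols else "T1")
            try:
                out.append(DecayCurve(
                    residue_id=str(key),
                    delays=grp[cols["delay"]].to_numpy(dtype=float) * scale,
                    intensities=grp[cols["intensity"]].to_numpy(dtype=float),
                    experiment=exp,
                ))
            except ValidationError as e:
                raise ValidationError(f"decay curve for residue {key}: {e}") from e
        return out

    if kind == "noe":
        cols = _resolve_columns(df, kind, column_map,
                                ["residue", "i_sat", "i_eq"], ["replicate"])
        out = []
        for i, row in df.iterrows():
            rep = str(row[cols["replicate"]]) if "replicate" in cols else "rep1"
            try:
                out.append(NoePair(
                    residue_id=str(row[cols["residue"]]),
                    i_sat=float(row[cols["i_sat"]]),
                    i_eq=float(row[cols["i_eq"]]),
                    replicate_id=rep,
                ))
            except ValidationError as e:
                raise ValidationError(f"row {i}: {e}") from e
        return out

    if kind == "dsc":
        cols = _resolve_columns(df, kind, column_map, ["temperature", "heat_capacity"])
        temps = df[cols["temperature"]].to_numpy(dtype=float)
        if opts.get("celsius", False):
            temps = temps + 273.15
        return [DSCTrace(
            temperatures=temps,
            heat_capacity=df[cols["heat_capacity"]].to_numpy(dtype=float),
            scan_label=opts.get("scan_label", "first_heat"),
            scan_rate=float(opts.get("scan_rate", 1.0)),
        )]

    if kind == "peaklist":
        cols = _resolve_columns(df, kind, column_map,
                                ["residue", "h_ppm", "n_ppm"], ["intensity"])
        recs = []
        for _, row in df.iterrows():
            inten = float(row[cols["intensity"]]) if "intensity" in cols else np.nan
            recs.append(PeakRecord(
                residue_id=str(row[cols["residue"]]),
                h_ppm=float(row[cols["h_ppm"]]),
                n_ppm=float(row[cols["n_ppm"]]),
                intensity=inten,
            ))
        return PeakList(records=recs)

    raise ValueError(f"unknown dataset kind {kind!r}")


_SPARKY_ASSIGN = re.compile(r"(\d+)")


def _looks_like_sparky(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.split()[:1] == ["Assignment"]


def _read_sparky(path: Path) -> PeakList:
    """Parse a Sparky-style list: Assignment, w1 (¹⁵N ppm), w2 (¹H ppm), Height."""
    recs = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if not toks or toks[0] == "Assignment":
                continue
            m = _SPARKY_ASSIGN.search(toks[0])
            if m is None:
                raise ValidationError(f"cannot parse residue number from {toks[0]!r}")
            height = float(toks[3]) if len(toks) > 3 else np.nan
            recs.append(PeakRecord(residue_id=m.group(1), h_ppm=float(toks[2]),
                                   n_ppm=float(toks[1]), intensity=height))
    return PeakList(records=recs)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _to_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    if isinstance(results, Mapping):
        return pd.DataFrame([results])
    if dataclasses.is_dataclass(results) and not isinstance(results, type):
        return pd.DataFrame([dataclasses.asdict(results)])
    seq = list(results)
    if seq and dataclasses.is_dataclass(seq[0]):
        return pd.DataFrame([dataclasses.asdict(r) for r in seq])
    return pd.DataFrame(seq)


def write_results(results, path, format: str = "tsv",
                  metadata: Mapping | None = None) -> None:
    """Serialize a stage result to TSV or JSON, round-trip safe to >=10 sig digits.

    Metadata (seed, constants, versions) is written as ``# key: value`` header
    lines in TSV mode and under a ``metadata`` key in JSON mode.
    """
    from . import __version__

    df = _to_frame(results)
    meta = {"foldstab_version": __version__}
    meta.update(metadata or {})
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    elif format == "json":
        payload = {"metadata": meta, "records": json.loads(df.to_json(orient="records", double_precision=15))}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path) -> pd.DataFrame:
    """Read back a file written by :func:`write_results`; metadata in ``.attrs``."""
    path = Path(path)
    if str(path).endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        df = pd.DataFrame(payload["records"])
        df.attrs["metadata"] = payload.get("metadata", {})
        return df
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition(":")
            meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    df.attrs["metadata"] = meta
    return df


def write_residue_attributes(profile: Mapping, path) -> int:
    """Write a two-column per-residue attribute file for structure viewers.

    One ``residue<TAB>value`` line per residue with a finite numeric value;
    non-finite (flagged) entries are omitted and the omission logged.  Returns
    the number of lines written.
    """
    if len(profile) == 0:
        raise ValidationError("attribute profile is empty (at least 1 residue required)")
    lines = []
    for res, val in sorted(profile.items(), key=lambda kv: _residue_sort_key(kv[0])):
        try:
            fval = float(val)
        except (TypeError, ValueError) as e:
            raise ValidationError(f"residue {res}: non-numeric attribute value {val!r}") from e
        if not np.isfinite(fval):
            logger.warning("residue %s: non-finite attribute value omitted", res)
            continue
        lines.append(f"{res}\t{fval:.6g}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
    return len(lines)


def _residue_sort_key(res):
    try:
        return (0, int(res))
    except (TypeError, ValueError):
        return (1, str(res))
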