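"""File formats: spectra/concentration CSV, config files, JCAMP-DX input.

Spectra CSV layout: first column ``wavenumber_cm-1``, one column per
sample (column header = sample id).  Concentration CSV: one row per
sample with a ``sample_id`` column and one column per analyte (mg/g).
Output files written by the pipeline start with provenance comment lines
(``# key=value``) that readers skip.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ReferenceTable, SpectraSet
from .instruments import BUILTIN_PROFILES, InstrumentProfile


def write_spectra_csv(
    path, spectra: SpectraSet, provenance: dict | None = None
) -> None:
    """Write a SpectraSet as a wavenumber-by-sample CSV."""
    df = pd.DataFrame(
        spectra.absorbance.T, columns=spectra.sample_ids
    )
    df.insert(0, "wavenumber_cm-1", spectra.wavenumbers)
    _write_with_provenance(path, df, provenance, extra={
        "instrument": spectra.instrument,
        "replicates": "grouped" if spectra.replicate_of is not None else "averaged",
    })


def read_spectra_csv(path, instrument: str = "") -> SpectraSet:
    """Read a wavenumber-by-sample CSV into a SpectraSet.

    Replicate grouping is inferred from sample ids of the form
    ``<sample>_r<k>``; ids without that suffix are treated as already
    averaged.  Either wavenumber order is accepted.
    """
    df = pd.read_csv(path, comment="#")
    wn_col = df.columns[0]
    wavenumbers = df[wn_col].to_numpy(dtype=float)
    sample_ids = [str(c) for c in df.columns[1:]]
    absorbance = df[df.columns[1:]].to_numpy(dtype=float).T
    rep_pattern = re.compile(r"^(.*)_r\d+$")
    matches = [rep_pattern.match(s) for s in sample_ids]
    replicate_of = [m.group(1) for m in matches] if all(matches) else None
    meta = _read_provenance(path)
    return SpectraSet(
        wavenumbers=wavenumbers,
        absorbance=absorbance,
        sample_ids=sample_ids,
        replicate_of=replicate_of,
        instrument=instrument or meta.get("instrument", ""),
    )


def write_concentrations_csv(
    path, table: ReferenceTable, provenance: dict | None = None
) -> None:
    df = table.concentrations.copy()
    df.insert(0, "sample_id", table.sample_ids)
    _write_with_provenance(path, df, provenance)


def read_concentrations_csv(path) -> ReferenceTable:
    df = pd.read_csv(path, comment="#")
    ids = [str(s) for s in df["sample_id"]]
    conc = df.drop(columns=["sample_id"])
    conc.index = ids
    return ReferenceTable(sample_ids=ids, concentrations=conc)


def _write_with_provenance(path, df: pd.DataFrame, provenance, extra=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = dict(extra or {})
    lines.update(provenance or {})
    with open(path, "w") as fh:
        for k, v in lines.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def _read_provenance(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].strip().split("=", 1)
                meta[k] = v
    return meta


# ---------------------------------------------------------------------------
# JCAMP-DX (single spectrum, AFFN XYDATA)
# ---------------------------------------------------------------------------

def read_jcamp(path) -> tuple[np.ndarray, np.ndarray]:
    """Read one spectrum from a JCAMP-DX file (AFFN ``(X++(Y..Y))`` or
    ``(XY..XY)`` data tables; no ASDF/DIF compression).

    Returns ``(x_axis, y_values)`` with XFACTOR/YFACTOR applied.  Covers
    the plain-text exports typical of NIR instruments; compressed JCAMP
    variants are out of scope.
    """
    xfactor = yfactor = 1.0
    mode = None
    xs: list[float] = []
    ys: list[float] = []
    num = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.replace(" ", "").replace("-", "").replace("_", "").upper()
                val = val.strip()
                if key == "XFACTOR":
                    xfactor = float(val)
                elif key == "YFACTOR":
                    yfactor = float(val)
                elif key == "XYDATA":
                    mode = "xyy" if "X++" in val.replace(" ", "") else "xyxy"
                elif key == "XYPOINTS":
                    mode = "xyxy"
                elif key == "END":
                    mode = None
                continue
            if mode is None or not line or line.startswith("$$"):
                continue
            vals = [float(v) for v in num.findall(line.split("$$")[0])]
            if not vals:
                continue
            if mode == "xyy":
                x0, yv = vals[0], vals[1:]
                if len(xs) >= 2 and len(ys) >= len(xs):
                    pass
                # x of subsequent points interpolated later from line starts
                xs.append(x0)
                ys.append(yv)
            else:
                for xi, yi in zip(vals[0::2], vals[1::2]):
                    xs.append(xi)
                    ys.append(yi)

    if mode is None and not xs:
        raise ValueError(f"no XYDATA/XYPOINTS table found in {path}")
    if ys and isinstance(ys[0], list):
        # (X++(Y..Y)): each line starts with the x of its first y; infer the
        # uniform step from consecutive line starts.
        counts = [len(v) for v in ys]
        flat_y = [y for block in ys for y in block]
        if len(xs) > 1:
            steps = np.diff(xs) / np.array(counts[:-1], dtype=float)
            step = float(np.mean(steps))
        else:
            step = 1.0
        flat_x = []
        for x0, cnt in zip(xs, counts):
            flat_x.extend(x0 + step * np.arange(cnt))
        x = np.asarray(flat_x, dtype=float)
        y = np.asarray(flat_y, dtype=float)
    else:
        x = np.asarray(xs, dtype=float)
        y = np.asarray(ys, dtype=float)
    return x * xfactor, y * yfactor


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

def load_profile_config(source) -> InstrumentProfile:
    """Build an InstrumentProfile from a mapping or a YAML/JSON file path.

    A plain string naming a built-in profile is also accepted.
    """
    if isinstance(source, InstrumentProfile):
        return source
    if isinstance(source, str) and source.lower() in BUILTIN_PROFILES:
        return BUILTIN_PROFILES[source.lower()]
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    d = dict(source)
    if "range" in d:  # (high, low) pair form
        d["wn_high"], d["wn_low"] = d.pop("range")
    if "sampling_interval" in d and "n_channels" not in d:
        step = float(d.pop("sampling_interval"))
        d["n_channels"] = int(round((d["wn_high"] - d["wn_low"]) / step)) + 1
    return InstrumentProfile(**d)
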