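"""File readers and writers: samples/factories/results CSV and the
ESRI ASCII grid raster dialect.

CSV is UTF-8, comma-separated with a mandatory header and "." decimal;
an empty concentration cell is a nondetect.  Floats serialize with the
shortest round-trip representation so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .factory import CRIResult, FactoryRecord
from .health import HealthRiskResult, SoilSample
from .idw import GridSpec, Raster

SAMPLE_META_COLS = ["id", "x", "y", "point_type", "pH"]


def _fmt(v) -> str:
    """Shortest round-trip text for a float; integers stay integral."""
    f = float(v)
    if f == int(f) and abs(f) < 1e16:
        return str(int(f))
    return repr(f)


# -- samples ------------------------------------------------------------------

def read_samples(path) -> list[SoilSample]:
    """Read the samples CSV (id,x,y,point_type,pH,<pollutant>...)."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in SAMPLE_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    pollutant_cols = [c for c in df.columns if c not in SAMPLE_META_COLS]
    samples = []
    for i, row in df.iterrows():
        conc = {}
        for pid in pollutant_cols:
            v = row[pid]
            if pd.isna(v):
                continue  # nondetect
            try:
                conc[pid] = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}, line {i + 2}: non-numeric concentration "
                    f"{v!r} for {pid}"
                ) from None
        try:
            samples.append(SoilSample(
                id=str(row["id"]), x=float(row["x"]), y=float(row["y"]),
                point_type=str(row["point_type"]), pH=float(row["pH"]), conc=conc,
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {i + 2}: {exc}") from exc
    return samples


def write_samples(samples: Sequence[SoilSample], path,
                  pollutant_order: Sequence[str] | None = None) -> None:
    if pollutant_order is None:
        seen: dict[str, None] = {}
        for s in samples:
            for pid in s.conc:
                seen.setdefault(pid)
        pollutant_order = list(seen)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(SAMPLE_META_COLS + list(pollutant_order)) + "\n")
        for s in samples:
            cells = [s.id, _fmt(s.x), _fmt(s.y), s.point_type, _fmt(s.pH)]
            cells += [(_fmt(s.conc[p]) if p in s.conc else "") for p in pollutant_order]
            fh.write(",".join(cells) + "\n")


# -- factories ----------------------------------------------------------------

FACTORY_META_COLS = ["id", "x", "y", "industry"]


def read_factories(path) -> list[FactoryRecord]:
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in FACTORY_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    raw_cols = [c for c in df.columns if c not in FACTORY_META_COLS]
    out = []
    for _, row in df.iterrows():
        raw = {}
        for c in raw_cols:
            v = row[c]
            if pd.isna(v):
                continue
            raw[c] = v.item() if hasattr(v, "item") else v
        out.append(FactoryRecord(id=str(row["id"]), x=float(row["x"]),
                                 y=float(row["y"]), industry=str(row["industry"]),
                                 raw=raw))
    return out


def write_factories(factories: Sequence[FactoryRecord], path) -> None:
    cols: dict[str, None] = {}
    for f in factories:
        for k in f.raw:
            cols.setdefault(k)
    raw_cols = list(cols)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(FACTORY_META_COLS + raw_cols) + "\n")
        for f in factories:
            cells = [f.id, _fmt(f.x), _fmt(f.y), f.industry]
            for c in raw_cols:
                v = f.raw.get(c, "")
                if isinstance(v, bool):
                    cells.append("true" if v else "false")
                elif isinstance(v, (int, float)):
                    cells.append(_fmt(v))
                else:
                    cells.append(str(v))
            fh.write(",".join(cells) + "\n")


# -- results ------------------------------------------------------------------

def write_health_results(results: Sequence[HealthRiskResult],
                         samples: Sequence[SoilSample], path) -> None:
    """id,x,y,tcr,thi,level plus per-pollutant cr_<id> columns."""
    by_id = {s.id: s for s in samples}
    pids: dict[str, None] = {}
    for r in results:
        for pid in r.cr:
            pids.setdefault(pid)
    cr_cols = [f"cr_{pid}" for pid in pids]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(["id", "x", "y", "tcr", "thi", "level"] + cr_cols) + "\n")
        for r in results:
            s = by_id[r.sample_id]
            cells = [r.sample_id, _fmt(s.x), _fmt(s.y), _fmt(r.tcr), _fmt(r.thi),
                     r.level.name]
            cells += [_fmt(r.cr.get(pid, 0.0)) for pid in pids]
            fh.write(",".join(cells) + "\n")


def read_health_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    needed = {"id", "x", "y", "tcr", "thi", "level"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_cri_results(results: Sequence[CRIResult],
                      factories: Sequence[FactoryRecord], path) -> None:
    by_id = {f.id: f for f in factories}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id,x,y,sub_sudden,sub_cumulative,sub_supervision,cri,level\n")
        for r in results:
            f = by_id[r.factory_id]
            fh.write(",".join([
                r.factory_id, _fmt(f.x), _fmt(f.y),
                _fmt(r.subscores["sudden"]), _fmt(r.subscores["cumulative"]),
                _fmt(r.subscores["supervision"]), _fmt(r.cri), r.level.name,
            ]) + "\n")


def read_cri_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    missing = {"id", "x", "y", "cri"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


# -- ESRI ASCII grid ----------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "NODATA_value")


def write_raster(r: Raster, path) -> None:
    """ESRI ASCII grid: canonical header order, north row first, full
    float precision."""
    s = r.spec
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"ncols {s.n_cols}\n")
        fh.write(f"nrows {s.n_rows}\n")
        fh.write(f"xllcorner {_fmt(s.x_origin)}\n")
        fh.write(f"yllcorner {_fmt(s.y_origin)}\n")
        fh.write(f"cellsize {_fmt(s.cell_size)}\n")
        fh.write(f"NODATA_value {_fmt(s.nodata)}\n")
        vals = np.where(r.mask, s.nodata, r.values)
        for row in vals:
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


def read_raster(path) -> Raster:
    with open(path, "r", encoding="utf-8") as fh:
        header: dict[str, float] = {}
        for key in _HEADER_KEYS:
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or parts[0].lower() != key.lower():
                raise ValueError(
                    f"{path}: expected header token {key!r}, got {line.strip()!r}"
                )
            header[key] = float(parts[1])
        rows = []
        for lineno, line in enumerate(fh, start=7):
            toks = line.split()
            if not toks:
                continue
            try:
                rows.append([float(t) for t in toks])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: unparseable token ({exc})") from None
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    if len(rows) != n_rows or any(len(row) != n_cols for row in rows):
        raise ValueError(
            f"{path}: data dimensions {len(rows)}x"
            f"{len(rows[0]) if rows else 0} do not match header {n_rows}x{n_cols}"
        )
    nodata = header["NODATA_value"]
    values = np.asarray(rows, dtype=float)
    spec = GridSpec(
        x_origin=header["xllcorner"], y_origin=header["yllcorner"],
        cell_size=header["cellsize"], n_cols=n_cols, n_rows=n_rows,
        nodata=nodata,
    )
    mask = values == nodata
    return Raster(spec=spec, values=values, mask=mask)


# -- misc ---------------------------------------------------------------------

def file_digest(path) -> str:
    """SHA-256 of a file, for provenance records."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_digest(raw: dict) -> str:
    """Stable digest of a configuration mapping."""
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_truth(truth, path) -> None:
    payload = {
        "seed": truth.seed,
        "plumes": [
            {"pollutant": p.pollutant, "center": list(p.center),
             "amplitude": p.amplitude, "length_scale": p.length_scale}
            for p in truth.plumes
        ],
        "landuse_zones": [
            {"rect": [r.x0, r.y0, r.x1, r.y1], "class": lu.value}
            for r, lu in truth.landuse_zones
        ],
        "factory_tiers": truth.factory_tiers,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
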