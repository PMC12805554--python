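"""Core tabular data structures, treatment encoding, and proxy transforms.

The central object is :class:`RegionTable`: one row per areal unit (region)
nested in a city, carrying a continuous outcome, a binary or graded
treatment, and ``p`` proxy columns ``w1..wp``.  Geometry (planar polygons)
is optional and only needed when spline bases are built from scratch.
"""

from __future__ import annotations

import dataclasses
import json
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

REQUIRED_COLUMNS = ("city", "region", "outcome", "treatment")
GRADES = ("A", "B", "C", "D")
TREATMENT_LEVELS = ("B", "C", "D")  # non-reference grades, in design order

_PROXY_RE = re.compile(r"^w(\d+)$")


def _proxy_columns(columns: Iterable[str]) -> list[str]:
    found = {}
    for c in columns:
        m = _PROXY_RE.match(c)
        if m:
            found[int(m.group(1))] = c
    if not found:
        return []
    idx = sorted(found)
    if idx != list(range(1, len(idx) + 1)):
        raise ValueError(f"proxy columns must be consecutive w1..wp, got {sorted(found.values())}")
    return [found[i] for i in idx]


@dataclasses.dataclass
class RegionTable:
    """Validated table of areal units with optional polygon geometry.

    Parameters
    ----------
    df
        DataFrame with columns ``city, region, outcome, treatment, w1..wp``.
    geometry
        Optional mapping ``(city, region) -> shapely geometry`` in planar
        (projected) coordinates.  No CRS handling is performed.
    """

    df: pd.DataFrame
    geometry: dict[tuple, BaseGeometry] | None = None

    def __post_init__(self) -> None:
        df = self.df
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        self.proxy_columns = _proxy_columns(df.columns)
        dup = df.duplicated(subset=["city", "region"])
        if dup.any():
            rows = df.loc[dup, ["city", "region"]].iloc[0]
            raise ValueError(f"duplicate (city, region) key: ({rows['city']}, {rows['region']})")
        for col in ["outcome", *self.proxy_columns]:
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            bad = ~np.isfinite(vals)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(f"non-finite value in column {col!r} at row {i} "
                                 f"(city={df['city'].iloc[i]}, region={df['region'].iloc[i]})")
        tr = df["treatment"]
        if tr.dtype == object:
            bad = ~tr.astype(str).isin(GRADES)
            if bad.any():
                raise ValueError(f"treatment grade outside A-D: {tr[bad].iloc[0]!r}")
        else:
            vals = pd.to_numeric(tr, errors="coerce")
            if vals.isna().any() or not set(np.unique(vals)).issubset({0, 1}):
                raise ValueError("binary treatment column must contain only 0/1")
        if self.geometry is not None:
            keys = set(zip(df["city"], df["region"]))
            for k in self.geometry:
                if k not in keys:
                    raise ValueError(f"geometry key {k} has no matching table row")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def p(self) -> int:
        return len(self.proxy_columns)

    @property
    def cities(self) -> list:
        return list(pd.unique(self.df["city"]))

    @property
    def treatment_mode(self) -> str:
        return "multilevel" if self.df["treatment"].dtype == object else "binary"

    def city_sizes(self) -> dict:
        return self.df.groupby("city", sort=False).size().to_dict()

    def outcome(self) -> np.ndarray:
        return self.df["outcome"].to_numpy(dtype=float)

    def proxies(self) -> np.ndarray:
        return self.df[self.proxy_columns].to_numpy(dtype=float)

    def city_index(self) -> np.ndarray:
        """Integer city code per row, 0-based, in first-appearance order."""
        codes, _ = pd.factorize(self.df["city"], sort=False)
        return codes

    def city_polygons(self, city) -> list[BaseGeometry]:
        if self.geometry is None:
            raise ValueError("table carries no geometry")
        sub = self.df.loc[self.df["city"] == city, "region"]
        try:
            return [self.geometry[(city, r)] for r in sub]
        except KeyError as e:  # pragma: no cover - guarded by loader
            raise ValueError(f"missing geometry for (city={city}, region={e.args[0]})") from e


def load_region_table(path_csv, path_geojson=None) -> RegionTable:
    """Load a region table from CSV, optionally attaching GeoJSON polygons.

    The CSV schema is ``city,region,outcome,treatment,w1..wp`` (header
    required).  The GeoJSON must be a FeatureCollection whose features carry
    ``city`` and ``region`` properties; every feature must match a CSV row.
    """
    df = pd.read_csv(path_csv)
    geometry = None
    if path_geojson is not None:
        with open(path_geojson) as fh:
            gj = json.load(fh)
        geometry = {}
        for feat in gj.get("features", []):
            props = feat.get("properties", {})
            if "city" not in props or "region" not in props:
                raise ValueError("GeoJSON feature lacks city/region properties")
            geometry[(props["city"], props["region"])] = shapely_shape(feat["geometry"])
    return RegionTable(df=df, geometry=geometry)


def write_region_table(table: RegionTable, path_csv, path_geojson=None) -> None:
    """Write a region table back to CSV (and its geometry to GeoJSON)."""
    table.df.to_csv(path_csv, index=False)
    if path_geojson is not None:
        if table.geometry is None:
            raise ValueError("table has no geometry to write")
        feats = []
        for (city, region), geom in table.geometry.items():
            feats.append({
                "type": "Feature",
                "properties": {"city": _jsonable(city), "region": _jsonable(region)},
                "geometry": shapely_mapping(geom),
            })
        with open(path_geojson, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def center_by_city(table: RegionTable, columns: Sequence[str]) -> RegionTable:
    """Return a copy with each named column centered to mean 0 within city."""
    df = table.df.copy()
    for col in columns:
        if col not in df.columns:
            raise KeyError(f"unknown column {col!r}")
        df[col] = df[col].astype(float) - df.groupby("city", sort=False)[col].transform("mean")
    return RegionTable(df=df, geometry=table.geometry)


def boxcox(values, lmbda: float | None = None, offset: float | None = None) -> np.ndarray:
    """Box-Cox transform ``(v^l - 1)/l`` (``log v`` at ``l = 0``).

    ``values`` must be strictly positive; zeros are shifted by ``offset``
    (default: half the smallest positive value, applied to all entries).
    When ``lmbda`` is None it is estimated by profile-likelihood
    maximization.
    """
    v = np.asarray(values, dtype=float)
    v = _apply_offset(v, offset)
    if lmbda is None:
        lmbda = boxcox_lambda(v)
    if lmbda == 0:
        return np.log(v)
    return (np.power(v, lmbda) - 1.0) / lmbda


def boxcox_lambda(values, offset: float | None = None) -> float:
    """Profile-likelihood (MLE) estimate of the Box-Cox exponent."""
    v = _apply_offset(np.asarray(values, dtype=float), offset)
    return float(stats.boxcox_normmax(v, method="mle"))


def _apply_offset(v: np.ndarray, offset: float | None) -> np.ndarray:
    if np.any(v <= 0):
        if offset is None:
            pos = v[v > 0]
            if pos.size == 0:
                raise ValueError("Box-Cox input has no positive values")
            if np.any(v < 0):
                raise ValueError("Box-Cox input has negative values; supply an explicit offset")
            offset = 0.5 * pos.min()
        v = v + offset
    if np.any(v <= 0):
        raise ValueError("Box-Cox input non-positive after offset")
    return v


def rank_inverse_normal(values) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offsets.

    Maps value of rank ``k`` (ties get the average rank) to
    ``ndtri((k - 3/8) / (n + 1/4))``, so exact zeros in a zero-inflated
    proxy share one common (negative) quantile.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.all(v == v[0]):
        raise ValueError("constant input: rank-inverse-normal transform undefined")
    ranks = stats.rankdata(v, method="average")
    return ndtri((ranks - 0.375) / (v.size + 0.25))


@dataclasses.dataclass
class TreatmentDesign:
    """Indicator encoding of the treatment column.

    ``matrix`` is ``n x K``: a single 0/1 column in binary mode, or three
    columns for grades B, C, D (grade A is the all-zero reference) in
    multilevel mode.
    """

    mode: str
    matrix: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.isin(m, (0.0, 1.0)).all():
            raise ValueError("indicator matrix must be 0/1")
        if self.mode == "multilevel" and np.any(m.sum(axis=1) > 1):
            raise ValueError("multilevel rows must have at most one active grade")
        self.matrix = m

    @property
    def K(self) -> int:
        return self.matrix.shape[1]


def encode_treatment(table: RegionTable, mode: str) -> TreatmentDesign:
    """Build the treatment indicator matrix (grade A = reference level)."""
    tr = table.df["treatment"]
    if mode == "binary":
        vals = pd.to_numeric(tr, errors="coerce").to_numpy(dtype=float)
        if np.isnan(vals).any() or not set(np.unique(vals)).issubset({0.0, 1.0}):
            raise ValueError("binary treatment values must be 0 or 1")
        return TreatmentDesign("binary", vals[:, None], ("treated",))
    if mode == "multilevel":
        grades = tr.astype(str).to_numpy()
        bad = ~np.isin(grades, GRADES)
        if bad.any():
            raise ValueError(f"grade outside A-D: {grades[bad][0]!r}")
        mat = np.column_stack([(grades == g).astype(float) for g in TREATMENT_LEVELS])
        return TreatmentDesign("multilevel", mat, TREATMENT_LEVELS)
    raise ValueError(f"unknown treatment mode {mode!r}")


def decode_treatment(design: TreatmentDesign) -> np.ndarray:
    """Inverse of :func:`encode_treatment` (recovers grades / 0-1 vector)."""
    if design.mode == "binary":
        return design.matrix[:, 0].astype(int)
    out = np.full(design.matrix.shape[0], "A", dtype="<U1")
    for k, g in enumerate(design.columns):
        out[design.matrix[:, k] == 1] = g
    return out
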