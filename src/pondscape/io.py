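"""Tabular data model: pond tables, incidence matrices, species traits, results.

Conventions: CSV, UTF-8, ``.`` decimal, empty cell = value absent (NaN).
Areas are hectares, conductivities mS/cm, coordinates planar metres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

POND_BOOL_COLS = ["extant_1957", "extant_2010", "sampled_1957", "sampled_2010"]
POND_NUM_COLS = ["x", "y", "area_1957", "area_2010", "cond_1957", "cond_2010"]
POND_COLS = ["pond_id"] + POND_NUM_COLS + POND_BOOL_COLS

EPOCHS = ("1957", "2010")


class DataError(ValueError):
    """Raised when an input table violates the data model."""


@dataclass
class PondTable:
    """One row per pond; indexed by ``pond_id``.

    Numeric NaN means "absent" (e.g. a pond that no longer exists in an
    epoch has no area there), never zero.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.name != "pond_id":
            raise DataError("PondTable must be indexed by pond_id")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise DataError(f"duplicate pond_id {dup!r}")
        missing = [c for c in POND_NUM_COLS + POND_BOOL_COLS if c not in df.columns]
        if missing:
            raise DataError(f"pond table missing columns: {missing}")
        for epoch in EPOCHS:
            bad = df[f"sampled_{epoch}"] & ~df[f"extant_{epoch}"]
            if bad.any():
                raise DataError(
                    f"pond {df.index[bad][0]!r} sampled_{epoch} without extant_{epoch}"
                )
            for kind in ("area", "cond"):
                col = df[f"{kind}_{epoch}"]
                bad = col.notna() & (col <= 0)
                if bad.any():
                    raise DataError(
                        f"pond {df.index[bad][0]!r}: non-positive {kind}_{epoch}"
                    )

    def __len__(self) -> int:
        return len(self.df)

    def extant(self, epoch: str) -> pd.DataFrame:
        return self.df[self.df[f"extant_{epoch}"]]

    def sampled_ids(self, epoch: str) -> list[str]:
        return list(self.df.index[self.df[f"sampled_{epoch}"]])

    def coords(self, ids: Sequence[str] | None = None) -> np.ndarray:
        sub = self.df if ids is None else self.df.loc[list(ids)]
        return sub[["x", "y"]].to_numpy(float)

    def areas(self, epoch: str, ids: Sequence[str]) -> pd.Series:
        return self.df.loc[list(ids), f"area_{epoch}"]

    def conductivities(self, epoch: str, ids: Sequence[str]) -> pd.Series:
        return self.df.loc[list(ids), f"cond_{epoch}"]


@dataclass
class OccurrenceMatrix:
    """Site x species incidence (0/1) for one epoch.

    Column/row order is stable (as constructed or as read from file).
    """

    epoch: str
    site_ids: list[str]
    species_ids: list[str]
    incidence: np.ndarray  # shape (n_sites, n_species), values in {0, 1}

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence)
        if inc.shape != (len(self.site_ids), len(self.species_ids)):
            raise DataError("incidence shape does not match id lists")
        if not np.isin(inc, (0, 1)).all():
            i, j = np.argwhere(~np.isin(inc, (0, 1)))[0]
            raise DataError(
                f"non-binary cell at site {self.site_ids[i]!r}, "
                f"species {self.species_ids[j]!r}"
            )
        self.incidence = inc.astype(np.int8)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def alpha(self) -> np.ndarray:
        """Per-site richness."""
        return self.incidence.sum(axis=1)

    @property
    def gamma(self) -> int:
        """Regional richness: number of species present in at least one site."""
        return int((self.incidence.sum(axis=0) > 0).sum())

    @property
    def species_present(self) -> set[str]:
        keep = self.incidence.sum(axis=0) > 0
        return {s for s, k in zip(self.species_ids, keep) if k}

    def drop_empty_species(self) -> "OccurrenceMatrix":
        keep = self.incidence.sum(axis=0) > 0
        return OccurrenceMatrix(
            self.epoch,
            list(self.site_ids),
            [s for s, k in zip(self.species_ids, keep) if k],
            self.incidence[:, keep],
        )

    def restrict_sites(self, ids: Sequence[str], drop_empty: bool = True) -> "OccurrenceMatrix":
        pos = {s: i for i, s in enumerate(self.site_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise DataError(f"unknown site ids: {missing}")
        sub = OccurrenceMatrix(
            self.epoch,
            list(ids),
            list(self.species_ids),
            self.incidence[[pos[s] for s in ids], :],
        )
        return sub.drop_empty_species() if drop_empty else sub

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.incidence, index=self.site_ids, columns=self.species_ids)
        df.index.name = "site_id"
        return df


def read_pond_table(path: str | Path) -> PondTable:
    """Read and validate a pond table CSV.

    Missing numeric cells become NaN ("absent"), never zero.
    """
    df = pd.read_csv(path, dtype={"pond_id": str})
    if "pond_id" not in df.columns:
        raise DataError("pond table needs a pond_id column")
    for c in POND_BOOL_COLS:
        if c not in df.columns:
            raise DataError(f"pond table missing column {c!r}")
        df[c] = _parse_bool(df[c], c)
    for c in POND_NUM_COLS:
        if c not in df.columns:
            raise DataError(f"pond table missing column {c!r}")
        df[c] = pd.to_numeric(df[c], errors="raise")
    return PondTable(df.set_index("pond_id"))


def write_pond_table(ponds: PondTable, path: str | Path) -> None:
    ponds.df.reset_index().to_csv(path, index=False)


def _parse_bool(col: pd.Series, name: str) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "t": True, "f": False, True: True, False: False, 1: True, 0: False,
    }
    out = col.map(lambda v: mapping.get(str(v).strip().lower() if isinstance(v, str) else v))
    if out.isna().any():
        raise DataError(f"column {name!r} contains a non-boolean cell")
    return out.astype(bool)


def read_occurrence_matrix(
    path: str | Path,
    epoch: str,
    ponds: PondTable | None = None,
    allow_empty_species: bool = False,
) -> OccurrenceMatrix:
    """Read a site x species incidence CSV (first column ``site_id``)."""
    df = pd.read_csv(path, dtype={"site_id": str})
    if df.columns[0] != "site_id":
        raise DataError("first column of an occurrence matrix must be site_id")
    df = df.set_index("site_id")
    inc = df.to_numpy()
    if not np.isin(inc, (0, 1)).all():
        i, j = np.argwhere(~np.isin(inc, (0, 1)))[0]
        raise DataError(
            f"non-binary cell at site {df.index[i]!r}, species {df.columns[j]!r}"
        )
    occ = OccurrenceMatrix(epoch, list(df.index), list(df.columns), inc)
    if not allow_empty_species:
        empty = [s for s, tot in zip(occ.species_ids, occ.incidence.sum(axis=0)) if tot == 0]
        if empty:
            raise DataError(f"all-zero species columns: {empty}")
    if ponds is not None:
        unknown = [s for s in occ.site_ids if s not in ponds.df.index]
        if unknown:
            raise DataError(f"occurrence sites not in pond table: {unknown}")
    return occ


def write_occurrence_matrix(occ: OccurrenceMatrix, path: str | Path) -> None:
    occ.to_dataframe().to_csv(path)


def read_body_sizes(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, dtype={"species_id": str})
    if list(df.columns[:2]) != ["species_id", "body_size_mm"]:
        raise DataError("body-size table needs columns species_id, body_size_mm")
    s = df.set_index("species_id")["body_size_mm"].astype(float)
    if (s <= 0).any():
        raise DataError("non-positive body size")
    return s


def derive_species_traits(
    occ_1957: OccurrenceMatrix,
    ponds: PondTable,
    body_sizes: pd.Series | Mapping[str, float],
    regional_2010: Iterable[str],
) -> pd.DataFrame:
    """Species trait table from the epoch-1 incidence matrix.

    occupancy_1957 : fraction of epoch-1 sampled sites occupied (0, 1]
    preference     : mean epoch-1 conductivity over occupied sites (mS/cm)
    extinct_2010   : absent from the epoch-2 regional species list
    """
    body_sizes = pd.Series(body_sizes, dtype=float)
    missing = [s for s in occ_1957.species_ids if s not in body_sizes.index]
    if missing:
        raise DataError(f"species without body size: {missing}")
    cond = ponds.conductivities("1957", occ_1957.site_ids)
    if cond.isna().any():
        raise DataError(
            f"missing epoch-1 conductivity for sites: {list(cond.index[cond.isna()])}"
        )
    cond = cond.to_numpy(float)
    n_sites = occ_1957.n_sites
    counts = occ_1957.incidence.sum(axis=0)
    if (counts == 0).any():
        bad = occ_1957.species_ids[int(np.argmax(counts == 0))]
        raise DataError(f"species with zero occupancy: {bad!r}")
    regional_2010 = set(regional_2010)
    pref = (occ_1957.incidence.T * cond).sum(axis=1) / counts
    out = pd.DataFrame(
        {
            "occupancy_1957": counts / n_sites,
            "body_size": body_sizes.loc[occ_1957.species_ids].to_numpy(),
            "preference": pref,
            "extinct_2010": [s not in regional_2010 for s in occ_1957.species_ids],
        },
        index=pd.Index(occ_1957.species_ids, name="species_id"),
    )
    return out


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="index"))
    return obj


def write_results(
    results: Mapping,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    """Serialise a result bundle as JSON with schema version and seed echo."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config": _jsonable(config) if config is not None else None,
        "results": _jsonable(dict(results)),
    }
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
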