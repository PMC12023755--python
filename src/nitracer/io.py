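"""Domain types and tabular I/O.

The analysis chain passes five kinds of tables around:

* isotope samples — one row per water sample with its dual nitrate isotope
  observation (δ¹⁵N, δ¹⁸O, both in per-mil) plus region/season labels;
* source signature tables — for every candidate nitrogen source and isotope,
  the signature distribution (mean, SD), the fractionation distribution
  (mean, SD) and an optional concentration weight;
* community count tables — sites × taxa non-negative integer counts;
* watershed covariate tables — per site-season records of the connectivity
  index, nitrogen concentrations, diversity indices and socio-environmental
  covariates;
* distance matrices — square symmetric dissimilarities with labels.

File conventions: CSV for sample/signature/covariate tables, TSV for
community tables (taxon names routinely contain commas).  Missing values are
not permitted in numeric columns — every downstream statistic assumes
complete cases, so readers fail fast.  Typed data formats are written at 12
significant digits (lossless round trip for doubles printed at that
precision); derived result tables are written at 6.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    CompletenessError,
    DomainError,
    ParseError,
    SchemaError,
)

__all__ = [
    "IsotopeSample",
    "SourceSignatureTable",
    "CommunityTable",
    "WatershedTable",
    "DistanceMatrix",
    "read_isotope_csv",
    "write_isotope_csv",
    "read_sources_csv",
    "write_sources_csv",
    "read_community_table",
    "write_community_table",
    "read_watershed_csv",
    "write_watershed_csv",
    "read_distance_csv",
    "write_distance_csv",
    "write_results",
]

ISOTOPES = ("d15n", "d18o")

WATERSHED_COLUMNS = (
    "site_id",
    "season",
    "connectivity",
    "tn",
    "no3",
    "nh4",
    "chao1",
    "shannon",
    "agriculture",
    "population",
    "wastewater",
    "environment",
)

_DATA_FMT = "%.12g"   # typed data formats round-trip losslessly
_RESULT_FMT = "%.6g"  # presentation/result tables


@dataclass(frozen=True)
class IsotopeSample:
    """A single water sample's dual nitrate-isotope observation."""

    sample_id: str
    region: str
    season: str
    d15n: float
    d18o: float

    def __post_init__(self) -> None:
        if not self.region or not self.season:
            raise DomainError("region and season labels must be non-empty")
        if not (np.isfinite(self.d15n) and np.isfinite(self.d18o)):
            raise DomainError(
                f"sample {self.sample_id!r}: isotope values must be finite"
            )

    def isotope_values(self) -> np.ndarray:
        """The (δ¹⁵N, δ¹⁸O) pair as a length-2 array (‰)."""
        return np.array([self.d15n, self.d18o])


class SourceSignatureTable:
    """Per-source, per-isotope signature and fractionation parameters.

    For source k and isotope j the table stores the signature distribution
    S_jk ~ N(mean_s, sd_s²), the fractionation distribution
    C_jk ~ N(mean_c, sd_c²) and a concentration weight q > 0 (default 1,
    i.e. no concentration dependence).  Arrays are shaped (K sources,
    J isotopes).
    """

    def __init__(
        self,
        sources: Sequence[str],
        isotopes: Sequence[str],
        mean_s: np.ndarray,
        sd_s: np.ndarray,
        mean_c: np.ndarray | None = None,
        sd_c: np.ndarray | None = None,
        conc_q: np.ndarray | None = None,
    ) -> None:
        self.sources = list(sources)
        self.isotopes = list(isotopes)
        K, J = len(self.sources), len(self.isotopes)
        if K < 1 or J < 1:
            raise DomainError("need at least one source and one isotope")
        if len(set(self.sources)) != K:
            raise DomainError("duplicate source names")

        def _arr(a, default):
            if a is None:
                return np.full((K, J), float(default))
            a = np.asarray(a, dtype=float)
            if a.shape != (K, J):
                raise SchemaError(
                    f"expected array of shape ({K}, {J}), got {a.shape}"
                )
            return a.copy()

        self.mean_s = _arr(mean_s, np.nan)
        self.sd_s = _arr(sd_s, np.nan)
        self.mean_c = _arr(mean_c, 0.0)
        self.sd_c = _arr(sd_c, 0.0)
        self.conc_q = _arr(conc_q, 1.0)
        for name, a in (("mean_s", self.mean_s), ("sd_s", self.sd_s)):
            if not np.all(np.isfinite(a)):
                raise CompletenessError(f"{name} has missing cells")
        if np.any(self.sd_s < 0) or np.any(self.sd_c < 0):
            raise DomainError("signature/fractionation SDs must be >= 0")
        if np.any(self.conc_q <= 0):
            raise DomainError("concentration weights must be > 0")

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_isotopes(self) -> int:
        return len(self.isotopes)

    def reorder(self, sources: Sequence[str]) -> "SourceSignatureTable":
        """A copy with sources permuted into the given order."""
        if sorted(sources) != sorted(self.sources):
            raise DomainError("reorder must use the same source names")
        idx = [self.sources.index(s) for s in sources]
        return SourceSignatureTable(
            [self.sources[i] for i in idx],
            self.isotopes,
            self.mean_s[idx],
            self.sd_s[idx],
            self.mean_c[idx],
            self.sd_c[idx],
            self.conc_q[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with one row per source × isotope."""
        rows = []
        for k, src in enumerate(self.sources):
            for j, iso in enumerate(self.isotopes):
                rows.append(
                    {
                        "source": src,
                        "isotope": iso,
                        "mean_s": self.mean_s[k, j],
                        "sd_s": self.sd_s[k, j],
                        "mean_c": self.mean_c[k, j],
                        "sd_c": self.sd_c[k, j],
                        "conc_q": self.conc_q[k, j],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SourceSignatureTable":
        required = {"source", "isotope", "mean_s", "sd_s"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"sources table missing columns: {sorted(missing)}")
        sources = list(dict.fromkeys(df["source"]))
        isotopes = list(dict.fromkeys(df["isotope"]))
        K, J = len(sources), len(isotopes)
        seen = set(zip(df["source"], df["isotope"]))
        gaps = [
            (s, i) for s in sources for i in isotopes if (s, i) not in seen
        ]
        if gaps:
            raise CompletenessError(f"missing source×isotope combinations: {gaps}")
        arrays = {}
        for col, default in (
            ("mean_s", None),
            ("sd_s", None),
            ("mean_c", 0.0),
            ("sd_c", 0.0),
            ("conc_q", 1.0),
        ):
            a = np.full((K, J), np.nan if default is None else default)
            if col in df.columns:
                for _, row in df.iterrows():
                    k = sources.index(row["source"])
                    j = isotopes.index(row["isotope"])
                    a[k, j] = float(row[col])
            arrays[col] = a
        return cls(sources, isotopes, **arrays)


@dataclass
class CommunityTable:
    """Sites × taxa count matrix with optional per-site metadata."""

    site_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.site_ids), len(self.taxon_ids)):
            raise SchemaError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.site_ids)} sites × {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ParseError("community counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise DomainError("community counts must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.site_ids, columns=self.taxon_ids
        )


class WatershedTable:
    """Per site-season covariate records for the coupling analysis.

    Wraps a DataFrame with the fixed column set ``WATERSHED_COLUMNS``;
    validates that the connectivity index is finite and that nitrogen
    concentrations are non-negative.
    """

    def __init__(self, data: pd.DataFrame) -> None:
        missing = set(WATERSHED_COLUMNS) - set(data.columns)
        if missing:
            raise SchemaError(f"watershed table missing columns: {sorted(missing)}")
        df = data.loc[:, list(WATERSHED_COLUMNS)].reset_index(drop=True)
        numeric = [c for c in WATERSHED_COLUMNS if c not in ("site_id", "season")]
        for col in numeric:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                bad = int(vals.isna().idxmax())
                raise ParseError(f"non-numeric value in column {col!r}, row {bad}")
            df[col] = vals.astype(float)
        if not np.all(np.isfinite(df["connectivity"])):
            raise DomainError("connectivity index must be finite")
        for col in ("tn", "no3", "nh4"):
            if np.any(df[col] < 0):
                raise DomainError(f"nitrogen concentration {col!r} must be >= 0")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise SchemaError(f"no watershed column {name!r}")
        return self.data[name].to_numpy()


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with ordered labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise SchemaError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DomainError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise DomainError("distance matrix diagonal must be exactly 0")
        if np.any(v < 0):
            raise DomainError("distances must be >= 0")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper triangle, row-major (scipy 'condensed' order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def align_to(self, labels: Sequence[str]) -> "DistanceMatrix":
        if sorted(labels) != sorted(self.labels):
            raise AlignmentError("distance matrices have different label sets")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {missing}")


def _parse_float(value, col: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"non-numeric value {value!r} in column {col!r}, data row {row}"
        ) from None


def read_isotope_csv(path: str | Path) -> list[IsotopeSample]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["sample_id", "region", "season", "d15n", "d18o"], "isotope CSV")
    samples = []
    for i, row in enumerate(df.itertuples(index=False)):
        samples.append(
            IsotopeSample(
                sample_id=str(row.sample_id),
                region=str(row.region),
                season=str(row.season),
                d15n=_parse_float(row.d15n, "d15n", i),
                d18o=_parse_float(row.d18o, "d18o", i),
            )
        )
    return samples


def write_isotope_csv(samples: Sequence[IsotopeSample], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "region": [s.region for s in samples],
            "season": [s.season for s in samples],
            "d15n": [s.d15n for s in samples],
            "d18o": [s.d18o for s in samples],
        }
    )
    df.to_csv(path, index=False, float_format=_DATA_FMT)


def read_sources_csv(path: str | Path) -> SourceSignatureTable:
    df = pd.read_csv(path)
    return SourceSignatureTable.from_frame(df)


def write_sources_csv(table: SourceSignatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, float_format=_DATA_FMT)


def read_community_table(
    path: str | Path, orientation: str = "sites-rows"
) -> CommunityTable:
    if orientation not in ("sites-rows", "taxa-rows"):
        raise DomainError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        raise ParseError("community table contains non-numeric cells")
    if not np.all(arr == np.floor(arr)):
        raise ParseError("community counts must be integers")
    arr = arr.astype(np.int64)
    if orientation == "taxa-rows":
        arr = arr.T
        sites, taxa = list(df.columns.astype(str)), list(df.index.astype(str))
    else:
        sites, taxa = list(df.index.astype(str)), list(df.columns.astype(str))
    return CommunityTable(sites, taxa, arr)


def write_community_table(
    table: CommunityTable, path: str | Path, orientation: str = "sites-rows"
) -> None:
    df = table.to_frame()
    if orientation == "taxa-rows":
        df = df.T
    df.to_csv(path, sep="\t")


def read_watershed_csv(path: str | Path) -> WatershedTable:
    return WatershedTable(pd.read_csv(path))


def write_watershed_csv(table: WatershedTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, float_format=_DATA_FMT)


def read_distance_csv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_distance_csv(d: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(d.values, index=d.labels, columns=d.labels).to_csv(
        path, float_format="%.12g"
    )


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> dict:
    """Write one CSV per result table plus a JSON run manifest.

    The manifest records the seed, the configuration, library versions and
    the list of files written, so a run can be reproduced exactly.
    Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, df in tables.items():
        fname = f"{name}.csv"
        df.to_csv(out / fname, index=False, float_format=_RESULT_FMT)
        files.append(fname)
    manifest = {
        "seed": seed,
        "config": dict(config) if config else {},
        "files": files,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
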