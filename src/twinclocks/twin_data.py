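"""Data model, validation and I/O for twin-pair phenotype tables.

The central container is :class:`TwinDataset`: an ordered collection of
:class:`TwinPair` records, each holding the phenotype of both co-twins at
one or two measurement waves plus named per-twin covariates (sex, age, ...).
Tables are read from and written to delimited text (CSV/TSV) in either a
*long* layout (one row per twin per wave) or a *wide* layout (one row per
pair).

Within-pair twin order is arbitrary everywhere: summaries and all model
likelihoods downstream are invariant to swapping the two twins of a pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Zygosity",
    "TwinPair",
    "TwinDataset",
    "GroupSummary",
    "TwinDataError",
    "SchemaError",
    "IntegrityError",
    "ParseError",
    "read_twin_table",
    "write_twin_table",
    "summarize",
]

NA_TOKEN = "NA"

#: zygosity tokens accepted on input (case-insensitive), besides "MZ"/"DZ"
MZ_SYNONYMS = frozenset({"MZ", "MONOZYGOTIC", "1"})
DZ_SYNONYMS = frozenset({"DZ", "DIZYGOTIC", "2"})


class TwinDataError(ValueError):
    """Base class for twin-table validation failures."""


class SchemaError(TwinDataError):
    """A required column is absent or the layout cannot be interpreted."""


class IntegrityError(TwinDataError):
    """The file parses but violates twin-design constraints."""


class ParseError(TwinDataError):
    """A cell cannot be converted to the required type."""


class Zygosity(str, Enum):
    MZ = "MZ"
    DZ = "DZ"

    @classmethod
    def parse(cls, token: object) -> "Zygosity":
        if isinstance(token, cls):
            return token
        s = str(token).strip().upper()
        if s in MZ_SYNONYMS:
            return cls.MZ
        if s in DZ_SYNONYMS:
            return cls.DZ
        raise IntegrityError(
            f"zygosity must be MZ or DZ (or a recognised synonym); got {token!r}"
        )


@dataclass
class TwinPair:
    """One same-sex twin pair.

    ``phenotype`` has shape ``(2, n_waves)`` (twin slot, wave); NaN marks a
    missing measurement.  ``covariates`` maps a name to an array of the same
    shape (covariates that do not vary by wave are simply repeated).
    """

    pair_id: str
    zygosity: Zygosity
    phenotype: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        if self.phenotype.ndim == 1:
            self.phenotype = self.phenotype.reshape(2, 1)
        if self.phenotype.shape[0] != 2 or self.phenotype.shape[1] not in (1, 2):
            raise IntegrityError(
                f"pair {self.pair_id}: phenotype must have shape (2, 1|2), "
                f"got {self.phenotype.shape}"
            )
        nw = self.phenotype.shape[1]
        fixed = {}
        for name, vals in self.covariates.items():
            arr = np.asarray(vals, dtype=float)
            if arr.ndim == 1:
                arr = np.repeat(arr.reshape(2, 1), nw, axis=1)
            if arr.shape != (2, nw):
                raise IntegrityError(
                    f"pair {self.pair_id}: covariate {name!r} shape {arr.shape} "
                    f"does not match phenotype shape (2, {nw})"
                )
            fixed[name] = arr
        self.covariates = fixed

    @property
    def n_waves(self) -> int:
        return self.phenotype.shape[1]

    def missing_slots(self) -> list[int]:
        """Twin slots (0/1) with no phenotype observation at any wave."""
        return [j for j in range(2) if np.all(np.isnan(self.phenotype[j]))]

    def swapped(self) -> "TwinPair":
        """The same pair with the two twin slots exchanged."""
        return TwinPair(
            self.pair_id,
            self.zygosity,
            self.phenotype[::-1].copy(),
            {k: v[::-1].copy() for k, v in self.covariates.items()},
        )


@dataclass
class TwinDataset:
    pairs: list[TwinPair]
    n_waves: int
    variable_name: str = "y"
    covariate_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_waves not in (1, 2):
            raise IntegrityError(f"n_waves must be 1 or 2, got {self.n_waves}")
        seen: set[str] = set()
        for p in self.pairs:
            if p.n_waves != self.n_waves:
                raise IntegrityError(
                    f"pair {p.pair_id}: wave count {p.n_waves} differs from "
                    f"dataset n_waves={self.n_waves}"
                )
            if p.pair_id in seen:
                raise IntegrityError(f"duplicate pair_id {p.pair_id!r}")
            seen.add(p.pair_id)
            if set(p.covariates) != set(self.covariate_names):
                raise IntegrityError(
                    f"pair {p.pair_id}: covariates {sorted(p.covariates)} do not "
                    f"match dataset covariate_names {sorted(self.covariate_names)}"
                )
        self._check_same_sex()

    def _check_same_sex(self) -> None:
        sex_cols = [c for c in self.covariate_names if c.lower() == "sex"]
        for col in sex_cols:
            for p in self.pairs:
                vals = p.covariates[col]
                v1, v2 = vals[0], vals[1]
                both = ~np.isnan(v1) & ~np.isnan(v2)
                if np.any(v1[both] != v2[both]):
                    raise IntegrityError(
                        f"pair {p.pair_id}: co-twins disagree on {col!r}; only "
                        "same-sex pairs are supported"
                    )

    # -- convenience accessors ----------------------------------------------

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def zygosity_counts(self) -> dict[Zygosity, int]:
        out = {Zygosity.MZ: 0, Zygosity.DZ: 0}
        for p in self.pairs:
            out[p.zygosity] += 1
        return out

    def require_both_zygosities(self) -> None:
        counts = self.zygosity_counts()
        if counts[Zygosity.MZ] == 0 or counts[Zygosity.DZ] == 0:
            raise IntegrityError(
                "model fitting requires at least one MZ and one DZ pair; got "
                f"{counts[Zygosity.MZ]} MZ and {counts[Zygosity.DZ]} DZ"
            )

    def phenotype_array(self) -> np.ndarray:
        """Phenotypes as an array of shape ``(n_pairs, 2, n_waves)``."""
        if not self.pairs:
            return np.empty((0, 2, self.n_waves))
        return np.stack([p.phenotype for p in self.pairs])

    def zygosity_array(self) -> np.ndarray:
        """Boolean mask, True where the pair is MZ."""
        return np.array([p.zygosity is Zygosity.MZ for p in self.pairs])

    def covariate_tensor(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Covariates as ``(n_pairs, 2, n_waves, n_cov)``."""
        names = list(self.covariate_names if names is None else names)
        missing = [n for n in names if n not in self.covariate_names]
        if missing:
            raise SchemaError(
                f"unknown covariates {missing}; available: {self.covariate_names}"
            )
        out = np.empty((self.n_pairs, 2, self.n_waves, len(names)))
        for i, p in enumerate(self.pairs):
            for k, name in enumerate(names):
                out[i, :, :, k] = p.covariates[name]
        return out

    def subset(self, mask: Iterable[bool]) -> "TwinDataset":
        kept = [p for p, m in zip(self.pairs, mask) if m]
        return TwinDataset(kept, self.n_waves, self.variable_name,
                           list(self.covariate_names), dict(self.meta))

    def swapped(self) -> "TwinDataset":
        """Dataset with twin order reversed in every pair (for invariance tests)."""
        return TwinDataset([p.swapped() for p in self.pairs], self.n_waves,
                           self.variable_name, list(self.covariate_names),
                           dict(self.meta))


@dataclass
class GroupSummary:
    """Per-zygosity, per-wave descriptive statistics.

    ``table`` has one row per (zygosity, wave) with columns ``n_pairs``,
    ``n_individuals``, ``mean``, ``sd`` and ``r_within`` — the double-entered
    within-pair Pearson correlation (NaN when undefined, e.g. constant input
    or fewer than two complete pairs).
    """

    table: pd.DataFrame

    def row(self, zygosity: Zygosity | str, wave: int = 1) -> pd.Series:
        z = Zygosity.parse(zygosity).value
        sel = self.table[(self.table.zygosity == z) & (self.table.wave == wave)]
        if sel.empty:
            raise KeyError(f"no summary row for {z} wave {wave}")
        return sel.iloc[0]


def _double_entry_corr(y: np.ndarray) -> float:
    """Order-invariant within-pair correlation from an (n, 2) array."""
    complete = ~np.isnan(y).any(axis=1)
    y = y[complete]
    if len(y) < 2:
        return float("nan")
    x1 = np.concatenate([y[:, 0], y[:, 1]])
    x2 = np.concatenate([y[:, 1], y[:, 0]])
    if np.std(x1) == 0 or np.std(x2) == 0:
        return float("nan")
    return float(np.corrcoef(x1, x2)[0, 1])


def summarize(dataset: TwinDataset) -> GroupSummary:
    """Descriptive statistics per zygosity group and wave.

    Missing values are excluded pairwise; a group with no complete pairs gets
    an undefined (NaN) correlation rather than an error.
    """
    pheno = dataset.phenotype_array()
    mz = dataset.zygosity_array()
    rows = []
    for zyg, mask in ((Zygosity.MZ, mz), (Zygosity.DZ, ~mz)):
        sub = pheno[mask]
        for w in range(dataset.n_waves):
            y = sub[:, :, w] if len(sub) else np.empty((0, 2))
            vals = y[~np.isnan(y)]
            rows.append({
                "zygosity": zyg.value,
                "wave": w + 1,
                "n_pairs": int(mask.sum()),
                "n_individuals": int(vals.size),
                "mean": float(np.mean(vals)) if vals.size else float("nan"),
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else
                      (0.0 if vals.size == 1 else float("nan")),
                "r_within": _double_entry_corr(y),
            })
    table = pd.DataFrame(rows)
    # constant input: sd == 0 -> correlation undefined
    table.loc[table["sd"] == 0.0, "r_within"] = float("nan")
    return GroupSummary(table)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_STRUCT_KEYS = ("pair_id", "zygosity", "twin", "wave", "phenotype")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _coerce_numeric(frame: pd.DataFrame, col: str, path: Path) -> pd.Series:
    raw = frame[col]
    try:
        # exact (round-trip) float parsing; pd.to_numeric can lose the last ulp
        return pd.Series(raw.to_numpy(dtype=float), index=raw.index)
    except (TypeError, ValueError):
        for row, val in raw.items():
            if val is None or (isinstance(val, float) and np.isnan(val)):
                continue
            try:
                float(val)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path.name}: non-numeric value {val!r} in column {col!r} "
                    f"at data row {row + 1}"
                ) from None
        raise  # pragma: no cover - unreachable


def _remap_sex(values: np.ndarray, meta: dict, colname: str) -> np.ndarray:
    """Accept 0/1 or 1/2 sex coding; normalise to 0/1 and record the mapping."""
    present = values[~np.isnan(values)]
    uniq = set(np.unique(present).tolist())
    if uniq <= {0.0, 1.0}:
        meta.setdefault("sex_coding", {})[colname] = "0/1 (unchanged)"
        return values
    if uniq <= {1.0, 2.0}:
        meta.setdefault("sex_coding", {})[colname] = "1/2 remapped to 0/1"
        return values - 1.0
    raise IntegrityError(
        f"column {colname!r}: sex must be coded 0/1 or 1/2; saw values {sorted(uniq)}"
    )


def read_twin_table(
    path: str | Path,
    layout: str = "long",
    column_map: Mapping[str, str] | None = None,
    variable: str | None = None,
    covariates: Sequence[str] | None = None,
    delimiter: str | None = None,
) -> TwinDataset:
    """Read a delimited twin-pair table.

    Parameters
    ----------
    layout
        ``"long"``: one row per twin (per wave for two-wave data) with
        columns ``pair_id, twin, [wave,] zygosity, <phenotype>, <covariates>``.
        ``"wide"``: one row per pair with per-twin phenotype columns
        ``<var>_t1 / <var>_t2`` (suffix ``_w1 / _w2`` added per wave for
        two-wave data) and per-twin covariate columns ``<cov>_t1 / <cov>_t2``.
    column_map
        Optional renaming of the structural columns (keys among
        ``pair_id, zygosity, twin, wave, phenotype``).
    variable
        Name of the phenotype column (long) or column stem (wide).  When
        omitted, the ``phenotype`` entry of *column_map* is used, else the
        first non-structural column.
    covariates
        Covariate column names / stems.  Default: every remaining column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(column_map or {})
    sep = _delimiter_for(path, delimiter)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                        na_values=["", NA_TOKEN], encoding="utf-8")
    frame.columns = [c.strip() for c in frame.columns]

    if layout == "long":
        return _read_long(frame, path, cmap, variable, covariates)
    if layout == "wide":
        return _read_wide(frame, path, cmap, variable, covariates)
    raise SchemaError(f"layout must be 'wide' or 'long', got {layout!r}")


def _require(frame: pd.DataFrame, col: str, path: Path) -> None:
    if col not in frame.columns:
        raise SchemaError(
            f"{path.name}: required column {col!r} not found; columns present: "
            f"{list(frame.columns)}"
        )


def _read_long(frame, path, cmap, variable, covariates) -> TwinDataset:
    c_pair = cmap.get("pair_id", "pair_id")
    c_zyg = cmap.get("zygosity", "zygosity")
    c_twin = cmap.get("twin", "twin")
    c_wave = cmap.get("wave", "wave")
    for col in (c_pair, c_zyg, c_twin):
        _require(frame, col, path)
    has_wave = c_wave in frame.columns
    struct = {c_pair, c_zyg, c_twin} | ({c_wave} if has_wave else set())

    var = variable or cmap.get("phenotype")
    if var is None:
        rest = [c for c in frame.columns if c not in struct]
        if not rest:
            raise SchemaError(f"{path.name}: no phenotype column found")
        var = rest[0]
    _require(frame, var, path)
    cov_names = list(covariates) if covariates is not None else [
        c for c in frame.columns if c not in struct and c != var
    ]
    for c in cov_names:
        _require(frame, c, path)

    twin_idx = _coerce_numeric(frame, c_twin, path)
    if not set(twin_idx.dropna().unique()) <= {1.0, 2.0}:
        raise IntegrityError(f"{path.name}: twin column must contain 1 or 2")
    wave_idx = (_coerce_numeric(frame, c_wave, path) if has_wave
                else pd.Series(1.0, index=frame.index))
    if frame.empty:
        # header-only file: the presence of a wave column marks two-wave data
        n_waves = 2 if has_wave else 1
    else:
        waves = sorted(wave_idx.dropna().unique())
        if waves not in ([1.0], [1.0, 2.0]):
            raise IntegrityError(
                f"{path.name}: wave column must contain 1 (and optionally 2); "
                f"got {waves}"
            )
        n_waves = len(waves)

    dup = frame.assign(_t=twin_idx, _w=wave_idx).duplicated(
        subset=[c_pair, "_t", "_w"], keep=False)
    if dup.any():
        row = int(dup.idxmax())
        raise IntegrityError(
            f"{path.name}: duplicate (pair_id, twin, wave) at data row {row + 1}"
        )

    values = _coerce_numeric(frame, var, path)
    cov_vals = {c: _coerce_numeric(frame, c, path) for c in cov_names}

    meta: dict = {"source": str(path), "layout": "long"}
    pairs: list[TwinPair] = []
    order = frame[c_pair].drop_duplicates().tolist()
    grouped = frame.groupby(c_pair, sort=False)
    for pid in order:
        rows = grouped.get_group(pid)
        zyg_tokens = rows[c_zyg].dropna().unique()
        zygs = {Zygosity.parse(t) for t in zyg_tokens}
        if len(zygs) != 1:
            raise IntegrityError(f"{path.name}: pair {pid!r} has inconsistent zygosity")
        pheno = np.full((2, n_waves), np.nan)
        covs = {c: np.full((2, n_waves), np.nan) for c in cov_names}
        for ridx in rows.index:
            t = int(twin_idx[ridx]) - 1
            w = int(wave_idx[ridx]) - 1
            pheno[t, w] = values[ridx]
            for c in cov_names:
                covs[c][t, w] = cov_vals[c][ridx]
        pairs.append(TwinPair(str(pid), zygs.pop(), pheno, covs))

    for c in cov_names:
        if c.lower() == "sex":
            stacked = np.stack([p.covariates[c] for p in pairs]) if pairs else \
                np.empty((0, 2, n_waves))
            remapped = _remap_sex(stacked.ravel(), meta, c).reshape(stacked.shape)
            for p, arr in zip(pairs, remapped):
                p.covariates[c] = arr
    return TwinDataset(pairs, n_waves, var, cov_names, meta)


_WIDE_RE = r"^{stem}_t([12])(?:_w([12]))?$"


def _wide_columns(frame: pd.DataFrame, stem: str) -> dict[tuple[int, int], str]:
    """Map (twin, wave) -> column name for a wide-format stem."""
    pat = re.compile(_WIDE_RE.format(stem=re.escape(stem)))
    out: dict[tuple[int, int], str] = {}
    for col in frame.columns:
        m = pat.match(col)
        if m:
            out[(int(m.group(1)), int(m.group(2) or 1))] = col
    if not out:
        # tolerate the bare "<stem>1"/"<stem>2" single-wave shorthand
        for col in frame.columns:
            m = re.match(rf"^{re.escape(stem)}([12])$", col)
            if m:
                out[(int(m.group(1)), 1)] = col
    return out


def _read_wide(frame, path, cmap, variable, covariates) -> TwinDataset:
    c_pair = cmap.get("pair_id", "pair_id")
    c_zyg = cmap.get("zygosity", "zygosity")
    for col in (c_pair, c_zyg):
        _require(frame, col, path)

    if variable is None:
        variable = cmap.get("phenotype")
    if variable is None:
        stems = {re.sub(r"_t[12](_w[12])?$|[12]$", "", c)
                 for c in frame.columns if c not in (c_pair, c_zyg)}
        stems.discard("")
        if not stems:
            raise SchemaError(f"{path.name}: no phenotype columns found")
        variable = sorted(stems)[0]
    pcols = _wide_columns(frame, variable)
    if not pcols:
        raise SchemaError(
            f"{path.name}: no columns matching phenotype stem {variable!r}"
        )
    n_waves = max(w for _, w in pcols)
    if covariates is not None:
        cov_names = list(covariates)
    else:
        used = {c_pair, c_zyg} | set(pcols.values())
        stems = []
        for c in frame.columns:
            if c in used:
                continue
            m = re.match(r"^(.*)_t[12](?:_w[12])?$", c)
            if m and m.group(1) not in stems:
                stems.append(m.group(1))
        cov_names = stems

    if frame[c_pair].duplicated().any():
        pid = frame[c_pair][frame[c_pair].duplicated()].iloc[0]
        raise IntegrityError(f"{path.name}: duplicate pair_id {pid!r}")

    numeric = {col: _coerce_numeric(frame, col, path) for col in pcols.values()}
    cov_cols = {c: _wide_columns(frame, c) for c in cov_names}
    for c, cols in cov_cols.items():
        if not cols:
            raise SchemaError(f"{path.name}: no columns for covariate stem {c!r}")
        for col in cols.values():
            numeric[col] = _coerce_numeric(frame, col, path)

    meta: dict = {"source": str(path), "layout": "wide"}
    pairs = []
    for ridx in frame.index:
        zyg = Zygosity.parse(frame.loc[ridx, c_zyg])
        pheno = np.full((2, n_waves), np.nan)
        for (t, w), col in pcols.items():
            pheno[t - 1, w - 1] = numeric[col][ridx]
        covs = {}
        for c, cols in cov_cols.items():
            arr = np.full((2, n_waves), np.nan)
            for (t, w), col in cols.items():
                arr[t - 1, w - 1] = numeric[col][ridx]
            if n_waves == 2 and all(w == 1 for _, w in cols):
                arr[:, 1] = arr[:, 0]
            covs[c] = arr
        pairs.append(TwinPair(str(frame.loc[ridx, c_pair]), zyg, pheno, covs))

    for c in cov_names:
        if c.lower() == "sex" and pairs:
            stacked = np.stack([p.covariates[c] for p in pairs])
            remapped = _remap_sex(stacked.ravel(), meta, c).reshape(stacked.shape)
            for p, arr in zip(pairs, remapped):
                p.covariates[c] = arr
    return TwinDataset(pairs, n_waves, variable, cov_names, meta)


def write_twin_table(
    dataset: TwinDataset,
    path: str | Path,
    layout: str = "long",
    delimiter: str | None = None,
) -> Path:
    """Write a dataset as delimited text; inverse of :func:`read_twin_table`."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    var = dataset.variable_name
    covs = dataset.covariate_names
    rows = []
    if layout == "long":
        for p in dataset.pairs:
            for t in range(2):
                for w in range(dataset.n_waves):
                    row = {"pair_id": p.pair_id, "twin": t + 1}
                    if dataset.n_waves == 2:
                        row["wave"] = w + 1
                    row["zygosity"] = p.zygosity.value
                    row[var] = p.phenotype[t, w]
                    for c in covs:
                        row[c] = p.covariates[c][t, w]
                    rows.append(row)
        cols = ["pair_id", "twin"] + (["wave"] if dataset.n_waves == 2 else []) \
            + ["zygosity", var] + list(covs)
    elif layout == "wide":
        for p in dataset.pairs:
            row = {"pair_id": p.pair_id, "zygosity": p.zygosity.value}
            for t in range(2):
                for w in range(dataset.n_waves):
                    suffix = f"_t{t+1}" + (f"_w{w+1}" if dataset.n_waves == 2 else "")
                    row[var + suffix] = p.phenotype[t, w]
                    for c in covs:
                        row[c + suffix] = p.covariates[c][t, w]
            rows.append(row)
        cols = ["pair_id", "zygosity"]
        for t in range(2):
            for w in range(dataset.n_waves):
                suffix = f"_t{t+1}" + (f"_w{w+1}" if dataset.n_waves == 2 else "")
                cols.append(var + suffix)
                cols.extend(c + suffix for c in covs)
    else:
        raise SchemaError(f"layout must be 'wide' or 'long', got {layout!r}")

    frame = pd.DataFrame(rows, columns=cols)
    try:
        # %.17g round-trips IEEE doubles exactly
        frame.to_csv(path, sep=sep, index=False, na_rep=NA_TOKEN,
                     encoding="utf-8", float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write twin table to {path}: {exc}") from exc
    return path
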