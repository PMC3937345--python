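"""Tabular data model and TSV input/output.

All tables share one orientation convention: samples are rows, features or
environmental variables are columns.  Files are tab-separated UTF-8 with a
single header row, no quoting, and ``NA`` as the only missing-value marker.
Emitted files sort rows by sample id and columns lexicographically so that a
write/read cycle is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ENV_METADATA",
    "SIZE_FRACTIONS",
    "LINEAGE_RANKS",
    "EnvTable",
    "AbundanceMatrix",
    "ModuleMap",
    "LineageTable",
    "read_env_table",
    "write_env_table",
    "read_abundance_table",
    "write_abundance_table",
    "read_module_map",
    "write_module_map",
    "read_lineage_table",
    "write_lineage_table",
]

#: Non-numeric sample metadata carried alongside the environmental variables.
ENV_METADATA = ("station", "depth", "size_fraction")

#: Filter size classes (µm) plus the merged pseudo-fraction.
SIZE_FRACTIONS = ("0.1-0.8", "0.8-3.0", "3.0-200", "combined")

#: Lineage ranks, most to least inclusive.
LINEAGE_RANKS = ("superkingdom", "phylum", "class", "order", "genus")

_MISSING = "NA"


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


@dataclass
class EnvTable:
    """Sample-by-environmental-variable table with sampling metadata.

    ``frame`` is indexed by sample id and contains the metadata columns
    ``station``, ``depth`` and ``size_fraction`` followed by an open set of
    numeric environmental variables (salinity in PSU, temperature in °C, …).
    Samples with missing environmental values are retained and flagged via
    :attr:`incomplete_samples`; they are dropped (with a warning) only when an
    analysis that cannot handle missing values is fitted.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.name is None:
            self.frame.index.name = "sample_id"
        _check_unique(self.frame.index, "sample_id")
        for col in ENV_METADATA:
            if col not in self.frame.columns:
                raise ValueError(f"missing metadata column {col!r}")
        depth = pd.to_numeric(self.frame["depth"])
        if (depth.dropna() < 0).any():
            bad = self.frame.index[depth < 0][0]
            raise ValueError(f"negative depth for sample {bad!r}")
        bad_frac = set(self.frame["size_fraction"].dropna()) - set(SIZE_FRACTIONS)
        if bad_frac:
            raise ValueError(f"unknown size_fraction label(s): {sorted(bad_frac)}")
        env = self.env
        for col in env.columns:
            if not np.issubdtype(env[col].dtype, np.number):
                raise ValueError(f"environmental column {col!r} is not numeric")
        if "salinity" in env.columns and (env["salinity"].dropna() < 0).any():
            bad = env.index[env["salinity"] < 0][0]
            raise ValueError(f"negative salinity for sample {bad!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    @property
    def env(self) -> pd.DataFrame:
        """The numeric environmental variables (metadata columns excluded)."""
        return self.frame.drop(columns=list(ENV_METADATA))

    @property
    def incomplete_samples(self) -> list[str]:
        """Samples with at least one missing environmental value."""
        return list(self.env.index[self.env.isna().any(axis=1)])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class AbundanceMatrix:
    """Non-negative sample-by-feature matrix with a normalization-state flag.

    ``feature_kind`` is one of ``taxon``, ``ko`` or ``module``; ``state`` is
    ``raw_counts``, ``genome_equivalent_normalized`` or ``proportions``.  In
    the ``proportions`` state every row must sum to 1 (within 1e-9) and
    all-zero rows are disallowed.
    """

    frame: pd.DataFrame
    feature_kind: str
    state: str = "raw_counts"

    _KINDS = ("taxon", "ko", "module")
    _STATES = ("raw_counts", "genome_equivalent_normalized", "proportions")

    def __post_init__(self) -> None:
        if self.feature_kind not in self._KINDS:
            raise ValueError(f"feature_kind must be one of {self._KINDS}")
        if self.state not in self._STATES:
            raise ValueError(f"state must be one of {self._STATES}")
        if self.frame.shape[0] == 0 or self.frame.shape[1] == 0:
            raise ValueError("abundance matrix is empty")
        _check_unique(self.frame.index, "sample_id")
        _check_unique(self.frame.columns, "feature id")
        values = self.frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance matrix contains non-finite values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.frame.index[i]!r}, "
                f"feature {self.frame.columns[j]!r}"
            )
        if self.frame.index.name is None:
            self.frame.index.name = "sample_id"
        if self.state == "proportions":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                s = self.frame.index[bad][0]
                raise ValueError(f"proportions row for sample {s!r} does not sum to 1")

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    @property
    def features(self) -> list[str]:
        return list(self.frame.columns)


@dataclass(frozen=True)
class ModuleMap:
    """Many-to-many KO → KEGG-module membership map.

    A KO may belong to several modules; every module has at least one member
    KO by construction.
    """

    ko_to_modules: Mapping[str, frozenset[str]]
    module_members: Mapping[str, tuple[str, ...]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ModuleMap":
        ko_to_modules: dict[str, set[str]] = {}
        members: dict[str, list[str]] = {}
        n = 0
        for ko, module in pairs:
            n += 1
            ko_to_modules.setdefault(ko, set()).add(module)
            if ko not in members.setdefault(module, []):
                members[module].append(ko)
        if n == 0:
            raise ValueError("module map has no entries")
        return cls(
            ko_to_modules={k: frozenset(v) for k, v in ko_to_modules.items()},
            module_members={m: tuple(sorted(v)) for m, v in members.items()},
        )

    @property
    def modules(self) -> list[str]:
        return sorted(self.module_members)

    def member_count(self, module: str) -> int:
        return len(self.module_members[module])

    def members(self, module: str) -> tuple[str, ...]:
        return self.module_members[module]


@dataclass
class LineageTable:
    """Ordered taxonomic lineage (superkingdom … genus) per taxon id."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.name is None:
            self.frame.index.name = "taxon"
        _check_unique(self.frame.index, "taxon")
        missing = [r for r in LINEAGE_RANKS if r not in self.frame.columns]
        if missing:
            raise ValueError(f"lineage table missing rank column(s): {missing}")
        self.frame = self.frame[list(LINEAGE_RANKS)]

    @property
    def taxa(self) -> list[str]:
        return list(self.frame.index)

    def ancestor(self, taxon: str, rank: str) -> str:
        """Ancestor label of ``taxon`` at ``rank``; '' if unannotated."""
        if rank not in LINEAGE_RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {LINEAGE_RANKS}")
        value = self.frame.at[taxon, rank]
        return "" if pd.isna(value) else str(value)

    def matching_taxa(self, label: str) -> list[str]:
        """Taxon ids whose lineage (any rank, or the id itself) contains ``label``.

        The special label ``"root"`` matches every taxon.
        """
        if label == "root":
            return self.taxa
        mask = self.frame.index == label
        for rank in LINEAGE_RANKS:
            mask = mask | (self.frame[rank] == label).to_numpy()
        return list(self.frame.index[mask])


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[_MISSING]
    )
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"{path}: table is empty")
    return df


def _to_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        try:
            # numpy's parser is correctly rounded (pd.to_numeric is not)
            out[col] = df[col].astype(float)
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0]
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r}, row {row}"
            ) from None
    return pd.DataFrame(out, index=df.index)


def read_env_table(path: str | Path) -> EnvTable:
    """Read a sample × environment TSV (first column ``sample_id``)."""
    df = _read_tsv(path)
    first = df.columns[0]
    dupes = df[first][df[first].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate sample_id {dupes.iloc[0]!r}")
    df = df.set_index(first)
    df.index.name = "sample_id"
    meta = df[[c for c in ENV_METADATA if c in df.columns]].copy()
    if "depth" in meta.columns:
        meta["depth"] = pd.to_numeric(meta["depth"])
    env = _to_numeric(df.drop(columns=[c for c in ENV_METADATA if c in df.columns]), path)
    return EnvTable(pd.concat([meta, env], axis=1))


def write_env_table(table: EnvTable, path: str | Path) -> None:
    env_cols = sorted(table.env.columns)
    out = table.frame[list(ENV_METADATA) + env_cols].sort_index()
    out.to_csv(path, sep="\t", na_rep=_MISSING)


def read_abundance_table(path: str | Path, feature_kind: str) -> AbundanceMatrix:
    """Read a sample × feature TSV of counts; resulting state is ``raw_counts``."""
    df = _read_tsv(path)
    first = df.columns[0]
    dupes = df[first][df[first].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate sample_id {dupes.iloc[0]!r}")
    df = df.set_index(first)
    df.index.name = "sample_id"
    values = _to_numeric(df, path)
    return AbundanceMatrix(values, feature_kind=feature_kind, state="raw_counts")


def write_abundance_table(matrix: AbundanceMatrix, path: str | Path) -> None:
    out = matrix.frame.sort_index()[sorted(matrix.frame.columns)]
    out.to_csv(path, sep="\t", na_rep=_MISSING)


def read_module_map(path: str | Path) -> ModuleMap:
    """Read a two-column (KO, module) TSV, one membership pair per line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValueError(f"{path}: module map file is empty")
    return ModuleMap.from_pairs(pairs)


def write_module_map(mmap: ModuleMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for module in sorted(mmap.module_members):
            for ko in mmap.module_members[module]:
                fh.write(f"{ko}\t{module}\n")


def read_lineage_table(path: str | Path) -> LineageTable:
    """Read a lineage TSV: taxon id plus one column per rank."""
    df = _read_tsv(path)
    first = df.columns[0]
    dupes = df[first][df[first].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate taxon {dupes.iloc[0]!r}")
    df = df.set_index(first)
    df.index.name = "taxon"
    return LineageTable(df)


def write_lineage_table(table: LineageTable, path: str | Path) -> None:
    table.frame.sort_index().to_csv(path, sep="\t", na_rep=_MISSING)
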