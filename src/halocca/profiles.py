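"""From annotation counts to analysis matrices.

Metagenome read counts scale with sequencing depth and with community genome
size: a community of large-genomed cells yields more reads per cell.  Dividing
per-sample counts by the number of genome equivalents (total base pairs /
average genome size) converts counts into per-genome abundances that are
comparable across samples.  The remaining operations reshape annotation-level
counts into the matrices the ordination and group-comparison steps consume:
size-fraction merging, taxonomic collapsing, KO → KEGG-module profiling and
taxon-stratified functional matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import LINEAGE_RANKS, AbundanceMatrix, LineageTable, ModuleMap

__all__ = [
    "GenomeEquivalents",
    "ANNOTATION_COLUMNS",
    "genome_equivalents_from_bp",
    "normalize_by_genome_equivalents",
    "merge_size_fractions",
    "collapse_taxonomy",
    "module_profile",
    "stratify_by_taxon",
    "relative_abundance",
    "read_genome_equivalents",
    "write_genome_equivalents",
    "read_annotation_table",
    "write_annotation_table",
]

#: Column order of the joint phylogenetic × functional annotation table.
ANNOTATION_COLUMNS = ("sample_id", "taxon", "KO", "count")


@dataclass
class GenomeEquivalents:
    """Per-sample genome equivalents (estimated number of genomes sampled)."""

    values: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = "sample_id"
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id {dup!r} in genome equivalents")
        if not np.isfinite(self.values.to_numpy()).all() or (self.values <= 0).any():
            bad = self.values.index[~(self.values > 0)][0]
            raise ValueError(f"non-positive genome equivalents for sample {bad!r}")

    def __getitem__(self, sample: str) -> float:
        return float(self.values[sample])


def genome_equivalents_from_bp(total_bp, avg_genome_size):
    """Genome equivalents = total sequenced base pairs / average genome size.

    Accepts scalars or aligned pandas Series (per sample).
    """
    total = np.asarray(total_bp, dtype=float)
    avg = np.asarray(avg_genome_size, dtype=float)
    if (total <= 0).any() or (avg <= 0).any():
        raise ValueError("total_bp and avg_genome_size must be positive")
    ge = total / avg
    if isinstance(total_bp, pd.Series):
        return GenomeEquivalents(pd.Series(ge, index=total_bp.index))
    return float(ge)


def normalize_by_genome_equivalents(
    matrix: AbundanceMatrix, ge: GenomeEquivalents
) -> AbundanceMatrix:
    """Divide each sample's row of raw counts by its genome equivalents."""
    if matrix.state != "raw_counts":
        raise ValueError(f"expected raw_counts input, got state {matrix.state!r}")
    missing = [s for s in matrix.samples if s not in ge.values.index]
    if missing:
        raise KeyError(f"no genome-equivalent entry for sample {missing[0]!r}")
    divisor = ge.values.reindex(matrix.frame.index)
    out = matrix.frame.div(divisor, axis=0)
    return AbundanceMatrix(out, matrix.feature_kind, "genome_equivalent_normalized")


def merge_size_fractions(
    matrices: Iterable[AbundanceMatrix],
    sample_keys: Mapping[str, tuple[str, float]],
) -> AbundanceMatrix:
    """Sum raw counts across size fractions sharing a (station, depth) key.

    ``sample_keys`` maps every input sample id to its (station, depth); merged
    sample ids are the deterministic ``"{station}_{depth:g}"``.  Merging happens
    on raw counts, before any normalization.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to merge")
    kinds = {m.feature_kind for m in matrices}
    if len(kinds) != 1:
        raise ValueError(f"mixed feature kinds: {sorted(kinds)}")
    states = {m.state for m in matrices}
    if states != {"raw_counts"}:
        raise ValueError(f"size fractions must be raw counts, got states {sorted(states)}")
    columns = set(matrices[0].frame.columns)
    for m in matrices[1:]:
        if set(m.frame.columns) != columns:
            raise ValueError("matrices do not share feature columns")
    cols = sorted(columns)
    stacked = pd.concat([m.frame[cols] for m in matrices], axis=0)
    missing = [s for s in stacked.index if s not in sample_keys]
    if missing:
        raise KeyError(f"no (station, depth) key for sample {missing[0]!r}")
    merged_ids = [
        f"{sample_keys[s][0]}_{sample_keys[s][1]:g}" for s in stacked.index
    ]
    out = stacked.groupby(pd.Index(merged_ids, name="sample_id")).sum().sort_index()
    return AbundanceMatrix(out, matrices[0].feature_kind, "raw_counts")


def collapse_taxonomy(
    matrix: AbundanceMatrix,
    lineage: LineageTable,
    rank: str,
    top: int | None = None,
) -> AbundanceMatrix:
    """Sum taxon columns over their ancestor at ``rank``.

    Features missing from the lineage table, or unannotated at ``rank``, are
    pooled into an explicit ``"unclassified"`` column so that row sums are
    conserved exactly.  With ``top`` set, only the ``top`` most abundant groups
    (by total) are kept and the remainder pooled into ``"Other"``.
    """
    if rank not in LINEAGE_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {LINEAGE_RANKS}")
    if matrix.feature_kind != "taxon":
        raise ValueError("collapse_taxonomy requires a taxon matrix")
    groups = []
    for taxon in matrix.frame.columns:
        if taxon in lineage.frame.index:
            anc = lineage.ancestor(taxon, rank)
            groups.append(anc if anc else "unclassified")
        else:
            groups.append("unclassified")
    out = matrix.frame.T.groupby(pd.Index(groups, name=rank)).sum().T
    if top is not None and out.shape[1] > top:
        totals = out.sum(axis=0).sort_values(ascending=False, kind="stable")
        keep = list(totals.index[:top])
        rest = [c for c in out.columns if c not in keep]
        pooled = out[rest].sum(axis=1)
        out = out[keep]
        out["Other"] = pooled
    out = out[sorted(out.columns)]
    return AbundanceMatrix(out, "taxon", matrix.state)


def module_profile(ko_matrix: AbundanceMatrix, mmap: ModuleMap) -> AbundanceMatrix:
    """KEGG-module abundance: mean over member KOs of their abundances.

    The mean (rather than the sum) removes module-size bias — a ten-KO module
    is not counted as ten times a one-KO module.  KOs absent from the matrix
    contribute zero.  Raises if the map and the matrix share no KO at all.
    """
    if ko_matrix.feature_kind != "ko":
        raise ValueError("module_profile requires a KO matrix")
    if ko_matrix.state == "proportions":
        raise ValueError("module_profile does not accept a proportions matrix")
    present = set(ko_matrix.frame.columns)
    if not any(ko in present for ko in mmap.ko_to_modules):
        raise ValueError("no KO of the module map occurs in the matrix")
    out = {}
    for module in mmap.modules:
        members = mmap.members(module)
        cols = [ko for ko in members if ko in present]
        if cols:
            total = ko_matrix.frame[cols].sum(axis=1)
        else:
            total = pd.Series(0.0, index=ko_matrix.frame.index)
        out[module] = total / len(members)
    frame = pd.DataFrame(out, index=ko_matrix.frame.index)
    return AbundanceMatrix(frame, "module", ko_matrix.state)


def stratify_by_taxon(
    annotations: pd.DataFrame,
    lineage: LineageTable,
    taxon: str,
    mmap: ModuleMap,
) -> AbundanceMatrix:
    """Module profile restricted to reads whose lineage contains ``taxon``.

    ``annotations`` is the joint table with columns (sample_id, taxon, KO,
    count).  Rows are filtered to taxa whose lineage includes ``taxon`` (the
    label ``"root"`` keeps everything), summed into a KO matrix over ALL
    samples of the table, and profiled into modules.  A warning is issued when
    the stratum is empty in at least half the samples; an error when it is
    empty everywhere.
    """
    _validate_annotations(annotations)
    matching = set(lineage.matching_taxa(taxon))
    if not matching:
        raise ValueError(f"taxon {taxon!r} not found at any rank of the lineage table")
    samples = sorted(annotations["sample_id"].unique())
    sub = annotations[annotations["taxon"].isin(matching)]
    ko_frame = (
        sub.pivot_table(index="sample_id", columns="KO", values="count", aggfunc="sum")
        .reindex(samples)
        .fillna(0.0)
    )
    if ko_frame.shape[1] == 0 or not (ko_frame.to_numpy() > 0).any():
        raise ValueError(f"taxon {taxon!r} has zero reads in every sample")
    n_empty = int((ko_frame.sum(axis=1) == 0).sum())
    if n_empty * 2 >= len(samples):
        warnings.warn(
            f"taxon {taxon!r} has zero reads in {n_empty}/{len(samples)} samples",
            stacklevel=2,
        )
    ko_matrix = AbundanceMatrix(ko_frame, "ko", "raw_counts")
    return module_profile(ko_matrix, mmap)


def relative_abundance(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Per-sample proportions: each row divided by its sum."""
    sums = matrix.frame.sum(axis=1)
    zero = sums.index[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero row for sample {zero[0]!r}")
    out = matrix.frame.div(sums, axis=0)
    return AbundanceMatrix(out, matrix.feature_kind, "proportions")


# ---------------------------------------------------------------------------
# IO helpers for the profile-stage tables
# ---------------------------------------------------------------------------


def _validate_annotations(annotations: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table missing column(s): {missing}")
    if (annotations["count"] < 0).any():
        raise ValueError("annotation table contains negative counts")
    keys = annotations[["sample_id", "taxon", "KO"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0]
        raise ValueError(
            f"duplicate annotation key ({dup['sample_id']}, {dup['taxon']}, {dup['KO']})"
        )


def read_genome_equivalents(path) -> GenomeEquivalents:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenomeEquivalents(df.iloc[:, 0])


def write_genome_equivalents(ge: GenomeEquivalents, path) -> None:
    out = ge.values.sort_index()
    out.name = "genome_equivalents"
    out.to_csv(path, sep="\t")


def read_annotation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "taxon": str, "KO": str})
    df["count"] = pd.to_numeric(df["count"])
    _validate_annotations(df)
    return df


def write_annotation_table(annotations: pd.DataFrame, path) -> None:
    _validate_annotations(annotations)
    out = annotations.sort_values(["sample_id", "taxon", "KO"], kind="stable")
    out.to_csv(path, sep="\t", index=False)
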