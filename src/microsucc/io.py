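"""Readers and writers for the tables and sequence files the pipeline touches.

All tables are plain tab-separated text with one header row; the first
column holds the row identifier.  Sequences travel as uncompressed FASTA.
Count tables are samples x taxa with integer cells; relative abundances are
rejected here and computed explicitly downstream, so the provenance of any
normalisation stays in one place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, SchemaError

logger = logging.getLogger(__name__)

SUBSTRATES = ("polyp", "tube")
INOCULA = ("bL", "bJ", "bA")
#: recolonization sampling days; the inoculum itself is timepoint "inoculum"
POST_TIMEPOINTS = (2, 7, 14, 28)
INOCULUM_TIMEPOINT = "inoculum"

META_COLUMNS = ("substrate", "inoculum", "timepoint", "replicate")

DNA_ALPHABET = frozenset("ACGTN")


def _normalize_timepoint(value) -> object:
    """Coerce a timepoint cell to the canonical representation:
    the string ``"inoculum"`` or one of the integers 2, 7, 14, 28."""
    if isinstance(value, str):
        v = value.strip()
        if v == INOCULUM_TIMEPOINT:
            return INOCULUM_TIMEPOINT
        try:
            value = int(v)
        except ValueError as exc:
            raise SchemaError(f"unrecognised timepoint {value!r}") from exc
    value = int(value)
    if value not in POST_TIMEPOINTS:
        raise SchemaError(
            f"timepoint {value} not in {POST_TIMEPOINTS} and not 'inoculum'"
        )
    return value


@dataclass
class CommunityTable:
    """Sample x taxon count matrix with per-sample experimental metadata.

    ``counts`` rows are samples, columns are taxa (ASVs); ``meta`` is indexed
    by sample id and carries substrate, inoculum, timepoint and replicate.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    taxonomy: pd.Series | None = None

    def validate(self) -> "CommunityTable":
        counts, meta = self.counts, self.meta
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].tolist()
            raise SchemaError(f"duplicate sample ids: {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate taxon ids: {dupes}")
        missing = [s for s in counts.index if s not in meta.index]
        if missing:
            raise SchemaError(f"samples missing from metadata: {missing}")
        for col in META_COLUMNS:
            if col not in meta.columns:
                raise SchemaError(f"metadata lacks required column {col!r}")
        bad_sub = set(meta["substrate"]) - set(SUBSTRATES)
        if bad_sub:
            raise SchemaError(f"unknown substrate values: {sorted(bad_sub)}")
        bad_inoc = set(meta["inoculum"]) - set(INOCULA)
        if bad_inoc:
            raise SchemaError(f"unknown inoculum values: {sorted(bad_inoc)}")
        self.meta = meta = meta.assign(
            timepoint=[_normalize_timepoint(t) for t in meta["timepoint"]]
        )
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)):
                raise ParseError("counts contain non-finite values")
            if not np.all(arr == np.floor(arr)):
                i, j = np.argwhere(arr != np.floor(arr))[0]
                raise ParseError(
                    "non-integer count at sample "
                    f"{counts.index[i]!r}, taxon {counts.columns[j]!r}"
                )
            self.counts = counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative count at sample {counts.index[i]!r}, "
                f"taxon {counts.columns[j]!r}"
            )
        zero = counts.index[arr.sum(axis=1) == 0].tolist()
        if zero:
            raise SchemaError(f"all-zero sample rows: {zero}")
        return self

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, sample_ids: Sequence[str]) -> "CommunityTable":
        ids = list(sample_ids)
        return CommunityTable(
            counts=self.counts.loc[ids],
            meta=self.meta.loc[ids],
            taxonomy=self.taxonomy,
        )

    def subset_substrate(
        self, substrate: str, keep_inoculum: bool = True
    ) -> "CommunityTable":
        """Restrict to one substrate.  Inoculum samples describe the shared
        source communities: by default they are kept regardless of their
        nominal substrate; with ``keep_inoculum=False`` they are dropped."""
        m = self.meta.loc[self.counts.index]
        is_inoc = m["timepoint"] == INOCULUM_TIMEPOINT
        keep = (m["substrate"] == substrate) & ~is_inoc
        if keep_inoculum:
            keep |= is_inoc
        return self.subset(list(self.counts.index[keep.to_numpy()]))


@dataclass
class PathwayPresence:
    """Binary taxon/genome x pathway matrix plus a pathway -> subsystem map.

    Rows are the units that carry genomes (genome ids or cluster ids);
    pathways with no subsystem annotation map to ``"unassigned"``.
    """

    presence: pd.DataFrame
    subsystem_of: dict[str, str] = field(default_factory=dict)

    def validate(self) -> "PathwayPresence":
        arr = self.presence.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise ParseError(
                "non-binary presence cell at "
                f"{self.presence.index[bad[0]]!r} / "
                f"{self.presence.columns[bad[1]]!r}"
            )
        for p in self.presence.columns:
            if p not in self.subsystem_of:
                logger.warning("pathway %s has no subsystem; set to 'unassigned'", p)
                self.subsystem_of[p] = "unassigned"
        return self

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.presence.columns)


# ---------------------------------------------------------------------------
# community tables


def read_community_table(
    counts_path: str | Path, meta_path: str | Path
) -> CommunityTable:
    """Read a samples x taxa count TSV plus its sample metadata TSV.

    Row/column order is preserved from file.  Raises :class:`SchemaError`
    when a sample lacks metadata and :class:`ParseError` on negative or
    non-integer counts.
    """
    try:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    except ValueError as exc:
        raise ParseError(f"cannot parse count table {counts_path}: {exc}") from exc
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    if "timepoint" not in meta.columns:
        raise SchemaError("metadata lacks required column 'timepoint'")
    meta["timepoint"] = [_normalize_timepoint(t) for t in meta["timepoint"]]
    if "replicate" in meta.columns:
        meta["replicate"] = pd.to_numeric(meta["replicate"], errors="coerce").astype(
            "Int64"
        )
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    meta.index = meta.index.astype(str)
    counts.index.name = counts.columns.name = meta.index.name = None
    return CommunityTable(counts=counts, meta=meta).validate()


def write_community_table(
    table: CommunityTable, counts_path: str | Path, meta_path: str | Path
) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
    table.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into ``[(id, sequence), ...]``, order preserved.

    Sequences are uppercased and U is mapped to T; the alphabet must then be
    a subset of ``{A,C,G,T,N}``.  Duplicate ids and empty sequences raise
    :class:`ParseError`.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ParseError(f"empty sequence for FASTA id {rec.id!r}")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ParseError(
                f"record {rec.id!r} contains non-DNA symbols {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# pathway presence


def read_pathway_presence(
    path: str | Path, subsystem_path: str | Path | None = None
) -> PathwayPresence:
    """Read a binary taxon x pathway TSV and an optional two-column
    (pathway, subsystem) TSV; unmapped pathways become ``"unassigned"``."""
    presence = pd.read_csv(path, sep="\t", index_col=0)
    presence.index = presence.index.astype(str)
    presence.columns = presence.columns.astype(str)
    presence.index.name = presence.columns.name = None
    arr = presence.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.isin(arr, (0, 1)).all():
        raise ParseError(f"pathway presence table {path} has non-binary cells")
    presence = presence.astype(np.int8)
    subsystem_of: dict[str, str] = {}
    if subsystem_path is not None:
        sub = pd.read_csv(subsystem_path, sep="\t", index_col=0, dtype=str)
        if sub.shape[1] < 1:
            raise ParseError(f"subsystem map {subsystem_path} needs two columns")
        subsystem_of = dict(zip(sub.index.astype(str), sub.iloc[:, 0]))
    return PathwayPresence(presence=presence, subsystem_of=subsystem_of).validate()


def write_pathway_presence(
    pp: PathwayPresence, path: str | Path, subsystem_path: str | Path | None = None
) -> None:
    pp.presence.to_csv(path, sep="\t", index_label="taxon_id")
    if subsystem_path is not None:
        pd.Series(pp.subsystem_of, name="subsystem").rename_axis("pathway").to_csv(
            subsystem_path, sep="\t"
        )


# ---------------------------------------------------------------------------
# schema report (CLI `validate` backend)


def schema_report(counts_path: str | Path, meta_path: str | Path) -> tuple[bool, str]:
    """Validate a table pair and return (ok, human-readable report)."""
    try:
        table = read_community_table(counts_path, meta_path)
    except (SchemaError, ParseError) as exc:
        return False, f"INVALID: {exc}"
    m = table.meta.loc[table.counts.index]
    lines = [
        "VALID",
        f"samples: {len(table.sample_ids)}",
        f"taxa: {len(table.taxa_ids)}",
        f"substrates: {sorted(set(m['substrate']))}",
        f"inocula: {sorted(set(m['inoculum']))}",
        f"timepoints: {sorted(map(str, set(m['timepoint'])))}",
        f"total counts: {int(table.counts.to_numpy().sum())}",
    ]
    return True, "\n".join(lines)
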