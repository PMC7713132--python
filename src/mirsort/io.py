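"""File formats, library metadata, normalization, and exact quantification.

Libraries are described by a TSV manifest (one row per sequencing library:
stage, pulldown, replicate, genome-mapped total, spike-in counts).  Read
stacks hold collapsed reads placed on precursors at exact-match offsets
(0-based, half-open spans internally; GFF3 is emitted 1-based inclusive).

Two normalizations are provided: reads-per-million genome-mapped reads
(RPM) and division by the mean of the four synthetic spike-in miRNAs, the
latter used for knockdown comparisons where global composition shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .sequence import clean_rna

logger = logging.getLogger("mirsort")

STAGES = ("planula", "primary_polyp", "adult")
PULLDOWNS = (
    "AGO1_IP",
    "AGO2_IP",
    "IgG_IP",
    "input",
    "KD_AGO1",
    "KD_AGO2",
    "KD_control",
    "oxidized",
    "non_oxidized",
)

#: The four synthetic spike-in miRNAs added before library prep; two are
#: 2'-O-methylated at their 3' ends and two are not.
DEFAULT_SPIKEIN_IDS = (
    "mmu-miR-125a-5p",
    "mmu-miR-148a-3p",
    "cel-lin-4-5p",
    "hsa-miR-659-5p",
)

N_SPIKEINS = 4

MANIFEST_COLUMNS = ("library_id", "stage", "pulldown", "replicate", "genome_mapped_total")


@dataclass
class SmallRNALibrary:
    """Metadata for one sequencing library, including normalization denominators."""

    library_id: str
    stage: str
    pulldown: str
    replicate: int
    genome_mapped_total: int
    spikein_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"{self.library_id}: unknown stage {self.stage!r}")
        if self.pulldown not in PULLDOWNS:
            raise ValidationError(f"{self.library_id}: unknown pulldown {self.pulldown!r}")
        if self.replicate < 1:
            raise ValidationError(f"{self.library_id}: replicate must be >= 1")
        if self.genome_mapped_total <= 0:
            raise ValidationError(f"{self.library_id}: genome_mapped_total must be > 0")
        if self.spikein_counts and len(self.spikein_counts) != N_SPIKEINS:
            raise ValidationError(
                f"{self.library_id}: expected {N_SPIKEINS} spike-in species, "
                f"got {len(self.spikein_counts)}"
            )
        if any(c < 0 for c in self.spikein_counts.values()):
            raise ValidationError(f"{self.library_id}: spike-in counts must be >= 0")

    @property
    def spikein_mean(self) -> float:
        if len(self.spikein_counts) != N_SPIKEINS:
            raise ValidationError(
                f"{self.library_id}: all {N_SPIKEINS} spike-in counts are required"
            )
        return float(np.mean(list(self.spikein_counts.values())))


STACK_COLUMNS = ["precursor_id", "library_id", "read_seq", "offset", "count", "multimap"]


@dataclass
class ReadStack:
    """Collapsed reads placed on one precursor across libraries.

    ``records`` columns: library_id, read_seq, offset (0-based start on the
    precursor), count, multimap (True if the read matched more than one
    precursor locus).
    """

    precursor_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in STACK_COLUMNS[1:] if c not in self.records.columns]
        if "multimap" in missing:
            self.records = self.records.assign(multimap=False)
            missing.remove("multimap")
        if missing:
            raise ValidationError(
                f"stack {self.precursor_id}: missing record columns {missing}"
            )
        if (self.records["count"] <= 0).any():
            raise ValidationError(f"stack {self.precursor_id}: counts must be positive")

    def validate_against(self, precursor_seq: str) -> None:
        seq = clean_rna(precursor_seq)
        for row in self.records.itertuples():
            off = int(row.offset)
            if seq[off : off + len(row.read_seq)] != row.read_seq:
                raise ValidationError(
                    f"stack {self.precursor_id}: read {row.read_seq} is not the "
                    f"precursor substring at offset {off}"
                )

    def counts_in_library(self, library_ids: Iterable[str]) -> pd.DataFrame:
        ids = set(library_ids)
        return self.records[self.records["library_id"].isin(ids)]

    def span_records(
        self, span: tuple[int, int], library_ids: Iterable[str] | None = None
    ) -> pd.DataFrame:
        """Records assigned to a precursor span by maximal overlap."""
        df = (
            self.records
            if library_ids is None
            else self.counts_in_library(library_ids)
        )
        if df.empty:
            return df
        lo, hi = span
        starts = df["offset"].to_numpy()
        ends = starts + df["read_seq"].str.len().to_numpy()
        overlap = np.minimum(ends, hi) - np.maximum(starts, lo)
        lengths = ends - starts
        return df[overlap >= lengths / 2.0]

    def total(self, library_ids: Iterable[str] | None = None) -> int:
        df = self.records if library_ids is None else self.counts_in_library(library_ids)
        return int(df["count"].sum())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = clean_rna(str(rec.seq), name=rec.id)
    if not seqs:
        raise ValidationError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(clean_rna(s, name=k)), id=k, description="")
        for k, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> list[SmallRNALibrary]:
    """Read a library manifest TSV; spike-in counts come from columns named
    ``spikein_<id>``."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: manifest is missing column(s) {missing}")
    if df["library_id"].duplicated().any():
        dups = df.loc[df["library_id"].duplicated(), "library_id"].tolist()
        raise ValidationError(f"{path}: duplicate library_id(s) {dups}")
    spike_cols = [c for c in df.columns if c.startswith("spikein_")]
    libs = []
    for i, row in df.iterrows():
        spikes = {
            c[len("spikein_") :]: int(row[c])
            for c in spike_cols
            if not pd.isna(row[c])
        }
        try:
            libs.append(
                SmallRNALibrary(
                    library_id=str(row["library_id"]),
                    stage=str(row["stage"]),
                    pulldown=str(row["pulldown"]),
                    replicate=int(row["replicate"]),
                    genome_mapped_total=int(row["genome_mapped_total"]),
                    spikein_counts=spikes,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}: line {i + 2}: {err}") from err
    return libs


def write_manifest(libraries: Iterable[SmallRNALibrary], path: str | Path) -> None:
    rows = []
    for lib in libraries:
        row = {
            "library_id": lib.library_id,
            "stage": lib.stage,
            "pulldown": lib.pulldown,
            "replicate": lib.replicate,
            "genome_mapped_total": lib.genome_mapped_total,
        }
        for sid, c in lib.spikein_counts.items():
            row[f"spikein_{sid}"] = c
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Read stacks
# ---------------------------------------------------------------------------

def write_stacks(stacks: Mapping[str, ReadStack], path: str | Path) -> None:
    frames = []
    for pid in sorted(stacks):
        df = stacks[pid].records.copy()
        df.insert(0, "precursor_id", pid)
        frames.append(df[STACK_COLUMNS])
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=STACK_COLUMNS)
    )
    out.to_csv(path, sep="\t", index=False)


def read_stacks(path: str | Path) -> dict[str, ReadStack]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in STACK_COLUMNS if c not in df.columns and c != "multimap"]
    if missing:
        raise ValidationError(f"{path}: stack file is missing column(s) {missing}")
    if "multimap" not in df.columns:
        df["multimap"] = False
    stacks = {}
    for pid, sub in df.groupby("precursor_id", sort=True):
        stacks[str(pid)] = ReadStack(
            precursor_id=str(pid),
            records=sub.drop(columns="precursor_id").reset_index(drop=True),
        )
    return stacks


def quantify_reads(
    reads_by_library: Mapping[str, Iterable[tuple[str, int]]],
    precursors: Mapping[str, str],
) -> dict[str, ReadStack]:
    """Assign collapsed reads to precursors by exact substring match.

    A read is placed at every matching position of every precursor (and
    flagged multimap when it matches more than one locus); reads matching
    nowhere are dropped with a logged tally.
    """
    if not precursors:
        raise ValidationError("quantify_reads: empty precursor set")
    pre = {pid: clean_rna(s, name=pid) for pid, s in precursors.items()}
    rows: dict[str, list] = {pid: [] for pid in pre}
    dropped = 0
    for lib_id, reads in reads_by_library.items():
        for seq, count in reads:
            s = clean_rna(seq)
            hits = []
            for pid, pseq in pre.items():
                start = pseq.find(s)
                while start != -1:
                    hits.append((pid, start))
                    start = pseq.find(s, start + 1)
            if not hits:
                dropped += int(count)
                continue
            multi = len(hits) > 1
            for pid, off in hits:
                rows[pid].append((lib_id, s, off, int(count), multi))
    if dropped:
        logger.info("quantify_reads: dropped %d read counts matching no precursor", dropped)
    stacks = {}
    for pid, recs in rows.items():
        if recs:
            stacks[pid] = ReadStack(
                precursor_id=pid,
                records=pd.DataFrame(recs, columns=STACK_COLUMNS[1:]),
            )
    return stacks


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_rpm(counts, library: SmallRNALibrary):
    """Reads-per-million genome-mapped reads: count × 1e6 / mapped total."""
    if library.genome_mapped_total <= 0:
        raise ValidationError(f"{library.library_id}: genome_mapped_total must be > 0")
    scale = 1e6 / library.genome_mapped_total
    if np.isscalar(counts):
        return float(counts) * scale
    return np.asarray(counts, dtype=float) * scale


def normalize_spikein(counts, library: SmallRNALibrary):
    """Counts divided by the mean of the library's four spike-in counts."""
    mean = library.spikein_mean
    if mean <= 0:
        raise ValidationError(f"{library.library_id}: spike-in mean must be > 0")
    if np.isscalar(counts):
        return float(counts) / mean
    return np.asarray(counts, dtype=float) / mean


def quantify_sequence_set(
    sequences: Iterable[str],
    stacks: Mapping[str, ReadStack],
    libraries: Iterable[SmallRNALibrary],
    rrna_set: Iterable[str] | None = None,
) -> pd.DataFrame:
    """RPM-normalized exact-match counts of a query sequence list per library.

    Queries matching an rRNA (exactly, or as substring of one) are removed
    first; remaining queries are summed over exact read matches in each
    library's stacks and RPM-normalized.  Used to quantify externally
    annotated endo-siRNA sequence lists in the IP libraries.
    """
    libs = list(libraries)
    queries = [clean_rna(s) for s in sequences]
    if not queries:
        raise ValidationError("quantify_sequence_set: empty sequence list")
    if rrna_set:
        rrnas = [clean_rna(r) for r in rrna_set]
        kept = [q for q in queries if not any(q == r or q in r for r in rrnas)]
        n_removed = len(queries) - len(kept)
        if n_removed:
            logger.info("quantify_sequence_set: removed %d rRNA-matching queries", n_removed)
        queries = kept
    table = pd.DataFrame(
        0.0, index=pd.Index(queries, name="sequence"), columns=[l.library_id for l in libs]
    )
    for stack in stacks.values():
        for row in stack.records.itertuples():
            if row.read_seq in table.index and row.library_id in table.columns:
                table.loc[row.read_seq, row.library_id] += row.count
    for lib in libs:
        table[lib.library_id] = normalize_rpm(table[lib.library_id].to_numpy(), lib)
    return table


# ---------------------------------------------------------------------------
# GFF3 (1-based inclusive coordinates on disk)
# ---------------------------------------------------------------------------

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_gff3(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS, dtype={"seqid": str}
    )
    if df.empty:
        return df
    bad = df[(df["start"] < 1) | (df["end"] < df["start"])]
    if not bad.empty:
        raise ValidationError(f"{path}: malformed GFF3 interval at data line {bad.index[0] + 1}")
    return df


def write_gff3(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        df[GFF3_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def gff3_attr(attributes: str, key: str) -> str | None:
    for part in str(attributes).split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


# ---------------------------------------------------------------------------
# Run metadata
# ---------------------------------------------------------------------------

def write_run_metadata(path: str | Path, metadata: Mapping) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(metadata), fh, sort_keys=True)


def read_run_metadata(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
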