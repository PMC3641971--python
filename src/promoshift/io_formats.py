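"""Readers and writers for the external formats the pipeline touches.

Coordinate convention
---------------------
BED input is 0-based half-open; *all* internal coordinates are 1-based
inclusive with the TSS at +1 and no position 0, so the core promoter
window -60..+40 spans exactly 100 bases and the extended window
-1000..-1 exactly 1000 bases.

Formats: MEME-minimal motif files (PSSMs), BED6 TSS tables, FASTA
promoter sequences, TSV expression matrices (log2 ratios vs. a common
reference sample), and GMT gene sets.
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
    "MotifClass",
    "PSSM",
    "TranscriptRecord",
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_pssm_set",
    "write_pssm_set",
    "read_tss_table",
    "write_tss_table",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_fasta",
    "write_fasta",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COLUMN_SUM_TOL = 1e-3


class MotifClass(str, Enum):
    ENHANCER = "enhancer"
    CORE_PROMOTER = "core_promoter"


class FormatError(ValueError):
    """A file violated its format or a container invariant."""


@dataclass(frozen=True)
class PSSM:
    """Position probability matrix over A,C,G,T with an identity and class.

    ``probs`` has shape (width, 4), columns ordered A,C,G,T; every row
    sums to 1 and all entries are non-negative.
    """

    motif_id: str
    motif_class: MotifClass
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise FormatError(
                f"motif {self.motif_id!r}: matrix must be (width>=1, 4), "
                f"got {probs.shape}"
            )
        if (probs < 0).any():
            raise FormatError(f"motif {self.motif_id!r}: negative probability")
        sums = probs.sum(axis=1)
        if np.abs(sums - 1.0).max() > _COLUMN_SUM_TOL:
            bad = int(np.abs(sums - 1.0).argmax()) + 1
            raise FormatError(
                f"motif {self.motif_id!r}: position {bad} probabilities sum to "
                f"{sums[bad - 1]:.6f}, not 1"
            )
        object.__setattr__(self, "probs", probs)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True)
class TranscriptRecord:
    """One TSS of one gene; the unit of all downstream analysis."""

    gene_id: str
    transcript_id: str
    seq_id: str
    tss_position: int  # 1-based first transcribed base
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.tss_position < 1:
            raise FormatError(
                f"{self.transcript_id}: tss_position must be >= 1, "
                f"got {self.tss_position}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"{self.transcript_id}: unknown strand {self.strand!r}"
            )


class ExpressionMatrix:
    """Transcripts x (time point, replicate) log2 ratios vs. the reference.

    Backed by a pandas DataFrame whose columns are a MultiIndex of
    (time_point, replicate); time points keep their file order and the
    replicate count is uniform.
    """

    def __init__(self, values: pd.DataFrame):
        if not isinstance(values.columns, pd.MultiIndex):
            raise FormatError("expression columns must be (time_point, replicate)")
        if values.isna().any().any():
            raise FormatError("expression matrix contains missing values")
        tps = list(dict.fromkeys(values.columns.get_level_values(0)))
        counts = {tp: sum(1 for c in values.columns if c[0] == tp) for tp in tps}
        if len(set(counts.values())) != 1:
            raise FormatError(f"ragged replicate counts: {counts}")
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise FormatError(f"duplicate transcript id {dup!r}")
        self.values = values
        self.time_points: list[str] = tps
        self.replicates: int = next(iter(counts.values()))

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_transcripts(self) -> int:
        return len(self.values)

    def replicate_means(self) -> pd.DataFrame:
        """Per-transcript mean log2 ratio per time point (replicates averaged)."""
        means = self.values.T.groupby(level=0).mean().T
        return means[self.time_points]

    def groups(self) -> list[np.ndarray]:
        """Replicate value arrays per time point, each (n_transcripts, reps)."""
        return [self.values.xs(tp, axis=1, level=0).to_numpy() for tp in self.time_points]

    def subset(self, transcript_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(transcript_ids)])


@dataclass
class GeneSetCollection:
    """Named sets of gene/transcript ids, with optional per-member sign tags."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    signs: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_pssm_set(path: str | Path, motif_class: MotifClass | str) -> list[PSSM]:
    """Parse a MEME-minimal motif file into validated PSSMs.

    Raises FormatError naming the motif and line on malformed matrices or
    columns whose probabilities sum more than 1e-3 away from 1.
    """
    motif_class = MotifClass(motif_class)
    lines = Path(path).read_text().splitlines()
    pssms: list[PSSM] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"line {i + 1}: MOTIF line without identifier")
            motif_id = parts[1]
            i += 1
            while i < n and not lines[i].strip().startswith("letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(
                        f"motif {motif_id!r}: missing letter-probability matrix"
                    )
                i += 1
            if i >= n:
                raise FormatError(
                    f"motif {motif_id!r}: missing letter-probability matrix"
                )
            header = lines[i].strip()
            m = re.search(r"w=\s*(\d+)", header)
            width = int(m.group(1)) if m else None
            i += 1
            rows: list[list[float]] = []
            while i < n:
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                try:
                    row = [float(x) for x in stripped.split()]
                except ValueError as exc:
                    raise FormatError(
                        f"motif {motif_id!r}, line {i + 1}: non-numeric matrix row"
                    ) from exc
                if len(row) != 4:
                    raise FormatError(
                        f"motif {motif_id!r}, line {i + 1}: expected 4 columns, "
                        f"got {len(row)}"
                    )
                rows.append(row)
                i += 1
            if width is not None and width != len(rows):
                raise FormatError(
                    f"motif {motif_id!r}: header says w={width} but "
                    f"{len(rows)} rows found"
                )
            pssms.append(PSSM(motif_id, motif_class, np.array(rows)))
        else:
            i += 1
    return pssms


def write_pssm_set(
    pssms: Iterable[PSSM],
    path: str | Path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    out = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    out.append("Background letter frequencies")
    out.append(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, background)))
    out.append("")
    for p in pssms:
        out.append(f"MOTIF {p.motif_id}")
        out.append(
            f"letter-probability matrix: alength= 4 w= {p.width} nsites= 1000000 E= 0"
        )
        for row in p.probs:
            out.append(" " + " ".join(f"{x:.9f}" for x in row))
        out.append("")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# BED6 TSS tables


def read_tss_table(path: str | Path) -> list[TranscriptRecord]:
    """Read a BED6 TSS table ('gene|transcript' names) into TranscriptRecords.

    The TSS is the interval start for '+' records and end-1 for '-'
    records (0-based half-open), then shifted to the internal 1-based
    convention.
    """
    records: list[TranscriptRecord] = []
    seen: set[tuple[str, str]] = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(f"line {ln}: expected 6 BED fields, got {len(fields)}")
        chrom, start, end, name, _score, strand = fields[:6]
        if strand not in ("+", "-"):
            raise FormatError(f"line {ln}: unknown strand symbol {strand!r}")
        if "|" not in name:
            raise FormatError(f"line {ln}: name must be 'gene|transcript', got {name!r}")
        gene_id, transcript_id = name.split("|", 1)
        key = (gene_id, transcript_id)
        if key in seen:
            raise FormatError(f"line {ln}: duplicate transcript id {name!r}")
        seen.add(key)
        start_i, end_i = int(start), int(end)
        tss0 = start_i if strand == "+" else end_i - 1
        records.append(
            TranscriptRecord(gene_id, transcript_id, chrom, tss0 + 1, strand)
        )
    return records


def write_tss_table(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    lines = []
    for r in records:
        tss0 = r.tss_position - 1
        lines.append(
            "\t".join(
                [r.seq_id, str(tss0), str(tss0 + 1), f"{r.gene_id}|{r.transcript_id}",
                 "0", r.strand]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression TSV


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (transcript_id, then <tp>_r<rep> columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    cols = []
    for c in df.columns:
        m = re.fullmatch(r"(.+)_r(\d+)", c)
        if not m:
            raise FormatError(f"column {c!r}: expected '<timepoint>_r<replicate>'")
        cols.append((m.group(1), int(m.group(2))))
    bad = df.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        rows, colixs = np.where(bad.isna())
        raise FormatError(
            f"non-numeric expression value at row {df.index[rows[0]]!r}, "
            f"column {df.columns[colixs[0]]!r}"
        )
    df = bad.astype(float)
    df.columns = pd.MultiIndex.from_tuples(cols, names=["time_point", "replicate"])
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.columns = [f"{tp}_r{rep}" for tp, rep in df.columns]
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read GMT (set name, description, then members, tab-separated).

    A trailing '+'/'-' on a member (e.g. 'gene1+') is stripped into a
    per-member induced/repressed sign tag.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    signs: dict[str, dict[str, int]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"line {ln}: GMT set {fields[0]!r} is empty")
        name, desc, members = fields[0], fields[1], fields[2:]
        if name in sets:
            raise FormatError(f"line {ln}: duplicate set name {name!r}")
        clean: set[str] = set()
        tagged: dict[str, int] = {}
        for m in members:
            if m and m[-1] in "+-":
                tagged[m[:-1]] = 1 if m[-1] == "+" else -1
                m = m[:-1]
            if m:
                clean.add(m)
        if not clean:
            raise FormatError(f"line {ln}: GMT set {name!r} is empty")
        sets[name] = clean
        descriptions[name] = desc
        if tagged:
            signs[name] = tagged
    return GeneSetCollection(sets, descriptions, signs)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in collection:
        desc = collection.descriptions.get(name, ".")
        sign = collection.signs.get(name, {})
        members = [
            m + ("+" if sign.get(m, 0) > 0 else "-" if sign.get(m, 0) < 0 else "")
            for m in sorted(collection[name])
        ]
        lines.append("\t".join([name, desc] + members))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA


_VALID_SEQ = re.compile(r"^[ACGTN]*$")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> upper-cased sequence mapping (ACGTN only)."""
    from Bio import SeqIO

    table: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not _VALID_SEQ.fullmatch(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise FormatError(f"record {rec.id!r}: invalid characters {bad}")
        if rec.id in table:
            raise FormatError(f"duplicate FASTA record id {rec.id!r}")
        table[rec.id] = seq
    return table


def write_fasta(seqs: Mapping[str, str], path: str | Path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
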