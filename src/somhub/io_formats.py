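"""Readers/writers for the external formats the pipeline touches.

Formats handled: GCT 1.2 expression matrices, tab-separated sample
sheets and probe annotation tables, GMT gene-set collections, JASPAR
PFM motif files, FASTA promoter files, and tab-separated edge lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TIMEPOINTS: tuple[str, ...] = ("P1", "P7", "P14", "P30", "P60")
GENOTYPES: tuple[str, ...] = ("control", "ko")

DNA_ALPHABET = "ACGT"


class FormatError(ValueError):
    """A file does not follow its declared layout."""


class ValidationError(ValueError):
    """Structurally well-formed input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDescriptor:
    """One array/sample: genotype, developmental timepoint and replicate."""

    sample_id: str
    genotype: str
    timepoint: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"unknown genotype {self.genotype!r} (expected one of {GENOTYPES})"
            )
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"unknown timepoint {self.timepoint!r} (expected one of {TIMEPOINTS})"
            )
        if int(self.replicate) < 1:
            raise ValidationError("replicate must be a positive integer")


def validate_sample_sheet(samples: Sequence[SampleDescriptor]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in sample sheet")
    combos = [(s.genotype, s.timepoint, s.replicate) for s in samples]
    if len(set(combos)) != len(combos):
        raise ValidationError("duplicate (genotype, timepoint, replicate) combination")


@dataclass
class ExpressionMatrix:
    """Probes/genes x samples intensity grid with sample descriptors.

    ``data`` is indexed by row id (probe or gene symbol) with one column
    per sample, ordered as ``samples``.
    """

    data: pd.DataFrame
    samples: list[SampleDescriptor]
    descriptions: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate row id {dup!r}")
        if len(self.samples) != self.data.shape[1]:
            raise ValidationError(
                f"sample sheet length {len(self.samples)} != column count "
                f"{self.data.shape[1]}"
            )
        validate_sample_sheet(self.samples)
        expected = [s.sample_id for s in self.samples]
        if list(self.data.columns) != expected:
            raise ValidationError("column order does not match sample descriptors")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_rows(self, row_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.data.loc[list(row_ids)].copy(), list(self.samples),
            None if self.descriptions is None else self.descriptions.loc[list(row_ids)],
        )

    def subset_samples(
        self, genotype: str | None = None, timepoint: str | None = None
    ) -> "ExpressionMatrix":
        keep = [
            s
            for s in self.samples
            if (genotype is None or s.genotype == genotype)
            and (timepoint is None or s.timepoint == timepoint)
        ]
        cols = [s.sample_id for s in keep]
        return ExpressionMatrix(self.data[cols].copy(), keep, self.descriptions)

    def columns_for(self, genotype: str | None = None, timepoint: str | None = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if (genotype is None or s.genotype == genotype)
            and (timepoint is None or s.timepoint == timepoint)
        ]


@dataclass
class ProbeAnnotation:
    """Probe -> gene mapping with quality class and control flag."""

    table: pd.DataFrame  # index probe_id; columns gene_symbol, quality, is_negative_control

    QUALITIES = ("good", "bad", "no_match")

    def __post_init__(self) -> None:
        required = {"gene_symbol", "quality", "is_negative_control"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing columns {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate probe_id in annotation")
        bad_quality = set(self.table["quality"]) - set(self.QUALITIES)
        if bad_quality:
            raise ValidationError(f"unknown quality classes {sorted(bad_quality)}")
        neg = self.table[self.table["is_negative_control"].astype(bool)]
        if (neg["gene_symbol"].fillna("").astype(str).str.strip() != "").any():
            raise ValidationError("negative-control probes must have empty gene_symbol")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def gene_symbol(self, probe_id: str) -> str:
        return str(self.table.at[probe_id, "gene_symbol"] or "")

    def quality(self, probe_id: str) -> str:
        return str(self.table.at[probe_id, "quality"])

    def is_negative_control(self, probe_id: str) -> bool:
        return bool(self.table.at[probe_id, "is_negative_control"])


@dataclass
class GeneSetCollection:
    """term_id -> (term_name, member gene symbols)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {term_id!r} has no members")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {term_id!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, term_id: str) -> tuple[str, ...]:
        return self.sets[term_id][1]


@dataclass
class Pwm:
    """Position weight matrix over {A,C,G,T} with background frequencies.

    ``probs`` holds column-normalized probabilities (4 x L, rows in
    A,C,G,T order); ``counts`` keeps the raw counts when read from a
    count file.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    counts: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4 or self.probs.shape[1] < 1:
            raise ValidationError("PWM must be a 4 x L matrix with L >= 1")
        col_sums = self.probs.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValidationError("PWM columns must each sum to 1")
        if self.background.shape != (4,) or (self.background <= 0).any():
            raise ValidationError("background must be 4 strictly positive frequencies")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValidationError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(DNA_ALPHABET[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            motif_id=self.motif_id,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            name=self.name,
        )


# ---------------------------------------------------------------------------
# GCT 1.2
# ---------------------------------------------------------------------------


def read_gct(path: str | Path, samples: Sequence[SampleDescriptor] | None = None) -> ExpressionMatrix:
    """Read a GCT 1.2 file.

    If ``samples`` is omitted, placeholder descriptors are synthesized
    from the column headers when they follow the
    ``<genotype>_<timepoint>_r<replicate>`` convention; otherwise a
    sample sheet must be supplied.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated GCT (need version, dimensions, header)")
    if lines[0].strip() != "#1.2":
        raise FormatError(f"{path}: unsupported GCT version line {lines[0]!r}")
    dims = lines[1].split("\t")
    if len(dims) != 2:
        raise FormatError(f"{path}: malformed dimension line {lines[1]!r}")
    try:
        n_rows, n_cols = int(dims[0]), int(dims[1])
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer dimensions {lines[1]!r}") from exc
    header = lines[2].split("\t")
    if header[:2] != ["Name", "Description"]:
        raise FormatError(f"{path}: GCT header must start with Name\\tDescription")
    col_ids = header[2:]
    if len(col_ids) != n_cols:
        raise FormatError(
            f"{path}: declared {n_cols} columns but header has {len(col_ids)}"
        )
    data_lines = [ln for ln in lines[3:] if ln.strip() != ""]
    if len(data_lines) != n_rows:
        raise FormatError(
            f"{path}: declared {n_rows} rows but found {len(data_lines)}"
        )
    row_ids: list[str] = []
    descriptions: list[str] = []
    values = np.empty((n_rows, n_cols))
    for i, ln in enumerate(data_lines):
        parts = ln.split("\t")
        if len(parts) != n_cols + 2:
            raise FormatError(f"{path}: row {i + 1} has {len(parts) - 2} values, expected {n_cols}")
        row_ids.append(parts[0])
        descriptions.append(parts[1])
        try:
            values[i] = [float(v) for v in parts[2:]]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value in row {parts[0]!r}") from exc
    if len(set(row_ids)) != n_rows:
        raise ValidationError(f"{path}: duplicate row ids")
    if samples is None:
        samples = [_descriptor_from_column(c) for c in col_ids]
    else:
        samples = list(samples)
        if [s.sample_id for s in samples] != col_ids:
            raise ValidationError(f"{path}: sample sheet does not match GCT columns")
    frame = pd.DataFrame(values, index=row_ids, columns=col_ids)
    return ExpressionMatrix(frame, list(samples), pd.Series(descriptions, index=row_ids))


def _descriptor_from_column(col: str) -> SampleDescriptor:
    parts = col.split("_")
    if len(parts) == 3 and parts[2].startswith("r"):
        try:
            return SampleDescriptor(col, parts[0], parts[1], int(parts[2][1:]))
        except (ValidationError, ValueError):
            pass
    raise ValidationError(
        f"cannot infer sample metadata from column {col!r}; provide a sample sheet"
    )


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    n_rows, n_cols = matrix.data.shape
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_rows}\t{n_cols}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        desc = matrix.descriptions
        for row_id, row in matrix.data.iterrows():
            d = "" if desc is None else str(desc.get(row_id, ""))
            fh.write(
                row_id + "\t" + d + "\t"
                + "\t".join(repr(float(v)) for v in row.to_numpy()) + "\n"
            )


# ---------------------------------------------------------------------------
# sample sheet / annotation
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = ["sample_id", "genotype", "timepoint", "replicate"]


def read_sample_sheet(path: str | Path) -> list[SampleDescriptor]:
    """Read a tab-separated sample sheet with the standard four columns."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_SHEET_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    samples = []
    for _, row in table.iterrows():
        try:
            replicate = int(row["replicate"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: non-integer replicate {row['replicate']!r}"
            ) from exc
        samples.append(
            SampleDescriptor(
                sample_id=str(row["sample_id"]).strip(),
                genotype=str(row["genotype"]).strip(),
                timepoint=str(row["timepoint"]).strip(),
                replicate=replicate,
            )
        )
    validate_sample_sheet(samples)
    return samples


def write_sample_sheet(samples: Sequence[SampleDescriptor], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "genotype": s.genotype,
                "timepoint": s.timepoint,
                "replicate": s.replicate,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"probe_id", "gene_symbol", "quality", "is_negative_control"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: annotation missing columns {sorted(missing)}")
    table["is_negative_control"] = table["is_negative_control"].str.lower().isin(
        {"true", "1", "yes"}
    )
    table["gene_symbol"] = table["gene_symbol"].str.strip()
    return ProbeAnnotation(table.set_index("probe_id"))


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    out = annotation.table.reset_index()
    out = out.rename(columns={out.columns[0]: "probe_id"})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term, description, then tab-separated members."""
    path = Path(path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            term_id, description = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            dupes = False
            for raw in fields[2:]:
                symbol = raw.strip()
                if not symbol:
                    continue
                if symbol in seen:
                    dupes = True
                    continue
                seen.add(symbol)
                members.append(symbol)
            if dupes:
                warnings.warn(
                    f"{path}:{lineno}: duplicate members in {term_id!r} deduplicated",
                    stacklevel=2,
                )
            if term_id in sets:
                raise ValidationError(f"{path}: duplicate term id {term_id!r}")
            sets[term_id] = (description, tuple(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term_id, (description, members) in collection.sets.items():
            fh.write("\t".join([term_id, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------


def read_jaspar_pfm(
    path: str | Path,
    background: Sequence[float] | None = None,
    pseudocount: float = 1.0,
) -> Pwm:
    """Read a JASPAR-style 4-row count matrix and convert to probabilities.

    A total pseudocount of ``pseudocount`` is distributed over the four
    bases proportionally to the background before normalization, so an
    all-zero base still gets a positive probability.
    """
    path = Path(path)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty PFM file")
    motif_id, name = "motif", ""
    if lines[0].startswith(">"):
        header = lines[0][1:].strip().split(None, 1)
        motif_id = header[0] if header else "motif"
        name = header[1] if len(header) > 1 else ""
        lines = lines[1:]
    if len(lines) != 4:
        raise FormatError(f"{path}: expected 4 count rows, found {len(lines)}")
    rows = []
    for base, line in zip(DNA_ALPHABET, lines):
        tokens = line.replace("[", " ").replace("]", " ").split()
        if tokens and tokens[0].upper() == base:
            tokens = tokens[1:]
        try:
            rows.append([float(t) for t in tokens])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric count in row {base}") from exc
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: count rows have unequal lengths {sorted(lengths)}")
    counts = np.array(rows, dtype=float)
    if (counts < 0).any():
        raise ValidationError(f"{path}: negative counts")
    padded = counts + pseudocount * bg[:, None]
    probs = padded / padded.sum(axis=0, keepdims=True)
    return Pwm(motif_id=motif_id, probs=probs, background=bg, counts=counts, name=name)


def write_jaspar_pfm(pwm: Pwm, path: str | Path) -> None:
    counts = pwm.counts if pwm.counts is not None else pwm.probs * 100.0
    with Path(path).open("w") as fh:
        fh.write(f">{pwm.motif_id} {pwm.name}".rstrip() + "\n")
        for base, row in zip(DNA_ALPHABET, counts):
            fh.write(base + " [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: sequence}`` map.

    Case is preserved: lowercase letters mark soft-masked repeats and
    are skipped by motif scanning downstream.
    """
    path = Path(path)
    records: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if current is not None:
                    records[current] = "".join(chunks)
                current = line[1:].split()[0]
                if current in records or not current:
                    raise ValidationError(f"{path}: duplicate or empty sequence id")
                chunks = []
            elif line.strip():
                if current is None:
                    raise FormatError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
    if current is not None:
        records[current] = "".join(chunks)
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for seq_id, seq in records.items():
            fh.write(f">{seq_id}\n")
            for start in range(0, len(seq), width):
                fh.write(seq[start : start + width] + "\n")


# ---------------------------------------------------------------------------
# edge list
# ---------------------------------------------------------------------------


def write_edge_list(
    tom: np.ndarray,
    row_ids: Sequence[str],
    min_connectivity: float,
    path: str | Path,
) -> int:
    """Write (node_a, node_b, weight) rows for pairs at/above the threshold.

    Returns the number of edges written.  Self-edges are never emitted.
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if tom.shape != (n, n) or not np.allclose(tom, tom.T, atol=1e-12):
        raise ValidationError("TOM input must be a symmetric square matrix")
    if len(row_ids) != n:
        raise ValidationError("row_ids length does not match matrix size")
    count = 0
    with Path(path).open("w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for i in range(n):
            for j in range(i + 1, n):
                if tom[i, j] >= min_connectivity:
                    fh.write(f"{row_ids[i]}\t{row_ids[j]}\t{tom[i, j]:.10g}\n")
                    count += 1
    return count
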