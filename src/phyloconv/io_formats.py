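"""Readers/writers for the pipeline's file formats and the gap-column filter.

Formats: amino acid alignments (FASTA), rooted trees (newick), binary
phenotype assignments (two-column TSV).  Alignment columns containing any
gap character are excluded before analysis; the surviving columns keep a
map back to their original 1-based coordinates so every report can cite
positions in the input alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import DEFAULT_BRANCH_EPSILON, Phylogeny

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
UNKNOWN = "X"
_VALID = set(AMINO_ACIDS) | {GAP, UNKNOWN}


class AlignmentFormatError(ValueError):
    pass


class PhenotypeError(ValueError):
    pass


@dataclass
class Alignment:
    """Amino acid alignment: tips x sites matrix of one-letter symbols.

    ``columns`` holds the original 1-based column index of each retained
    site, so coordinates stay stable across gap filtering.
    """

    ids: list[str]
    matrix: np.ndarray  # dtype '<U1', shape (n_seqs, n_sites)
    columns: np.ndarray = field(default=None)  # 1-based original coords

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise AlignmentFormatError("alignment matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise AlignmentFormatError("one identifier required per row")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentFormatError("sequence identifiers are not unique")
        if self.columns is None:
            self.columns = np.arange(1, self.matrix.shape[1] + 1)
        self.columns = np.asarray(self.columns, dtype=np.int64)
        if len(self.columns) != self.matrix.shape[1]:
            raise AlignmentFormatError("column map length mismatch")

    @property
    def n_seqs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, name: str) -> str:
        return "".join(self.matrix[self.ids.index(name)])

    def site(self, j: int) -> dict[str, str]:
        """Tip-label -> symbol mapping for retained column ``j`` (0-based)."""
        return {sid: self.matrix[i, j] for i, sid in enumerate(self.ids)}


def _validate_symbols(matrix: np.ndarray) -> None:
    observed = set(np.unique(matrix))
    bad = observed - _VALID
    if bad:
        raise AlignmentFormatError(
            f"invalid alignment symbols {sorted(bad)!r}; expected the 20 "
            f"amino acids, '-' (gap) or 'X' (unknown)"
        )


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an amino acid alignment (FASTA); symbols are upper-cased."""
    if format != "fasta":
        raise ValueError(f"unsupported alignment format: {format!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentFormatError(
            f"ragged alignment: sequence lengths {sorted(lengths)}"
        )
    matrix = np.array([list(s) for s in seqs], dtype="<U1")
    _validate_symbols(matrix)
    return Alignment(ids=ids, matrix=matrix)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=sid, description="")
        for sid, row in zip(aln.ids, aln.matrix)
    ]
    SeqIO.write(records, str(path), "fasta")


def drop_gap_columns(aln: Alignment) -> Alignment:
    """Remove every column that contains at least one gap.

    Mirrors the common trimming step in which any gapped alignment column
    is excluded before ancestral reconstruction.  Idempotent; the retained
    column map composes across repeated application.
    """
    keep = ~(aln.matrix == GAP).any(axis=0)
    if not keep.any():
        raise AlignmentFormatError("all alignment columns contain gaps")
    return Alignment(
        ids=list(aln.ids), matrix=aln.matrix[:, keep], columns=aln.columns[keep]
    )


def read_tree(path: str | Path, epsilon: float = DEFAULT_BRANCH_EPSILON) -> Phylogeny:
    """Read a rooted newick tree; zero branch lengths become ``epsilon``."""
    with open(path) as fh:
        newick = fh.read()
    return Phylogeny.from_newick(newick, epsilon=epsilon)


def read_phenotypes(path: str | Path, tree: Phylogeny) -> dict[str, int]:
    """Read a two-column TSV (tip label, state in {0,1}); header optional.

    Every tree tip must be assigned exactly once; records for labels not in
    the tree are an error, as are states outside {0, 1}.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise PhenotypeError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            rows.append((parts[0].strip(), parts[1].strip()))
    if rows and rows[0][1] not in {"0", "1"}:
        rows = rows[1:]  # header line
    table: dict[str, int] = {}
    for label, state in rows:
        if state not in {"0", "1"}:
            raise PhenotypeError(
                f"phenotype state for {label!r} is {state!r}, expected 0 or 1"
            )
        if label in table:
            raise PhenotypeError(f"duplicate phenotype record for {label!r}")
        table[label] = int(state)
    tips = set(tree.tip_labels)
    missing = sorted(tips - set(table))
    if missing:
        raise PhenotypeError(f"phenotype table is missing tips: {missing}")
    extra = sorted(set(table) - tips)
    if extra:
        raise PhenotypeError(f"phenotype table has unknown tips: {extra}")
    return table


def write_phenotypes(table: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tip\tstate\n")
        for label, state in table.items():
            fh.write(f"{label}\t{state}\n")
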