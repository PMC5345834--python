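"""Readers, writers and the shared data model.

Everything downstream of this module speaks in four currencies:

* :class:`SequenceRecord` — a single nucleotide sequence (genome contig,
  marker gene, or one row of an alignment),
* :class:`AlignmentBlock` — an aligned set of marker-gene sequences,
* :class:`LabeledMatrix` — a square pairwise similarity or distance matrix
  with strain labels (the currency of the whole pipeline),
* :class:`StrainRecord` — per-strain metadata (type-strain flag, prior
  species name, isolation region).

External formats are plain text: FASTA (via Biopython), CSV/TSV matrices and
metadata tables (via pandas), and Newick trees (scikit-bio ``TreeNode``
objects; the writer here controls branch-length formatting).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

__all__ = [
    "SequenceRecord",
    "AlignmentBlock",
    "LabeledMatrix",
    "StrainRecord",
    "KIND_SCALE",
    "MARKER_LOCI",
    "read_fasta",
    "write_fasta",
    "read_labeled_matrix",
    "write_labeled_matrix",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
]

#: Declared diagonal value per matrix kind. Percent similarities carry 100 on
#: the diagonal, tetranucleotide correlations 1.0, distances 0.0.
KIND_SCALE = {
    "ANIb": 100.0,
    "ANIm": 100.0,
    "TETRA": 1.0,
    "dDDH": 100.0,
    "MLSA-identity": 100.0,
    "16S-identity": 100.0,
    "distance": 0.0,
}

#: Recognised marker-gene locus names (16S rRNA plus the eight housekeeping
#: genes used for MLSA) and the concatenated alignment.
MARKER_LOCI = (
    "16S",
    "atpD",
    "clpA",
    "dnaJ",
    "gyrB",
    "rpoD",
    "rpoH",
    "rpoS",
    "secF",
    "MLSA",
)

_VALID_CHARS = set("ACGTN-")


def _normalize_seq(seq: str) -> str:
    """Upper-case, map U->T; raise on characters outside {A,C,G,T,N,-}."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_CHARS
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    return s


@dataclass
class SequenceRecord:
    """One nucleotide sequence with an identifier.

    Gaps ('-') are only meaningful inside alignments; genome sequences must
    be gap-free (checked by the consumers that require it).
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} is empty")
        self.seq = _normalize_seq(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentBlock:
    """A gapped or ungapped alignment of >=2 equal-length sequences.

    ``locus`` names the marker gene; columns are indexed 1-based in all user
    facing messages.
    """

    records: list[SequenceRecord]
    locus: str

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least two sequences")
        if self.locus not in MARKER_LOCI:
            raise ValueError(
                f"unknown locus {self.locus!r}; expected one of {MARKER_LOCI}"
            )
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            offenders = sorted({r.id for r in self.records})
            raise ValueError(
                f"alignment {self.locus}: sequences have unequal lengths "
                f"(ids: {offenders})"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence id(s) in alignment: {dup}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass
class LabeledMatrix:
    """Square pairwise matrix with strain labels.

    ``kind`` declares the scale (see :data:`KIND_SCALE`): the diagonal is
    forced to the declared value and off-diagonal entries are range-checked.
    """

    labels: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KIND_SCALE:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate strain labels in matrix")

    # -- basic accessors -------------------------------------------------

    @property
    def scale(self) -> float:
        return KIND_SCALE[self.kind]

    @property
    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def loc(self, a: str, b: str) -> float:
        idx = self.index
        return float(self.values[idx[a], idx[b]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def subset(self, labels: Sequence[str]) -> "LabeledMatrix":
        idx = self.index
        missing = [l for l in labels if l not in idx]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        sel = [idx[l] for l in labels]
        return LabeledMatrix(list(labels), self.values[np.ix_(sel, sel)], self.kind)

    # -- validation / normalisation --------------------------------------

    def symmetrize(self, max_asymmetry: float = 0.5) -> "LabeledMatrix":
        """Average M and M^T; error if any |M_ij - M_ji| exceeds the
        tolerance (0.5 on the percent scale signals data corruption).

        Idempotent: symmetrizing a symmetric matrix is the identity.
        """
        tol = max_asymmetry if self.scale != 1.0 else max_asymmetry / 100.0
        asym = np.abs(self.values - self.values.T)
        worst = float(np.nanmax(asym)) if asym.size else 0.0
        if worst > tol:
            i, j = np.unravel_index(np.nanargmax(asym), asym.shape)
            raise ValueError(
                f"matrix asymmetry {worst:.4g} between "
                f"{self.labels[i]!r} and {self.labels[j]!r} exceeds {tol}"
            )
        vals = (self.values + self.values.T) / 2.0
        np.fill_diagonal(vals, self.scale)
        return LabeledMatrix(self.labels, vals, self.kind)

    def validate(self) -> "LabeledMatrix":
        """Check symmetry (tight tolerance), diagonal, and value ranges."""
        if np.nanmax(np.abs(self.values - self.values.T)) > 1e-9:
            raise ValueError("matrix not symmetric; call symmetrize() first")
        if np.max(np.abs(np.diag(self.values) - self.scale)) > 1e-9:
            raise ValueError(f"diagonal must equal declared scale {self.scale}")
        v = self.values
        if self.kind == "TETRA":
            if np.nanmin(v) < -1 - 1e-9 or np.nanmax(v) > 1 + 1e-9:
                raise ValueError("TETRA values must lie in [-1, 1]")
        elif self.kind == "distance":
            if np.nanmin(v) < -1e-9:
                raise ValueError("distances must be >= 0")
        else:
            if np.nanmin(v) < -1e-9 or np.nanmax(v) > 100 + 1e-9:
                raise ValueError("percent values must lie in [0, 100]")
        return self

    def to_distance(self) -> "LabeledMatrix":
        """Convert a similarity matrix to distances.

        Percent scales use (100 - s)/100; tetranucleotide correlations use
        1 - r. Distance matrices pass through unchanged.
        """
        if self.kind == "distance":
            return self
        if self.kind == "TETRA":
            vals = 1.0 - self.values
        else:
            vals = (100.0 - self.values) / 100.0
        vals = np.clip(vals, 0.0, None)
        np.fill_diagonal(vals, 0.0)
        return LabeledMatrix(list(self.labels), vals, "distance")


@dataclass
class StrainRecord:
    """Metadata for one strain.

    ``is_type`` marks a described species' nomenclatural type strain;
    ``is_putative_type`` marks a PT strain chosen to represent a novel
    genomic species cluster.
    """

    id: str
    is_type: bool = False
    species_name: str = ""
    region: str = "unknown"
    is_putative_type: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("strain id must be non-empty")
        if self.is_type and not self.species_name:
            raise ValueError(
                f"type strain {self.id!r} must carry a species name"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, aligned: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving file order.

    With ``aligned=True`` all sequences must share one length (gap characters
    allowed); duplicate ids and empty records are always errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if aligned:
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            by_len: dict[int, list[str]] = {}
            for r in records:
                by_len.setdefault(len(r), []).append(r.id)
            raise ValueError(
                f"aligned FASTA {path} has unequal lengths: {by_len}"
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Labeled matrices (CSV or TSV; delimiter sniffed)
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_labeled_matrix(path: str | Path, kind: str,
                        max_asymmetry: float = 0.5) -> LabeledMatrix:
    """Read a labelled square table, symmetrize by averaging, force the
    diagonal to the declared scale, and range-check.

    The first row and first column must both carry the strain labels (same
    set; row order wins). Accepts comma- or tab-separated files, as exported
    from supplementary spreadsheets.
    """
    df = _read_table(path)
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if len(rows) != len(cols):
        raise ValueError(
            f"{path}: matrix is not square ({len(rows)} rows x {len(cols)} columns)"
        )
    if set(rows) != set(cols):
        raise ValueError(f"{path}: row and column label sets differ")
    df = df.loc[rows, rows]  # align column order to row order
    m = LabeledMatrix(rows, df.to_numpy(dtype=float), kind)
    return m.symmetrize(max_asymmetry=max_asymmetry).validate()


def write_labeled_matrix(matrix: LabeledMatrix, path: str | Path,
                         sep: str = "\t") -> None:
    matrix.to_dataframe().to_csv(path, sep=sep, float_format="%.6g")


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path,
                  region_vocabulary: Sequence[str] | None = None
                  ) -> list[StrainRecord]:
    """Read a strain metadata table with columns
    strain_id, is_type, species_name, region [, is_putative_type]."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str).fillna("")
    required = {"strain_id", "is_type", "species_name", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    out = []
    truthy = {"1", "true", "yes", "t"}
    for _, row in df.iterrows():
        region = row["region"] or "unknown"
        if region_vocabulary is not None and region != "unknown" \
                and region not in region_vocabulary:
            raise ValueError(
                f"{path}: region {region!r} for strain {row['strain_id']!r} "
                "is not in the configured vocabulary"
            )
        out.append(StrainRecord(
            id=row["strain_id"],
            is_type=row["is_type"].strip().lower() in truthy,
            species_name=row["species_name"],
            region=region,
            is_putative_type=row.get("is_putative_type", "").strip().lower() in truthy,
        ))
    ids = [r.id for r in out]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate strain ids in metadata")
    return out


def write_metadata(records: Iterable[StrainRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [{
            "strain_id": r.id,
            "is_type": str(r.is_type).lower(),
            "species_name": r.species_name,
            "region": r.region,
            "is_putative_type": str(r.is_putative_type).lower(),
        } for r in records]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _quote_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _newick_node(node: TreeNode, seen: set[int]) -> str:
    if id(node) in seen:
        raise ValueError("cyclic tree structure")
    seen.add(id(node))
    if node.is_tip():
        s = _quote_label(str(node.name))
    else:
        inner = ",".join(_newick_node(c, seen) for c in node.children)
        label = "" if node.name is None else _quote_label(str(node.name))
        s = f"({inner}){label}"
    if node.length is not None:
        s += f":{node.length:.6f}"
    return s


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick with branch lengths at 6 decimals and any
    internal-node names (support values) as internal labels.

    Round-trips through :func:`read_newick`.
    """
    text = _newick_node(tree, set()) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(source: str | Path) -> TreeNode:
    """Parse Newick text or a file path into a scikit-bio TreeNode."""
    p = Path(str(source))
    if p.exists():
        return TreeNode.read(str(p), format="newick")
    return TreeNode.read(io.StringIO(str(source)), format="newick")
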