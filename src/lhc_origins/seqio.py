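"""Sequence, alignment and tree input/output.

Protein records travel with the per-sequence metadata the family
classifier needs (organism, taxonomic lineage, and whether the gene is
nuclear- or plastid-encoded).  Metadata is carried in FASTA headers as
space-separated ``key=value`` tokens; a sidecar TSV with columns
``id, organism, lineage, compartment`` is accepted as an alternative and
takes precedence over header tokens.

All coordinates in this package are 0-based, half-open intervals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues legal in unaligned sequences ('X' = unknown, marginalized)
ALPHABET = set(AMINO_ACIDS) | {"X"}
#: additionally legal in aligned context
GAP = "-"

LINEAGES = ("cyanobacteria", "phage", "glaucophyte", "red", "green",
            "complex_red", "other")
COMPARTMENTS = ("nuclear", "plastid", "unknown")


class SeqFormatError(ValueError):
    """Malformed sequence input."""


@dataclass
class SeqRecord:
    """A protein sequence plus classification metadata."""

    id: str
    residues: str
    description: str = ""
    organism: str = ""
    lineage: str = "other"
    compartment: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqFormatError("record id must be nonempty")
        if self.lineage not in LINEAGES:
            raise SeqFormatError(f"unknown lineage {self.lineage!r}")
        if self.compartment not in COMPARTMENTS:
            raise SeqFormatError(f"unknown compartment {self.compartment!r}")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "SeqRecord":
        return replace(self, residues=self.residues.replace(GAP, ""))


@dataclass
class Alignment:
    """An ordered list of equal-length (gapped) records."""

    records: list[SeqRecord]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise SeqFormatError(f"ragged alignment, lengths {sorted(lengths)}")
        if not self.records or not self.records[0].residues:
            raise SeqFormatError("empty alignment")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def subset_columns(self, cols: Sequence[int]) -> "Alignment":
        return Alignment([
            replace(r, residues="".join(r.residues[j] for j in cols))
            for r in self.records
        ])


def _validate_residues(rec_id: str, residues: str, aligned: bool) -> None:
    allowed = ALPHABET | {GAP} if aligned else ALPHABET
    for pos, ch in enumerate(residues):
        if ch not in allowed:
            raise SeqFormatError(
                f"record {rec_id!r}: invalid residue {ch!r} at position {pos}"
            )


def _check_unique_ids(records: Iterable[SeqRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise SeqFormatError(f"duplicate record id {r.id!r}")
        seen.add(r.id)


def _parse_meta_tokens(description: str) -> dict[str, str]:
    meta = {}
    for tok in description.split():
        if "=" in tok:
            k, _, v = tok.partition("=")
            if k in ("organism", "lineage", "compartment"):
                meta[k] = v
    return meta


def read_metadata_tsv(path) -> dict[str, dict[str, str]]:
    """Read a sidecar metadata table keyed by sequence id."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "id" not in df.columns:
        raise SeqFormatError("metadata TSV needs an 'id' column")
    out: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        out[row["id"]] = {k: row[k] for k in ("organism", "lineage", "compartment")
                          if k in df.columns and row[k]}
    return out


def read_fasta(source, aligned: bool = False,
               metadata: dict[str, dict[str, str]] | None = None) -> list[SeqRecord]:
    """Read FASTA into :class:`SeqRecord` objects.

    Header tokens of the form ``organism=``, ``lineage=``, ``compartment=``
    populate the metadata fields; entries in *metadata* (e.g. from
    :func:`read_metadata_tsv`) override header tokens.
    """
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        records = []
        for bio in SeqIO.parse(handle, "fasta"):
            meta = _parse_meta_tokens(bio.description)
            if metadata and bio.id in metadata:
                meta.update(metadata[bio.id])
            residues = str(bio.seq).upper()
            _validate_residues(bio.id, residues, aligned)
            records.append(SeqRecord(
                id=bio.id,
                residues=residues,
                description=bio.description[len(bio.id):].strip(),
                organism=meta.get("organism", ""),
                lineage=meta.get("lineage", "other"),
                compartment=meta.get("compartment", "unknown"),
            ))
    finally:
        if close:
            handle.close()
    if not records:
        raise SeqFormatError("no FASTA records found")
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable[SeqRecord], dest) -> None:
    """Write records with metadata encoded as header key=value tokens."""
    bio_records = []
    for r in records:
        desc_parts = []
        if r.description:
            desc_parts.append(r.description)
        if r.organism:
            desc_parts.append(f"organism={r.organism}")
        desc_parts.append(f"lineage={r.lineage}")
        desc_parts.append(f"compartment={r.compartment}")
        bio_records.append(
            _BioRecord(Seq(r.residues), id=r.id, description=" ".join(desc_parts))
        )
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            SeqIO.write(bio_records, fh, "fasta-2line")
    else:
        SeqIO.write(bio_records, dest, "fasta-2line")


def read_alignment(source, metadata=None) -> Alignment:
    return Alignment(read_fasta(source, aligned=True, metadata=metadata))


def read_newick(source) -> dendropy.Tree:
    """Parse a single Newick tree; tip labels must be unique."""
    if isinstance(source, (str, Path)) and "(" not in str(source) \
            and Path(str(source)).exists():
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    if text.count("(") != text.count(")"):
        raise SeqFormatError("unbalanced parentheses in Newick string")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise SeqFormatError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise SeqFormatError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise SeqFormatError("negative branch length in input tree")
    return tree


def write_newick(tree: dendropy.Tree, dest=None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text + "\n")
        else:
            dest.write(text + "\n")
    return text


def read_character_matrix(source):
    """Read a binary taxa-by-characters presence/absence TSV.

    First column holds taxon labels (matching tree tips); remaining
    columns are 0/1 per family character.  Returns a
    :class:`lhc_origins.trees_tests.CharacterMatrix`.
    """
    from .trees_tests import CharacterMatrix

    df = pd.read_csv(source, sep="\t", index_col=0)
    bad = ~df.isin([0, 1]).all(axis=None)
    if bad:
        raise SeqFormatError("character matrix entries must be 0 or 1")
    return CharacterMatrix(
        taxa=[str(t) for t in df.index],
        characters=[str(c) for c in df.columns],
        matrix=df.to_numpy(dtype=int),
    )


def fasta_string(records: Iterable[SeqRecord]) -> str:
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()
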