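"""Readers/writers for the external formats the pipeline touches, plus the
shared primitive types every other module builds on.

Internal coordinates are 0-based half-open everywhere; the GFF3/TSV readers
convert from 1-based inclusive at the boundary.  Dated trees are read with
dendropy and validated for ultrametricity (node ages in million years, myr).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = frozenset("-.")
_DNA = frozenset("ACGTN")


class PlastevolError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PlastevolError):
    """Malformed input file (syntax-level problem)."""


class ValidationError(PlastevolError):
    """Well-formed input that violates a semantic contract."""


def revcomp(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class GenomeInterval:
    """Half-open interval [start, end) on a linearized genome."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomeInterval") -> int:
        """Number of bases shared with another interval."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class PlastomeRecord:
    """One plastome: sequence, gene annotations and a pathway-category label.

    Gene names are unique per record, so annotations are kept as an ordered
    mapping name -> GenomeInterval.
    """

    id: str
    sequence: str
    genes: dict[str, GenomeInterval] = field(default_factory=dict)
    category: str = "unknown"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValidationError(
                f"record {self.id}: non-DNA characters {sorted(bad)}"
            )
        if self.category not in ("C3", "CAM", "C3-CAM", "unknown"):
            raise ValidationError(f"record {self.id}: bad category {self.category!r}")
        for name, iv in self.genes.items():
            if iv.end > len(self.sequence):
                raise ValidationError(
                    f"record {self.id}: gene {name} interval [{iv.start}, {iv.end}) "
                    f"outside sequence of length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (id, uppercased sequence).

    Alignment FASTA is read with the same function; gap characters are kept.
    """
    with open(path) as handle:
        text = handle.read()
    stripped = text.lstrip()
    if not stripped:
        raise FormatError(f"{path}: empty FASTA file")
    if not stripped.startswith(">"):
        raise FormatError(f"{path}: malformed FASTA (missing '>' header)")
    records = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records, width: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA, wrapped at `width` columns."""
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# Annotations (GFF3 gene features, or a 5-column TSV with the same 1-based
# inclusive coordinate convention: seqid, gene, start, end, strand)


def _looks_like_gff3(path) -> bool:
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith("##gff-version"):
                return True
            if line.startswith("#"):
                continue
            return len(line.split("\t")) == 9
    return False


def read_annotations(path) -> dict[str, dict[str, GenomeInterval]]:
    """Read gene annotations into {seqid: {gene name: GenomeInterval}}.

    Accepts GFF3 (only features of type 'gene' are used; the name is taken
    from the Name, gene or ID attribute, in that order) or a header-less TSV
    with columns seqid, gene, start, end, strand.  Both formats use 1-based
    inclusive coordinates, converted here to 0-based half-open.
    """
    if _looks_like_gff3(path):
        return _read_gff3(path)
    return _read_annotation_tsv(path)


def _to_interval(seqid: str, gene: str, start_1based, end_incl, strand) -> GenomeInterval:
    try:
        start = int(start_1based)
        end = int(end_incl)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{seqid}/{gene}: non-integer coordinates") from exc
    if start < 1:
        raise ValidationError(f"{seqid}/{gene}: start {start} < 1 (1-based input)")
    if end < start:
        raise ValidationError(f"{seqid}/{gene}: end {end} < start {start}")
    return GenomeInterval(start - 1, end, strand if strand in ("+", "-") else "+")


def _read_gff3(path) -> dict[str, dict[str, GenomeInterval]]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    result: dict[str, dict[str, GenomeInterval]] = {}
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        name = (
            feat.attributes.get("Name", [None])[0]
            or feat.attributes.get("gene", [None])[0]
            or feat.id
        )
        per_seq = result.setdefault(feat.seqid, {})
        if name in per_seq:
            raise ValidationError(f"{feat.seqid}: duplicate gene name {name!r}")
        per_seq[name] = _to_interval(feat.seqid, name, feat.start, feat.end, feat.strand)
    if not result:
        raise FormatError(f"{path}: no gene features found")
    return result


def _read_annotation_tsv(path) -> dict[str, dict[str, GenomeInterval]]:
    result: dict[str, dict[str, GenomeInterval]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 tab-separated columns "
                    f"(seqid, gene, start, end, strand), got {len(parts)}"
                )
            seqid, gene, start, end, strand = parts
            per_seq = result.setdefault(seqid, {})
            if gene in per_seq:
                raise ValidationError(f"{seqid}: duplicate gene name {gene!r}")
            per_seq[gene] = _to_interval(seqid, gene, start, end, strand)
    if not result:
        raise FormatError(f"{path}: no annotation rows found")
    return result


def write_annotations_tsv(path, annotations: dict[str, dict[str, GenomeInterval]]) -> None:
    """Write annotations as the 5-column TSV (1-based inclusive coordinates)."""
    with open(path, "w") as handle:
        for seqid, genes in annotations.items():
            for name, iv in genes.items():
                handle.write(
                    f"{seqid}\t{name}\t{iv.start + 1}\t{iv.end}\t{iv.strand}\n"
                )


def cross_check_annotations(
    annotations: dict[str, dict[str, GenomeInterval]],
    sequences: dict[str, str],
) -> None:
    """Validate that every annotated interval lies within its sequence."""
    for seqid, genes in annotations.items():
        if seqid not in sequences:
            continue
        n = len(sequences[seqid])
        for name, iv in genes.items():
            if iv.end > n:
                raise ValidationError(
                    f"{seqid}/{name}: interval end {iv.end} beyond sequence length {n}"
                )


# ---------------------------------------------------------------------------
# Dated tree

ULTRAMETRICITY_TOL_MYR = 1e-6


@dataclass
class DatedTree:
    """Rooted ultrametric tree with node ages in myr (tip ages = 0).

    Thin wrapper over a dendropy Tree that exposes the quantities the
    pipeline needs: tip labels, root age, and terminal branch durations.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate tip labels in tree")
        try:
            self.tree.calc_node_ages(
                ultrametricity_precision=ULTRAMETRICITY_TOL_MYR
            )
        except (
            dendropy.utility.error.UltrametricityError,
            dendropy.utility.error.ProcessFailedException,
        ) as exc:
            raise ValidationError(f"tree is not ultrametric: {exc}") from exc

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def root_age(self) -> float:
        return float(self.tree.seed_node.age)

    def terminal_duration(self, label: str) -> float:
        """Duration (myr) of the terminal branch subtending the given tip."""
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == label:
                if leaf.edge.length is None:
                    raise ValidationError(f"tip {label}: missing branch length")
                return float(leaf.edge.length)
        raise ValidationError(f"tip {label!r} not in tree")

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_dated_tree(path) -> DatedTree:
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise FormatError(f"{path}: cannot parse Newick: {exc}") from exc
    return DatedTree(tree)


def dated_tree_from_string(newick: str) -> DatedTree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise FormatError(f"cannot parse Newick string: {exc}") from exc
    return DatedTree(tree)
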