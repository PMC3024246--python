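"""Core data types and readers/writers for the formats the pipeline touches.

Conventions used throughout the package:

* Coordinates are 0-based, half-open (BED-compatible) everywhere.
* Sequences are stored uppercase over the alphabet ``{A, C, G, T, N}``;
  ``U`` is converted to ``T`` on input.  ``N`` never matches anything in
  identity computations, including another ``N``.
* All regions are assumed to be supplied in a common orientation; no
  reverse-complement search is performed.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RegionSequence",
    "SpeciesTree",
    "TreeNode",
    "CharacterMatrix",
    "RegionLoadError",
    "NewickParseError",
    "read_region_fasta",
    "write_region_fasta",
    "parse_newick",
    "read_newick",
    "write_bed",
    "read_bed",
    "to_one_based",
    "from_one_based",
]

CLUSTER_IDS = ("12", "34", "56")
REGION_CLASSES = ("intergenic", "flanking5", "flanking3")

_VALID_BASES = frozenset("ACGTN")


class RegionLoadError(ValueError):
    """Raised when a region FASTA violates the loading contract."""


class NewickParseError(ValueError):
    """Raised when a newick string cannot be turned into a valid species tree."""


def _normalize_seq(raw: str, context: str = "") -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise RegionLoadError(
            f"invalid characters {sorted(bad)} in sequence {context or '<anonymous>'}; "
            "allowed alphabet is A/C/G/T/N (case-insensitive, U accepted)"
        )
    if not seq:
        raise RegionLoadError(f"empty sequence {context or '<anonymous>'}")
    return seq


@dataclass(frozen=True)
class RegionSequence:
    """One species' orthologous cluster region (intergenic or flanking).

    Parameters
    ----------
    species_id : taxon label.
    cluster_id : one of ``"12"``, ``"34"``, ``"56"`` for the dlx1-dlx2,
        dlx3-dlx4 and dlx5-dlx6 bi-gene clusters.
    region_class : ``"intergenic"``, ``"flanking5"`` or ``"flanking3"``.
    seq : nucleotide sequence, normalized to uppercase A/C/G/T/N.
    origin_offset : 0-based coordinate of the first base in the source record.
    """

    species_id: str
    cluster_id: str
    region_class: str
    seq: str
    origin_offset: int = 0

    def __post_init__(self) -> None:
        if self.cluster_id not in CLUSTER_IDS:
            raise RegionLoadError(
                f"unknown cluster_id {self.cluster_id!r}; expected one of {CLUSTER_IDS}"
            )
        if self.region_class not in REGION_CLASSES:
            raise RegionLoadError(
                f"unknown region_class {self.region_class!r}; expected one of {REGION_CLASSES}"
            )
        if self.origin_offset < 0:
            raise RegionLoadError("origin_offset must be >= 0")
        object.__setattr__(self, "seq", _normalize_seq(self.seq, self.key_str()))

    def key(self) -> tuple[str, str, str]:
        return (self.species_id, self.cluster_id, self.region_class)

    def key_str(self) -> str:
        return f"{self.species_id}|{self.cluster_id}|{self.region_class}"

    def __len__(self) -> int:
        return len(self.seq)


def _resolve_header(header: str) -> tuple[str, str, str]:
    parts = header.split("|")
    if len(parts) != 3:
        raise RegionLoadError(
            f"cannot resolve FASTA header {header!r}: expected 'species|cluster|region'"
        )
    return parts[0], parts[1], parts[2]


def read_region_fasta(
    path: str | Path,
    metadata: Mapping[str, tuple[str, str, str]] | None = None,
) -> list[RegionSequence]:
    """Load a set of region sequences from FASTA.

    Record ids follow the self-describing dialect ``species|cluster|region``;
    a sidecar ``metadata`` mapping (record id -> (species, cluster, region))
    overrides the header for the ids it contains.
    """
    regions: list[RegionSequence] = []
    seen: dict[tuple[str, str, str], str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if metadata is not None and record.id in metadata:
            species, cluster, region_class = metadata[record.id]
        else:
            species, cluster, region_class = _resolve_header(record.id)
        seq = str(record.seq)
        if not seq:
            raise RegionLoadError(f"empty sequence for record {record.id!r}")
        rs = RegionSequence(species, cluster, region_class, seq)
        if rs.key() in seen:
            raise RegionLoadError(
                f"duplicate (species, cluster, region): records {seen[rs.key()]!r} "
                f"and {record.id!r} both resolve to {rs.key()}"
            )
        seen[rs.key()] = record.id
        regions.append(rs)
    return regions


def write_region_fasta(regions: Iterable[RegionSequence], path: str | Path) -> None:
    """Write regions as FASTA with ``species|cluster|region`` headers."""
    records = [
        SeqRecord(Seq(r.seq), id=r.key_str(), description="") for r in regions
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


class TreeNode:
    """Node of a rooted species tree; the branch above a node is named by it."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, n_children={len(self.children)})"


class SpeciesTree:
    """Rooted species tree with uniquely labeled leaves.

    Branch lengths, when present, are expected substitutions per site and
    must be non-negative.  Each branch is identified by the label of its
    child node; the branch above the root is the "root stem".
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._assign_missing_labels()
        self._index: dict[str, TreeNode] = {}
        for node in self.preorder():
            if node.label in self._index:
                raise NewickParseError(f"duplicate node label {node.label!r}")
            if node.length is not None and node.length < 0:
                raise NewickParseError(
                    f"negative branch length {node.length} on branch {node.label!r}"
                )
            if not node.is_leaf and len(node.children) < 2:
                raise NewickParseError(
                    f"internal node {node.label!r} has a single child (unifurcation)"
                )
            self._index[node.label] = node
        # cache leaf label sets for mrca queries
        self._leafset: dict[str, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                self._leafset[node.label] = frozenset([node.label])
            else:
                acc: set[str] = set()
                for child in node.children:
                    acc |= self._leafset[child.label]
                self._leafset[node.label] = frozenset(acc)

    def _assign_missing_labels(self) -> None:
        used = {n.label for n in self.preorder() if n.label}
        counter = 1
        for node in self.preorder():
            if not node.label:
                while f"clade_{counter}" in used:
                    counter += 1
                node.label = f"clade_{counter}"
                used.add(node.label)

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterable[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    # -- queries -----------------------------------------------------------
    def node(self, label: str) -> TreeNode:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r} in tree") from None

    def has_node(self, label: str) -> bool:
        return label in self._index

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    def leafset(self, label: str) -> frozenset[str]:
        return self._leafset[label]

    def mrca(self, labels: Iterable[str]) -> TreeNode:
        """Most recent common ancestor of the given leaf labels."""
        want = frozenset(labels)
        if not want:
            raise ValueError("mrca of an empty label set is undefined")
        missing = want - self._leafset[self.root.label]
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        node = self.root
        while True:
            nxt = None
            for child in node.children:
                if want <= self._leafset[child.label]:
                    nxt = child
                    break
            if nxt is None:
                return node
            node = nxt

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        anc = self.mrca([a, b])
        total = 0.0
        for leaf in (a, b):
            node = self.node(leaf)
            while node is not anc:
                total += node.length or 0.0
                node = node.parent  # type: ignore[assignment]
        return total

    # -- serialization -----------------------------------------------------
    def to_newick(self, with_lengths: bool = True) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.label
            else:
                inner = ",".join(render(c) for c in node.children)
                s = f"({inner}){node.label}"
            if with_lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return render(self.root) + ";"


def parse_newick(text: str) -> SpeciesTree:
    """Parse a newick string into a validated :class:`SpeciesTree`.

    Polytomies are preserved.  Unbalanced parentheses, duplicate leaf
    labels, unifurcations and negative branch lengths are rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed newick: {exc}") from None

    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label or ""
        node = TreeNode(label, dnode.edge.length)
        for dchild in dnode.child_nodes():
            child = convert(dchild)
            child.parent = node
            node.children.append(child)
        return node

    root = convert(dtree.seed_node)
    tree = SpeciesTree(root)
    leaf_labels = tree.leaf_labels
    if len(leaf_labels) != len(set(leaf_labels)):
        dupes = sorted({x for x in leaf_labels if leaf_labels.count(x) > 1})
        raise NewickParseError(f"duplicate leaf labels: {dupes}")
    return tree


def read_newick(path: str | Path) -> SpeciesTree:
    return parse_newick(Path(path).read_text())


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------

STATES = ("0", "1", "?")


class CharacterMatrix:
    """Taxa x binary characters with an explicit missing state.

    States are ``1`` (present), ``0`` (absent) and ``?`` (missing /
    unknown).  Internally held as a pandas DataFrame of strings; taxon
    order and character order are preserved.
    """

    def __init__(self, frame: pd.DataFrame):
        bad = set(map(str, frame.to_numpy().ravel())) - set(STATES)
        if bad:
            raise ValueError(f"invalid matrix states {sorted(bad)}; allowed: 0/1/?")
        if frame.index.has_duplicates or frame.columns.has_duplicates:
            raise ValueError("duplicate taxon or character labels")
        self.frame = frame.astype(str)

    @classmethod
    def from_dict(
        cls,
        states: Mapping[str, Mapping[str, str | int]],
        taxa: Sequence[str] | None = None,
        characters: Sequence[str] | None = None,
    ) -> "CharacterMatrix":
        """Build from ``{character: {taxon: state}}``."""
        characters = list(characters) if characters is not None else list(states)
        if taxa is None:
            seen: list[str] = []
            for ch in characters:
                for t in states[ch]:
                    if t not in seen:
                        seen.append(t)
            taxa = seen
        frame = pd.DataFrame(
            [[str(states[ch][t]) for ch in characters] for t in taxa],
            index=list(taxa),
            columns=characters,
        )
        return cls(frame)

    @property
    def taxa(self) -> list[str]:
        return list(self.frame.index)

    @property
    def characters(self) -> list[str]:
        return list(self.frame.columns)

    def state(self, taxon: str, character: str) -> int | None:
        """Observed state: 1, 0 or None for '?'."""
        s = self.frame.at[taxon, character]
        return None if s == "?" else int(s)

    def column(self, character: str) -> dict[str, int | None]:
        return {t: self.state(t, character) for t in self.taxa}

    @property
    def vacuous_characters(self) -> list[str]:
        """Characters with no taxon observed present."""
        return [c for c in self.characters if not (self.frame[c] == "1").any()]

    def subset_taxa(self, taxa: Sequence[str]) -> "CharacterMatrix":
        return CharacterMatrix(self.frame.loc[list(taxa)])

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CharacterMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return self.frame.equals(other.frame)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(
    features: Iterable,
    reference: str,
    chrom: str = "chrRegion",
    include_sub_elements: bool = False,
) -> str:
    """Render conserved elements as 6-column BED text.

    Features need ``name``, ``start``, ``end`` and ``mean_identity``
    attributes (and, if present, a matching ``ref_species``).  The score
    column is ``round(mean_identity * 10)``; strand is always ``+``.
    """
    rows: list[tuple[int, int, str, int]] = []
    for f in features:
        ref = getattr(f, "ref_species", reference)
        if ref != reference:
            raise ValueError(
                f"mixed reference species: feature {getattr(f, 'name', f)!r} is on "
                f"{ref!r}, expected {reference!r}"
            )
        rows.append((f.start, f.end, f.name, round(f.mean_identity * 10)))
        if include_sub_elements:
            for sub in getattr(f, "sub_elements", ()) or ():
                rows.append(
                    (sub.start, sub.end, sub.name, round(sub.mean_identity * 10))
                )
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    out = _stdio.StringIO()
    out.write(f"# conserved elements on reference {reference}\n")
    for start, end, name, score in rows:
        out.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t+\n")
    return out.getvalue()


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str

    @property
    def mean_identity(self) -> float:
        return self.score / 10.0


def read_bed(text: str) -> list[BedRecord]:
    records = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, name, score, strand = line.split("\t")
        records.append(
            BedRecord(chrom, int(start), int(end), name, int(score), strand)
        )
    return records


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_one_based(first: int, last: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return first - 1, last
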