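"""Input/output layer: gapped FASTA alignments, rooted newick trees and
phenotype tables, plus per-species consensus building.

Conventions
-----------
* Alignment coordinates are 0-based half-open internally and 1-based
  inclusive in every user-facing report.
* Species identifiers are parsed from FASTA headers as the token before the
  first ``|`` (configurable delimiter); a header without the delimiter is
  its own species.
* Trees are stored rooted, with the outgroup as a child of the root.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import (
    AlignmentRaggedError,
    AlphabetError,
    EmptyGroupError,
    FormatError,
    OutgroupNotFoundError,
    UnitError,
)

logger = logging.getLogger("phyloindel")

NUCLEOTIDE_ALPHABET = frozenset("ACGTN-")

VELOCITY_DESCRIPTORS = ["VCL", "VSL", "VAP", "LIN", "STR", "ALH", "BCF"]
PHENOTYPE_COLUMNS = ["species", "body_mass", "testes_mass"] + VELOCITY_DESCRIPTORS
PERCENT_DESCRIPTORS = {"LIN", "STR"}


# ---------------------------------------------------------------------------
# Sequences and alignments
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """One aligned nucleotide sequence (individual or species consensus)."""

    id: str
    seq: str
    is_outgroup: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise AlphabetError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq.upper()) - NUCLEOTIDE_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass
class GappedAlignment:
    """A gap-aware multiple alignment with an individual-to-species map."""

    records: list[SequenceRecord]
    species_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentRaggedError("alignment has no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise AlignmentRaggedError(
                f"records have unequal lengths: {sorted(lengths)}"
            )
        for r in self.records:
            self.species_map.setdefault(r.id, r.id)

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            sp = self.species_map[r.id]
            if sp not in seen:
                seen.append(sp)
        return seen

    def get(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def by_species(self) -> dict[str, list[SequenceRecord]]:
        groups: dict[str, list[SequenceRecord]] = {}
        for r in self.records:
            groups.setdefault(self.species_map[r.id], []).append(r)
        return groups

    def column(self, col: int) -> str:
        return "".join(r.seq[col] for r in self.records)


def parse_species_id(header: str, delimiter: str = "|") -> str:
    """Species label = token before the first delimiter in a FASTA id."""
    return header.split(delimiter, 1)[0]


def read_alignment(
    path,
    *,
    outgroup: str | None = None,
    species_delimiter: str = "|",
) -> GappedAlignment:
    """Read a gapped FASTA alignment.

    Raises :class:`AlignmentRaggedError` on unequal record lengths and
    :class:`AlphabetError` on characters outside ``{A,C,G,T,N,-}``.
    """
    records = []
    for bio in SeqIO.parse(str(path), "fasta"):
        sp = parse_species_id(bio.id, species_delimiter)
        records.append(
            SequenceRecord(bio.id, str(bio.seq), is_outgroup=(sp == outgroup))
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    species_map = {r.id: parse_species_id(r.id, species_delimiter) for r in records}
    return GappedAlignment(records, species_map)


def write_alignment(aln: GappedAlignment, path) -> None:
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description="") for r in aln.records
    ]
    SeqIO.write(bio, str(path), "fasta")


@dataclass
class PolymorphismReport:
    """Columns (1-based) where conspecific individuals disagree."""

    substitution_columns: list[int] = field(default_factory=list)
    indel_columns: list[int] = field(default_factory=list)
    tie_columns: list[int] = field(default_factory=list)

    @property
    def has_indel_polymorphism(self) -> bool:
        return bool(self.indel_columns)


def build_consensus(
    individuals: list[SequenceRecord], *, consensus_id: str | None = None
) -> tuple[SequenceRecord, PolymorphismReport]:
    """Majority-rule consensus across conspecific individuals.

    Ties (possible only with an even number of individuals) take the state of
    the first-listed individual and flag the column. Columns where a gap
    disagrees with a residue are reported as indel polymorphisms; pure base
    disagreements as substitution polymorphisms.
    """
    if not individuals:
        raise EmptyGroupError("no individuals supplied for consensus")
    lengths = {len(r) for r in individuals}
    if len(lengths) > 1:
        raise AlignmentRaggedError(
            f"consensus individuals have unequal lengths: {sorted(lengths)}"
        )
    n_cols = lengths.pop()
    report = PolymorphismReport()
    out = []
    for col in range(n_cols):
        states = [r.seq[col] for r in individuals]
        uniq = set(states)
        if len(uniq) > 1:
            if "-" in uniq:
                report.indel_columns.append(col + 1)
            else:
                report.substitution_columns.append(col + 1)
            counts: dict[str, int] = {}
            for s in states:
                counts[s] = counts.get(s, 0) + 1
            best = max(counts.values())
            winners = [s for s, c in counts.items() if c == best]
            if len(winners) > 1:
                report.tie_columns.append(col + 1)
                out.append(states[0])
            else:
                out.append(winners[0])
        else:
            out.append(states[0])
    cid = consensus_id or individuals[0].id
    return (
        SequenceRecord(cid, "".join(out), is_outgroup=individuals[0].is_outgroup),
        report,
    )


def species_consensus_alignment(
    aln: GappedAlignment,
) -> tuple[GappedAlignment, dict[str, PolymorphismReport]]:
    """Collapse an individual-level alignment to one consensus per species."""
    records = []
    reports: dict[str, PolymorphismReport] = {}
    for sp, group in aln.by_species().items():
        cons, rep = build_consensus(group, consensus_id=sp)
        records.append(cons)
        reports[sp] = rep
    return GappedAlignment(records, {r.id: r.id for r in records}), reports


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class Node:
    """A node of a rooted phylogeny."""

    __slots__ = ("name", "length", "parent", "children")

    def __init__(self, name: str = "", length: float = 0.0):
        self.name = name
        self.length = length  # length of the branch above this node
        self.parent: Node | None = None
        self.children: list[Node] = []

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.name!r}, {self.length})"


class Phylogeny:
    """Rooted tree with named tips, branch lengths and an outgroup label.

    Internal nodes carry stable labels ``N1, N2, ...`` assigned in preorder;
    a branch is identified by the label of its child node.
    """

    def __init__(self, root: Node, outgroup: str | None = None):
        self.root = root
        self.outgroup = outgroup
        self._relabel_internals()
        tips = self.tip_labels()
        if len(tips) != len(set(tips)):
            raise FormatError("duplicate tip labels in tree")
        if outgroup is not None and outgroup not in tips:
            raise OutgroupNotFoundError(
                f"outgroup {outgroup!r} not among tips {sorted(tips)}"
            )

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, outgroup: str | None = None) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse errors
            raise FormatError(f"unparseable newick: {exc}") from exc
        return cls.from_dendropy(dtree, outgroup=outgroup)

    @classmethod
    def from_dendropy(
        cls, dtree: dendropy.Tree, outgroup: str | None = None
    ) -> "Phylogeny":
        labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        if outgroup is not None:
            if outgroup not in labels:
                raise OutgroupNotFoundError(
                    f"outgroup {outgroup!r} not among tips {sorted(labels)}"
                )
            og = next(
                lf for lf in dtree.leaf_node_iter() if lf.taxon.label == outgroup
            )
            root_children = dtree.seed_node.child_nodes()
            already = og in root_children and len(root_children) == 2
            if not already:
                elen = og.edge.length or 0.0
                dtree.reroot_at_edge(
                    og.edge, length1=elen / 2.0, length2=elen / 2.0,
                    update_bipartitions=False,
                )

        def convert(dnode) -> Node:
            name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            node = Node(name=name, length=dnode.edge.length or 0.0)
            for c in dnode.child_nodes():
                node.add_child(convert(c))
            return node

        root = convert(dtree.seed_node)
        root.length = 0.0
        return cls(root, outgroup=outgroup)

    def _relabel_internals(self) -> None:
        i = 0
        for node in self.preorder():
            if not node.is_tip:
                i += 1
                node.name = f"N{i}"

    # -- traversal ---------------------------------------------------------
    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.name for n in self.tips()]

    def edges(self) -> list[Node]:
        """All branches, identified by their child node (root excluded)."""
        return [n for n in self.preorder() if n.parent is not None]

    def node(self, name: str) -> Node:
        for n in self.preorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def path_to_root(self, tip_label: str) -> list[Node]:
        """Branches (child nodes) on the path from the root to a tip."""
        node = self.node(tip_label)
        path = []
        while node.parent is not None:
            path.append(node)
            node = node.parent
        return list(reversed(path))

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    # -- derived quantities -------------------------------------------------
    def ingroup_tip_labels(self) -> list[str]:
        return [t for t in self.tip_labels() if t != self.outgroup]

    def brownian_covariance(self, taxa: list[str] | None = None) -> pd.DataFrame:
        """Shared root-to-MRCA path lengths between tips (Brownian V)."""
        taxa = taxa or self.tip_labels()
        depth: dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node.parent is not None:
                depth[id(node)] = depth[id(node.parent)] + node.length
        # tips under each node
        under: dict[int, list[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                under[id(node)] = [node.name]
            else:
                under[id(node)] = [
                    t for c in node.children for t in under[id(c)]
                ]
        n = len(taxa)
        V = pd.DataFrame(np.zeros((n, n)), index=taxa, columns=taxa)
        for t in taxa:
            V.loc[t, t] = depth[id(self.node(t))]
        keep = set(taxa)
        for node in self.preorder():
            if node.is_tip:
                continue
            kids = [
                [t for t in under[id(c)] if t in keep] for c in node.children
            ]
            d = depth[id(node)]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    for a in kids[i]:
                        for b in kids[j]:
                            V.loc[a, b] = d
                            V.loc[b, a] = d
        return V

    def prune_to(self, taxa: list[str]) -> "Phylogeny":
        """Subtree spanned by the given tips, unifurcations suppressed."""
        keep = set(taxa)
        missing = keep - set(self.tip_labels())
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")

        def rec(node: Node) -> Node | None:
            if node.is_tip:
                if node.name in keep:
                    new = Node(node.name, node.length)
                    return new
                return None
            kept = [rec(c) for c in node.children]
            kept = [k for k in kept if k is not None]
            if not kept:
                return None
            if len(kept) == 1:
                kept[0].length += node.length
                return kept[0]
            new = Node(node.name, node.length)
            for k in kept:
                new.add_child(k)
            return new

        new_root = rec(self.root)
        if new_root is None:
            raise KeyError("no requested tips present")
        new_root.length = 0.0
        og = self.outgroup if self.outgroup in keep else None
        return Phylogeny(new_root, outgroup=og)

    # -- serialisation -------------------------------------------------------
    def to_newick(self, *, internal_labels: bool = False) -> str:
        def rec(node: Node) -> str:
            if node.is_tip:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(rec(c) for c in node.children)
            label = node.name if internal_labels else ""
            if node.parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.10g}"

        return rec(self.root) + ";"

    def copy(self) -> "Phylogeny":
        return Phylogeny.from_newick(
            self.to_newick(), outgroup=self.outgroup
        )


def read_tree(path, outgroup: str) -> Phylogeny:
    """Read a newick tree and root it on the outgroup branch."""
    with open(path) as fh:
        newick = fh.read()
    return Phylogeny.from_newick(newick, outgroup=outgroup)


def write_tree(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Per-species phenotypes: masses (g) and seven CASA velocity descriptors.

    VCL/VSL/VAP in um/s, LIN/STR in percent, ALH in um/s (as printed in the
    source tables), BCF in Hz. Missing values are permitted and flagged.
    """

    data: pd.DataFrame
    missing: dict[str, list[str]] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.data["species"])

    def complete_velocity_species(self) -> list[str]:
        sub = self.data.set_index("species")[VELOCITY_DESCRIPTORS]
        return list(sub.dropna().index)


def read_phenotypes(path, tree: Phylogeny | None = None) -> PhenotypeTable:
    """Read a phenotype CSV and validate units.

    Negative/zero masses and percentages outside [0, 100] raise
    :class:`UnitError`; species missing from the tree are warned about but
    retained.
    """
    df = pd.read_csv(path)
    required = {"species", "body_mass", "testes_mass"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: missing required columns {sorted(required - set(df.columns))}"
        )
    return validate_phenotypes(df, tree=tree, source=str(path))


def validate_phenotypes(
    df: pd.DataFrame, tree: Phylogeny | None = None, source: str = "<frame>"
) -> PhenotypeTable:
    df = df.copy()
    df["species"] = df["species"].astype(str).str.strip()
    for col in ("body_mass", "testes_mass"):
        vals = df[col]
        if (vals.dropna() <= 0).any():
            raise UnitError(f"{source}: non-positive {col}")
    for col in VELOCITY_DESCRIPTORS:
        if col not in df.columns:
            df[col] = np.nan
            continue
        vals = df[col].dropna()
        if (vals < 0).any():
            raise UnitError(f"{source}: negative {col}")
        if col in PERCENT_DESCRIPTORS and (vals > 100).any():
            raise UnitError(f"{source}: {col} above 100%")
    missing: dict[str, list[str]] = {}
    for col in ["body_mass", "testes_mass"] + VELOCITY_DESCRIPTORS:
        gone = list(df.loc[df[col].isna(), "species"])
        if gone:
            missing[col] = gone
    if tree is not None:
        tips = set(tree.tip_labels())
        not_in_tree = [s for s in df["species"] if s not in tips]
        no_phenotype = sorted(tips - set(df["species"]) - {tree.outgroup})
        if not_in_tree:
            warnings.warn(
                f"{source}: species not in tree (rows retained): {not_in_tree}"
            )
        if no_phenotype:
            missing["_tree_tips_without_phenotypes"] = no_phenotype
            logger.info("tree tips without phenotype rows: %s", no_phenotype)
    return PhenotypeTable(df, missing)


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.data.to_csv(path, index=False)
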