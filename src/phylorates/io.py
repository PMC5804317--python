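"""Input/output: alignments (FASTA), trees (Newick), partition sidecars, results JSON.

Character conventions
---------------------
Nucleotide canonical states are A, C, G, T (U is normalized to T); protein
states follow the PAML ordering ``ARNDCQEGHILKMFPSTWYV``.  Gap symbols
(``-``, ``?``, ``.``) are treated as fully missing data; IUPAC nucleotide
ambiguity codes and the protein codes X/B/Z are partially missing data.
All are retained so that a rate is reported for every alignment column.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Union

import dendropy
import numpy as np
from Bio import SeqIO

from .exceptions import BindError, FormatError

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

NUC_STATES = "ACGT"
PROTEIN_STATES = "ARNDCQEGHILKMFPSTWYV"

GAP_CHARS = frozenset("-?.")

# IUPAC nucleotide ambiguity codes -> set of canonical states
NUC_AMBIGUITY = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
PROTEIN_AMBIGUITY = {
    "X": PROTEIN_STATES,
    "B": "ND",   # asparagine or aspartate
    "Z": "QE",   # glutamine or glutamate
}


def alphabet_states(alphabet: str) -> str:
    if alphabet == NUCLEOTIDE:
        return NUC_STATES
    if alphabet == PROTEIN:
        return PROTEIN_STATES
    raise ValueError(f"unknown alphabet {alphabet!r}")


def ambiguity_map(alphabet: str) -> dict:
    return NUC_AMBIGUITY if alphabet == NUCLEOTIDE else PROTEIN_AMBIGUITY


def state_sets(alphabet: str) -> dict:
    """Map every accepted character to the tuple of state indices it allows."""
    states = alphabet_states(alphabet)
    index = {c: i for i, c in enumerate(states)}
    out = {c: (i,) for c, i in index.items()}
    for code, members in ambiguity_map(alphabet).items():
        out[code] = tuple(index[m] for m in members)
    everything = tuple(range(len(states)))
    for g in GAP_CHARS:
        out[g] = everything
    return out


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment.

    ``data`` is a (n_taxa, n_sites) array of single characters, upper-cased.
    """

    taxa: list
    data: np.ndarray
    alphabet: str

    def __post_init__(self):
        if len(self.taxa) != len(set(self.taxa)):
            raise FormatError("duplicate taxon labels in alignment")
        if any(not t for t in self.taxa):
            raise FormatError("empty taxon label in alignment")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise FormatError("alignment matrix shape does not match taxa")
        if self.data.shape[1] < 1:
            raise FormatError("alignment has zero sites")
        allowed = set(state_sets(self.alphabet))
        flat = set(np.unique(self.data))
        bad = flat - allowed
        if bad:
            rows, cols = np.where(np.isin(self.data, sorted(bad)))
            t, s = self.taxa[rows[0]], cols[0] + 1
            raise FormatError(
                f"character {self.data[rows[0], cols[0]]!r} at site {s} of "
                f"{t!r} is not a {self.alphabet} state, ambiguity code or gap"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return int(self.data.shape[1])

    def column(self, site: int) -> np.ndarray:
        """Characters of the 0-based column ``site``."""
        return self.data[:, site]

    def __eq__(self, other):
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and self.alphabet == other.alphabet
            and self.data.shape == other.data.shape
            and bool((self.data == other.data).all())
        )


def read_alignment(path: Union[str, os.PathLike], alphabet: str) -> Alignment:
    """Read a FASTA alignment; characters are upper-cased, U becomes T."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    taxa = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    if alphabet == NUCLEOTIDE:
        seqs = [s.replace("U", "T") for s in seqs]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        ref = len(seqs[0])
        for t, s in zip(taxa, seqs):
            if len(s) != ref:
                raise FormatError(
                    f"ragged alignment: {t!r} has length {len(s)}, expected {ref}"
                )
    data = np.array([list(s) for s in seqs], dtype="<U1")
    return Alignment(taxa=taxa, data=data, alphabet=alphabet)


def write_alignment(aln: Alignment, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        for t, row in zip(aln.taxa, aln.data):
            fh.write(f">{t}\n{''.join(row)}\n")


@dataclass
class Tree:
    """A tip-labelled phylogeny; branch lengths are optional (None = absent)."""

    dtree: dendropy.Tree

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises assorted parse errors
            raise FormatError(f"could not parse Newick: {exc}") from exc
        labels = [lf.taxon.label for lf in dt.leaf_node_iter()]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise FormatError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in dt.preorder_edge_iter():
            if edge.length is not None:
                if not np.isfinite(edge.length) or edge.length < 0:
                    raise FormatError(
                        f"branch length {edge.length} is negative or non-finite"
                    )
        return cls(dtree=dt)

    @property
    def tip_labels(self) -> list:
        return [lf.taxon.label for lf in self.dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.dtree.leaf_nodes())

    def has_lengths(self) -> bool:
        """True when every non-root edge carries a branch length."""
        root = self.dtree.seed_node
        return all(
            nd.edge.length is not None
            for nd in self.dtree.preorder_node_iter()
            if nd is not root
        )

    def branch_lengths(self) -> list:
        root = self.dtree.seed_node
        return [
            nd.edge.length
            for nd in self.dtree.preorder_node_iter()
            if nd is not root
        ]

    def newick(self) -> str:
        return self.dtree.as_string(schema="newick", suppress_rooting=True).strip()

    def clone(self) -> "Tree":
        return Tree(dtree=self.dtree.clone(depth=1))


def read_tree(path_or_string: str) -> Tree:
    """Parse a Newick tree from a file path or a literal string."""
    text = path_or_string
    if os.path.exists(str(path_or_string)):
        with open(path_or_string) as fh:
            text = fh.read()
    if "(" not in text:
        raise FormatError("input does not look like Newick (no parentheses)")
    return Tree.from_newick(text)


@dataclass
class Partition:
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    tree: Tree

    @property
    def sites(self) -> range:
        """0-based site indices covered by this partition."""
        return range(self.start - 1, self.end)


@dataclass
class PartitionSet:
    partitions: list

    def __iter__(self):
        return iter(self.partitions)

    def __len__(self):
        return len(self.partitions)


def read_partitions(path: Union[str, os.PathLike]) -> PartitionSet:
    """Read a partition sidecar: one ``start-end<TAB>newick`` line per partition."""
    parts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rng, nwk = line.split("\t", 1)
                lo, hi = rng.split("-")
                start, end = int(lo), int(hi)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: expected 'start-end<TAB>newick'"
                ) from exc
            if start < 1 or end < start:
                raise FormatError(f"{path}:{lineno}: bad range {rng}")
            parts.append(Partition(start, end, Tree.from_newick(nwk)))
    if not parts:
        raise FormatError(f"no partitions in {path}")
    return PartitionSet(parts)


def bind_partitions(
    aln: Alignment, spec: Union[PartitionSet, Tree]
) -> PartitionSet:
    """Validate a partition layout against an alignment.

    A single tree becomes a one-partition set spanning all sites.  Every
    tree's tip set must equal the alignment taxon set; ranges must be
    contiguous, disjoint and jointly cover 1..length.
    """
    if isinstance(spec, Tree):
        spec = PartitionSet([Partition(1, aln.length, spec)])
    taxa = set(aln.taxa)
    for i, part in enumerate(spec):
        tips = set(part.tree.tip_labels)
        if tips != taxa:
            only_tree = sorted(tips - taxa)
            only_aln = sorted(taxa - tips)
            raise BindError(
                f"partition {i + 1}: tree tips and alignment taxa differ; "
                f"tree-only={only_tree}, alignment-only={only_aln}"
            )
    ordered = sorted(spec.partitions, key=lambda p: p.start)
    cursor = 1
    for part in ordered:
        if part.start < cursor:
            raise BindError(
                f"partition ranges overlap at site {part.start}"
            )
        if part.start > cursor:
            raise BindError(
                f"partition ranges leave sites {cursor}-{part.start - 1} uncovered"
            )
        cursor = part.end + 1
    if cursor != aln.length + 1:
        raise BindError(
            f"partition ranges cover 1-{cursor - 1} but the alignment has "
            f"{aln.length} sites"
        )
    return PartitionSet(ordered)


RESULT_HEADERS = [
    ["Partition", "0-based index of the partition the site belongs to"],
    ["MLE", "Maximum-likelihood estimate of the relative site rate"],
    ["Lower", "Lower bound of the approximate 95% profile-likelihood CI"],
    ["Upper", "Upper bound of the approximate 95% profile-likelihood CI"],
    ["LogL", "Site log-likelihood at the rate MLE"],
]


@dataclass
class ResultsDocument:
    """Final analysis results: one numeric row per alignment site.

    Rows are ``[partition, MLE, lower, upper, logL]`` in input site order.
    """

    headers: list = field(default_factory=lambda: [list(h) for h in RESULT_HEADERS])
    content: list = field(default_factory=list)
    partition_summaries: list = field(default_factory=list)
    input_info: dict = field(default_factory=dict)
    analysis_info: dict = field(default_factory=dict)

    def validate(self) -> None:
        arity = len(self.headers)
        for i, row in enumerate(self.content):
            if len(row) != arity:
                raise ValueError(f"row {i} has {len(row)} fields, expected {arity}")
        n = self.input_info.get("number of sites")
        if n is not None and n != len(self.content):
            raise ValueError(
                f"{len(self.content)} rows for {n} sites; one row per site required"
            )

    def to_dict(self) -> dict:
        return {
            "analysis": self.analysis_info,
            "input": self.input_info,
            "partitions": self.partition_summaries,
            "mle": {"headers": self.headers, "content": self.content},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResultsDocument":
        return cls(
            headers=d["mle"]["headers"],
            content=d["mle"]["content"],
            partition_summaries=d.get("partitions", []),
            input_info=d.get("input", {}),
            analysis_info=d.get("analysis", {}),
        )

    def __eq__(self, other):
        return isinstance(other, ResultsDocument) and self.to_dict() == other.to_dict()


def write_results(
    doc: ResultsDocument,
    input_path: Union[str, os.PathLike],
    output_path: Optional[Union[str, os.PathLike]] = None,
) -> str:
    """Write the results JSON next to the input file (suffix ``.leisr.json``)."""
    doc.validate()
    out = str(output_path) if output_path else str(input_path) + ".leisr.json"
    with open(out, "w") as fh:
        json.dump(doc.to_dict(), fh, indent=1)
        fh.write("\n")
    return out


def read_results(path: Union[str, os.PathLike]) -> ResultsDocument:
    with open(path) as fh:
        return ResultsDocument.from_dict(json.load(fh))
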