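"""Orthologous-intron grouping from precomputed protein alignments.

Upstream ortholog detection (reciprocal best hits) and global protein
alignment are consumed as inputs: each pairwise alignment arrives as two
equal-length gapped protein rows. Intron positions are anchored to codon
(residue) coordinates, mapped into alignment columns, and a pair of
introns is linked as orthologous when both fall in the same alignment
column with equal phase inside a region of good local alignment (>= 40%
identical residues within +/-10 columns). Pairwise links are then
clustered into groups by maximal-clique listing, so every member of a
group is a recorded ortholog of every other member (e.g. links A-B, A-C,
B-C, B-D yield the groups A-B-C and B-D).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .annotation import IntronRecord, Transcript, compute_phase

DEFAULT_MIN_QUALITY = 0.40
DEFAULT_WINDOW = 10
#: guard against accidental dense graphs; clique listing is exponential
#: in the worst case while real ortholog-link graphs are sparse
MAX_CLIQUE_NODES = 200_000


@dataclass
class PairwiseAlignment:
    """Two equal-length gapped protein rows for an ortholog transcript pair."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows must have equal length")

    def __len__(self):
        return len(self.row_a)


@dataclass
class IntronAnchor:
    """An intron pinned to a protein coordinate: the 1-based residue index
    of the codon containing (or immediately following) the junction, plus
    the intron's phase."""

    intron_id: str
    transcript_id: str
    residue_index: int
    phase: int


@dataclass(frozen=True)
class OrthologGroup:
    members: tuple[str, ...]


def anchor_introns(
    transcript: Transcript, introns: list[IntronRecord]
) -> list[IntronAnchor]:
    """Protein-coordinate anchors for CDS-defined introns.

    residue_index = floor(upstream CDS nt / 3) + 1; exon-defined introns
    (phase undefined) are skipped.
    """
    feats = sorted(transcript.features, key=lambda f: f[1])
    if transcript.strand == "-":
        feats = feats[::-1]
    cumulative = []
    total = 0
    for _, start, stop in feats:
        total += stop - start + 1
        cumulative.append(total)
    anchors = []
    ordered = sorted(introns, key=lambda r: r.rank)
    for intron in ordered:
        if intron.defined_by != "CDS" or intron.phase is None:
            continue
        upstream_nt = cumulative[intron.rank - 1]
        anchors.append(
            IntronAnchor(
                intron_id=intron.intron_id,
                transcript_id=transcript.transcript_id,
                residue_index=upstream_nt // 3 + 1,
                phase=intron.phase,
            )
        )
    return anchors


def alignment_quality(
    aln: PairwiseAlignment, column: int, window: int = DEFAULT_WINDOW
) -> float:
    """Fraction of identical residue pairs within +/-window columns.

    `column` is 1-based. The window is truncated at the alignment ends
    and the denominator is the number of columns actually examined; gap
    columns count in the denominator but never as matches.
    """
    if not 1 <= column <= len(aln):
        raise ValueError(f"column {column} outside alignment of length {len(aln)}")
    lo = max(0, column - 1 - window)
    hi = min(len(aln), column + window)
    matches = sum(
        1
        for i in range(lo, hi)
        if aln.row_a[i] == aln.row_b[i] and aln.row_a[i] != "-"
    )
    return matches / (hi - lo)


def _residue_to_column(row: str) -> dict[int, int]:
    """Map 1-based residue indices to 1-based alignment columns."""
    mapping = {}
    residue = 0
    for col, ch in enumerate(row, start=1):
        if ch != "-":
            residue += 1
            mapping[residue] = col
    return mapping


def link_orthologous_introns(
    aln: PairwiseAlignment,
    anchors_a: list[IntronAnchor],
    anchors_b: list[IntronAnchor],
    min_quality: float = DEFAULT_MIN_QUALITY,
    window: int = DEFAULT_WINDOW,
) -> list[tuple[str, str]]:
    """Orthologous intron pairs between two aligned transcripts.

    Two anchors link iff they map to the same alignment column, share
    phase, and local alignment quality at that column is >= min_quality.
    """
    map_a = _residue_to_column(aln.row_a)
    map_b = _residue_to_column(aln.row_b)
    cols_a: dict[tuple[int, int], IntronAnchor] = {}
    for anchor in anchors_a:
        col = map_a.get(anchor.residue_index)
        if col is None:
            raise ValueError(
                f"anchor {anchor.intron_id}: residue {anchor.residue_index} "
                f"beyond protein {aln.id_a}"
            )
        cols_a[(col, anchor.phase)] = anchor
    links = []
    for anchor in anchors_b:
        col = map_b.get(anchor.residue_index)
        if col is None:
            raise ValueError(
                f"anchor {anchor.intron_id}: residue {anchor.residue_index} "
                f"beyond protein {aln.id_b}"
            )
        partner = cols_a.get((col, anchor.phase))
        if partner is None:
            continue
        if alignment_quality(aln, col, window) >= min_quality:
            links.append((partner.intron_id, anchor.intron_id))
    links.sort()
    return links


def clique_groups(links: list[tuple[str, str]]) -> list[OrthologGroup]:
    """All maximal cliques of size >= 2 in the link graph, via pivoting
    Bron-Kerbosch; members sorted, deterministic output order."""
    g = nx.Graph()
    for a, b in links:
        if a == b:
            raise ValueError(f"self-link rejected: {a}")
        g.add_edge(a, b)
    if g.number_of_nodes() > MAX_CLIQUE_NODES:
        raise ValueError(
            f"link graph has {g.number_of_nodes()} nodes, exceeding the "
            f"{MAX_CLIQUE_NODES}-node ceiling for clique listing"
        )
    groups = [
        OrthologGroup(members=tuple(sorted(c)))
        for c in nx.find_cliques(g)
        if len(c) >= 2
    ]
    groups.sort(key=lambda grp: grp.members)
    return groups


def write_groups(groups: list[OrthologGroup], handle) -> None:
    """Group table: group_id <TAB> comma-joined member intron ids."""
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("group_id\tmembers\n")
        for i, grp in enumerate(groups, start=1):
            handle.write(f"{i}\t{','.join(grp.members)}\n")
    finally:
        if close:
            handle.close()


def read_alignment_fasta(handle) -> PairwiseAlignment:
    """Read a two-record aligned FASTA into a PairwiseAlignment."""
    from Bio import SeqIO
    import io

    if isinstance(handle, str) and "\n" not in handle:
        records = list(SeqIO.parse(handle, "fasta"))
    else:
        records = list(SeqIO.parse(io.StringIO(str(handle)), "fasta"))
    if len(records) != 2:
        raise ValueError(
            f"expected exactly 2 aligned records, got {len(records)}"
        )
    a, b = records
    return PairwiseAlignment(
        id_a=a.id, id_b=b.id, row_a=str(a.seq).upper(), row_b=str(b.seq).upper()
    )
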