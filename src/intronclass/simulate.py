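"""Synthetic genomes, training sets and ortholog fixtures.

Generates FASTA + GFF3 genomes whose introns carry planted U2- or
U12-type splice-site and branch-point motifs sampled around configurable
consensus sequences, plus labeled training-sequence files and synthetic
ortholog alignment pairs. Every intron's coordinates, class, phase and
planted motif position are recorded in a truth table, so extraction,
scoring, classification and orthology can all be validated against known
ground truth without any genome download. All generators are
deterministic per seed.

The generators emulate motif composition and class imbalance only: codon
usage, GC content, splicing regulation and realistic exon structure are
deliberately not modeled.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import reverse_complement
from .orthology import IntronAnchor, PairwiseAlignment

BASES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: default class consensus 12-mers spanning -3..+9 (3 exonic + 9 intronic nt)
U2_CONSENSUS_5SS = "CAGGTAAGTTTT"
U12_CONSENSUS_5SS = "AAGGTATCCTTT"
#: branch-point 12-mer with the branch adenosine at positions 9-10
U12_CONSENSUS_BPS = "CTTTCCTTAACT"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic genome generator.

    `introns_per_gene` is either a fixed int or ("poisson", lam) /
    ("uniform", lo, hi); `intron_length` is ("lognormal", mu, sigma) on
    the log scale, clamped to [min_intron_length, max_intron_length].
    `motif_fidelity` is the per-position probability that a planted motif
    base equals its consensus (otherwise uniform over the other three).
    """

    seed: int = 42
    n_genes: int = 20
    introns_per_gene: int | tuple = 3
    u12_fraction: float = 0.01
    u2_consensus_5ss: str = U2_CONSENSUS_5SS
    u12_consensus_5ss: str = U12_CONSENSUS_5SS
    u12_consensus_bps: str = U12_CONSENSUS_BPS
    motif_fidelity: float = 0.95
    intron_length: tuple = ("lognormal", 4.8, 0.35)
    min_intron_length: int = 70
    max_intron_length: int = 2000
    exon_length_range: tuple[int, int] = (60, 150)
    genome_padding: int = 200
    assembly: str = "sim1"
    chrom: str = "chr1"

    def __post_init__(self):
        for name in ("u2_consensus_5ss", "u12_consensus_5ss", "u12_consensus_bps"):
            if len(getattr(self, name)) != 12:
                raise ValueError(f"{name} must be 12 nt")
        if not 0 <= self.u12_fraction <= 1:
            raise ValueError("u12_fraction must be in [0, 1]")
        if not 0 <= self.motif_fidelity <= 1:
            raise ValueError("motif_fidelity must be in [0, 1]")


@dataclass
class SimulatedGenome:
    fasta: str
    gff3: str
    truth: pd.DataFrame
    genome: dict[str, str]
    config: SimulationConfig

    def write(self, fasta_path: str, gff3_path: str, truth_path: str) -> None:
        with open(fasta_path, "w") as fh:
            fh.write(self.fasta)
        with open(gff3_path, "w") as fh:
            fh.write(self.gff3)
        self.truth.to_csv(truth_path, sep="\t", index=False)


def _sample_motif(rng, consensus: str, fidelity: float) -> str:
    out = []
    for base in consensus:
        if rng.random() < fidelity:
            out.append(base)
        else:
            out.append(rng.choice([b for b in BASES if b != base]))
    return "".join(out)


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n)) if n > 0 else ""


def _n_introns(rng, spec) -> int:
    if isinstance(spec, int):
        return spec
    kind = spec[0]
    if kind == "poisson":
        return int(rng.poisson(spec[1]))
    if kind == "uniform":
        return int(rng.integers(spec[1], spec[2] + 1))
    raise ValueError(f"unknown introns_per_gene spec {spec!r}")


def _intron_length(rng, cfg: SimulationConfig) -> int:
    kind, *params = cfg.intron_length
    if kind == "lognormal":
        mu, sigma = params
        L = int(round(np.exp(rng.normal(mu, sigma))))
    elif kind == "fixed":
        L = int(params[0])
    else:
        raise ValueError(f"unknown intron_length spec {cfg.intron_length!r}")
    return int(np.clip(L, cfg.min_intron_length, cfg.max_intron_length))


def _build_intron(
    rng, cfg: SimulationConfig, intron_class: str
) -> tuple[str, str, int | None]:
    """Transcript-orientation intron sequence with planted motifs.

    Returns (sequence, sampled 5'SS 12-mer, planted BPS start label or
    None). The first 3 nt of the sampled 5'SS belong to the upstream
    exon and are planted there by the caller.
    """
    L = _intron_length(rng, cfg)
    consensus = (
        cfg.u12_consensus_5ss if intron_class == "U12" else cfg.u2_consensus_5ss
    )
    five_ss = _sample_motif(rng, consensus, cfg.motif_fidelity)
    acceptor = "AC" if five_ss[3:5] == "AT" else "AG"
    seq = list(_random_seq(rng, L))
    seq[:9] = list(five_ss[3:])
    seq[-2:] = list(acceptor)
    bps_label = None
    if intron_class == "U12":
        # motif start label in [-45, -17] keeps the 12-mer inside -55..-5
        bps_label = int(rng.integers(-45, -16))
        motif = _sample_motif(rng, cfg.u12_consensus_bps, cfg.motif_fidelity)
        idx = L + bps_label  # label -k is 0-based index L-k
        seq[idx : idx + 12] = list(motif)
    return "".join(seq), five_ss, bps_label


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Build a single-chromosome multi-gene genome with planted introns.

    Exactly round(u12_fraction * total introns) introns are planted as
    U12-type (chosen uniformly), so the class tally is a generator
    condition rather than a random draw. Genes alternate strands; every
    gene is fully coding (exon and CDS entries coincide), with total CDS
    length a multiple of 3.
    """
    rng = np.random.default_rng(config.seed)
    gene_intron_counts = [
        _n_introns(rng, config.introns_per_gene) for _ in range(config.n_genes)
    ]
    total_introns = sum(gene_intron_counts)
    n_u12 = int(round(config.u12_fraction * total_introns))
    u12_slots = set(
        rng.choice(total_introns, size=n_u12, replace=False).tolist()
        if n_u12
        else []
    )

    chrom_parts: list[str] = []
    pos = 0  # 0-based length so far
    gff = ["##gff-version 3"]
    truth_rows = []
    slot = 0
    for g in range(config.n_genes):
        gene_id = f"gene{g + 1}"
        tx_id = f"tx{g + 1}"
        strand = "+" if g % 2 == 0 else "-"
        n_int = gene_intron_counts[g]
        n_exons = n_int + 1
        exon_lens = [
            int(rng.integers(*config.exon_length_range)) for _ in range(n_exons)
        ]
        total_cds = sum(exon_lens)
        exon_lens[-1] += (-total_cds) % 3  # full final codon

        classes = []
        for _ in range(n_int):
            classes.append("U12" if slot in u12_slots else "U2")
            slot += 1

        # transcript-orientation gene segment
        parts: list[str] = []
        intervals: list[tuple[int, int]] = []  # exon (start, stop), 1-based local
        intron_local: list[tuple[int, int, str, str, int | None]] = []
        cursor = 0
        cum_cds = 0
        for i, ex_len in enumerate(exon_lens):
            exon_seq = _random_seq(rng, ex_len)
            if i < n_int:
                intron_seq, five_ss, bps_label = _build_intron(
                    rng, config, classes[i]
                )
                exon_seq = exon_seq[:-3] + five_ss[:3]  # exonic -3..-1
                parts.append(exon_seq)
                intervals.append((cursor + 1, cursor + ex_len))
                cursor += ex_len
                cum_cds += ex_len
                intron_local.append(
                    (
                        cursor + 1,
                        cursor + len(intron_seq),
                        classes[i],
                        five_ss,
                        bps_label,
                    )
                )
                truth_rows.append(
                    {
                        "gene_id": gene_id,
                        "transcript_id": tx_id,
                        "rank": i + 1,
                        "intron_class": classes[i],
                        "phase": cum_cds % 3,
                        "length": len(intron_seq),
                        "bps_label": bps_label,
                        "five_ss": five_ss,
                    }
                )
                parts.append(intron_seq)
                cursor += len(intron_seq)
            else:
                parts.append(exon_seq)
                intervals.append((cursor + 1, cursor + ex_len))
                cursor += ex_len
        segment = "".join(parts)
        S = len(segment)

        pad = _random_seq(rng, config.genome_padding)
        chrom_parts.append(pad)
        pos += len(pad)
        offset = pos  # 0-based start of segment on the chromosome
        if strand == "+":
            chrom_parts.append(segment)
            to_genomic = lambda a, b: (offset + a, offset + b)
        else:
            chrom_parts.append(reverse_complement(segment))
            to_genomic = lambda a, b: (offset + S - b + 1, offset + S - a + 1)
        pos += S

        gene_lo, gene_hi = to_genomic(1, S)
        if gene_lo > gene_hi:
            gene_lo, gene_hi = gene_hi, gene_lo
        gff.append(
            f"{config.chrom}\tsim\tgene\t{gene_lo}\t{gene_hi}\t.\t{strand}\t."
            f"\tID={gene_id}"
        )
        gff.append(
            f"{config.chrom}\tsim\tmRNA\t{gene_lo}\t{gene_hi}\t.\t{strand}\t."
            f"\tID={tx_id};Parent={gene_id}"
        )
        for a, b in intervals:
            lo, hi = sorted(to_genomic(a, b))
            for kind in ("exon", "CDS"):
                gff.append(
                    f"{config.chrom}\tsim\t{kind}\t{lo}\t{hi}\t.\t{strand}\t."
                    f"\tParent={tx_id}"
                )
        # genomic coordinates for the truth rows of this gene
        base = len(truth_rows) - len(intron_local)
        for j, (a, b, _, _, _) in enumerate(intron_local):
            lo, hi = sorted(to_genomic(a, b))
            truth_rows[base + j].update(
                {
                    "chrom": config.chrom,
                    "start": lo,
                    "stop": hi,
                    "strand": strand,
                    "intron_id": (
                        f"{config.assembly}:{config.chrom}:{lo}-{hi}({strand})"
                    ),
                }
            )
    chrom_parts.append(_random_seq(rng, config.genome_padding))
    chrom_seq = "".join(chrom_parts)

    fasta = io.StringIO()
    fasta.write(f">{config.chrom}\n")
    for i in range(0, len(chrom_seq), 60):
        fasta.write(chrom_seq[i : i + 60] + "\n")

    truth = pd.DataFrame(truth_rows)[
        [
            "intron_id",
            "gene_id",
            "transcript_id",
            "chrom",
            "start",
            "stop",
            "strand",
            "rank",
            "intron_class",
            "phase",
            "length",
            "bps_label",
            "five_ss",
        ]
    ]
    return SimulatedGenome(
        fasta=fasta.getvalue(),
        gff3="\n".join(gff) + "\n",
        truth=truth,
        genome={config.chrom: chrom_seq},
        config=config,
    )


# ---------------------------------------------------------------------------
# training sets

BPS_REGION_LEN = 51


def simulate_training_set(
    n_u2: int,
    n_u12: int,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[str, str]:
    """Labeled training files, mirroring the real regime where U2
    sequences vastly outnumber U12 ones.

    Returns (u12_text, u2_text); each line is `five_ss<TAB>bps_region`
    with a 12-nt 5'SS window and a 51-nt branch-point region. U12 regions
    carry a planted branch-point 12-mer; U2 regions are pure background.
    """
    if n_u2 < 1 or n_u12 < 1:
        raise ValueError("both class counts must be >= 1")
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    u12_lines = []
    for _ in range(n_u12):
        five = _sample_motif(rng, cfg.u12_consensus_5ss, cfg.motif_fidelity)
        region = list(_random_seq(rng, BPS_REGION_LEN))
        start = int(rng.integers(0, BPS_REGION_LEN - 12 + 1))
        motif = _sample_motif(rng, cfg.u12_consensus_bps, cfg.motif_fidelity)
        region[start : start + 12] = list(motif)
        u12_lines.append(f"{five}\t{''.join(region)}")
    u2_lines = []
    for _ in range(n_u2):
        five = _sample_motif(rng, cfg.u2_consensus_5ss, cfg.motif_fidelity)
        u2_lines.append(f"{five}\t{_random_seq(rng, BPS_REGION_LEN)}")
    return "\n".join(u12_lines) + "\n", "\n".join(u2_lines) + "\n"


def read_training_file(source: str) -> list[tuple[str, str]]:
    """Parse a training file (path or literal text): one `five_ss TAB
    bps_region` pair per line."""
    if "\n" in source or "\t" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    pairs = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(
                f"training line {lineno}: expected 2 tab-separated fields"
            )
        pairs.append((fields[0].upper(), fields[1].upper()))
    return pairs


# ---------------------------------------------------------------------------
# ortholog fixtures


def simulate_ortholog_pair(
    conservation: float,
    planted_shared_introns: int,
    seed: int = 42,
    length: int = 200,
) -> tuple[PairwiseAlignment, list[IntronAnchor], list[IntronAnchor], list[tuple[str, str]]]:
    """A gapless protein alignment pair at the given identity with shared
    intron positions planted at matching residues and phases.

    Returns (alignment, anchors_a, anchors_b, truth_links).
    """
    if not 0 <= conservation <= 1:
        raise ValueError("conservation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    prot_a = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    prot_b = list(prot_a)
    for i in range(length):
        if rng.random() >= conservation:
            prot_b[i] = rng.choice([a for a in AMINO_ACIDS if a != prot_a[i]])
    aln = PairwiseAlignment("txA", "txB", prot_a, "".join(prot_b))
    positions = sorted(
        rng.choice(
            np.arange(1, length + 1),
            size=min(planted_shared_introns, length),
            replace=False,
        ).tolist()
    )
    anchors_a, anchors_b, links = [], [], []
    for k, residue in enumerate(positions, start=1):
        phase = int(rng.integers(0, 3))
        ida, idb = f"spA:i{k}", f"spB:i{k}"
        anchors_a.append(IntronAnchor(ida, "txA", residue, phase))
        anchors_b.append(IntronAnchor(idb, "txB", residue, phase))
        links.append((ida, idb))
    return aln, anchors_a, anchors_b, links
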