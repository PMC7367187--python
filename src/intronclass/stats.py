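"""Evolutionary statistics over classified introns.

Covers the downstream analyses run on class-annotated intron sets: phase
bias per class (chi-squared against a uniform null), nucleotide
composition at the -1 exonic position, terminal-dinucleotide tables,
deduplication of alternative splice variants via a coordinate graph, a
binomial test for non-random clustering of U12-type introns within genes,
length summaries with the cross-species genome-size correlation, and the
count of codon families whose wobble position can be G.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from Bio.Data import CodonTable

from .annotation import IntronRecord, terminal_category

TERMINAL_CATEGORIES = ("GT-AG", "GC-AG", "AT-AC", "other")


@dataclass
class PhaseTable:
    counts: pd.DataFrame  # class x phase {0,1,2}
    chi2: dict[str, float]
    p_value: dict[str, float]


@dataclass
class ClusteringTestResult:
    n_genes_with_u12: int
    x_u12_fraction: float
    m_mean_introns: float
    p_multi: float
    observed_multi: int
    point_mass: float
    p_value: float
    degenerate: bool = False


def _classes(records_or_rows):
    """Normalize input to (class_label, record) pairs."""
    for item in records_or_rows:
        if isinstance(item, tuple):
            yield item
        else:
            yield item[0], item[1]


def phase_bias_test(
    introns: list[tuple[str, IntronRecord]] | pd.DataFrame,
    expected: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> PhaseTable:
    """Chi-squared goodness-of-fit of per-class phase counts.

    Input: either (class_label, IntronRecord) pairs or a DataFrame with
    columns `call` and `phase`. The null is a uniform phase distribution
    by default (2 df); arbitrary expected fractions may be supplied.
    Classes with zero phase-defined introns are omitted.
    """
    if isinstance(introns, pd.DataFrame):
        rows = list(zip(introns["call"], introns["phase"]))
    else:
        rows = [(cls, rec.phase) for cls, rec in _classes(introns)]
    counts: dict[str, np.ndarray] = {}
    for cls, phase in rows:
        if phase is None or (isinstance(phase, float) and np.isnan(phase)):
            continue
        counts.setdefault(cls, np.zeros(3, dtype=int))[int(phase)] += 1
    table = pd.DataFrame(
        {cls: v for cls, v in counts.items()}, index=[0, 1, 2]
    ).T
    chi2: dict[str, float] = {}
    pval: dict[str, float] = {}
    exp = np.asarray(expected, dtype=float)
    exp = exp / exp.sum()
    for cls, obs in counts.items():
        n = obs.sum()
        if n == 0:
            continue
        res = sps.chisquare(obs, f_exp=exp * n)
        chi2[cls] = float(res.statistic)
        pval[cls] = float(res.pvalue)
    return PhaseTable(counts=table, chi2=chi2, p_value=pval)


def minus1_table(
    introns: list[tuple[str, IntronRecord]],
    grouping: str = "phase",
) -> pd.DataFrame:
    """Fractions of A/C/G/T immediately upstream of the 5' splice site.

    The -1 base is the last base of the upstream exonic flank (transcript
    orientation). Rows are (class, group) where group is the intron phase
    or its terminal-dinucleotide category; fractions exclude N and each
    row sums to 1. Empty groups are omitted.
    """
    if grouping not in ("phase", "terminal_dinucleotides"):
        raise ValueError("grouping must be 'phase' or 'terminal_dinucleotides'")
    tallies: dict[tuple, dict[str, int]] = {}
    for cls, rec in _classes(introns):
        if not rec.upstream_flank:
            continue
        base = rec.upstream_flank[-1].upper()
        if base not in "ACGT":
            continue
        if grouping == "phase":
            if rec.phase is None:
                continue
            group = rec.phase
        else:
            group = terminal_category(rec.terminal_dinucleotides)
        key = (cls, group)
        tallies.setdefault(key, {b: 0 for b in "ACGT"})[base] += 1
    rows = {}
    for key, tally in sorted(tallies.items(), key=lambda kv: str(kv[0])):
        total = sum(tally.values())
        rows[key] = {b: tally[b] / total for b in "ACGT"}
    return pd.DataFrame.from_dict(rows, orient="index")


def terminal_dinucleotide_table(
    introns: list[tuple[str, IntronRecord]]
) -> pd.DataFrame:
    """Percentages of GT-AG / GC-AG / AT-AC / other termini per class
    (rows sum to 100)."""
    tallies: dict[str, dict[str, int]] = {}
    for cls, rec in _classes(introns):
        cat = terminal_category(rec.terminal_dinucleotides)
        tallies.setdefault(cls, {c: 0 for c in TERMINAL_CATEGORIES})[cat] += 1
    rows = {}
    for cls, tally in sorted(tallies.items()):
        total = sum(tally.values())
        rows[cls] = {c: 100.0 * tally[c] / total for c in TERMINAL_CATEGORIES}
    return pd.DataFrame.from_dict(rows, orient="index")


def dedup_splice_variants(
    rows: list[tuple[str, str, int, int]]
) -> tuple[int, list[tuple[str, str, int, int]]]:
    """Collapse alternatively spliced variants of the same intron.

    Each row (assembly, chrom, start, stop) contributes two genomic
    position nodes joined by an edge; variants sharing a donor or
    acceptor coalesce into one connected component, which counts as a
    single unique intron. Returns the component count and one
    representative row per component (the lexicographically smallest
    (start, stop) among its rows).
    """
    g = nx.Graph()
    clean = []
    for assembly, chrom, start, stop in rows:
        row = (assembly, chrom, int(start), int(stop))
        clean.append(row)
        g.add_edge((assembly, chrom, row[2]), (assembly, chrom, row[3]))
    node_comp: dict[tuple, int] = {}
    for i, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            node_comp[node] = i
    best: dict[int, tuple] = {}
    for row in clean:
        cid = node_comp[(row[0], row[1], row[2])]
        if cid not in best or (row[2], row[3]) < (best[cid][2], best[cid][3]):
            best[cid] = row
    representatives = sorted(best.values())
    return len(representatives), representatives


def u12_clustering_test(
    genes: list[tuple[str, int, int]]
) -> ClusteringTestResult:
    """Binomial test for clustering of U12-type introns within genes.

    Under random placement, the number of U12-containing genes that hold
    multiple U12-type introns is Binomial(n, p) with n = genes with at
    least one U12 intron and p = 1 - (1 - x)^(m-1), where x is the
    genome-wide U12 fraction and m the mean introns per (intron-bearing)
    gene. Both the point mass P(X = k) and the upper tail P(X >= k) are
    reported for k = observed multi-U12 gene count; the tail is labeled
    as the p-value.
    """
    genes = [(g, int(n), int(k)) for g, n, k in genes]
    total_introns = sum(n for _, n, _ in genes if n > 0)
    total_u12 = sum(k for _, _, k in genes)
    if total_introns == 0:
        raise ValueError("no introns in gene table")
    x = total_u12 / total_introns
    with_introns = [n for _, n, _ in genes if n > 0]
    m = float(np.mean(with_introns))
    n_u12_genes = sum(1 for _, _, k in genes if k >= 1)
    if n_u12_genes == 0:
        raise ValueError("need at least one gene with a U12-type intron")
    observed_multi = sum(1 for _, _, k in genes if k >= 2)
    p_multi = 1.0 - (1.0 - x) ** (m - 1.0)
    degenerate = x == 0
    point = float(sps.binom.pmf(observed_multi, n_u12_genes, p_multi))
    tail = float(sps.binom.sf(observed_multi - 1, n_u12_genes, p_multi))
    return ClusteringTestResult(
        n_genes_with_u12=n_u12_genes,
        x_u12_fraction=x,
        m_mean_introns=m,
        p_multi=p_multi,
        observed_multi=observed_multi,
        point_mass=point,
        p_value=tail,
        degenerate=degenerate,
    )


def wobble_g_families() -> int:
    """Number of the 20 codon families (sense codons grouped by encoded
    amino acid, standard code) containing at least one codon ending in G.

    The -1 exonic base of a phase 0 intron is the wobble position of the
    preceding codon; families with a G-ending codon are free to carry a
    G there synonymously.
    """
    table = CodonTable.unambiguous_dna_by_id[1]
    families: dict[str, set[str]] = {}
    for codon, aa in table.forward_table.items():
        families.setdefault(aa, set()).add(codon)
    assert len(families) == 20
    return sum(
        1
        for codons in families.values()
        if any(c.endswith("G") for c in codons)
    )


def length_summary(
    species_records: list[tuple[str, float, list[tuple[str, IntronRecord]]]],
) -> pd.DataFrame:
    """Per-species, per-class mean intron lengths plus the cross-species
    Pearson correlation between mean length and genome size.

    Input: (species, genome_size_bp, [(class_label, IntronRecord), ...]).
    Returns a tidy frame with one row per (species, class) carrying the
    count, mean length, log10 mean length and genome size; the Pearson r
    per class is in `attrs['pearson_r']` (NaN when fewer than two species
    carry the class or the inputs have zero variance).
    """
    rows = []
    for species, genome_size, recs in species_records:
        by_class: dict[str, list[int]] = {}
        for cls, rec in _classes(recs):
            by_class.setdefault(cls, []).append(rec.length)
        for cls, lengths in sorted(by_class.items()):
            rows.append(
                {
                    "species": species,
                    "class": cls,
                    "count": len(lengths),
                    "mean_length": float(np.mean(lengths)),
                    "log10_mean_length": float(np.log10(np.mean(lengths))),
                    "genome_size": genome_size,
                }
            )
    df = pd.DataFrame(rows)
    pearson: dict[str, float] = {}
    if not df.empty:
        for cls, sub in df.groupby("class"):
            if len(sub) < 2:
                pearson[cls] = float("nan")
                continue
            if sub["mean_length"].std() == 0 or sub["genome_size"].std() == 0:
                pearson[cls] = float("nan")  # zero variance: undefined
                continue
            r, _ = sps.pearsonr(sub["mean_length"], sub["genome_size"])
            pearson[cls] = float(r)
    df.attrs["pearson_r"] = pearson
    return df
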