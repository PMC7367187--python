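"""End-to-end genome classification.

Glues the modules together the way the command-line tool runs them:
parse annotation (exon- and/or CDS-defined), keep the longest isoform
per gene, extract introns, two-pass PWM scoring with the empirical U2
BPS matrix, score the labeled training sequences in the same scoring
space, fit the calibrated linear SVM, and call every intron U2-type or
U12-type at the probability threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import annotation as ann
from .annotation import IntronRecord, extract_introns, longest_isoforms, parse_annotation
from .classifier import IntronClassifier, classify
from .pwm import PositionWeightMatrix, build_pwm
from .scoring import (
    MotifScore,
    PwmSet,
    build_u12_bps_pwm,
    score_genome,
    score_log_ratio,
    _scan,
)
from .simulate import read_training_file


def extract_all_introns(
    annotation_source: str,
    genome,
    feature: str = "both",
    assembly: str = "",
) -> list[IntronRecord]:
    """Introns from the longest isoform per gene.

    feature="cds" or "exon" runs a single pass; "both" runs both and
    merges them, CDS-defined records (which carry phase) winning at
    shared coordinates and exon-only (UTR / non-coding) introns retained
    with phase undefined.
    """
    def run(kind: str) -> list[IntronRecord]:
        transcripts = parse_annotation(annotation_source, kind)
        records: list[IntronRecord] = []
        for tx in longest_isoforms(transcripts):
            records.extend(extract_introns(tx, genome, assembly=assembly))
        return records

    if feature == "exon":
        return sorted(run("exon"), key=lambda r: r.coord_key)
    if feature == "cds":
        return sorted(run("CDS"), key=lambda r: r.coord_key)
    if feature == "both":
        return ann.merge_runs(run("CDS"), run("exon"))
    raise ValueError("feature must be 'exon', 'cds' or 'both'")


def _donor_subtype(five_ss: str, intron_class: str) -> str:
    donor = five_ss[3:5]
    if intron_class == "U12" and donor == "AT":
        return "AT-AC"
    if intron_class == "U2" and donor == "GC":
        return "GC-AG"
    return "GT-AG"


def build_pwm_set(
    u12_training: list[tuple[str, str]],
    u2_training: list[tuple[str, str]],
    pseudo_count: float = 0.001,
    min_subtype_count: int = 5,
) -> PwmSet:
    """PWMs from labeled training pairs (five_ss, bps_region).

    5'SS matrices (offset -3) are built per class; subtype-specific
    matrices (AT-AC for U12, GC-AG for U2) are added when at least
    `min_subtype_count` training sequences carry that donor. The U12 BPS
    matrix comes from the training branch-point regions, restricted to
    motifs with the branch adenosine at position 9 or 10.
    """
    pwm_set = PwmSet()
    for cls, pairs in (("U12", u12_training), ("U2", u2_training)):
        if not pairs:
            raise ValueError(f"empty {cls} training set")
        by_subtype: dict[str, list[str]] = {}
        for five, _ in pairs:
            by_subtype.setdefault(_donor_subtype(five, cls), []).append(five)
        main = max(by_subtype, key=lambda k: len(by_subtype[k]))
        pwm_set.add(
            build_pwm(
                by_subtype[main],
                offset=-3,
                pseudo_count=pseudo_count,
                name=f"{cls}-5SS-{main}",
                intron_class=cls,
                motif="5SS",
                subtype=main,
            )
        )
        if main != "GT-AG":  # guarantee the GT-AG fallback exists
            pwm_set.add(
                build_pwm(
                    [f for fs in by_subtype.values() for f in fs],
                    offset=-3,
                    pseudo_count=pseudo_count,
                    name=f"{cls}-5SS-GT-AG",
                    intron_class=cls,
                    motif="5SS",
                    subtype="GT-AG",
                )
            )
        for sub, seqs in by_subtype.items():
            if sub != main and len(seqs) >= min_subtype_count:
                pwm_set.add(
                    build_pwm(
                        seqs,
                        offset=-3,
                        pseudo_count=pseudo_count,
                        name=f"{cls}-5SS-{sub}",
                        intron_class=cls,
                        motif="5SS",
                        subtype=sub,
                    )
                )
    pwm_set.add(
        build_u12_bps_pwm(
            [region for _, region in u12_training],
            pseudo_count=pseudo_count,
            offset=1,
            name="U12-BPS",
        )
    )
    return pwm_set


def training_vectors(
    pairs: list[tuple[str, str]],
    intron_class: str,
    pwm_set: PwmSet,
    u2_bps: PositionWeightMatrix,
) -> np.ndarray:
    """(5'SS, BPS) log-ratio vectors of training pairs in the same
    scoring space as the genome introns (empirical U2 BPS included)."""
    rows = []
    for five, region in pairs:
        sub = _donor_subtype(five, intron_class)
        u12_5 = pwm_set.select("U12", "5SS", sub if intron_class == "U12" else "GT-AG")
        u2_5 = pwm_set.select("U2", "5SS", sub if intron_class == "U2" else "GT-AG")
        f = score_log_ratio(u12_5, u2_5, five)
        u12_bps = pwm_set.select("U12", "BPS", sub)
        hit = _scan(region, lambda k: score_log_ratio(u12_bps, u2_bps, k))
        if hit is None:
            continue
        rows.append([f, hit.log_ratio])
    return np.array(rows, dtype=float)


def bracket_terminus(
    intron: IntronRecord, motif: MotifScore | None = None, width: int = 40
) -> str:
    """Last `width` intron nt with the branch-point motif in brackets."""
    tail = intron.full_seq[-width:]
    if motif is None:
        return tail
    region_lo = max(0, intron.length + ann.BPS_REGION_START)
    mstart = region_lo + motif.position
    tail_lo = intron.length - len(tail)
    a, b = mstart - tail_lo, mstart - tail_lo + len(motif.motif_seq)
    if a < 0 or b > len(tail):
        return tail
    return f"{tail[:a]}[{tail[a:b]}]{tail[b:]}"


def classify_genome(
    introns: list[IntronRecord],
    u12_training,
    u2_training,
    C: float | None = None,
    threshold: float = 0.90,
    seed: int = 42,
    percentile: float = 95.0,
) -> tuple[pd.DataFrame, IntronClassifier, PwmSet, PositionWeightMatrix]:
    """Run the full classification pipeline over an intron set.

    Training inputs are paths, literal text, or parsed (five_ss,
    bps_region) lists. Returns the per-intron table (one row per input
    intron, including unclassifiable too-short ones), the fitted model,
    the PWM set and the empirical U2 BPS matrix.
    """
    if isinstance(u12_training, str):
        u12_training = read_training_file(u12_training)
    if isinstance(u2_training, str):
        u2_training = read_training_file(u2_training)
    pwm_set = build_pwm_set(u12_training, u2_training)
    vectors, u2_bps = score_genome(introns, pwm_set, percentile)
    X12 = training_vectors(u12_training, "U12", pwm_set, u2_bps)
    X2 = training_vectors(u2_training, "U2", pwm_set, u2_bps)
    X = np.vstack([X12, X2])
    y = np.array(["U12"] * len(X12) + ["U2"] * len(X2))
    model = IntronClassifier(C=C, threshold=threshold, random_state=seed).fit(X, y)
    results = classify(vectors, model)
    table = intron_table(introns, vectors, results)
    return table, model, pwm_set, u2_bps


def intron_table(introns, vectors, results) -> pd.DataFrame:
    """Tab-separable per-intron table with coordinates, windows, scores,
    the U12 probability (as a percentage) and the class call."""
    by_id_vec = {v.intron_id: v for v in vectors}
    by_id_res = {r.intron_id: r for r in results}
    rows = []
    for intron in introns:
        v = by_id_vec.get(intron.intron_id)
        r = by_id_res.get(intron.intron_id)
        motif = v.bps_motif if v is not None else None
        rows.append(
            {
                "intron_id": intron.intron_id,
                "five_ss_bits": None if v is None else v.five_ss,
                "bps_bits": None if v is None else v.bps,
                "bps_motif": None if motif is None else motif.motif_seq,
                "bps_position": None if motif is None else motif.position,
                "p_u12_pct": (
                    None if r is None or r.p_u12 is None else 100.0 * r.p_u12
                ),
                "call": "too_short" if r is None else r.call,
                "chrom": intron.chrom,
                "start": intron.start,
                "stop": intron.stop,
                "length": intron.length,
                "strand": intron.strand,
                "rank": intron.rank,
                "phase": intron.phase,
                "terminal_dinucleotides": "-".join(
                    intron.terminal_dinucleotides
                ),
                "upstream_flank": intron.upstream_flank,
                "terminus_3p": bracket_terminus(intron, motif),
                "downstream_flank": intron.downstream_flank,
                "full_seq": intron.full_seq,
                "gene_id": intron.gene_id,
                "transcript_id": intron.transcript_id,
            }
        )
    return pd.DataFrame(rows)
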