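"""Intron extraction from genome annotation.

Introns are obtained by interpolating between adjacent coding features
(exon or CDS entries of a GFF3 or GTF file) within the longest isoform of
each gene. Exon-defined runs capture introns in untranslated and
non-coding regions (phase undefined); CDS-defined runs carry reading-frame
phase. The two runs are merged with CDS-defined records taking precedence
at shared coordinates.

All genomic coordinates are 1-based inclusive, matching GFF3/GTF.
Sequence fields (full_seq, windows, flanks) are in transcript orientation:
minus-strand sequences are reverse-complemented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: introns shorter than this are extracted but flagged and excluded from
#: classification (prevents the 5'SS and BPS windows from overlapping)
MIN_CLASSIFIABLE_LENGTH = 30

FLANK_LENGTH = 50
FIVE_SS_EXONIC = 3   # exonic positions -3..-1
FIVE_SS_INTRONIC = 9  # intronic positions +1..+9
BPS_REGION_START = -55  # position label of the region's 5'-most base
BPS_REGION_STOP = -5    # position label of the region's 3'-most base


class AnnotationParseError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Transcript:
    """An isoform as an ordered run of same-kind features.

    `features` holds (kind, start, stop) tuples, 1-based inclusive, sorted
    by genomic start; all features share `chrom` and `strand` and are of a
    single kind ("exon" or "CDS") per parsing run.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    features: list[tuple[str, int, int]] = field(default_factory=list)

    def feature_length(self) -> int:
        return sum(stop - start + 1 for _, start, stop in self.features)


@dataclass
class IntronRecord:
    """One intron with coordinates, sequence windows and (later) class call.

    start/stop are genomic 1-based inclusive; rank is 1 for the 5'-most
    intron in transcript orientation; phase is None for exon-defined
    introns. seq_5ss spans positions -3..+9 (12 nt), seq_bps_region spans
    -55..-5 relative to the last intron base (truncated at the intron
    start for short introns).
    """

    intron_id: str
    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    stop: int
    strand: str
    length: int
    rank: int
    phase: int | None
    terminal_dinucleotides: tuple[str, str]
    seq_5ss: str
    seq_bps_region: str
    upstream_flank: str
    downstream_flank: str
    full_seq: str
    defined_by: str = "exon"
    too_short: bool = False

    @property
    def subtype(self) -> str:
        return terminal_category(self.terminal_dinucleotides)

    @property
    def coord_key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.stop, self.strand)


def terminal_category(dinucs: tuple[str, str]) -> str:
    """Bucket terminal dinucleotides into GT-AG / GC-AG / AT-AC / other."""
    pair = (dinucs[0].upper(), dinucs[1].upper())
    if pair == ("GT", "AG"):
        return "GT-AG"
    if pair == ("GC", "AG"):
        return "GC-AG"
    if pair == ("AT", "AC"):
        return "AT-AC"
    return "other"


# ---------------------------------------------------------------------------
# annotation parsing


def _precheck_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise AnnotationParseError(
                f"malformed annotation line {lineno}: expected 9 tab-separated "
                f"fields, got {len(line.split(chr(9)))}"
            )


def _transcript_ids_of(feature) -> list[str]:
    """Transcript attribution of an exon/CDS row (GFF3 Parent or GTF
    transcript_id); empty list when absent."""
    if "transcript_id" in feature.attributes:
        return list(feature.attributes["transcript_id"])
    if "Parent" in feature.attributes:
        return list(feature.attributes["Parent"])
    return []


def parse_annotation(
    annotation: str, feature_kind: str = "exon"
) -> list[Transcript]:
    """Parse a GFF3 or GTF file (path or literal text) into Transcripts.

    Each returned Transcript contains only features of `feature_kind`
    ("exon" or "CDS"), sorted by genomic start. Features lacking
    transcript attribution are skipped with a warning. Both attribute
    dialects (GFF3 ``Parent=``, GTF ``transcript_id ""``) are supported.
    """
    if feature_kind not in ("exon", "CDS"):
        raise ValueError("feature_kind must be 'exon' or 'CDS'")
    if "\n" in annotation or "\t" in annotation:
        text = annotation
    else:
        with open(annotation) as fh:
            text = fh.read()
    _precheck_lines(text)
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise AnnotationParseError(f"could not parse annotation: {exc}") from exc

    # transcript -> gene map from transcript-level features
    tx_gene: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype in ("exon", "CDS"):
            continue
        ids = feat.attributes.get("transcript_id") or (
            feat.attributes.get("ID") if feat.featuretype != "gene" else None
        )
        if not ids:
            continue
        gene = feat.attributes.get("gene_id") or feat.attributes.get("Parent")
        if gene:
            for tid in ids:
                tx_gene.setdefault(tid, gene[0])

    transcripts: dict[str, Transcript] = {}
    for feat in db.features_of_type(feature_kind):
        tids = _transcript_ids_of(feat)
        if not tids:
            logger.warning(
                "%s feature %s:%d-%d has no transcript attribution; skipped",
                feature_kind, feat.seqid, feat.start, feat.end,
            )
            continue
        gene_attr = feat.attributes.get("gene_id")
        for tid in tids:
            tx = transcripts.get(tid)
            if tx is None:
                gene = tx_gene.get(tid) or (gene_attr[0] if gene_attr else tid)
                tx = Transcript(
                    transcript_id=tid,
                    gene_id=gene,
                    chrom=feat.seqid,
                    strand=feat.strand,
                    features=[],
                )
                transcripts[tid] = tx
            tx.features.append((feature_kind, feat.start, feat.end))

    out = []
    for tx in transcripts.values():
        tx.features.sort(key=lambda f: (f[1], f[2]))
        out.append(tx)
    out.sort(key=lambda t: t.transcript_id)
    return out


def select_longest_isoform(transcripts: list[Transcript]) -> Transcript:
    """The transcript maximizing summed feature length; ties go to the
    lexicographically smallest transcript_id."""
    if not transcripts:
        raise ValueError("empty transcript list")
    return min(
        transcripts, key=lambda t: (-t.feature_length(), t.transcript_id)
    )


def longest_isoforms(transcripts: list[Transcript]) -> list[Transcript]:
    """One longest isoform per gene."""
    by_gene: dict[str, list[Transcript]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    return [select_longest_isoform(v) for _, v in sorted(by_gene.items())]


# ---------------------------------------------------------------------------
# sequence access


def fetch_sequence(genome, chrom: str, start: int, stop: int) -> str:
    """1-based inclusive slice of a chromosome, N-padded beyond its ends.

    `genome` may be a mapping of chrom -> sequence string or a
    pyfaidx.Fasta object.
    """
    seq_obj = genome[chrom]
    chrom_seq = seq_obj if isinstance(seq_obj, str) else None
    if chrom_seq is not None:
        n = len(chrom_seq)
    else:
        n = len(seq_obj)
    left_pad = max(0, 1 - start)
    right_pad = max(0, stop - n)
    lo = max(1, start)
    hi = min(n, stop)
    if hi < lo:
        core = ""
    elif chrom_seq is not None:
        core = chrom_seq[lo - 1 : hi]
    else:
        core = str(seq_obj[lo - 1 : hi])
    return ("N" * left_pad) + core.upper() + ("N" * right_pad)


# ---------------------------------------------------------------------------
# intron extraction


def compute_phase(transcript: Transcript, intron_index: int) -> int | None:
    """Reading-frame phase of the intron after the given junction.

    `intron_index` is 0-based in transcript orientation (intron_index 0
    lies after the first CDS feature). Phase = (summed CDS length 5' of
    the intron) mod 3; exon-defined transcripts return None.
    """
    kinds = {k for k, _, _ in transcript.features}
    if kinds != {"CDS"}:
        return None
    feats = sorted(transcript.features, key=lambda f: f[1])
    if transcript.strand == "-":
        feats = feats[::-1]
    if not 0 <= intron_index < len(feats) - 1:
        raise IndexError(f"intron_index {intron_index} out of range")
    upstream = sum(
        stop - start + 1 for _, start, stop in feats[: intron_index + 1]
    )
    return upstream % 3


def extract_introns(
    transcript: Transcript, genome, assembly: str = ""
) -> list[IntronRecord]:
    """Introns between adjacent features, with all sequence windows filled.

    Adjacent abutting features yield no intron; overlapping features raise.
    Windows overrunning a chromosome end are N-padded; the BPS region is
    truncated at the intron 5' end for short introns. Introns shorter than
    MIN_CLASSIFIABLE_LENGTH are flagged `too_short`.
    """
    feats = sorted(transcript.features, key=lambda f: (f[1], f[2]))
    for (_, _, prev_stop), (_, nxt_start, _) in zip(feats, feats[1:]):
        if nxt_start <= prev_stop:
            raise ValueError(
                f"overlapping features in transcript {transcript.transcript_id}"
            )
    gaps = []
    for (_, _, prev_stop), (_, nxt_start, _) in zip(feats, feats[1:]):
        if nxt_start - prev_stop > 1:
            gaps.append((prev_stop + 1, nxt_start - 1))

    minus = transcript.strand == "-"
    n = len(gaps)
    records = []
    for i, (start, stop) in enumerate(gaps):
        rank = (n - i) if minus else (i + 1)
        length = stop - start + 1
        raw = fetch_sequence(genome, transcript.chrom, start, stop)
        full_seq = reverse_complement(raw) if minus else raw
        if minus:
            up_raw = fetch_sequence(
                genome, transcript.chrom, stop + 1, stop + FLANK_LENGTH
            )
            upstream = reverse_complement(up_raw)
            down_raw = fetch_sequence(
                genome, transcript.chrom, start - FLANK_LENGTH, start - 1
            )
            downstream = reverse_complement(down_raw)
        else:
            upstream = fetch_sequence(
                genome, transcript.chrom, start - FLANK_LENGTH, start - 1
            )
            downstream = fetch_sequence(
                genome, transcript.chrom, stop + 1, stop + FLANK_LENGTH
            )
        seq_5ss = upstream[-FIVE_SS_EXONIC:] + full_seq[:FIVE_SS_INTRONIC].ljust(
            FIVE_SS_INTRONIC, "N"
        )
        # positions -55..-5: indices length-55 .. length-5 (0-based), truncated
        bps_lo = max(0, length + BPS_REGION_START)
        bps_hi = length + BPS_REGION_STOP + 1
        seq_bps_region = full_seq[bps_lo:bps_hi] if bps_hi > 0 else ""
        kind = feats[0][0]
        # intron_index in transcript orientation matches rank - 1
        phase = (
            compute_phase(transcript, rank - 1) if kind == "CDS" else None
        )
        records.append(
            IntronRecord(
                intron_id=(
                    f"{assembly}:{transcript.chrom}:{start}-{stop}"
                    f"({transcript.strand})"
                ),
                gene_id=transcript.gene_id,
                transcript_id=transcript.transcript_id,
                chrom=transcript.chrom,
                start=start,
                stop=stop,
                strand=transcript.strand,
                length=length,
                rank=rank,
                phase=phase,
                terminal_dinucleotides=(full_seq[:2], full_seq[-2:]),
                seq_5ss=seq_5ss,
                seq_bps_region=seq_bps_region,
                upstream_flank=upstream,
                downstream_flank=downstream,
                full_seq=full_seq,
                defined_by=kind,
                too_short=length < MIN_CLASSIFIABLE_LENGTH,
            )
        )
    records.sort(key=lambda r: r.rank)
    return records


def merge_runs(
    cds_introns: list[IntronRecord], exon_introns: list[IntronRecord]
) -> list[IntronRecord]:
    """Union of the two runs keyed by (chrom, start, stop, strand);
    CDS-defined records win on collision (they carry phase), exon-only
    introns are retained with phase undefined."""
    merged: dict[tuple, IntronRecord] = {}
    for rec in exon_introns:
        merged[rec.coord_key] = rec
    for rec in cds_introns:
        merged[rec.coord_key] = rec
    return sorted(
        merged.values(), key=lambda r: (r.chrom, r.start, r.stop, r.strand)
    )


# ---------------------------------------------------------------------------
# abbreviated sequence display

ELLIPSIS = "…"


def format_abbreviated(intron: IntronRecord, best_bps) -> str:
    """Render the compact one-line view of an intron:
    6 nt upstream exon | first 10 intron nt ... best BPS 12-mer ... last
    5 intron nt | 6 nt downstream exon (transcript orientation).

    `best_bps` is a MotifScore whose position is the 0-based offset of the
    motif within the intron's BPS search region. Introns too short for
    distinct segments fall back to the full sequence between bars.
    """
    up6 = intron.upstream_flank[-6:]
    down6 = intron.downstream_flank[:6]
    L = intron.length
    region_lo = max(0, L + BPS_REGION_START)
    motif_start = region_lo + best_bps.position
    motif = best_bps.motif_seq
    if motif_start < 10 or motif_start + len(motif) > L - 5:
        return f"{up6}|{intron.full_seq}|{down6}"
    return (
        f"{up6}|{intron.full_seq[:10]}{ELLIPSIS}{motif}{ELLIPSIS}"
        f"{intron.full_seq[-5:]}|{down6}"
    )


def parse_abbreviated(text: str) -> dict:
    """Recover segments and terminal dinucleotides from the abbreviated
    display form (as printed in intron tables)."""
    up, middle, down = text.split("|")
    parts = middle.split(ELLIPSIS)
    if len(parts) == 3:
        first10, bps, last5 = parts
    else:
        first10, bps, last5 = middle, "", middle
    dinucs = (first10[:2], last5[-2:])
    return {
        "upstream_exon": up,
        "first10": first10,
        "bps": bps,
        "last5": last5,
        "downstream_exon": down,
        "terminal_dinucleotides": dinucs,
        "category": terminal_category(dinucs),
    }
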