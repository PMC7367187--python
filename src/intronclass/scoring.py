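"""Log-ratio scoring of 5' splice sites and branch points.

Every intron receives a two-dimensional score vector: the U12/U2 log2
ratio of its 12-nt 5'SS window (-3..+9) and of its best branch-point
12-mer, searched within -55..-5 of the last intron base. U2-type introns
have no extended branch-point consensus, so the U2 BPS matrix is derived
empirically from the input introns themselves: the best U12-scored BPS
12-mers of all introns whose 5'SS score lies below the 95th percentile
(introns unlikely to be U12-type) are pooled into a species-specific U2
BPS matrix. Scoring is therefore two-pass: 5'SS scores first, then the
empirical matrix, then BPS log ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import IntronRecord
from .pwm import PositionWeightMatrix, build_pwm, score_log_ratio

BPS_WIDTH = 12
#: 1-based positions within the 12-mer where the branch adenosine may sit
BRANCH_A_POSITIONS = (9, 10)
#: minimum input size for a stable 95th-percentile estimate
MIN_INTRONS_FOR_EMPIRICAL = 20


@dataclass
class MotifScore:
    """A scored motif occurrence: log2(U12/U2) in bits, the motif sequence,
    and the 0-based offset of its start within the searched window."""

    log_ratio: float
    motif_seq: str
    position: int


@dataclass
class ScoreVector:
    """The (5'SS, BPS) log-ratio pair fed to the classifier."""

    intron_id: str
    five_ss: float | None
    bps: float | None
    bps_motif: MotifScore | None = None
    too_short: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.five_ss, self.bps], dtype=float)


class PwmSet:
    """Lookup of PWMs keyed by (intron_class, motif, subtype).

    Subtype dispatch: AT-AC introns use AT-AC U12 matrices where present;
    GC-AG introns use the GC-AG U2 5'SS matrix where present; everything
    else (including non-canonical termini) falls back to GT-AG matrices.
    """

    def __init__(self, pwms: list[PositionWeightMatrix] | None = None):
        self._by_key: dict[tuple[str, str, str], PositionWeightMatrix] = {}
        for pwm in pwms or []:
            self.add(pwm)

    def add(self, pwm: PositionWeightMatrix) -> None:
        self._by_key[(pwm.intron_class, pwm.motif, pwm.subtype)] = pwm

    def select(
        self, intron_class: str, motif: str, subtype: str
    ) -> PositionWeightMatrix:
        pwm = self._by_key.get((intron_class, motif, subtype))
        if pwm is None:
            pwm = self._by_key.get((intron_class, motif, "GT-AG"))
        if pwm is None:
            raise KeyError(
                f"no {intron_class} {motif} matrix for subtype {subtype} "
                "and no GT-AG fallback"
            )
        return pwm

    def matrices(self) -> list[PositionWeightMatrix]:
        return list(self._by_key.values())


def score_five_prime(intron: IntronRecord, pwm_set: PwmSet) -> float | None:
    """U12/U2 log ratio of the intron's 12-nt 5'SS window, or None for
    introns flagged too short to classify."""
    if intron.too_short or len(intron.seq_5ss) != 12:
        return None
    sub = intron.subtype
    u12 = pwm_set.select("U12", "5SS", sub)
    u2 = pwm_set.select("U2", "5SS", sub)
    return score_log_ratio(u12, u2, intron.seq_5ss)


def _scan(region: str, score_fn) -> MotifScore | None:
    """Exhaustive 12-mer scan; ties broken toward the 3'-most position."""
    if len(region) < BPS_WIDTH:
        return None
    best: MotifScore | None = None
    for pos in range(len(region) - BPS_WIDTH + 1):
        kmer = region[pos : pos + BPS_WIDTH]
        s = score_fn(kmer)
        if best is None or s >= best.log_ratio:
            best = MotifScore(log_ratio=s, motif_seq=kmer, position=pos)
    return best


def best_bps(
    intron: IntronRecord,
    u12_bps: PositionWeightMatrix,
    u2_bps: PositionWeightMatrix,
) -> MotifScore | None:
    """The 12-mer of the BPS region with the highest U12/U2 log ratio.

    Returns None (`too_short`) when the region holds no complete 12-mer.
    """
    return _scan(
        intron.seq_bps_region,
        lambda kmer: score_log_ratio(u12_bps, u2_bps, kmer),
    )


def best_u12_motif(
    region: str, u12_bps: PositionWeightMatrix
) -> MotifScore | None:
    """The 12-mer maximizing the U12 BPS log probability alone (used when
    no U2 matrix exists yet, i.e. while deriving the empirical U2 BPS)."""
    return _scan(region, u12_bps.log_probability)


def has_branch_adenosine(kmer: str) -> bool:
    return any(kmer[p - 1] == "A" for p in BRANCH_A_POSITIONS)


def build_u12_bps_pwm(
    regions: list[str],
    pseudo_count: float = 0.001,
    offset: int = 1,
    name: str = "U12-BPS",
    subtype: str = "GT-AG",
) -> PositionWeightMatrix:
    """U12 BPS matrix from training branch-point regions.

    Regions of exactly 12 nt are taken as the motif directly; longer
    regions are scanned. Candidate motifs must carry an A at position 9
    or 10 of the 12-mer (the branch adenosine); violators are excluded
    from matrix building (but scanning at scoring time is unrestricted).
    For regions needing a scan, a provisional matrix pooled from every
    branch-A 12-mer picks each region's best candidate, and the final
    matrix is rebuilt from those winners.
    """
    direct = [r for r in regions if len(r) == BPS_WIDTH]
    to_scan = [r for r in regions if len(r) > BPS_WIDTH]
    motifs = [m for m in direct if has_branch_adenosine(m)]
    if to_scan:
        pool = [
            r[i : i + BPS_WIDTH]
            for r in to_scan
            for i in range(len(r) - BPS_WIDTH + 1)
            if has_branch_adenosine(r[i : i + BPS_WIDTH])
        ]
        if pool:
            provisional = build_pwm(pool, offset=offset, pseudo_count=pseudo_count)
            for r in to_scan:
                best = None
                for i in range(len(r) - BPS_WIDTH + 1):
                    kmer = r[i : i + BPS_WIDTH]
                    if not has_branch_adenosine(kmer):
                        continue
                    s = provisional.log_probability(kmer)
                    if best is None or s >= best[0]:
                        best = (s, kmer)
                if best is not None:
                    motifs.append(best[1])
    if not motifs:
        raise ValueError(
            "no branch-point candidates with an A at position 9 or 10"
        )
    return build_pwm(
        motifs,
        offset=offset,
        pseudo_count=pseudo_count,
        name=name,
        intron_class="U12",
        motif="BPS",
        subtype=subtype,
    )


def derive_empirical_u2_bps(
    introns: list[IntronRecord],
    five_ss_scores: list[float | None],
    pwm_set: PwmSet,
    percentile: float = 95.0,
) -> PositionWeightMatrix:
    """Species-specific U2 BPS matrix from the input introns themselves.

    Takes every intron whose 5'SS score is strictly below the given
    percentile of all 5'SS scores (i.e. introns unlikely to be U12-type),
    finds each one's best U12-scored BPS 12-mer, and builds a BPS matrix
    from those motifs. This makes BPS scoring conservative: the U2 matrix
    is defined by the most U12-like branch points in the empirical data.
    """
    scored = [
        (intron, s)
        for intron, s in zip(introns, five_ss_scores)
        if s is not None
    ]
    if len(scored) < MIN_INTRONS_FOR_EMPIRICAL:
        raise ValueError(
            f"need at least {MIN_INTRONS_FOR_EMPIRICAL} scored introns to "
            f"derive the empirical U2 BPS matrix, got {len(scored)}"
        )
    values = np.array([s for _, s in scored])
    cutoff = float(np.percentile(values, percentile))  # linear interpolation
    below = [intron for intron, s in scored if s < cutoff]
    if not below:
        raise ValueError(
            "no introns below the 5'SS score percentile cutoff "
            "(degenerate, homogeneous score distribution)"
        )
    motifs = []
    template = None
    for intron in below:
        u12_bps = pwm_set.select("U12", "BPS", intron.subtype)
        template = template or u12_bps
        hit = best_u12_motif(intron.seq_bps_region, u12_bps)
        if hit is not None:
            motifs.append(hit.motif_seq)
    if not motifs:
        raise ValueError("no BPS regions long enough to hold a 12-mer")
    return build_pwm(
        motifs,
        offset=template.offset,
        pseudo_count=template.pseudo_count,
        name="empirical-U2-BPS",
        intron_class="U2",
        motif="BPS",
        subtype="GT-AG",
    )


def score_genome(
    introns: list[IntronRecord],
    pwm_set: PwmSet,
    percentile: float = 95.0,
) -> tuple[list[ScoreVector], PositionWeightMatrix | None]:
    """Two-pass scoring of a whole intron set.

    Pass 1 scores all 5'SS windows; the empirical U2 BPS matrix is then
    derived from the sub-95th-percentile introns; pass 2 computes the BPS
    log ratio of every intron against it. Introns too short to score are
    returned with None scores and `too_short` set — never dropped.

    Returns the score vectors (one per input intron, input order) and the
    empirical U2 BPS matrix (None when the input set is empty).
    """
    if not introns:
        return [], None
    five = [score_five_prime(intron, pwm_set) for intron in introns]
    u2_bps = derive_empirical_u2_bps(introns, five, pwm_set, percentile)
    out = []
    for intron, f in zip(introns, five):
        if f is None:
            out.append(
                ScoreVector(intron.intron_id, None, None, too_short=True)
            )
            continue
        u12_bps = pwm_set.select("U12", "BPS", intron.subtype)
        hit = best_bps(intron, u12_bps, u2_bps)
        if hit is None:
            out.append(
                ScoreVector(intron.intron_id, f, None, too_short=True)
            )
        else:
            out.append(
                ScoreVector(intron.intron_id, f, hit.log_ratio, bps_motif=hit)
            )
    return out, u2_bps
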