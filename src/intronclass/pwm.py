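"""Position weight matrices for splice-site motifs.

A PWM here is a per-position base-frequency model over {A, C, G, T}. Motifs
are scored as log2 probability ratios between a U12-type and a U2-type
matrix; a small pseudo-count frequency is added to every cell at scoring
time so that zero-frequency bases incur a large but finite penalty.

Position labels follow splice-site convention and skip zero: +1 is the
first intron base, -1 the last. A 5'SS matrix spans -3..+9 (12 columns,
three exonic positions followed by nine intronic ones); BPS matrices span
12 columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: default pseudo-count frequency added to every matrix cell when scoring
DEFAULT_PSEUDO_COUNT = 0.001


def position_labels(offset: int, n: int) -> list[int]:
    """Position labels starting at `offset`, skipping zero.

    >>> position_labels(-3, 5)
    [-3, -2, -1, 1, 2]
    """
    labels = []
    p = offset
    for _ in range(n):
        if p == 0:
            p = 1
        labels.append(p)
        p += 1
    return labels


@dataclass
class PositionWeightMatrix:
    """Per-position base frequencies with a coordinate offset.

    Parameters
    ----------
    name : str
        Identifier used in PWM files.
    intron_class : {"U2", "U12"}
    motif : {"5SS", "BPS"}
    subtype : {"GT-AG", "GC-AG", "AT-AC"}
        Terminal-dinucleotide subtype the matrix models.
    offset : int
        Signed position label of the first column (zero is skipped).
    freqs : ndarray of shape (n_columns, 4)
        Base frequencies per column, ordered A, C, G, T. Each row sums to 1
        (before pseudo-count addition).
    pseudo_count : float
        Frequency added to every cell at scoring time.
    """

    name: str
    intron_class: str
    motif: str
    subtype: str
    offset: int
    freqs: np.ndarray
    pseudo_count: float = DEFAULT_PSEUDO_COUNT

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValueError("freqs must have shape (n_columns, 4)")
        sums = self.freqs.sum(axis=1)
        if not np.allclose(sums[sums > 0], 1.0, atol=1e-9):
            raise ValueError("non-empty PWM columns must sum to 1")

    def __len__(self) -> int:
        return self.freqs.shape[0]

    @property
    def labels(self) -> list[int]:
        return position_labels(self.offset, len(self))

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))

    def log_probability(self, seq: str) -> float:
        """Sum over positions of log2(freq + pseudo_count); N contributes 0."""
        if len(seq) != len(self):
            raise ValueError(
                f"sequence length {len(seq)} != PWM width {len(self)}"
            )
        total = 0.0
        pc = self.pseudo_count
        for i, base in enumerate(seq.upper()):
            idx = _BASE_INDEX.get(base)
            if idx is None:  # N or other ambiguity code
                continue
            total += np.log2(self.freqs[i, idx] + pc)
        return float(total)


def build_pwm(
    sequences: list[str],
    offset: int = 1,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
    *,
    name: str = "pwm",
    intron_class: str = "U2",
    motif: str = "5SS",
    subtype: str = "GT-AG",
) -> PositionWeightMatrix:
    """Build a PWM from equal-length sequences.

    Column frequencies are base counts divided by the column total; N (and
    any non-ACGT character) is excluded from both counts and totals. The
    pseudo-count is recorded on the matrix and applied at scoring time,
    not folded into the frequencies.
    """
    if not sequences:
        raise ValueError("cannot build a PWM from an empty sequence list")
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise ValueError("all sequences must have equal length")
    counts = np.zeros((width, 4), dtype=float)
    for s in sequences:
        for i, base in enumerate(s.upper()):
            idx = _BASE_INDEX.get(base)
            if idx is not None:
                counts[i, idx] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freqs = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    return PositionWeightMatrix(
        name=name,
        intron_class=intron_class,
        motif=motif,
        subtype=subtype,
        offset=offset,
        freqs=freqs,
        pseudo_count=pseudo_count,
    )


def score_log_ratio(
    u12: PositionWeightMatrix, u2: PositionWeightMatrix, seq: str
) -> float:
    """log2 of the U12/U2 probability ratio of `seq`, in bits.

    Positive values mean the sequence looks U12-like, negative U2-like.
    An N at position i contributes exactly zero (the pseudo-counts cancel).
    """
    if len(u12) != len(u2):
        raise ValueError("U12 and U2 matrices must have equal width")
    if len(seq) != len(u12):
        raise ValueError(
            f"sequence length {len(seq)} != PWM width {len(u12)}"
        )
    total = 0.0
    for i, base in enumerate(seq.upper()):
        idx = _BASE_INDEX.get(base)
        if idx is None:
            continue
        total += np.log2(
            (u12.freqs[i, idx] + u12.pseudo_count)
            / (u2.freqs[i, idx] + u2.pseudo_count)
        )
    return float(total)


# ---------------------------------------------------------------------------
# plain-text PWM files: one block per matrix, header
#   >name  class  motif  subtype  offset  [pseudo_count]
# followed by one tab-separated line of A C G T frequencies per column.


def write_pwms(pwms: list[PositionWeightMatrix], handle) -> None:
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        for pwm in pwms:
            handle.write(
                f">{pwm.name}\t{pwm.intron_class}\t{pwm.motif}\t"
                f"{pwm.subtype}\t{pwm.offset}\t{pwm.pseudo_count!r}\n"
            )
            for row in pwm.freqs:
                handle.write("\t".join(repr(float(v)) for v in row) + "\n")
    finally:
        if close:
            handle.close()


def read_pwms(handle) -> list[PositionWeightMatrix]:
    if isinstance(handle, str):
        with open(handle) as fh:
            return read_pwms(fh)
    if isinstance(handle, io.StringIO):
        handle.seek(0)
    pwms: list[PositionWeightMatrix] = []
    header = None
    rows: list[list[float]] = []

    def flush():
        if header is None:
            return
        name, cls, motif, subtype, offset = header[:5]
        pc = float(header[5]) if len(header) > 5 else DEFAULT_PSEUDO_COUNT
        pwms.append(
            PositionWeightMatrix(
                name=name,
                intron_class=cls,
                motif=motif,
                subtype=subtype,
                offset=int(offset),
                freqs=np.array(rows),
                pseudo_count=pc,
            )
        )

    for line in handle:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].split("\t")
            rows = []
        else:
            rows.append([float(v) for v in line.split("\t")])
    flush()
    return pwms
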