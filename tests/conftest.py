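import numpy as np
import pytest

from intronclass.annotation import IntronRecord
from intronclass.pipeline import build_pwm_set
from intronclass.simulate import (
    SimulationConfig,
    simulate_genome,
    simulate_training_set,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(
        seed=11, n_genes=30, introns_per_gene=3, u12_fraction=0.1
    )


@pytest.fixture(scope="session")
def sim_genome(sim_config):
    return simulate_genome(sim_config)


@pytest.fixture(scope="session")
def training_pairs():
    """Parsed (five_ss, bps_region) training pairs, imbalanced U2 >> U12."""
    from intronclass.simulate import read_training_file

    u12_text, u2_text = simulate_training_set(400, 40, seed=7)
    return read_training_file(u12_text), read_training_file(u2_text)


@pytest.fixture(scope="session")
def pwm_set(training_pairs):
    u12, u2 = training_pairs
    return build_pwm_set(u12, u2)


def make_intron(
    full_seq,
    upstream="A" * 50,
    downstream="T" * 50,
    chrom="chr1",
    start=1001,
    strand="+",
    rank=1,
    phase=0,
    gene_id="g1",
    transcript_id="t1",
    defined_by="CDS",
):
    """Construct an IntronRecord directly from its sequence (windows are
    derived the same way extraction derives them)."""
    L = len(full_seq)
    stop = start + L - 1
    seq_5ss = upstream[-3:] + full_seq[:9].ljust(9, "N")
    bps_lo = max(0, L - 55)
    bps_hi = L - 4
    return IntronRecord(
        intron_id=f"test:{chrom}:{start}-{stop}({strand})",
        gene_id=gene_id,
        transcript_id=transcript_id,
        chrom=chrom,
        start=start,
        stop=stop,
        strand=strand,
        length=L,
        rank=rank,
        phase=phase,
        terminal_dinucleotides=(full_seq[:2], full_seq[-2:]),
        seq_5ss=seq_5ss,
        seq_bps_region=full_seq[bps_lo:bps_hi] if bps_hi > 0 else "",
        upstream_flank=upstream,
        downstream_flank=downstream,
        full_seq=full_seq,
        defined_by=defined_by,
        too_short=L < 30,
    )


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
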