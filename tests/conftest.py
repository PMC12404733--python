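import numpy as np
import pandas as pd
import pytest

from wobbleseq.reference import IsodecoderRecord, ReferenceSet
from wobbleseq.simulate import demo_reference


def _random_seq(rng, length, anticodon, anticodon_start=33):
    seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, length - 3)) + "CCA")
    seq[anticodon_start : anticodon_start + 3] = list(anticodon)
    return "".join(seq)


@pytest.fixture
def small_refset():
    """Six isodecoders: two same-family Ala-AGC sharing a long 3' suffix
    (tie material), one diverged Ala-AGC, one non-ANN Gly-GCC, one Val-AAC,
    and one mitochondrial record."""
    rng = np.random.default_rng(11)
    ala1 = _random_seq(rng, 76, "AGC")
    # differs from ala1 only at position 5: reads shorter than 71 nt tie
    ala2 = ala1[:5] + ("A" if ala1[5] != "A" else "C") + ala1[6:]
    records = {}
    for iso_id, seq, aa, ac, genome in [
        ("Ala-AGC-1", ala1, "Ala", "AGC", "nuclear"),
        ("Ala-AGC-2", ala2, "Ala", "AGC", "nuclear"),
        ("Ala-AGC-3", _random_seq(rng, 76, "AGC"), "Ala", "AGC", "nuclear"),
        ("Gly-GCC-1", _random_seq(rng, 76, "GCC"), "Gly", "GCC", "nuclear"),
        ("Val-AAC-1", _random_seq(rng, 76, "AAC"), "Val", "AAC", "nuclear"),
        ("MT-Met-CAT-1", _random_seq(rng, 72, "CAT"), "Met", "CAT", "mitochondrial"),
    ]:
        records[iso_id] = IsodecoderRecord(
            id=iso_id,
            sequence=seq,
            amino_acid=aa,
            anticodon=ac,
            anticodon_start=33,
            genome=genome,
            mod_sites=((8, "m1G9"), (57, "m1A58")),
        )
    return ReferenceSet(records=records)


@pytest.fixture(scope="session")
def demo_refset():
    return demo_reference(seed=1)
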