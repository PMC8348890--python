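import numpy as np
import pytest

from anis.freqdb import SequenceRecord, count_pentapeptides
from anis.profile import FrequencyProfile

# residues drawn without X/B/Z so windows are always canonical
from anis.freqdb import ALPHABET


def random_records(rng, n_records, min_len=20, max_len=80, prefix="R"):
    letters = np.array(list(ALPHABET))
    out = []
    for i in range(n_records):
        n = int(rng.integers(min_len, max_len + 1))
        out.append(
            SequenceRecord(id=f"{prefix}{i}", residues="".join(rng.choice(letters, n)))
        )
    return out


def random_profile(rng, n=None, lo=30, hi=80, fmax=100):
    """Random integer-valued frequency profile on a dummy record."""
    if n is None:
        n = int(rng.integers(lo, hi + 1))
    values = rng.integers(1, fmax, size=n - 4).astype(float)
    rec = SequenceRecord(id=f"rand{n}_{int(rng.integers(1 << 30))}", residues="A" * n)
    return FrequencyProfile(record=rec, values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    return count_pentapeptides(random_records(rng, 20, 20, 60))


@pytest.fixture
def fasta_file(tmp_path):
    def write(records, name="test.fasta"):
        path = tmp_path / name
        with open(path, "wt") as fh:
            for rec in records:
                fh.write(f">{rec.id}\n{rec.residues}\n")
        return path

    return write
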