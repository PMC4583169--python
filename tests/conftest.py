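import math

import pytest

from flexlogo import default_scale
from flexlogo.seq_io import SequenceSet


@pytest.fixture(scope="session")
def scale():
    return default_scale()


def brute_base_ic(sequences):
    """Independent brute-force base IC: plain counting, no numpy."""
    L = len(sequences[0])
    out = []
    for i in range(L):
        col = [s[i] for s in sequences if s[i] in "ACGT"]
        if not col:
            out.append(None)
            continue
        h = 0.0
        for b in "ACGT":
            c = col.count(b)
            if c:
                p = c / len(col)
                h -= p * math.log2(p)
        out.append(math.log2(4) - h)
    return out


def brute_linkage_ic(sequences, scale):
    """Independent brute-force linkage IC over the 9 TRX states."""
    L = len(sequences[0])
    out = []
    for j in range(L - 1):
        states = []
        for s in sequences:
            dimer = s[j : j + 2]
            if set(dimer) <= set("ACGT"):
                states.append(scale.score_of[scale.class_of[dimer]])
        if not states:
            out.append(None)
            continue
        h = 0.0
        for v in set(states):
            p = states.count(v) / len(states)
            h -= p * math.log2(p)
        out.append(math.log2(9) - h)
    return out


@pytest.fixture
def tiny_set():
    return SequenceSet(sequences=("ACGT", "ACGA", "ANAT"))
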