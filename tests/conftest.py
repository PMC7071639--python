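import random
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from tracekit.chromatogram import SimulationSpec, synthesize_chromatogram


def random_seq(n: int, seed: int) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def simulate(alleles, fractions=None, noise_sd=10.0, seed=0, name="sim"):
    if isinstance(alleles, str):
        alleles = (alleles,)
    if fractions is None:
        fractions = (1.0,) if len(alleles) == 1 else (0.5, 0.5)
    return synthesize_chromatogram(SimulationSpec(
        tuple(alleles), tuple(fractions), noise_sd=noise_sd, seed=seed,
        name=name))


def het_reads(template: str, read_len: int, pos: int, kind: str, arg):
    """Equal-length allele reads from a template carrying one het edit."""
    a1 = template[:read_len]
    if kind == "del":
        edited = template[:pos] + template[pos + int(arg):]
    elif kind == "ins":
        edited = template[:pos] + str(arg) + template[pos:]
    elif kind == "snv":
        edited = template[:pos] + str(arg) + template[pos + 1:]
    else:
        raise ValueError(kind)
    return a1, edited[:read_len]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
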