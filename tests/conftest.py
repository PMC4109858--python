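"""Shared fixtures: small hand-built alignment blocks and cached simulations.

Simulations are module-scoped where several tests share one run; everything
is seeded so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from selindel.alignio import AlignmentBlock

BASES = "ACGT"


def make_block(ref: str, qry: str, **kw) -> AlignmentBlock:
    defaults = dict(
        ref_chrom="chr1", ref_start=0, ref_strand="+",
        qry_chrom="chr1", qry_start=0, qry_strand="+",
        ref_src_size=0, qry_src_size=0, block_id="test",
    )
    defaults.update(kw)
    return AlignmentBlock(ref_text=ref, qry_text=qry, **defaults)


def random_block(rng: np.random.Generator, width: int, gap_rate: float = 0.1,
                 sub_rate: float = 0.1) -> AlignmentBlock:
    """Random pairwise block with gap runs in either row (never both)."""
    ref = []
    qry = []
    i = 0
    while i < width:
        r = rng.random()
        if r < gap_rate and i > 0:
            run = int(rng.integers(1, 4))
            which = rng.random() < 0.5
            for _ in range(min(run, width - i)):
                b = BASES[rng.integers(4)]
                if which:
                    ref.append("-")
                    qry.append(b)
                else:
                    ref.append(b)
                    qry.append("-")
                i += 1
        else:
            b = BASES[rng.integers(4)]
            ref.append(b)
            if rng.random() < sub_rate:
                qry.append(BASES[rng.integers(4)])
            else:
                qry.append(b)
            i += 1
    # avoid all-gap rows
    if all(c == "-" for c in ref) or all(c == "-" for c in qry):
        return random_block(rng, width, gap_rate, sub_rate)
    return make_block("".join(ref), "".join(qry))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140724)


@pytest.fixture(scope="session")
def neutral_sim():
    """Fully neutral 4 Mb simulation (no constrained elements)."""
    from selindel.simulate import SimConfig, simulate

    cfg = SimConfig(length=4_000_000, d_total=0.3, alpha_true=0.0, seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def constrained_sim():
    """Default-condition 4 Mb simulation with 5% constrained sequence."""
    from selindel.simulate import SimConfig, simulate

    cfg = SimConfig(length=4_000_000, d_total=0.3, alpha_true=0.05, seed=17)
    return simulate(cfg)
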