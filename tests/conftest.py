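import numpy as np
import pytest

from ednaqpcr.published import PUBLISHED_ASSAYS


@pytest.fixture(scope="session")
def assays():
    return PUBLISHED_ASSAYS


@pytest.fixture(scope="session")
def humpback(assays):
    return assays["humpback_whale"]


def synthetic_template(assay, pad=30, seed=7):
    """Synthetic template embedding an assay's printed footprints.

    The interior between the published oligo footprints is not public, so
    filler between them is deterministic synthetic background; only the
    oligo footprints and their published coordinates are authentic.
    Returns (template, f_coord, p_coord, r_coord) with 1-based
    coordinates on the returned string.
    """
    from ednaqpcr.oligos import reverse_complement

    rng = np.random.default_rng(seed)
    bases = "ACGT"

    def bg(n):
        return "".join(bases[i] for i in rng.integers(0, 4, n))

    f, p, r = assay.forward, assay.probe, assay.reverse
    f0, p0, r0 = f.coordinate, p.coordinate, r.coordinate
    gap1 = p0 - (f0 + len(f))          # between F end and P start
    gap2 = (r0 - len(r) + 1) - (p0 + len(p))  # between P end and R footprint start
    amplicon = f.sequence + bg(gap1) + p.sequence + bg(gap2) + reverse_complement(r.sequence)
    assert len(amplicon) == r0 - f0 + 1
    template = bg(pad) + amplicon + bg(pad)
    return template, pad + 1, pad + 1 + (p0 - f0), pad + 1 + (r0 - f0)
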