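import numpy as np
import pytest

from cbekit.coords import TargetSite
from cbekit.simulate import EditorProfile


@pytest.fixture
def plus_site():
    """A plus-strand site with a hand-built amplicon.

    Protospacer occupies amplicon indices 35..54, PAM (AGG) 55..57; the
    quantification window spans indices 25..67.  Cytosines sit at
    protospacer positions 4, 6, 8 with upstream contexts AC, TC, GC.
    """
    rng = np.random.default_rng(1234)
    proto = list("GTAACTCAGTAAGTTAGTAT")
    proto[3], proto[5], proto[7] = "C", "C", "C"
    proto[2], proto[4], proto[6] = "A", "T", "G"
    flank5 = "".join(rng.choice(list("ACGT"), 35))
    flank3 = "".join(rng.choice(list("ACGT"), 35))
    amplicon = flank5 + "".join(proto) + "AGG" + flank3[:32]
    return TargetSite("plus_site", amplicon, 35, "+")


@pytest.fixture
def flat_profile():
    """Editor with uniform 0.5 activity at positions 1..10, no context bias."""
    return EditorProfile("flat", {cp: 0.5 for cp in range(1, 11)})
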