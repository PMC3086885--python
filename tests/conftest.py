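import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module


@pytest.fixture
def rng():
    return np.random.default_rng(20110503)


@pytest.fixture
def random_dna(rng):
    def make(length: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=length))

    return make


@pytest.fixture
def typical_locus():
    """A speciated palindromic MITE hairpin locus with a planted precise
    miR/miR* read population (plus strand only)."""
    from temir.profiling import reads_from_table
    from temir.synthetic import (
        SrnaProfileSpec,
        generate_te_family,
        simulate_srna_reads,
        speciate_hairpin_copy,
    )

    fam = generate_te_family("MITE", 200, 80, 2, 0.05, 42, family_id="MITE_fix")
    locus = speciate_hairpin_copy(fam, (10, 31), seed=43)
    spec = SrnaProfileSpec(strand_category="plus_only", excision="precise",
                           mir_window=(10, 31))
    table = simulate_srna_reads(locus, spec, depth=800, n_datasets=2, seed=44)
    return {"family": fam, "locus": locus, "mir_window": (10, 31),
            "table": table, "reads": reads_from_table(table)}
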