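import numpy as np
import pytest

from evotol import calibrate_reference
from evotol.variants import VariantCall


@pytest.fixture
def reference_params():
    """Reference-background dose-response: OD ratio 2.0 at 1%, no growth above 1.45%."""
    return calibrate_reference(2.0, 1.45)


def random_call_set(rng: np.random.Generator, n: int) -> list[VariantCall]:
    """Random SNV-ish calls spanning all filter-rule regimes."""
    bases = np.array(list("ACGTNR"))
    calls = []
    for _ in range(n):
        ref = str(rng.choice(bases[:4]))
        alt = str(rng.choice(bases))
        if alt == ref:
            alt = "N"
        calls.append(
            VariantCall(
                chrom=f"chr{int(rng.integers(1, 4))}",
                pos=int(rng.integers(1, 5000)),
                ref=ref,
                alt=alt,
                qual=float(rng.integers(0, 60)),
                depth=int(rng.integers(0, 500)),
            )
        )
    return calls
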