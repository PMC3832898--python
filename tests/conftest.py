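import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from transchar.synthetic import SsrPlanEntry, SynthConfig, generate_transcripts

# one repeat per region type, motifs spanning all three period classes
MIXED_PLAN = (
    ("AC", 6, "UTR5"),
    ("AG", 7, "UTR3"),
    ("AT", 5, "ORF"),
    ("AAG", 6, "ORF"),
    ("AC", 5, "NONCODING"),
    ("CA", 6, "STRADDLE5"),
    ("CT", 5, "STRADDLE3"),
    ("TAT", 5, "STRADDLE3"),
    ("GGA", 5, "STRADDLE5"),
    ("AAAT", 5, "UTR3"),
    ("ATC", 5, "ORF"),
    ("AGG", 8, "ORF"),
)


def random_dna(rng: np.random.Generator, length: int, n_prob: float = 0.0) -> str:
    alphabet = "ACGTN" if n_prob else "ACGT"
    p = (
        [(1 - n_prob) / 4] * 4 + [n_prob]
        if n_prob
        else [0.25] * 4
    )
    return "".join(np.array(list(alphabet))[rng.choice(len(alphabet), size=length, p=p)])


@pytest.fixture(scope="session")
def mixed_cohort():
    """Small synthetic cohort exercising every SSR region type."""
    cfg = SynthConfig(
        n_transcripts=60,
        seed=11,
        ssr_plan=tuple(SsrPlanEntry(*e) for e in MIXED_PLAN),
        reverse_strand_prob=0.3,
    )
    transcripts, truth = generate_transcripts(cfg)
    return cfg, transcripts, truth
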