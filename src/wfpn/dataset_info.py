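"""Provenance constants of the multi-center pressure-injury image corpus.

The default preprocessing constants of this package were derived from a
corpus pooled from three hospital cohorts plus the public PIID set.
After excluding unstageable, suspected deep-tissue and mucosal injuries
the included per-source counts were:
"""

from __future__ import annotations

from typing import Dict

# images included per source after clinical screening
SOURCE_INCLUDED_COUNTS: Dict[str, int] = {
    "whu_renmin": 291,
    "union_tongji": 72,
    "zhongshan_xiamen": 65,
    "piid_public": 1091,
}

#: total images in the pooled corpus
TOTAL_INCLUDED: int = 1519

#: per-stage image counts of the pooled corpus (stages 1-4)
STAGE_COUNTS = (385, 523, 318, 293)

#: per-channel RGB mean of the corpus, used as the default normalisation
CORPUS_MEAN = (0.537, 0.424, 0.393)
#: per-channel RGB std of the corpus
CORPUS_STD = (0.523, 0.416, 0.376)


def total_included() -> int:
    """Sum of the per-source included counts."""
    return sum(SOURCE_INCLUDED_COUNTS.values())
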