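"""Integer genotype codes shared across the package.

A RIL genotype at any locus is one of the two parental homozygotes (IM/IM or
PR/PR), residual heterozygous (IM/PR), or missing. Codes are chosen so that
``IM`` and ``PR`` map to +1/−1 under :func:`signed` for linkage and QTL
regression arithmetic.
"""

from __future__ import annotations

import numpy as np

IM: int = 0  # IM/IM homozygote (IM767 parent allele)
PR: int = 1  # PR/PR homozygote (Point Reyes parent allele)
HET: int = 2  # IM/PR residual heterozygote
MISSING: int = -1

GENO_LABELS = {IM: "IM", PR: "PR", HET: "HET", MISSING: "NA"}
LABEL_CODES = {v: k for k, v in GENO_LABELS.items()}


def signed(calls: np.ndarray) -> np.ndarray:
    """Map genotype codes to +1 (IM), −1 (PR) and 0 (HET or missing)."""
    out = np.zeros(np.shape(calls), dtype=np.float64)
    out[np.asarray(calls) == IM] = 1.0
    out[np.asarray(calls) == PR] = -1.0
    return out
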